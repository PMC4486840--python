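import numpy as np
import pandas as pd
import pytest

from qtlbridge.containers import GeneSet, GenotypeMatrix, TraitTable


@pytest.fixture
def tiny_panel() -> GenotypeMatrix:
    """Ten lines × four markers on two chromosomes, no missing calls."""
    markers = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "cM": [5.0, 10.0, 15.0, 5.0],
            "Mb": [10.0, 20.0, 30.0, 10.0],
        },
        index=pd.Index(["m1", "m2", "m3", "m4"], name="locus"),
    )
    rng = np.random.default_rng(42)
    calls = pd.DataFrame(
        rng.choice([-1.0, 1.0], size=(4, 10)),
        index=markers.index,
        columns=[f"L{i}" for i in range(10)],
    )
    return GenotypeMatrix(markers, calls)


@pytest.fixture
def small_gene_set() -> GeneSet:
    """Three mouse genes on chr1, coordinates in bp."""
    return GeneSet(
        pd.DataFrame(
            {
                "gene_id": ["Mg1", "Mg2", "Mg3"],
                "symbol": ["Mg1", "Mg2", "Mg3"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [10_000_000, 25_000_000, 60_000_000],
                "end": [10_050_000, 25_050_000, 60_050_000],
                "strand": ["+", "+", "-"],
            }
        )
    )


def make_trait(values: dict[str, float], trait_id: str = "t") -> TraitTable:
    return TraitTable(trait_id, pd.Series(values))
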