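import numpy as np
import pandas as pd
import pytest

from methscape.models import GeneModel, TrueMethylome


@pytest.fixture
def tiny_genome() -> dict[str, str]:
    """Hand-written 60 bp scaffold with known CpG positions.

    scaffold_A: CGs at 2, 10 and 24; isolated non-CpG cytosines elsewhere.
    """
    seq = "AACGTTTACACGTTAAGGATCCTACGTAGTTACATTGGATCCATGAACCTTAGGATTACA"
    return {"scaffold_A": seq}


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("g1", "chr1", 5000, 8000, "+", [(5000, 6000), (7000, 8000)]),
        GeneModel("g2", "chr1", 12000, 15000, "-", [(12000, 13000), (14000, 15000)]),
    ]


def make_sites(rows: list[tuple[str, int, int, int]]) -> pd.DataFrame:
    """Strand-combined CpG table from (scaffold, position, n, m) tuples."""
    df = pd.DataFrame(rows, columns=["scaffold", "position", "n", "m"])
    with np.errstate(invalid="ignore"):
        df["ratio"] = np.where(df["n"] > 0, df["m"] / df["n"].clip(lower=1), np.nan)
    return df


def truth_sites(methylome: TrueMethylome, coverage: int = 10) -> pd.DataFrame:
    """Perfect-coverage CpG table straight from the simulator truth."""
    rows = [
        (s, p, coverage, int(round(coverage * lvl)))
        for (s, p), lvl in methylome.items()
    ]
    return make_sites(rows)
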