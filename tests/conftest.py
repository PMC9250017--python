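import numpy as np
import pandas as pd
import pytest

from clockvar.inference import bootstrap_auc_compare
from clockvar.io import CellTable
from clockvar.synthetic import SynthConfig, generate_cells
from clockvar.variability import slice_statistics


def make_table(
    n_slices: int = 2,
    cells_per_slice: int = 10,
    her1=None,
    her7=None,
    volume: float = 500.0,
    genotype: str = "wt",
    seed: int = 0,
) -> CellTable:
    """Small deterministic cell table for unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_slices):
        for c in range(cells_per_slice):
            h1 = her1 if her1 is not None else int(rng.poisson(20))
            h7 = her7 if her7 is not None else int(rng.poisson(20))
            rows.append(("e1", genotype, "right", s, f"c{c}", h1, h7, volume))
    df = pd.DataFrame(rows, columns=[
        "embryo_id", "genotype", "half", "slice_index", "cell_id",
        "her1_count", "her7_count", "volume",
    ])
    return CellTable(df)


@pytest.fixture(scope="session")
def wt_synth():
    """Default-condition synthetic wild-type table + ground truth."""
    return generate_cells(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def null_comparisons():
    """200 genotype comparisons of independent same-parameter datasets.

    Shared by the calibration checks of the paired t-test and of the
    percentile-bootstrap p-value.
    """
    p_t, p_boot = [], []
    for i in range(200):
        cfg_a = SynthConfig(n_embryos=1, n_slices=30, cells_per_slice=10,
                            seed=10_000 + 2 * i)
        cfg_b = SynthConfig(n_embryos=1, n_slices=30, cells_per_slice=10,
                            seed=10_001 + 2 * i)
        table_a, _ = generate_cells(cfg_a)
        table_b, _ = generate_cells(cfg_b)
        pts_a = slice_statistics(table_a).points
        pts_b = slice_statistics(table_b).points
        comp = bootstrap_auc_compare(pts_a, pts_b, component="total", seed=i)
        p_t.append(comp.p_value)
        p_boot.append(comp.p_value_bootstrap)
    return {"p_t": np.array(p_t), "p_boot": np.array(p_boot)}
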