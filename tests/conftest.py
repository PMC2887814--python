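import numpy as np
import pandas as pd
import pytest

from ecrestrict.data_model import ExpressionMatrix, SampleSheet


def make_sheet(rows):
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "lineage", "subgroup",
                       "replicate"]))


@pytest.fixture
def small_sheet():
    """Two target cell types in two subgroups, two background types,
    duplicates each."""
    rows = []
    for ct, sub in (("ECA", "alpha"), ("ECB", "beta")):
        for r in (1, 2):
            rows.append((f"{ct}_r{r}", ct, "target", sub, r))
    for ct in ("FIB", "LYM"):
        for r in (1, 2):
            rows.append((f"{ct}_r{r}", ct, "background", "", r))
    return make_sheet(rows)


@pytest.fixture
def small_matrix(small_sheet):
    """8 samples x 6 genes; genes 0-1 strongly target-enriched."""
    rng = np.random.default_rng(7)
    base = np.array([50.0, 120.0, 80.0, 200.0, 30.0, 65.0])
    values = base[:, None] * np.exp(0.05 * rng.standard_normal((6, 8)))
    is_target = np.array([s.startswith("EC") for s in small_sheet.sample_ids])
    values[0, is_target] *= 40.0
    values[1, is_target] *= 12.0
    genes = [f"g{i}" for i in range(6)]
    return ExpressionMatrix(tuple(genes), small_sheet.sample_ids, values)


@pytest.fixture
def reference_sheet():
    """One target cell among ten reference cells."""
    rows = [("REF_EC", "reference_EC", "target", "", 1)]
    rows += [(f"REF_C{i}", f"cell_{i}", "background", "", 1) for i in range(9)]
    return make_sheet(rows)


@pytest.fixture
def reference_matrix(reference_sheet):
    """Same 6 genes; genes 0-1 high only in the target reference cell."""
    rng = np.random.default_rng(11)
    base = np.array([40.0, 90.0, 70.0, 150.0, 25.0, 55.0])
    values = base[:, None] * np.exp(0.05 * rng.standard_normal((6, 10)))
    values[0, 0] *= 30.0
    values[1, 0] *= 8.0
    genes = [f"g{i}" for i in range(6)]
    return ExpressionMatrix(tuple(genes), reference_sheet.sample_ids, values)
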