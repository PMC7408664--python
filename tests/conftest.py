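import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ctcsig as cs
from ctcsig.array_io import EXPERIMENTAL, NEGATIVE_CONTROL, SPOT_COLUMNS

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


def make_spot_table(
    signals,
    neg_controls=(),
    above_bg=None,
    nonuniform=None,
    replicate=None,
    sample_id="S1",
    group="patient",
    gene_symbols=None,
):
    """Hand-built SpotTable: experimental spots followed by negative controls."""
    n = len(signals)
    above_bg = [True] * n if above_bg is None else list(above_bg)
    nonuniform = [False] * n if nonuniform is None else list(nonuniform)
    replicate = [False] * n if replicate is None else list(replicate)
    genes = (
        [f"G{i + 1}" for i in range(n)] if gene_symbols is None else list(gene_symbols)
    )
    rows = []
    for i, s in enumerate(signals):
        rows.append(
            (f"PR{i + 1:03d}", genes[i], float(s), float(s) - 1.0, 1.0,
             nonuniform[i], replicate[i], above_bg[i], EXPERIMENTAL)
        )
    for j, s in enumerate(neg_controls):
        rows.append(
            (f"NC{j + 1:03d}", np.nan, float(s), float(s) - 1.0, 1.0,
             False, False, False, NEGATIVE_CONTROL)
        )
    return cs.SpotTable(
        sample_id=sample_id,
        group=group,
        data=pd.DataFrame(rows, columns=SPOT_COLUMNS),
    )


def make_expression_matrix(detected: pd.DataFrame, groups: pd.Series, values=None):
    """ExpressionMatrix from a boolean detection frame (values default to 0)."""
    if values is None:
        values = pd.DataFrame(
            np.zeros(detected.shape), index=detected.index, columns=detected.columns
        )
    return cs.ExpressionMatrix(values=values, detected=detected, groups=groups)


@pytest.fixture
def array_cohort():
    """Small spiked cohort with clean margins (no outliers) plus ground truth."""
    cfg = cs.ArraySimConfig(
        n_genes=300, n_ctc_genes=12, n_negative_controls=40, outlier_rate=0.0, seed=11
    )
    tables, truth = cs.simulate_array_cohort(cfg)
    return cfg, tables, truth


@pytest.fixture
def qpcr_cohort():
    cfg = cs.QpcrSimConfig(seed=5)
    return cfg, cs.simulate_qpcr_cohort(cfg)
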