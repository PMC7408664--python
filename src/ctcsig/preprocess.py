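"""Spot QC filtering, detection calls, quantile normalization, probe collapse.

Three spot-level quality criteria are applied per array, in order:

(a) non-uniform pixel outliers and population replicate outliers (upstream
    feature-extraction flags);
(b) spots not distinguishable from their own background (the upstream
    above-background flag — the background is estimated per spot by the
    scanner software, so it is consumed, not recomputed);
(c) spots in the range of the negative controls, operationalized as
    processed signal <= mean + k*SD of the array's negative-control
    processed signals (k = 3 by convention; k = 0 switches the criterion
    off).

A probe is "detected" on an array iff it passes (a), (b) and (c). The
intensity matrix is log2-transformed and quantile-normalized across all
arrays over the full experimental probe set — every spot has a measured
signal, and dropping any probe that fails QC on any single array would
discard precisely the probes whose patient-restricted detection the
downstream signature rule looks for. Detection stays a parallel boolean
layer (normalize first, filter later, the limma convention). Probes are
collapsed to genes by the median, with a gene called detected when any of
its probes is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import EXPERIMENTAL, NEGATIVE_CONTROL, ExpressionMatrix, SpotTable
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: floor (linear scale) applied before log2 so zero signals stay finite
LOG2_FLOOR = 2.0 ** -10


@dataclass(frozen=True)
class FilterPolicy:
    """Which QC criteria to apply and how.

    ``negcontrol_k`` scales the negative-control threshold
    (mean + k*SD of negative-control processed signals); 0 disables
    criterion (c) — with k > 0, an array without negative controls is a
    configuration error. ``use_processed_signal`` selects the processed
    signal (lower replicate CV) over the background-subtracted one.
    """

    drop_nonuniform_outliers: bool = True
    drop_replicate_outliers: bool = True
    require_above_background: bool = True
    negcontrol_k: float = 3.0
    use_processed_signal: bool = True

    def __post_init__(self) -> None:
        if self.negcontrol_k < 0:
            raise ConfigError(f"negcontrol_k={self.negcontrol_k} must be >= 0")

    @property
    def signal_column(self) -> str:
        return "processed_signal" if self.use_processed_signal else "bg_sub_signal"


@dataclass
class FilterReport:
    """Per-array QC bookkeeping.

    ``filtered_spots`` counts experimental spots removed by the criteria
    (each spot attributed once, to the first failing criterion in order
    a, b, c); control spots are removed from downstream analysis regardless
    and tracked separately.
    """

    sample_id: str
    total_spots: int
    filtered_spots: int
    criterion_a: int
    criterion_b: int
    criterion_c: int
    control_spots: int
    negcontrol_threshold: float

    @property
    def filtered_fraction(self) -> float:
        return self.filtered_spots / self.total_spots if self.total_spots else 0.0

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_spots": self.total_spots,
            "filtered_spots": self.filtered_spots,
            "filtered_fraction": self.filtered_fraction,
            "criterion_a": self.criterion_a,
            "criterion_b": self.criterion_b,
            "criterion_c": self.criterion_c,
            "control_spots": self.control_spots,
            "negcontrol_threshold": self.negcontrol_threshold,
        }


def negcontrol_threshold(t: SpotTable, p: FilterPolicy) -> float:
    """mean + k*SD of the array's negative-control signals (-inf when k=0)."""
    if p.negcontrol_k == 0:
        return -np.inf
    neg = t.data.loc[t.data["control_type"] == NEGATIVE_CONTROL, p.signal_column]
    if neg.empty:
        raise ConfigError(
            f"{t.sample_id}: criterion (c) needs negative-control spots "
            "(negcontrol_k > 0 but none present)"
        )
    sd = float(neg.std(ddof=1)) if len(neg) > 1 else 0.0
    return float(neg.mean()) + p.negcontrol_k * sd


def _criterion_masks(t: SpotTable, p: FilterPolicy):
    """Boolean failure masks (a, b, c) over all spots; controls are False."""
    d = t.data
    exp = d["control_type"] == EXPERIMENTAL
    a = pd.Series(False, index=d.index)
    if p.drop_nonuniform_outliers:
        a |= d["flag_nonuniform_outlier"]
    if p.drop_replicate_outliers:
        a |= d["flag_replicate_outlier"]
    b = ~d["flag_above_background"] if p.require_above_background else pd.Series(False, index=d.index)
    thr = negcontrol_threshold(t, p)
    c = d[p.signal_column] <= thr if np.isfinite(thr) else pd.Series(False, index=d.index)
    return (a & exp, b & exp, c & exp, exp, thr)


def qc_filter_spots(t: SpotTable, p: FilterPolicy) -> tuple[SpotTable, FilterReport]:
    """Apply criteria (a)-(c); return the surviving experimental spots.

    A spot failing several criteria is counted once, under the first failing
    criterion in order a, b, c. Controls never propagate downstream. Row
    order is preserved.
    """
    a, b, c, exp, thr = _criterion_masks(t, p)
    first_a = a
    first_b = b & ~a
    first_c = c & ~a & ~b
    fail = a | b | c
    keep = exp & ~fail
    report = FilterReport(
        sample_id=t.sample_id,
        total_spots=len(t.data),
        filtered_spots=int((fail & exp).sum()),
        criterion_a=int(first_a.sum()),
        criterion_b=int(first_b.sum()),
        criterion_c=int(first_c.sum()),
        control_spots=int((~exp).sum()),
        negcontrol_threshold=thr,
    )
    logger.info(
        "%s: %d/%d experimental spots filtered (a=%d b=%d c=%d), threshold=%.4g",
        t.sample_id, report.filtered_spots, report.total_spots,
        report.criterion_a, report.criterion_b, report.criterion_c, thr,
    )
    out = SpotTable(
        sample_id=t.sample_id, group=t.group, data=t.data[keep].reset_index(drop=True)
    )
    return out, report


def detection_call(t: SpotTable, p: FilterPolicy) -> pd.Series:
    """Per-probe detection call for one array.

    A probe is detected iff its spot is above background, exceeds the
    negative-control threshold and carries no outlier flag. Deterministic
    given the table and policy; indexed by probe_id over experimental spots
    in row order.
    """
    a, b, c, exp, _ = _criterion_masks(t, p)
    det = exp & ~a & ~b & ~c
    out = det[exp]
    out.index = t.data.loc[exp, "probe_id"]
    return out.rename(t.sample_id)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization of a probe x sample matrix.

    Each sample's rank-r value is replaced by the across-sample mean of the
    rank-r values; a group of tied values receives the mean of the
    substitutes of the ranks it occupies. Afterwards the sorted columns of
    all samples are identical.
    """
    if matrix.shape[1] < 2:
        raise DataError("quantile normalization needs >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("quantile normalization requires finite input")
    n = x.shape[0]
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        col_sorted = x[order, j]
        # average the substitutes over each tie run
        vals = mean_sorted.copy()
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            if k > i:
                vals[i : k + 1] = vals[i : k + 1].mean()
            i = k + 1
        out[order, j] = vals
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(
    values: pd.DataFrame, probe_to_gene: pd.Series, detected: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse probe-level matrices to gene level.

    Gene value = median of its probes' values per sample; gene detected iff
    any probe detected. Probes absent from the map (unannotated) keep their
    probe_id as the gene name. Empty input yields empty output.
    """
    if values.empty:
        return values.copy(), detected.copy()
    if values.shape != detected.shape or not values.index.equals(detected.index):
        raise DataError("values/detected probe matrices differ in shape or index")
    genes = values.index.to_series().map(probe_to_gene)
    genes = genes.where(genes.notna(), values.index.to_series())
    gv = values.groupby(genes.values).median()
    gd = detected.groupby(genes.values).any()
    gv.index.name = "gene"
    gd.index.name = "gene"
    return gv.sort_index(), gd.sort_index()


def build_expression_matrix(
    tables: list[SpotTable], policy: FilterPolicy | None = None
) -> tuple[ExpressionMatrix, list[FilterReport]]:
    """Full preprocessing: QC reports, detection calls, log2, quantile
    normalization over the shared experimental probe set, probe collapse.

    All arrays must share the experimental probe set (same design). Returns
    the gene x sample matrix plus the per-array filter reports.
    """
    if len(tables) < 2:
        raise DataError("need >= 2 arrays")
    policy = policy or FilterPolicy()

    reports = [qc_filter_spots(t, policy)[1] for t in tables]
    detected = pd.concat([detection_call(t, policy) for t in tables], axis=1)
    if detected.isna().any().any():
        raise DataError("arrays do not share a common experimental probe set")

    sig = {}
    probe_to_gene = {}
    for t in tables:
        exp = t.experimental()
        s = exp.set_index("probe_id")[policy.signal_column]
        sig[t.sample_id] = np.log2(np.maximum(s.astype(float), LOG2_FLOOR))
        ann = exp.dropna(subset=["gene_symbol"])
        probe_to_gene.update(zip(ann["probe_id"], ann["gene_symbol"]))
    values = pd.DataFrame(sig).loc[detected.index]

    norm = quantile_normalize(values)
    gv, gd = collapse_probes(norm, pd.Series(probe_to_gene), detected)
    groups = pd.Series({t.sample_id: t.group for t in tables}).loc[gv.columns]
    return ExpressionMatrix(values=gv, detected=gd, groups=groups), reports


def write_filter_reports(reports: list[FilterReport], path) -> None:
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(path, sep="\t", index=False)
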