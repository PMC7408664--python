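"""qPCR validation statistics.

Expression scoring uses the cycle-floor convention: a marker's score is
(floor - mean Ct_gene) - (floor - mean Ct_CD45), i.e. expression relative to
the leukocyte marker CD45, which quantifies the non-specifically captured
blood cells. Replicate wells are averaged before normalization; wells with
no amplification sit at the floor (default 40 cycles), so an undetected
marker scores -(floor - Ct_CD45). Higher score = higher expression.

Group comparisons use the two-tailed Mann-Whitney U test (exact for small
untied samples, tie-corrected normal approximation with continuity
correction otherwise) with Benjamini-Hochberg FDR adjustment across markers;
discrimination is summarized per marker and for the combined panel (logistic
model on the marker scores) by ROC/AUC with a DeLong confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .synthgen import QpcrDataset

PATIENT = "patient"
CONTROL = "control"


# ---------------------------------------------------------------------------
# CD45 normalization
# ---------------------------------------------------------------------------


def normalize_ct(d: QpcrDataset) -> pd.DataFrame:
    """CD45-normalized expression scores, samples x genes.

    Replicates are averaged first; score = mean(Ct_ref) - mean(Ct_gene)
    (equivalently (floor-Ct_gene) - (floor-Ct_ref)). A sample that was never
    measured for a gene is missing (NaN), not zero. A sample without the
    reference gene raises :class:`DataError` naming it.
    """
    data = d.data
    means = data.groupby(["sample_id", "gene"])["ct"].mean().unstack("gene")
    if d.reference_gene not in means.columns:
        raise DataError(f"reference gene {d.reference_gene!r} absent from dataset")
    ref = means[d.reference_gene]
    missing_ref = ref.index[ref.isna()].tolist()
    if missing_ref:
        raise DataError(
            f"samples lacking reference gene {d.reference_gene}: {missing_ref}"
        )
    # score = ref_ct - gene_ct, column-wise against the per-sample reference
    return means.drop(columns=d.reference_gene).mul(-1).add(ref, axis=0)


# ---------------------------------------------------------------------------
# rank tests and FDR
# ---------------------------------------------------------------------------


def mannwhitney_test(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    U counts pairs with x > y (ties half). ``mode``: "exact" enumerates the
    null distribution (valid only without cross-group ties), "normal" uses
    the tie-corrected normal approximation with continuity correction,
    "auto" picks exact when min(n) <= 8 and the pooled values are untied.
    Two identical constant groups give p = 1 (degenerate, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be nonempty")
    if mode not in ("exact", "normal", "auto"):
        raise ConfigError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return float(x.size * y.size / 2.0), 1.0
    if mode == "auto":
        mode = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        mode = "normal"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float
    points: pd.DataFrame  # threshold, fpr, tpr


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC from the structural components."""
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    m, n = pos.size, neg.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, positive=PATIENT, alpha: float = 0.05) -> RocResult:
    """AUC (= U/(n1*n2), ties half), ROC points at every distinct threshold,
    and a DeLong confidence interval truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive
    pos, neg = scores[is_pos], scores[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise DataError("roc_auc needs both classes present")
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    var = _delong_variance(pos, neg)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return RocResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        variance=float(var),
        points=points,
    )


# ---------------------------------------------------------------------------
# combined panel (logistic model)
# ---------------------------------------------------------------------------


@dataclass
class PanelModel:
    """Binomial-logit model combining the marker scores.

    ``fitted_scores`` is the linear predictor per sample (the panel score
    the ROC is built on). ``separation`` flags a perfectly separable fit:
    coefficients are then reported at the iteration cap and the AUC (1.0)
    remains valid.
    """

    genes: list
    intercept: float
    coefficients: pd.Series
    fitted_scores: pd.Series
    converged: bool
    separation: bool
    n_iter: int
    deviance: float
    auc: float
    ci_low: float
    ci_high: float
    roc_points: pd.DataFrame


def fit_panel_logistic(
    scores: pd.DataFrame,
    labels,
    positive=PATIENT,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PanelModel:
    """Fit the combined panel by IRLS and score it with ROC/AUC.

    Complete cases only; convergence on relative deviance change < ``tol``
    (at most ``max_iter`` iterations). With perfectly separated classes the
    likelihood has no maximum: the fit stops at the cap, flags
    ``separation`` and warns.
    """
    labels = pd.Series(np.asarray(labels), index=scores.index)
    cc = scores.dropna(axis=0, how="any").index
    X_df = scores.loc[cc]
    y = (labels.loc[cc] == positive).to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise DataError("both classes must be present")
    if len(cc) < scores.shape[1] + 2:
        raise DataError(
            f"{len(cc)} complete cases for {scores.shape[1]} markers: need >= genes+2"
        )
    X = np.column_stack([np.ones(len(cc)), X_df.to_numpy(dtype=float)])

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    dev_old = np.inf
    converged = False
    n_iter = 0
    eps = 1e-12
    for n_iter in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(p * (1 - p), eps)
        z = eta + (y - p) / w
        wx = X * w[:, None]
        beta = np.linalg.solve(X.T @ wx, X.T @ (w * z))
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        dev = -2.0 * np.sum(
            y * np.log(np.maximum(p, eps)) + (1 - y) * np.log(np.maximum(1 - p, eps))
        )
        if np.isfinite(dev_old) and abs(dev - dev_old) <= tol * (abs(dev_old) + eps):
            converged = True
            break
        dev_old = dev

    perfect = bool(np.all(np.abs(y - p) < 1e-6))
    separation = perfect and (not converged or dev < 1e-6)
    if separation:
        warnings.warn(
            "perfect separation: coefficients reported at the iteration cap",
            stacklevel=2,
        )
    fitted = pd.Series(eta, index=cc, name="panel_score")
    roc = roc_auc(fitted.to_numpy(), labels.loc[cc].to_numpy(), positive=positive)
    return PanelModel(
        genes=list(scores.columns),
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=scores.columns),
        fitted_scores=fitted,
        converged=converged,
        separation=separation,
        n_iter=n_iter,
        deviance=float(dev),
        auc=roc.auc,
        ci_low=roc.ci_low,
        ci_high=roc.ci_high,
        roc_points=roc.points,
    )


# ---------------------------------------------------------------------------
# correlation, dichotomization, per-marker table
# ---------------------------------------------------------------------------


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("pearson_corr needs paired vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("pearson_corr requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def nearest_rank_percentile(values, q: float) -> float:
    """q-quantile by the nearest-rank definition: the ceil(q*n)-th order
    statistic (1-based)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise DataError("empty input")
    k = max(1, ceil(q * v.size))
    return float(v[k - 1])


def dichotomize(scores: pd.Series, cut) -> tuple[pd.Series, float]:
    """Split samples into low/high expression groups.

    ``cut`` is "median", "p70" (nearest-rank 70th percentile) or a number
    (fixed cutoff, e.g. a published marker cutoff). low <=> score <= cut
    value; returns the labels and the cut value actually used.
    """
    scores = pd.Series(scores).astype(float)
    if isinstance(cut, str):
        if len(scores) < 2:
            raise DataError("data-driven cuts need >= 2 samples")
        if cut == "median":
            cut_value = float(scores.median())
        elif cut in ("p70", "percentile70"):
            cut_value = nearest_rank_percentile(scores.to_numpy(), 0.7)
        else:
            raise ConfigError(f"unknown cut {cut!r}")
        if scores.nunique() == 1:
            warnings.warn("all scores equal: every sample assigned low", stacklevel=2)
    else:
        cut_value = float(cut)
    labels = pd.Series(
        np.where(scores <= cut_value, "low", "high"), index=scores.index, name="group"
    )
    return labels, cut_value


def marker_test_table(
    scores: pd.DataFrame, groups: pd.Series, mode: str = "auto", positive=PATIENT
) -> pd.DataFrame:
    """Per-marker validation table: group sizes and medians, U, p, BH q, AUC.

    One row per marker (column of ``scores``); missing scores are dropped per
    marker. q-values adjust the p-values across all markers in the table.
    """
    groups = groups.loc[scores.index]
    rows = []
    for gene in scores.columns:
        s = scores[gene].dropna()
        g = groups.loc[s.index]
        x = s[g == positive].to_numpy()
        y = s[g != positive].to_numpy()
        u, p = mannwhitney_test(x, y, mode=mode)
        roc = roc_auc(s.to_numpy(), g.to_numpy(), positive=positive)
        rows.append(
            {
                "gene": gene,
                "n_patient": x.size,
                "n_control": y.size,
                "median_patient": float(np.median(x)),
                "median_control": float(np.median(y)),
                "U": u,
                "p_value": p,
                "auc": roc.auc,
                "auc_ci_low": roc.ci_low,
                "auc_ci_high": roc.ci_high,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
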