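"""Kaplan-Meier estimation, log-rank tests and Cox regression for
marker-dichotomized groups.

Follow-up is in months; the event flag marks observed progression/death,
false means right-censoring. At tied times, events precede censorings (the
usual product-limit convention). "Mean" survival is the restricted mean:
the area under the Kaplan-Meier curve up to the largest observed time, the
quantity mainstream clinical-statistics software prints next to the
Kaplan-Meier table, with its standard large-sample variance. Cox models are
fit by Newton-Raphson on the partial likelihood with Breslow handling of
ties (Efron available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biomarker_stats import dichotomize
from .errors import DataError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _as_surv_arrays(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0:
        raise DataError("empty survival data")
    if t.size != e.size:
        raise DataError("time and event lengths differ")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise DataError("times must be finite and > 0")
    return t, e


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance and summaries.

    ``times``/``n_risk``/``n_event`` describe the distinct event times;
    ``survival`` and ``variance`` are the estimate and its Greenwood
    variance there. The restricted mean integrates S(t) over [0, tmax]
    where tmax is the largest observed (event or censoring) time.
    Median (and its log-log CI bounds) are NaN when S never reaches 0.5.
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_subjects: int
    tmax: float
    median: float
    median_ci: tuple
    restricted_mean: float
    restricted_mean_se: float
    restricted_mean_ci: tuple

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times, with
    Greenwood variance; median = smallest t with S(t) <= 0.5; restricted
    mean = area under S up to the largest observed time with the standard
    variance sum over event times.
    """
    t, e = _as_surv_arrays(time, event)
    n = t.size
    tmax = float(t.max())
    ev_times = np.unique(t[e])
    n_risk = np.array([(t >= u).sum() for u in ev_times], dtype=float)
    n_event = np.array([((t == u) & e).sum() for u in ev_times], dtype=float)

    frac = 1.0 - n_event / n_risk
    surv = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d))); infinite term when
    # the last subject fails is treated as 0 variance at S = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_risk > n_event, n_event / (n_risk * (n_risk - n_event)), np.nan)
    gw = np.cumsum(np.nan_to_num(inc, nan=0.0))
    var = surv**2 * gw

    median = np.nan
    below = np.flatnonzero(surv <= 0.5 + 1e-12)
    if below.size:
        median = float(ev_times[below[0]])

    # log(-log S) pointwise 95% bands -> median CI (Brookmeyer-Crowley style)
    med_lo = med_hi = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.log(surv)
        se_cll = np.sqrt(gw) / np.abs(logs)
        lower = surv ** np.exp(Z95 * se_cll)
        upper = surv ** np.exp(-Z95 * se_cll)
    ok = np.isfinite(lower)
    lo_idx = np.flatnonzero(ok & (lower <= 0.5 + 1e-12))
    hi_idx = np.flatnonzero(ok & (upper <= 0.5 + 1e-12))
    if lo_idx.size:
        med_lo = float(ev_times[lo_idx[0]])
    if hi_idx.size:
        med_hi = float(ev_times[hi_idx[0]])

    # restricted mean: step-area of S over [0, tmax]
    grid = np.concatenate([[0.0], ev_times[ev_times <= tmax], [tmax]])
    grid = np.unique(grid)
    s_left = np.array([1.0 if g == 0 else None for g in grid[:-1]], dtype=float)
    s_vals = np.concatenate([[1.0], surv])
    ev_grid = np.concatenate([[0.0], ev_times])
    idx = np.searchsorted(ev_grid, grid[:-1], side="right") - 1
    s_left = s_vals[idx]
    rmst = float(np.sum(s_left * np.diff(grid)))

    # Klein-Moeschberger variance of the restricted mean
    areas = []
    for i, u in enumerate(ev_times):
        if u >= tmax:
            areas.append(0.0)
            continue
        g = grid[grid >= u]
        ii = np.searchsorted(ev_grid, g[:-1], side="right") - 1
        areas.append(float(np.sum(s_vals[ii] * np.diff(g))))
    areas = np.asarray(areas)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            n_risk > n_event,
            areas**2 * n_event / (n_risk * (n_risk - n_event)),
            0.0,
        )
    rm_var = float(np.sum(terms))
    rm_se = float(np.sqrt(rm_var))

    return KMCurve(
        times=ev_times,
        n_risk=n_risk,
        n_event=n_event,
        survival=surv,
        variance=var,
        n_subjects=n,
        tmax=tmax,
        median=median,
        median_ci=(med_lo, med_hi),
        restricted_mean=rmst,
        restricted_mean_se=rm_se,
        restricted_mean_ci=(rmst - Z95 * rm_se, rmst + Z95 * rm_se),
    )


def logrank_test(time, event, group) -> tuple[float, int, float]:
    """Two-group log-rank test.

    Returns (chi_square, df=1, two-sided p). Observed-minus-expected events
    in group 1 against the hypergeometric variance at each distinct event
    time.
    """
    t, e = _as_surv_arrays(time, event)
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise DataError(f"log-rank needs exactly 2 groups, got {list(levels)}")
    if min((g == lv).sum() for lv in levels) == 0:
        raise DataError("a group has zero subjects")
    in1 = g == levels[0]
    o_minus_e = 0.0
    v = 0.0
    for u in np.unique(t[e]):
        at_risk = t >= u
        n_i = at_risk.sum()
        d_i = ((t == u) & e).sum()
        n1_i = (at_risk & in1).sum()
        d1_i = ((t == u) & e & in1).sum()
        o_minus_e += d1_i - d_i * n1_i / n_i
        if n_i > 1:
            v += d_i * (n1_i / n_i) * (1 - n1_i / n_i) * (n_i - d_i) / (n_i - 1)
    if v <= 0:
        return 0.0, 1, 1.0
    chi2 = o_minus_e**2 / v
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


@dataclass
class CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Wald inference)."""

    coef: pd.Series
    se: pd.Series
    hazard_ratio: pd.Series
    hr_ci_low: pd.Series
    hr_ci_high: pd.Series
    loglik: float
    score_chi2: float  # score test at beta = 0 (log-rank analogue)
    converged: bool
    monotone_likelihood: bool
    n_iter: int
    ties: str


def _cox_derivatives(beta, t, e, X, ties):
    """(loglik, score, information) of the partial likelihood."""
    eta = X @ beta
    w = np.exp(np.clip(eta, -500, 500))
    ll = 0.0
    score = np.zeros(X.shape[1])
    info = np.zeros((X.shape[1], X.shape[1]))
    for u in np.unique(t[e]):
        risk = t >= u
        dead = (t == u) & e
        d = int(dead.sum())
        s0 = w[risk].sum()
        s1 = (w[risk, None] * X[risk]).sum(axis=0)
        s2 = (w[risk, None, None] * X[risk, :, None] * X[risk, None, :]).sum(axis=0)
        xd = X[dead]
        ll += eta[dead].sum()
        score += xd.sum(axis=0)
        if ties == "efron" and d > 1:
            s0d = w[dead].sum()
            s1d = (w[dead, None] * xd).sum(axis=0)
            s2d = (w[dead, None, None] * xd[:, :, None] * xd[:, None, :]).sum(axis=0)
            for l in range(d):
                f = l / d
                a0 = s0 - f * s0d
                a1 = s1 - f * s1d
                a2 = s2 - f * s2d
                ll -= np.log(a0)
                score -= a1 / a0
                info += a2 / a0 - np.outer(a1, a1) / a0**2
        else:  # breslow
            ll -= d * np.log(s0)
            score -= d * s1 / s0
            info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
    return ll, score, info


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Convergence when the largest score component falls below ``tol``; a fit
    that runs out of iterations with a drifting coefficient is flagged as a
    monotone likelihood (separation in time order) and reported at the cap
    with a warning. Wald SEs from the inverse observed information.
    """
    if ties not in ("breslow", "efron"):
        raise DataError(f"unknown tie handling {ties!r}")
    X_df = pd.DataFrame(covariates)
    t, e = _as_surv_arrays(time, event)
    if e.sum() == 0:
        raise DataError("no events observed")
    X = X_df.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise DataError("covariates must be finite")
    names = list(X_df.columns)
    # drop zero-variance covariates from the iteration: their MLE is 0
    active = np.ptp(X, axis=0) > 0

    beta = np.zeros(X.shape[1])
    _, score0, info0 = _cox_derivatives(beta, t, e, X, ties)
    if active.any():
        inf_a = info0[np.ix_(active, active)]
        sc_a = score0[active]
        score_chi2 = float(sc_a @ np.linalg.solve(inf_a, sc_a))
    else:
        score_chi2 = 0.0

    converged = not active.any()
    monotone = False
    n_iter = 0
    ll = _cox_derivatives(beta, t, e, X, ties)[0]
    if active.any():
        Xa = X[:, active]
        # standardize internally so the divergence bound is scale-free
        sd = Xa.std(axis=0, ddof=0)
        Xs = Xa / sd
        ba = np.zeros(Xs.shape[1])
        for n_iter in range(1, max_iter + 1):
            ll, sc, inf = _cox_derivatives(ba, t, e, Xs, ties)
            if np.max(np.abs(sc)) < tol:
                converged = True
                break
            if np.max(np.abs(ba)) > 15.0:
                # coefficient drifting without bound: monotone likelihood
                monotone = True
                break
            step = np.linalg.solve(inf, sc)
            nrm = np.max(np.abs(step))
            if nrm > 5.0:  # dampen huge steps to keep the iteration stable
                step *= 5.0 / nrm
            ba = ba + step
        beta[active] = ba / sd
        ll, _, inf = _cox_derivatives(ba, t, e, Xs, ties)
        # map the information back to the original covariate scale
        inf = inf * np.outer(sd, sd)
    if not converged:
        warnings.warn(
            "Cox fit did not converge"
            + (" (monotone likelihood suspected)" if monotone else ""),
            stacklevel=2,
        )

    se = np.full(X.shape[1], np.nan)
    if active.any():
        cov = np.linalg.inv(inf)
        se[active] = np.sqrt(np.diag(cov))
    se[~active] = 0.0

    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    hr = np.exp(coef)
    return CoxResult(
        coef=coef,
        se=se_s,
        hazard_ratio=hr,
        hr_ci_low=np.exp(coef - Z95 * se_s),
        hr_ci_high=np.exp(coef + Z95 * se_s),
        loglik=float(ll),
        score_chi2=score_chi2,
        converged=converged,
        monotone_likelihood=monotone,
        n_iter=n_iter,
        ties=ties,
    )


def marker_survival_report(
    scores: pd.DataFrame,
    cuts: dict,
    surv: pd.DataFrame,
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Per-marker dichotomized survival table.

    For each marker in ``cuts`` the scores are split low/high (fixed numeric
    cutoffs or "median"/"p70"), each group is summarized by the restricted
    mean with its 95% CI, and the groups are compared by the log-rank test.
    Markers leaving one group empty are skipped with a warning. One row per
    (marker, group); the log-rank p is repeated on both rows of a marker.
    """
    surv = surv.set_index("sample_id") if "sample_id" in surv.columns else surv
    rows = []
    for marker, cut in cuts.items():
        if marker not in scores.columns:
            warnings.warn(f"{marker}: no scores, skipped", stacklevel=2)
            continue
        s = scores[marker].dropna()
        common = s.index.intersection(surv.index)
        if len(common) == 0:
            warnings.warn(f"{marker}: no overlap with survival data, skipped", stacklevel=2)
            continue
        labels, cut_value = dichotomize(s.loc[common], cut)
        sub = surv.loc[common]
        if labels.nunique() < 2:
            warnings.warn(f"{marker}: a group is empty after the cut, skipped", stacklevel=2)
            continue
        chi2, _, p = logrank_test(sub["time"], sub["event"], labels)
        for level in ("low", "high"):
            km = km_estimate(
                sub.loc[labels == level, "time"], sub.loc[labels == level, "event"]
            )
            rows.append(
                {
                    "endpoint": endpoint,
                    "marker": marker,
                    "group": level,
                    "n": int((labels == level).sum()),
                    "cut_value": cut_value,
                    "mean_survival": km.restricted_mean,
                    "ci_low": km.restricted_mean_ci[0],
                    "ci_high": km.restricted_mean_ci[1],
                    "logrank_chi2": chi2,
                    "logrank_p": p,
                }
            )
    return pd.DataFrame(rows)
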