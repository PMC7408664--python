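"""Synthetic cohorts with the statistical structure the analysis assumes.

The array generator emulates an EpCAM-enrichment experiment on blood: every
sample (patient or healthy donor) carries a lymphocyte background
transcriptome, while a set of spiked "CTC genes" is expressed only in a
random subset of patient arrays — the ground truth the signature stage must
recover. The qPCR generator produces duplicate-well Ct tables with a CD45
reference per sample and configurable patient-vs-control shifts of the
CD45-normalized score, and survival times whose log-hazard is a linear
combination of the marker scores.

Ground truth is emitted alongside the data in a separate structure and is
never consumed by the pipeline, so recovery tests cannot leak labels. Fixed
seeds make every output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import EXPERIMENTAL, NEGATIVE_CONTROL, SPOT_COLUMNS, SpotTable
from .errors import ConfigError

# ---------------------------------------------------------------------------
# array cohort
# ---------------------------------------------------------------------------

#: markers carried by the default qPCR panel; the first six were the ones
#: with significant patient/control shifts, ARL4A the non-significant seventh
PANEL_GENES = ("HOXB13", "MAOA", "FGD4", "MOSPD1", "QKI", "SDK1", "ARL4A")
VALIDATED_GENES = PANEL_GENES[:6]


@dataclass(frozen=True)
class ArraySimConfig:
    """Design of a simulated two-group array cohort.

    Intensities are log-normal on the log2 scale: blood-background genes sit
    at ``background_mu`` +/- ``background_sigma`` (log2 units) in every
    sample, spiked CTC genes add ``signal_shift`` on top of the background
    level in the patient arrays that carry them, and unexpressed spots (CTC
    genes elsewhere, negative controls) are drawn from a low-intensity noise
    floor at ``floor_mu`` +/- ``floor_sigma``. ``outlier_rate`` is the
    fraction of spots flagged as non-uniform/replicate outliers.
    """

    n_patients: int = 9
    n_healthy: int = 6
    n_genes: int = 2000
    probes_per_gene: int = 2
    n_negative_controls: int = 100
    n_ctc_genes: int = 40
    ctc_presence_prob: float = 0.7
    background_mu: float = 8.0
    background_sigma: float = 1.0
    signal_shift: float = 6.0
    outlier_rate: float = 0.02
    floor_mu: float = 4.0
    floor_sigma: float = 0.5
    unannotated_frac: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_healthy": self.n_healthy,
            "n_genes": self.n_genes,
            "probes_per_gene": self.probes_per_gene,
            "n_negative_controls": self.n_negative_controls,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not 0 <= self.n_ctc_genes <= self.n_genes:
            raise ConfigError(
                f"n_ctc_genes={self.n_ctc_genes} must lie in [0, n_genes={self.n_genes}]"
            )
        for name in ("ctc_presence_prob", "outlier_rate", "unannotated_frac"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.signal_shift < 0:
            raise ConfigError("signal_shift must be >= 0")
        for name in ("background_sigma", "floor_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Which genes were spiked and which patient arrays carry each of them."""

    ctc_genes: list
    carriers: dict  # gene -> sorted list of patient sample ids
    patient_ids: list
    healthy_ids: list

    def occupancy(self, gene: str) -> int:
        return len(self.carriers[gene])

    def recoverable(self, min_patients: int = 5) -> set:
        """Spiked genes whose realized patient occupancy meets the presence rule."""
        return {g for g in self.ctc_genes if self.occupancy(g) >= min_patients}


def _sample_ids(cfg: ArraySimConfig) -> tuple[list, list]:
    pats = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    heal = [f"H{i + 1:02d}" for i in range(cfg.n_healthy)]
    return pats, heal


def simulate_array_cohort(cfg: ArraySimConfig) -> tuple[list[SpotTable], GroundTruth]:
    """Generate one spot table per sample plus the spike-in ground truth.

    A spot's processed signal is 2**level with the level drawn from the
    expressed distribution (background, plus ``signal_shift`` for carried CTC
    genes) or the noise floor. The above-background flag encodes whether the
    spot carries true signal — the analogue of the scanner software's
    per-spot background test. Outlier flags land on a random
    ``outlier_rate`` fraction of spots, split between the non-uniform and
    replicate flavours.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    patients, healthy = _sample_ids(cfg)

    genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
    ctc_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_ctc_genes, replace=False))
    ctc_genes = [genes[i] for i in ctc_idx]
    is_ctc = np.zeros(cfg.n_genes, dtype=bool)
    is_ctc[ctc_idx] = True

    # a fraction of non-spiked genes has no annotation (empty symbol)
    unannotated = rng.random(cfg.n_genes) < cfg.unannotated_frac
    unannotated[ctc_idx] = False

    carriers = {
        g: sorted(
            p for p in patients if rng.random() < cfg.ctc_presence_prob
        )
        for g in ctc_genes
    }

    probe_ids = [
        f"PR{i + 1:05d}_{k + 1}"
        for i in range(cfg.n_genes)
        for k in range(cfg.probes_per_gene)
    ]
    probe_gene_idx = np.repeat(np.arange(cfg.n_genes), cfg.probes_per_gene)
    neg_ids = [f"NEGCTRL{i + 1:04d}" for i in range(cfg.n_negative_controls)]

    tables = []
    for sid, grp in [(p, "patient") for p in patients] + [
        (h, "healthy") for h in healthy
    ]:
        expressed_gene = ~is_ctc.copy()
        if grp == "patient":
            for g, idx in zip(ctc_genes, ctc_idx):
                if sid in carriers[g]:
                    expressed_gene[idx] = True
        expressed = expressed_gene[probe_gene_idx]

        n_exp = len(probe_ids)
        level = np.where(
            expressed,
            cfg.background_mu
            + cfg.signal_shift * is_ctc[probe_gene_idx]
            + rng.normal(0.0, cfg.background_sigma, n_exp),
            cfg.floor_mu + rng.normal(0.0, cfg.floor_sigma, n_exp),
        )
        neg_level = cfg.floor_mu + rng.normal(0.0, cfg.floor_sigma, cfg.n_negative_controls)

        signal = np.concatenate([2.0 ** level, 2.0 ** neg_level])
        bg_estimate = 2.0 ** (
            cfg.floor_mu + rng.normal(0.0, 0.1 * cfg.floor_sigma, signal.size)
        )
        above_bg = np.concatenate(
            [expressed, np.zeros(cfg.n_negative_controls, dtype=bool)]
        )
        out = rng.random(signal.size) < cfg.outlier_rate
        which = rng.random(signal.size) < 0.5
        symbols = np.concatenate(
            [
                np.where(unannotated[probe_gene_idx], None, np.array(genes)[probe_gene_idx]),
                np.full(cfg.n_negative_controls, None),
            ]
        )
        df = pd.DataFrame(
            {
                "probe_id": probe_ids + neg_ids,
                "gene_symbol": symbols,
                "processed_signal": signal,
                "bg_sub_signal": signal - bg_estimate,
                "bg_estimate": bg_estimate,
                "flag_nonuniform_outlier": out & which,
                "flag_replicate_outlier": out & ~which,
                "flag_above_background": above_bg,
                "control_type": [EXPERIMENTAL] * n_exp
                + [NEGATIVE_CONTROL] * cfg.n_negative_controls,
            },
            columns=SPOT_COLUMNS,
        )
        tables.append(SpotTable(sample_id=sid, group=grp, data=df))

    truth = GroundTruth(
        ctc_genes=ctc_genes,
        carriers=carriers,
        patient_ids=patients,
        healthy_ids=healthy,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# qPCR cohort
# ---------------------------------------------------------------------------


#: published high/low expression cutoffs (CD45-normalized score units) for
#: the six validated markers; medians / 70th percentiles of the validation
#: cohort, reused as fixed cuts when reproducing the survival table layout
TABLE2_CUTS = {
    "HOXB13": -3.8,
    "MAOA": -4.1,
    "FGD4": 0.4,
    "MOSPD1": -4.0,
    "QKI": 0.5,
    "SDK1": -2.0,
}


def _default_effects() -> dict:
    eff = {g: 2.0 for g in VALIDATED_GENES}
    eff["ARL4A"] = 0.0
    return eff


def _default_baselines() -> dict:
    # patient-group mean score (baseline + effect) anchored at each marker's
    # published cutoff, which was a quantile of the real patient scores; this
    # keeps simulated cohorts straddling the fixed cuts, as the real one did
    base = {g: TABLE2_CUTS[g] - 2.0 for g in VALIDATED_GENES}
    base["ARL4A"] = -5.0
    return base


def _default_hazards() -> dict:
    hz = {g: 0.3 for g in VALIDATED_GENES}
    hz["ARL4A"] = 0.0
    return hz


@dataclass(frozen=True)
class QpcrSimConfig:
    """Design of a simulated qPCR validation cohort.

    Each sample gets a CD45 reference Ct around ``cd45_mu``; a marker's true
    CD45-normalized score is ``baseline_score`` (scalar, or per-gene mapping —
    by default anchored so the patient-group mean sits at the marker's
    published cutoff) plus its entry in ``effect_sizes`` for patients. Wells are run in duplicate with Gaussian
    replicate noise ``ct_sigma`` (cycle units) and clipped at ``ct_floor``
    (the instrument's maximum observable cycle). ``hazard_coefs`` drive the
    survival generator; ``censor_rate`` is the probability a follow-up record
    is right-censored.
    """

    n_patients: int = 28
    n_controls: int = 15
    genes: tuple = PANEL_GENES
    effect_sizes: dict = field(default_factory=_default_effects)
    ct_sigma: float = 1.0
    ct_floor: float = 40.0
    baseline_score: float | dict = field(default_factory=_default_baselines)
    cd45_mu: float = 25.0
    cd45_sigma: float = 1.5
    n_replicates: int = 2
    hazard_coefs: dict = field(default_factory=_default_hazards)
    median_survival_months: float = 8.0
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0 or self.n_replicates <= 0:
            raise ConfigError("cohort sizes and replicate count must be positive")
        if self.ct_sigma < 0:
            raise ConfigError(f"ct_sigma={self.ct_sigma} must be >= 0")
        if self.ct_floor <= 0:
            raise ConfigError("ct_floor must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigError(f"censor_rate={self.censor_rate} outside [0, 1]")
        if self.median_survival_months <= 0:
            raise ConfigError("median_survival_months must be > 0")


@dataclass
class QpcrDataset:
    """Tidy per-well Ct table: sample_id, group, gene, well, ct.

    The reference gene (CD45) appears as ordinary rows; ``ct_floor`` is the
    maximum observable cycle (undetected wells sit at the floor).
    """

    data: pd.DataFrame
    ct_floor: float = 40.0
    reference_gene: str = "CD45"

    def groups(self) -> pd.Series:
        g = self.data.drop_duplicates("sample_id").set_index("sample_id")["group"]
        return g.rename("group")


def simulate_qpcr_cohort(cfg: QpcrSimConfig) -> QpcrDataset:
    """Duplicate-well Ct values for patients and controls plus CD45 reference.

    The true gene Ct of a sample is its CD45 Ct minus the true score, so the
    CD45-normalized score (cycle-floor convention) recovers
    ``baseline_score`` (+ effect in patients) exactly in the noiseless limit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = [(f"PT{i + 1:02d}", "patient") for i in range(cfg.n_patients)] + [
        (f"CT{i + 1:02d}", "control") for i in range(cfg.n_controls)
    ]
    rows = []
    for sid, grp in samples:
        cd45_true = rng.normal(cfg.cd45_mu, cfg.cd45_sigma)
        for w in range(cfg.n_replicates):
            ct = min(cd45_true + rng.normal(0.0, cfg.ct_sigma), cfg.ct_floor)
            rows.append((sid, grp, "CD45", w + 1, ct))
        for gene in cfg.genes:
            base = (
                cfg.baseline_score.get(gene, -5.0)
                if isinstance(cfg.baseline_score, dict)
                else cfg.baseline_score
            )
            score_true = base + (
                cfg.effect_sizes.get(gene, 0.0) if grp == "patient" else 0.0
            )
            ct_true = cd45_true - score_true
            for w in range(cfg.n_replicates):
                ct = min(ct_true + rng.normal(0.0, cfg.ct_sigma), cfg.ct_floor)
                rows.append((sid, grp, gene, w + 1, ct))
    data = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "well", "ct"])
    return QpcrDataset(data=data, ct_floor=cfg.ct_floor)


def simulate_survival(
    cfg: QpcrSimConfig, scores: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Exponential event times driven by the marker scores.

    The per-patient log relative hazard is sum(hazard_coefs * scores),
    mean-centered so the baseline rate (tuned to give a median of
    ``median_survival_months`` at the cohort-average score) sets the time
    scale regardless of where the scores sit. A record is right-censored
    with probability ``censor_rate``, at a uniform time before its event.

    Parameters
    ----------
    scores : DataFrame, samples x genes (must cover every hazard-weighted gene)

    Returns
    -------
    DataFrame with columns sample_id, time (months, > 0), event (bool).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = [g for g, c in cfg.hazard_coefs.items() if c != 0.0] or list(
        cfg.hazard_coefs
    )
    missing = [g for g in genes if g not in scores.columns]
    if missing:
        raise ConfigError(f"scores missing hazard-weighted genes: {missing}")
    if scores[genes].isna().any().any():
        raise ConfigError("scores contain missing values for hazard-weighted genes")

    coefs = np.array([cfg.hazard_coefs[g] for g in genes])
    lp = scores[genes].to_numpy(dtype=float) @ coefs
    lp = lp - lp.mean()
    rate0 = np.log(2.0) / cfg.median_survival_months
    t_event = rng.exponential(1.0 / (rate0 * np.exp(lp)))
    censored = rng.random(len(t_event)) < cfg.censor_rate
    t_obs = np.where(censored, rng.uniform(0.0, t_event), t_event)
    t_obs = np.maximum(t_obs, 1e-6)
    return pd.DataFrame(
        {
            "sample_id": list(scores.index),
            "time": t_obs,
            "event": ~censored,
        }
    )


# ---------------------------------------------------------------------------
# delimited-text writers (formats the io/stats modules read back)
# ---------------------------------------------------------------------------


def write_qpcr_table(d: QpcrDataset, path) -> None:
    with open(path, "wt") as fh:
        fh.write(f"#ct_floor\t{d.ct_floor:g}\n#reference_gene\t{d.reference_gene}\n")
        d.data.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_qpcr_table(path) -> QpcrDataset:
    import io

    meta = {}
    with open(path, "rt") as fh:
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].rstrip("\n").partition("\t")
            meta[k] = v
            line = fh.readline()
        data = pd.read_csv(io.StringIO(line + fh.read()), sep="\t")
    return QpcrDataset(
        data=data,
        ct_floor=float(meta.get("ct_floor", 40.0)),
        reference_gene=meta.get("reference_gene", "CD45"),
    )


def write_survival_table(t: pd.DataFrame, path) -> None:
    out = t.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_survival_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", comment="#")
    t["event"] = t["event"].astype(bool)
    return t
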