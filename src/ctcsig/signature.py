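"""CTC-specific gene selection by healthy-background subtraction.

Healthy-donor arrays measure what EpCAM enrichment drags along from normal
blood (mostly lymphocytes). A gene is CTC-specific when it is detected in at
least ``min_patient_count`` patient arrays while being detected in at most
``max_healthy_count`` healthy arrays (default 0: any healthy detection
excludes). Presence is evaluated on the gene-level detection-call matrix,
not on intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .array_io import ExpressionMatrix
from .errors import ConfigError, DataError

PATIENT = "patient"
HEALTHY = "healthy"


@dataclass(frozen=True)
class SignatureRule:
    """k-of-n presence rule: detected in >= min_patient_count patients and
    <= max_healthy_count healthy donors."""

    min_patient_count: int = 5
    max_healthy_count: int = 0

    def validate(self, n_patients: int, n_healthy: int) -> None:
        if not 1 <= self.min_patient_count <= n_patients:
            raise ConfigError(
                f"min_patient_count={self.min_patient_count} infeasible for "
                f"{n_patients} patient arrays"
            )
        if not 0 <= self.max_healthy_count <= n_healthy:
            raise ConfigError(
                f"max_healthy_count={self.max_healthy_count} infeasible for "
                f"{n_healthy} healthy arrays"
            )


@dataclass
class SignatureResult:
    """Selected genes with their per-group presence counts.

    ``genes`` is sorted by descending patient presence then name, so the
    ordering is deterministic. ``annotated``/``unannotated`` are filled by
    :func:`annotate_signature`.
    """

    genes: list
    counts: pd.DataFrame  # index gene, columns patient_count / healthy_count
    rule: SignatureRule
    n_patients: int
    n_healthy: int
    annotated: list = field(default_factory=list)
    unannotated: list = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def presence_counts(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene detection counts in each group.

    Returns a DataFrame indexed by gene with ``patient_count`` and
    ``healthy_count`` columns, bounded by the group sizes.
    """
    unknown = set(m.groups.unique()) - {PATIENT, HEALTHY}
    if unknown:
        raise DataError(f"samples with unknown group label: {sorted(unknown)}")
    pats = m.samples_in_group(PATIENT)
    heal = m.samples_in_group(HEALTHY)
    if not pats or not heal:
        raise DataError("need at least one patient and one healthy sample")
    return pd.DataFrame(
        {
            "patient_count": m.detected[pats].sum(axis=1).astype(int),
            "healthy_count": m.detected[heal].sum(axis=1).astype(int),
        }
    )


def select_ctc_genes(m: ExpressionMatrix, rule: SignatureRule | None = None) -> SignatureResult:
    """Apply the presence rule to the detection matrix.

    A gene is selected iff healthy_count <= max_healthy_count and
    patient_count >= min_patient_count; output order is
    (descending patient_count, gene name).
    """
    rule = rule or SignatureRule()
    counts = presence_counts(m)
    n_pat = len(m.samples_in_group(PATIENT))
    n_heal = len(m.samples_in_group(HEALTHY))
    rule.validate(n_pat, n_heal)
    sel = counts[
        (counts["patient_count"] >= rule.min_patient_count)
        & (counts["healthy_count"] <= rule.max_healthy_count)
    ].copy()
    sel = (
        sel.assign(_g=sel.index)
        .sort_values(by=["patient_count", "_g"], ascending=[False, True])
        .drop(columns="_g")
    )
    return SignatureResult(
        genes=list(sel.index),
        counts=sel,
        rule=rule,
        n_patients=n_pat,
        n_healthy=n_heal,
    )


def annotate_signature(s: SignatureResult, annotation: dict) -> SignatureResult:
    """Partition the selected genes by annotation status.

    ``annotation`` maps gene name -> symbol and may be partial; genes absent
    from the map (or mapped to an empty value) are reported unannotated.
    """
    annotated = [g for g in s.genes if annotation.get(g)]
    s.annotated = annotated
    s.unannotated = [g for g in s.genes if g not in set(annotated)]
    return s


def write_signature_report(s: SignatureResult, path) -> None:
    """Two-section delimited report: rule echo, then selected genes with counts."""
    with open(path, "wt") as fh:
        fh.write(
            "#rule\tmin_patient_count={}\tmax_healthy_count={}\t"
            "n_patients={}\tn_healthy={}\tn_selected={}\n".format(
                s.rule.min_patient_count,
                s.rule.max_healthy_count,
                s.n_patients,
                s.n_healthy,
                s.n_genes,
            )
        )
        if s.annotated or s.unannotated:
            fh.write(
                f"#annotation\tannotated={len(s.annotated)}\t"
                f"unannotated={len(s.unannotated)}\n"
            )
        s.counts.to_csv(fh, sep="\t", index_label="gene")
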