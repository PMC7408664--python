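"""Reading and writing spot-level array tables and expression matrices.

Spot tables follow a small, configurable subset of the Agilent Feature
Extraction tab-delimited dialect: one row per spot, with a probe name, an
optional gene symbol, the processed and background-subtracted signals, a
per-spot background estimate, boolean QC flags (0/1) and a control-type
code (0 = experimental probe, -1 = negative control, anything else =
other control).  The column-name mapping is configuration so that real
Feature Extraction exports and synthetic fixtures share one reader.

Intensities are stored linear here; the log2 transform belongs to the
preprocessing stage because the spot-level QC criteria are defined on raw
signals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

EXPERIMENTAL = "experimental"
NEGATIVE_CONTROL = "negative_control"
OTHER_CONTROL = "other_control"

#: canonical spot-table columns, in storage order
SPOT_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "processed_signal",
    "bg_sub_signal",
    "bg_estimate",
    "flag_nonuniform_outlier",
    "flag_replicate_outlier",
    "flag_above_background",
    "control_type",
]

_FLAG_COLUMNS = [
    "flag_nonuniform_outlier",
    "flag_replicate_outlier",
    "flag_above_background",
]

_NUMERIC_COLUMNS = ["processed_signal", "bg_sub_signal", "bg_estimate"]


@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from canonical spot fields to file column names.

    Defaults follow the Agilent Feature Extraction naming. ``negative_control_code``
    is the value of the control-type column marking negative controls (FE uses -1);
    0 marks experimental probes, any other value an unspecified control.
    """

    probe_id: str = "ProbeName"
    gene_symbol: str = "GeneName"
    processed_signal: str = "gProcessedSignal"
    bg_sub_signal: str = "gBGSubSignal"
    bg_estimate: str = "gBGUsed"
    flag_nonuniform_outlier: str = "gIsFeatNonUnifOL"
    flag_replicate_outlier: str = "gIsFeatPopnOL"
    flag_above_background: str = "gIsWellAboveBG"
    control_type: str = "ControlType"
    negative_control_code: int = -1

    def column_map(self) -> dict:
        """canonical name -> file column name"""
        return {c: getattr(self, c) for c in SPOT_COLUMNS}


DEFAULT_DIALECT = ColumnDialect()


@dataclass
class SpotTable:
    """One array's spot-level records.

    ``data`` holds one row per spot with the canonical :data:`SPOT_COLUMNS`;
    missing gene symbols are NaN (preserved, never dropped). Row order is
    meaningful and preserved by IO.
    """

    sample_id: str
    group: str  # "patient" or "healthy"
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"SpotTable missing columns: {missing}")
        sig = self.data["processed_signal"].to_numpy(dtype=float)
        if not np.all(np.isfinite(sig)):
            raise FormatError(f"{self.sample_id}: non-finite processed_signal")
        if (self.data["probe_id"].astype(str) == "").any():
            raise FormatError(f"{self.sample_id}: empty probe_id")

    @property
    def n_spots(self) -> int:
        return len(self.data)

    def experimental(self) -> pd.DataFrame:
        return self.data[self.data["control_type"] == EXPERIMENTAL]


def _decode_control_type(raw: pd.Series, dialect: ColumnDialect) -> pd.Series:
    code = pd.to_numeric(raw, errors="coerce")
    out = pd.Series(OTHER_CONTROL, index=raw.index, dtype=object)
    out[code == 0] = EXPERIMENTAL
    out[code == dialect.negative_control_code] = NEGATIVE_CONTROL
    return out


def _encode_control_type(ct: pd.Series, dialect: ColumnDialect) -> pd.Series:
    mapping = {
        EXPERIMENTAL: 0,
        NEGATIVE_CONTROL: dialect.negative_control_code,
        OTHER_CONTROL: 1,
    }
    return ct.map(mapping)


def read_spot_table(
    path,
    dialect: ColumnDialect = DEFAULT_DIALECT,
    sample_id: str | None = None,
    group: str | None = None,
) -> SpotTable:
    """Read one tab-delimited spot table.

    Leading ``#key<TAB>value`` comment lines may carry ``sample_id`` and
    ``group``; explicit arguments override them. Flags are parsed from 0/1
    text; a missing mapped column raises :class:`SchemaError` naming it, and
    an unparsable numeric cell raises :class:`FormatError` with its line
    number.
    """
    meta: dict[str, str] = {}
    with open(path, "rt") as fh:
        header_line = 1
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].rstrip("\n").partition("\t")
            meta[key.strip()] = val.strip()
            header_line += 1
            line = fh.readline()
        df = pd.read_csv(
            io.StringIO(line + fh.read()), sep="\t", dtype=str, keep_default_na=False
        )

    colmap = dialect.column_map()
    for canonical, name in colmap.items():
        if name not in df.columns:
            raise SchemaError(f"{path}: missing column '{name}' (for {canonical})")
    df = df.rename(columns={v: k for k, v in colmap.items()})[SPOT_COLUMNS]

    for col in _NUMERIC_COLUMNS + _FLAG_COLUMNS + ["control_type"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & (df[col].astype(str).str.strip() != "")
        blank = df[col].astype(str).str.strip() == ""
        if bad.any() or blank.any():
            row = int(np.flatnonzero((bad | blank).to_numpy())[0])
            raise FormatError(
                f"{path}: unparsable value {df[col].iloc[row]!r} in column "
                f"'{colmap[col]}' at line {header_line + 1 + row}"
            )
        df[col] = vals.astype(float)
    for col in _FLAG_COLUMNS:
        df[col] = df[col] != 0
    df["control_type"] = _decode_control_type(df["control_type"], dialect)
    df["gene_symbol"] = df["gene_symbol"].replace("", np.nan)

    return SpotTable(
        sample_id=sample_id or meta.get("sample_id", str(path)),
        group=group or meta.get("group", "unknown"),
        data=df.reset_index(drop=True),
    )


def write_spot_table(t: SpotTable, path, dialect: ColumnDialect = DEFAULT_DIALECT) -> None:
    """Write a spot table in the (sub)dialect :func:`read_spot_table` consumes.

    ``sample_id`` and ``group`` go into leading ``#`` comment lines so the
    round trip is lossless; row order is preserved.
    """
    df = t.data.copy()
    for col in _FLAG_COLUMNS:
        df[col] = df[col].astype(int)
    df["control_type"] = _encode_control_type(df["control_type"], dialect)
    df["gene_symbol"] = df["gene_symbol"].fillna("")
    for col in _NUMERIC_COLUMNS:
        df[col] = df[col].map(lambda v: format(float(v), ".17g"))
    df = df.rename(columns=dialect.column_map())
    with open(path, "wt") as fh:
        fh.write(f"#sample_id\t{t.sample_id}\n#group\t{t.group}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Gene x sample normalized log2 intensities plus parallel detection calls.

    ``values`` and ``detected`` share index (gene names, unique) and columns
    (sample ids); ``groups`` maps each sample to its cohort label
    ("patient"/"healthy").
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.shape != self.detected.shape:
            raise FormatError(
                f"values {self.values.shape} and detected {self.detected.shape} "
                "dimensions differ"
            )
        if not (
            self.values.index.equals(self.detected.index)
            and self.values.columns.equals(self.detected.columns)
        ):
            raise FormatError("values/detected axes differ")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene names: {dups[:5]}")
        if not self.values.columns.equals(self.groups.index):
            raise FormatError("groups index does not match sample columns")
        det = self.detected.to_numpy(dtype=bool)
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals[det])):
            raise FormatError("non-finite expression value at a detected position")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])


def _detected_path(path) -> str:
    return f"{path}.detected.tsv"


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write values to ``path`` and detection calls to ``<path>.detected.tsv``.

    Values carry 17 significant digits (round trip exact to float64, and in
    particular to 12 significant digits). Group labels live in a ``#groups``
    comment line aligned with the sample columns. Refuses to write a matrix
    violating its invariants.
    """
    m.validate()
    groups_line = "\t".join(["#groups"] + [str(m.groups[s]) for s in m.samples])
    with open(path, "wt") as fh:
        fh.write(groups_line + "\n")
        m.values.to_csv(fh, sep="\t", index_label="gene", float_format="%.17g")
    with open(_detected_path(path), "wt") as fh:
        m.detected.astype(int).to_csv(fh, sep="\t", index_label="gene")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Inverse of :func:`write_expression_matrix` (identity to >=12 sig. digits)."""
    with open(path, "rt") as fh:
        first = fh.readline().rstrip("\n").split("\t")
        if not first or first[0] != "#groups":
            raise FormatError(f"{path}: missing #groups header line")
        body = fh.read()
    values = pd.read_csv(io.StringIO(body), sep="\t", index_col="gene")
    values.index = values.index.astype(str)
    if len(first) - 1 != values.shape[1]:
        raise FormatError(f"{path}: #groups length != number of sample columns")
    groups = pd.Series(first[1:], index=values.columns)
    detected = pd.read_csv(_detected_path(path), sep="\t", index_col="gene")
    detected.index = detected.index.astype(str)
    if detected.shape != values.shape or not detected.index.equals(values.index):
        raise FormatError(f"{path}: detection matrix does not match value matrix")
    detected = detected.astype(bool)
    detected.columns = values.columns
    return ExpressionMatrix(values=values.astype(float), detected=detected, groups=groups)


def find_sample_files(series_dir, pattern: str = "*.txt") -> list:
    """Locate per-sample supplementary spot files under a GEO-series-style
    directory layout (flat or one level of subdirectories). Purely local —
    no network access."""
    from pathlib import Path

    root = Path(series_dir)
    hits = sorted(root.glob(pattern)) + sorted(root.glob(f"*/{pattern}"))
    return [p for p in hits if p.is_file()]
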