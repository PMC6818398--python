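"""Reading, validating, writing and re-aggregating clonotype tables and cohort metadata.

A clonotype table is a tab-separated file with one row per unique TCR-beta
rearrangement: the CDR3 nucleotide sequence, its amino-acid translation, the
V and J gene segments, and a read count.  Three header dialects are accepted
(``native``, ``vdjtools``, ``airr``); frequency columns, if present, are
ignored and recomputed downstream so that upstream normalisation is never
trusted.

Rows that are not productive (a stop codon in the CDR3 amino-acid sequence),
or that fail basic structural checks (invalid nucleotide alphabet, length not
a multiple of three, nt/aa length mismatch, non-positive count), are dropped
and counted in a per-reason rejection tally attached to the returned
:class:`Repertoire` — mirroring a productive-reads-only analysis rather than
aborting on dirty input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "Clonotype",
    "Repertoire",
    "SampleMetadata",
    "ClonotypeFormatError",
    "EmptyRepertoireError",
    "AggregationError",
    "MetadataError",
    "KEY_LEVELS",
    "key_columns",
    "read_clonotype_table",
    "write_repertoire",
    "aggregate",
    "read_metadata",
    "write_metadata",
    "metadata_records",
]

KeyLevel = Literal["nt+VJ", "nt", "aa"]

#: Aggregation levels ordered finest -> coarsest.
KEY_LEVELS: tuple[str, ...] = ("nt+VJ", "nt", "aa")

_LEVEL_RANK = {level: i for i, level in enumerate(KEY_LEVELS)}

_KEY_COLUMNS: dict[str, list[str]] = {
    "nt+VJ": ["cdr3_nt", "v_segment", "j_segment"],
    "nt": ["cdr3_nt"],
    "aa": ["cdr3_aa"],
}

#: Header maps: dialect column name -> canonical column name.
DIALECTS: dict[str, dict[str, str]] = {
    "native": {
        "cdr3_nt": "cdr3_nt",
        "cdr3_aa": "cdr3_aa",
        "v_segment": "v_segment",
        "j_segment": "j_segment",
        "count": "count",
    },
    "vdjtools": {
        "cdr3nt": "cdr3_nt",
        "cdr3aa": "cdr3_aa",
        "v": "v_segment",
        "j": "j_segment",
        "count": "count",
    },
    "airr": {
        "junction": "cdr3_nt",
        "junction_aa": "cdr3_aa",
        "v_call": "v_segment",
        "j_call": "j_segment",
        "duplicate_count": "count",
    },
}

_NT_RE = re.compile(r"^[ACGT]+$")
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


class ClonotypeFormatError(ValueError):
    """A clonotype table does not conform to the declared dialect."""


class EmptyRepertoireError(ValueError):
    """No productive clonotypes survived validation."""


class AggregationError(ValueError):
    """Requested key level is finer than the data supports."""


class MetadataError(ValueError):
    """Cohort metadata failed validation."""


@dataclass(frozen=True)
class Clonotype:
    """One productive TCR-beta rearrangement.

    The CDR3 nucleotide sequence must be in frame (length divisible by 3)
    and its translation free of stop codons.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_segment: str
    j_segment: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if "*" in self.cdr3_aa:
            raise ValueError("unproductive clonotype: stop codon in CDR3 aa")
        if self.cdr3_nt and self.cdr3_aa and len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ValueError("cdr3_nt length must be 3x cdr3_aa length")


def key_columns(key_level: str) -> list[str]:
    """Columns that define clonotype identity at ``key_level``."""
    try:
        return list(_KEY_COLUMNS[key_level])
    except KeyError:
        raise ValueError(f"unknown key level {key_level!r}; expected one of {KEY_LEVELS}") from None


@dataclass
class Repertoire:
    """One sample's clonotype collection, unique under the active key level.

    The table holds one row per clonotype with at least the key columns and
    an integer ``count``. ``total_reads`` is always the column sum, and clone
    frequencies (computed downstream) therefore sum to one.
    """

    sample_id: str
    patient_id: str
    tissue: str
    table: pd.DataFrame
    key_level: str = "nt+VJ"
    rejections: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = key_columns(self.key_level)
        missing = [c for c in cols + ["count"] if c not in self.table.columns]
        if missing:
            raise ClonotypeFormatError(f"repertoire table missing columns: {missing}")
        if len(self.table) == 0:
            raise EmptyRepertoireError(f"sample {self.sample_id}: no clonotypes")
        if (self.table["count"] < 1).any():
            raise ValueError(f"sample {self.sample_id}: non-positive clone counts")
        if self.table.duplicated(subset=cols).any():
            raise ValueError(
                f"sample {self.sample_id}: duplicate clonotype keys at level {self.key_level}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def n_unique(self) -> int:
        return len(self.table)

    @property
    def total_reads(self) -> int:
        return int(self.table["count"].sum())

    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy(dtype=np.int64)

    def keys(self) -> pd.Series:
        """Clonotype identity strings at the active key level."""
        cols = key_columns(self.key_level)
        if len(cols) == 1:
            return self.table[cols[0]].astype(str)
        return self.table[cols].astype(str).agg("|".join, axis=1)


def _strip_allele(names: pd.Series) -> pd.Series:
    # "TRBV11-2*01" -> "TRBV11-2"; segment-level analysis only
    return names.astype(str).str.split("*", n=1).str[0].str.strip()


def read_clonotype_table(
    path: str | Path,
    dialect: str = "native",
    *,
    sample_id: str | None = None,
    patient_id: str | None = None,
    tissue: str = "",
    key_level: str = "nt+VJ",
) -> Repertoire:
    """Read one clonotype TSV into a validated :class:`Repertoire`.

    Rows failing productivity or structural checks are dropped and tallied in
    ``Repertoire.rejections`` (keys: ``unproductive``, ``bad_nt``, ``bad_aa``,
    ``length_mismatch``, ``bad_count``; plus ``accepted`` input rows kept
    before duplicate merging). Duplicate keys are merged by summing counts.

    Raises
    ------
    ClonotypeFormatError
        If a required column for the dialect is missing.
    EmptyRepertoireError
        If no row survives validation.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    colmap = DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise ClonotypeFormatError(
            f"{path.name}: missing required column(s) {missing} for dialect {dialect!r}"
        )
    df = df[list(colmap)].rename(columns=colmap)

    n_input = len(df)
    df["cdr3_nt"] = df["cdr3_nt"].astype(str).str.upper().str.strip()
    df["cdr3_aa"] = df["cdr3_aa"].astype(str).str.strip()
    df["v_segment"] = _strip_allele(df["v_segment"])
    df["j_segment"] = _strip_allele(df["j_segment"])

    count = pd.to_numeric(df["count"], errors="coerce")
    ok_count = count.notna() & (count >= 1) & (count == count.round())
    unproductive = df["cdr3_aa"].str.contains(r"\*", regex=True) | (
        df["cdr3_aa"].isin(["", "nan", "None"])
    )
    ok_nt = df["cdr3_nt"].str.match(_NT_RE) & (df["cdr3_nt"].str.len() % 3 == 0)
    ok_aa = df["cdr3_aa"].str.match(_AA_RE)
    ok_len = df["cdr3_nt"].str.len() == 3 * df["cdr3_aa"].str.len()

    # one rejection reason per row, checked in priority order
    reason = pd.Series("", index=df.index)
    reason[~ok_len] = "length_mismatch"
    reason[~ok_aa & ~unproductive] = "bad_aa"
    reason[~ok_nt] = "bad_nt"
    reason[unproductive] = "unproductive"
    reason[~ok_count] = "bad_count"

    keep = reason == ""
    tally = reason[~keep].value_counts().to_dict()
    tally = {k: int(v) for k, v in tally.items()}
    tally["accepted"] = int(keep.sum())
    assert sum(tally.values()) == n_input

    df = df[keep].copy()
    df["count"] = count[keep].astype(np.int64)
    if len(df) == 0:
        raise EmptyRepertoireError(f"{path.name}: no productive clonotypes after validation")

    cols = key_columns(key_level)
    other = [c for c in ("cdr3_nt", "cdr3_aa", "v_segment", "j_segment") if c not in cols]
    agg = {"count": "sum", **{c: "first" for c in other}}
    df = df.groupby(cols, as_index=False, sort=True).agg(agg)
    df = df[[*cols, *other, "count"]]

    sid = sample_id if sample_id is not None else path.stem
    return Repertoire(
        sample_id=sid,
        patient_id=patient_id if patient_id is not None else sid,
        tissue=tissue,
        table=df,
        key_level=key_level,
        rejections=tally,
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as a native-dialect TSV (key columns, sequences, count)."""
    cols = [c for c in ("cdr3_nt", "cdr3_aa", "v_segment", "j_segment") if c in rep.table.columns]
    out = rep.table[[*cols, "count"]].copy()
    out = out.sort_values(cols, kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def aggregate(rep: Repertoire, new_key_level: str) -> Repertoire:
    """Re-aggregate a repertoire to a coarser clone definition.

    nt+VJ -> nt collapses clones that share a CDR3 nucleotide sequence but
    differ in segment assignment; nt -> aa collapses synonymous rearrangements.
    Counts are summed within the new key, so total reads are preserved and the
    unique-clone count can only shrink.

    Raises :class:`AggregationError` for a refinement request (e.g. aa -> nt).
    """
    if new_key_level not in _LEVEL_RANK:
        raise ValueError(f"unknown key level {new_key_level!r}")
    if _LEVEL_RANK[new_key_level] < _LEVEL_RANK[rep.key_level]:
        raise AggregationError(
            f"cannot refine {rep.key_level!r} to {new_key_level!r}: information lost"
        )
    if new_key_level == rep.key_level:
        return rep
    cols = key_columns(new_key_level)
    missing = [c for c in cols if c not in rep.table.columns]
    if missing:
        raise AggregationError(f"columns {missing} unavailable at level {rep.key_level!r}")
    # cdr3_aa is determined by cdr3_nt, so carrying 'first' is lossless at nt level
    carry = {"cdr3_aa": "first"} if (new_key_level == "nt" and "cdr3_aa" in rep.table) else {}
    df = rep.table.groupby(cols, as_index=False, sort=True).agg({"count": "sum", **carry})
    return Repertoire(
        sample_id=rep.sample_id,
        patient_id=rep.patient_id,
        tissue=rep.tissue,
        table=df,
        key_level=new_key_level,
        rejections=dict(rep.rejections),
    )


# ---------------------------------------------------------------------------
# cohort metadata


@dataclass(frozen=True)
class SampleMetadata:
    """Per-patient clinical covariates and right-censored survival fields."""

    patient_id: str
    age: float
    sex: str
    pathological_type: str
    differentiation: str
    tnm_stage_group: str
    os_time: float | None = None
    os_event: int | None = None
    dfs_time: float | None = None
    dfs_event: int | None = None


_METADATA_REQUIRED = ["patient_id", "age", "sex", "path_type", "differentiation", "tnm_stage"]
_SURVIVAL_COLS = ["os_time", "os_event", "dfs_time", "dfs_event"]
_PATH_TYPES = {"ADC", "SCC", "SCLC"}
_UNKNOWN_DIFF = {"", "-", "–", "—", "na", "nan", "none", "unknown"}
_STAGE_RE = re.compile(r"\(?\s*(III|II|I)\s*\)?\s*$")


def _parse_stage(value: str, row: int) -> str:
    m = _STAGE_RE.search(str(value).strip())
    if not m:
        raise MetadataError(f"row {row}: cannot parse TNM stage group from {value!r}")
    return m.group(1)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort metadata TSV (one row per patient).

    Accepts TNM stage either as a bare group ("III") or a full annotation
    ("T3N2M0 (III)"); differentiation dashes/blanks map to ``unknown``.
    Survival columns are optional as a block.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df) == 0:
        raise MetadataError(f"{path.name}: metadata file has no rows")
    missing = [c for c in _METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise MetadataError(f"{path.name}: missing required column(s) {missing}")
    out = pd.DataFrame()
    out["patient_id"] = df["patient_id"].astype(str).str.strip()
    if out["patient_id"].duplicated().any():
        raise MetadataError(f"{path.name}: duplicate patient_id")

    age = pd.to_numeric(df["age"], errors="coerce")
    if age.isna().any():
        bad = int(age.index[age.isna()][0])
        raise MetadataError(f"row {bad}: non-numeric age {df['age'].iloc[bad]!r}")
    if (age <= 0).any():
        raise MetadataError("age must be positive")
    out["age"] = age.astype(float)

    out["sex"] = df["sex"].astype(str).str.strip().str.capitalize()
    path_type = df["path_type"].astype(str).str.strip().str.upper()
    bad = ~path_type.isin(_PATH_TYPES)
    if bad.any():
        raise MetadataError(
            f"row {int(bad.idxmax())}: unknown pathological type {path_type[bad.idxmax()]!r}"
        )
    out["path_type"] = path_type

    diff = df["differentiation"].astype(str).str.strip()
    diff = diff.where(~diff.str.lower().isin(_UNKNOWN_DIFF), "unknown")
    bad = ~diff.isin({"L", "M", "H", "unknown"})
    if bad.any():
        raise MetadataError(
            f"row {int(bad.idxmax())}: unknown differentiation code {diff[bad.idxmax()]!r}"
        )
    out["differentiation"] = diff

    out["tnm_stage"] = [
        _parse_stage(v, i) for i, v in enumerate(df["tnm_stage"].astype(str))
    ]

    present = [c for c in _SURVIVAL_COLS if c in df.columns]
    for c in present:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise MetadataError(f"column {c}: non-numeric value")
        if c.endswith("_event") and not vals.isin([0, 1]).all():
            raise MetadataError(f"column {c}: event flags must be 0/1")
        if c.endswith("_time") and (vals < 0).any():
            raise MetadataError(f"column {c}: negative time")
        out[c] = vals.astype(int) if c.endswith("_event") else vals.astype(float)
    return out


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def metadata_records(metadata: pd.DataFrame) -> list[SampleMetadata]:
    """View validated metadata rows as :class:`SampleMetadata` records."""
    recs = []
    for row in metadata.itertuples(index=False):
        recs.append(
            SampleMetadata(
                patient_id=row.patient_id,
                age=row.age,
                sex=row.sex,
                pathological_type=row.path_type,
                differentiation=row.differentiation,
                tnm_stage_group=row.tnm_stage,
                os_time=getattr(row, "os_time", None),
                os_event=getattr(row, "os_event", None),
                dfs_time=getattr(row, "dfs_time", None),
                dfs_event=getattr(row, "dfs_event", None),
            )
        )
    return recs
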