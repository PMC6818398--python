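"""TRBV/TRBJ segment and family usage, and tumor-vs-normal differential usage.

Usage of a segment is its share of the repertoire: read-weighted by default
(the share of productive reads carried by clones using the segment), or
clone-weighted (its share of unique clones).  A gene *family* is the segment
name truncated before the sub-family number ("TRBV6-5" -> "TRBV6"); names
without a dash are their own family.

Differential usage between paired tumor and normal samples uses a paired
two-tailed t-test per segment on per-sample frequencies, with the fold change
defined as mean tumor frequency over mean normal frequency.  A segment is
flagged significant only when both the fold-change gate (FC > 1.5 or
FC < 1/1.5) and p < 0.05 hold.  No multiple-testing correction is applied by
default; Benjamini-Hochberg adjusted q-values are available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clonotype_io import Repertoire, EmptyRepertoireError

__all__ = [
    "UsageProfile",
    "merge_to_family",
    "usage_profile",
    "usage_matrix",
    "differential_usage",
    "FC_GATE",
    "PSEUDO_FREQUENCY",
]

#: fold-change gate for calling a segment differentially used
FC_GATE = 1.5
#: floor applied to mean frequencies before forming a ratio (below any
#: plausibly reported segment frequency)
PSEUDO_FREQUENCY = 1e-6

_LOCUS_COLUMN = {"V": "v_segment", "J": "j_segment"}


class NomenclatureError(ValueError):
    """Segment name is not TRB V/J nomenclature."""


@dataclass(frozen=True)
class UsageProfile:
    sample_id: str
    locus: str
    level: str  # "segment" | "family"
    freq: dict[str, float]


def merge_to_family(segment_name: str) -> str:
    """Collapse a TRBV/TRBJ segment name to its gene family.

    Allele suffixes are dropped first, then the name is truncated at the
    first dash: "TRBV6-5*01" -> "TRBV6", "TRBJ2-7" -> "TRBJ2"; names without
    a sub-family number ("TRBV18") are their own family.
    """
    name = str(segment_name).split("*", 1)[0].strip()
    if not (name.startswith("TRBV") or name.startswith("TRBJ")):
        raise NomenclatureError(f"not a TRB V/J segment name: {segment_name!r}")
    return name.split("-", 1)[0]


def usage_profile(
    rep: Repertoire, locus: str = "V", level: str = "segment", weighting: str = "reads"
) -> UsageProfile:
    """Normalised segment (or family) usage frequencies for one sample."""
    if locus not in _LOCUS_COLUMN:
        raise ValueError(f"locus must be 'V' or 'J', got {locus!r}")
    col = _LOCUS_COLUMN[locus]
    if col not in rep.table.columns:
        raise ValueError(f"sample {rep.sample_id}: no {locus} segment calls at level {rep.key_level!r}")
    if len(rep.table) == 0:
        raise EmptyRepertoireError(rep.sample_id)
    names = rep.table[col]
    if level == "family":
        names = names.map(merge_to_family)
    elif level != "segment":
        raise ValueError(f"level must be 'segment' or 'family', got {level!r}")
    if weighting == "reads":
        w = rep.table["count"].astype(float)
    elif weighting == "clones":
        w = pd.Series(1.0, index=rep.table.index)
    else:
        raise ValueError(f"weighting must be 'reads' or 'clones', got {weighting!r}")
    totals = w.groupby(names.to_numpy()).sum()
    freq = (totals / totals.sum()).sort_index()
    return UsageProfile(
        sample_id=rep.sample_id, locus=locus, level=level, freq=freq.to_dict()
    )


def usage_matrix(
    reps: list[Repertoire], locus: str = "V", level: str = "segment", weighting: str = "reads"
) -> pd.DataFrame:
    """Samples x segments frequency matrix; segments absent from a sample are 0."""
    rows = {
        rep.sample_id: usage_profile(rep, locus, level, weighting).freq for rep in reps
    }
    mat = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return mat[sorted(mat.columns)]


def _paired_t(diff: np.ndarray) -> tuple[float, float]:
    # degenerate zero-variance pairs: identical profiles are a clean null
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        return float(np.inf), 0.0
    res = stats.ttest_rel(diff, np.zeros_like(diff))
    return float(res.statistic), float(res.pvalue)


def differential_usage(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    *,
    fc_gate: float = FC_GATE,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-segment paired comparison of usage between matched tissues.

    ``tumor`` and ``normal`` are usage matrices whose rows are aligned by
    patient (same order, one row per patient).  Returns one row per segment:
    mean frequencies, fold change (tumor/normal, with a small pseudo-frequency
    floor against division by zero), the paired t-test p-value, and the
    significance flag ``(FC > fc_gate or FC < 1/fc_gate) and p < alpha``.
    With ``bh_correction`` a ``q_value`` column is added and used for the flag.
    """
    if len(tumor) != len(normal):
        raise ValueError("tumor and normal matrices must have one aligned row per patient")
    if len(tumor) < 2:
        raise ValueError("differential usage needs at least 2 patient pairs")
    segments = sorted(set(tumor.columns) | set(normal.columns))
    t_mat = tumor.reindex(columns=segments, fill_value=0.0)
    n_mat = normal.reindex(columns=segments, fill_value=0.0)

    rows = []
    for seg in segments:
        t_freq = t_mat[seg].to_numpy(dtype=float)
        n_freq = n_mat[seg].to_numpy(dtype=float)
        mean_t, mean_n = float(t_freq.mean()), float(n_freq.mean())
        fc = max(mean_t, PSEUDO_FREQUENCY) / max(mean_n, PSEUDO_FREQUENCY)
        statistic, p = _paired_t(t_freq - n_freq)
        rows.append(
            {
                "segment": seg,
                "mean_freq_tumor": mean_t,
                "mean_freq_normal": mean_n,
                "fold_change": fc,
                "t_statistic": statistic,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    gate = (out["fold_change"] > fc_gate) | (out["fold_change"] < 1.0 / fc_gate)
    if bh_correction:
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
        out["significant"] = gate & (out["q_value"] < alpha)
    else:
        out["significant"] = gate & (out["p_value"] < alpha)
    return out
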