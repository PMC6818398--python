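"""Clone sharing between paired tumor and normal repertoires.

Shared clones are exact string matches of the clone key at the chosen
resolution — CDR3 nucleotide sequence (``nt``) or amino-acid sequence
(``aa``).  The overlap rate is reported per tissue: the percentage of that
tissue's unique clones that are also seen in the matched tissue, so the
tissue with the larger repertoire gets the smaller rate for a fixed
intersection.  Sharing is presence/absence only; abundances do not enter.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clonotype_io import (
    Repertoire,
    EmptyRepertoireError,
    aggregate,
    key_columns,
)

__all__ = ["OverlapResult", "shared_clones", "overlap_rate"]


@dataclass(frozen=True)
class OverlapResult:
    patient_id: str
    key_level: str
    shared_count: int
    rate_a: float
    rate_b: float

    @property
    def rate_tumor(self) -> float:  # convention: repertoire A is tumor
        return self.rate_a

    @property
    def rate_normal(self) -> float:
        return self.rate_b


def _key_set(rep: Repertoire, key_level: str) -> set[str]:
    if rep.key_level != key_level:
        rep = aggregate(rep, key_level)
    col = key_columns(key_level)
    if len(col) == 1:
        return set(rep.table[col[0]].astype(str))
    return set(rep.keys())


def shared_clones(rep_a: Repertoire, rep_b: Repertoire, key_level: str = "nt") -> set[str]:
    """Clone keys present in both repertoires at ``key_level``."""
    return _key_set(rep_a, key_level) & _key_set(rep_b, key_level)


def overlap_rate(rep_a: Repertoire, rep_b: Repertoire, key_level: str = "nt") -> OverlapResult:
    """Per-tissue overlap: rate_X = 100 * |A ∩ B| / n_unique(X) at ``key_level``."""
    keys_a = _key_set(rep_a, key_level)
    keys_b = _key_set(rep_b, key_level)
    if not keys_a or not keys_b:
        raise EmptyRepertoireError("overlap rate undefined for an empty repertoire")
    shared = len(keys_a & keys_b)
    return OverlapResult(
        patient_id=rep_a.patient_id,
        key_level=key_level,
        shared_count=shared,
        rate_a=100.0 * shared / len(keys_a),
        rate_b=100.0 * shared / len(keys_b),
    )
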