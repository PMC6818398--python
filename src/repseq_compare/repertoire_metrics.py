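"""Per-sample repertoire statistics.

Everything here is a function of one sample's clone-size vector (and, for the
spectratype, its CDR3 amino-acid lengths): clone frequencies, the clone-size
frequency spectrum, the highly-expanded-clone (HEC) rate, TOP-N cumulative
frequency, the inverse Simpson diversity index, and the CDR3 length
distribution.

Conventions that matter for reproducibility:

* The HEC rate counts clones whose read frequency is strictly above the
  threshold (default 0.1%) and divides by the number of *unique clones*, not
  by reads.
* Spectrum bins follow the same strictness: a clone exactly on a bin edge
  falls in the lower bin, so the top bin coincides with the HEC definition.
* TOP-N ties are broken by count descending, then clonotype key ascending,
  so listings are deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonotype_io import Repertoire, EmptyRepertoireError

__all__ = [
    "DiversityResult",
    "FrequencySpectrum",
    "SpectratypeDistribution",
    "clone_frequencies",
    "inverse_simpson",
    "hec_rate",
    "frequency_spectrum",
    "top_n_cumulative_frequency",
    "top_clones_table",
    "cdr3_length_distribution",
    "downsample",
    "sample_metrics",
    "DEFAULT_SPECTRUM_EDGES",
]

#: Default spectrum bin edges, in percent of total reads.
DEFAULT_SPECTRUM_EDGES: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 0.1)


@dataclass(frozen=True)
class DiversityResult:
    """Inverse Simpson diversity: the effective number of equally abundant clones."""

    inverse_simpson_di: float
    n_unique: int
    key_level: str


@dataclass(frozen=True)
class FrequencySpectrum:
    """Share of unique clones per frequency bin (percent-scale edges)."""

    bin_edges: tuple[float, ...]
    bin_shares: tuple[float, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        e = self.bin_edges
        mids = [f"({e[i]:g}%,{e[i + 1]:g}%]" for i in range(len(e) - 1)]
        return (f"<={e[0]:g}%", *mids, f">{e[-1]:g}%")


@dataclass(frozen=True)
class SpectratypeDistribution:
    """CDR3 amino-acid length distribution (share of unique clones per length)."""

    shares: dict[int, float]
    mode: int


def _freqs(rep: Repertoire) -> np.ndarray:
    counts = rep.counts()
    total = counts.sum()
    if total <= 0:
        raise EmptyRepertoireError(f"sample {rep.sample_id}: no reads")
    return counts / total


def clone_frequencies(rep: Repertoire) -> np.ndarray:
    """Read frequencies p_i = count_i / total_reads, summing to one."""
    return _freqs(rep)


def inverse_simpson(rep: Repertoire) -> DiversityResult:
    """Inverse Simpson diversity index DI = 1 / sum_i p_i^2.

    DI equals the unique-clone count for a perfectly even repertoire and
    approaches 1 as a single clone dominates.
    """
    p = _freqs(rep)
    di = 1.0 / float(np.sum(p * p))
    return DiversityResult(inverse_simpson_di=di, n_unique=rep.n_unique, key_level=rep.key_level)


def hec_rate(rep: Repertoire, threshold_percent: float = 0.1) -> float:
    """Fraction of unique clones with read frequency strictly above the threshold."""
    if threshold_percent < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold_percent}")
    p = _freqs(rep)
    return float(np.sum(p * 100.0 > threshold_percent)) / rep.n_unique


def frequency_spectrum(
    rep: Repertoire, bin_edges: tuple[float, ...] = DEFAULT_SPECTRUM_EDGES
) -> FrequencySpectrum:
    """Bin unique clones by read frequency (edges in percent).

    A clone exactly on an edge belongs to the lower bin, so the top bin is
    the strict ">last edge" class and matches :func:`hec_rate` at that edge.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0) or np.any(edges <= 0):
        raise ValueError("bin edges must be positive and strictly increasing")
    pct = _freqs(rep) * 100.0
    idx = np.searchsorted(edges, pct, side="left")
    shares = np.bincount(idx, minlength=len(edges) + 1) / rep.n_unique
    return FrequencySpectrum(bin_edges=tuple(edges), bin_shares=tuple(shares))


def _top_order(rep: Repertoire) -> np.ndarray:
    """Row order by count descending, clonotype key ascending (deterministic)."""
    keys = rep.keys().to_numpy()
    counts = rep.counts()
    return np.lexsort((keys, -counts))


def top_n_cumulative_frequency(rep: Repertoire, n: int = 100) -> float:
    """Cumulative read frequency (percent) of the N most abundant clones."""
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    p = _freqs(rep)
    if n >= rep.n_unique:
        return 100.0
    order = _top_order(rep)
    return float(np.sum(p[order[:n]]) * 100.0)


def top_clones_table(rep: Repertoire, n: int = 20) -> pd.DataFrame:
    """Deterministic top-N listing: key columns, count, frequency (descending)."""
    if n < 1:
        raise ValueError(f"N must be >= 1, got {n}")
    p = _freqs(rep)
    order = _top_order(rep)[:n]
    out = rep.table.iloc[order].copy()
    out["frequency"] = p[order]
    return out.reset_index(drop=True)


def cdr3_length_distribution(rep: Repertoire, weighting: str = "clones") -> SpectratypeDistribution:
    """CDR3 aa length distribution, weighted by unique clones (default) or reads."""
    if "cdr3_aa" not in rep.table.columns:
        raise ValueError(f"sample {rep.sample_id}: amino-acid sequences unavailable")
    lengths = rep.table["cdr3_aa"].str.len().to_numpy()
    if weighting == "clones":
        w = np.ones(len(lengths))
    elif weighting == "reads":
        w = rep.counts().astype(float)
    else:
        raise ValueError(f"weighting must be 'clones' or 'reads', got {weighting!r}")
    totals: dict[int, float] = {}
    for length, weight in zip(lengths, w):
        totals[int(length)] = totals.get(int(length), 0.0) + float(weight)
    z = sum(totals.values())
    shares = {length: weight / z for length, weight in sorted(totals.items())}
    mode = max(shares, key=lambda length: (shares[length], -length))
    return SpectratypeDistribution(shares=shares, mode=mode)


def downsample(rep: Repertoire, n_reads: int, rng: np.random.Generator) -> Repertoire:
    """Multinomially subsample reads; clones drawn zero times are dropped."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    p = _freqs(rep)
    new_counts = rng.multinomial(n_reads, p)
    keep = new_counts > 0
    table = rep.table[keep].copy()
    table["count"] = new_counts[keep]
    return Repertoire(
        sample_id=rep.sample_id,
        patient_id=rep.patient_id,
        tissue=rep.tissue,
        table=table,
        key_level=rep.key_level,
    )


def sample_metrics(
    rep: Repertoire,
    hec_threshold_percent: float = 0.1,
    top_n: int = 100,
    spectrum_edges: tuple[float, ...] = DEFAULT_SPECTRUM_EDGES,
) -> dict[str, float]:
    """Tidy bundle of the per-sample statistics used in cohort comparisons."""
    from .clonotype_io import aggregate  # local import to avoid cycle at module load

    di = inverse_simpson(rep)
    spectrum = frequency_spectrum(rep, spectrum_edges)
    spectra = cdr3_length_distribution(rep) if "cdr3_aa" in rep.table.columns else None
    metrics: dict[str, float] = {
        "productive_reads": float(rep.total_reads),
        "unique_clones": float(rep.n_unique),
        "inverse_simpson_di": di.inverse_simpson_di,
        "hec_rate_pct": hec_rate(rep, hec_threshold_percent) * 100.0,
        f"top{top_n}_cumulative_pct": top_n_cumulative_frequency(rep, top_n),
    }
    if "cdr3_nt" in rep.table.columns:
        metrics["unique_nt_clones"] = float(aggregate(rep, "nt").n_unique)
    if "cdr3_aa" in rep.table.columns:
        metrics["unique_aa_clones"] = float(aggregate(rep, "aa").n_unique)
    for label, share in zip(spectrum.labels, spectrum.bin_shares):
        metrics[f"spectrum{label}"] = share
    if spectra is not None:
        metrics["cdr3_length_mode"] = float(spectra.mode)
    return metrics
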