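"""Synthetic paired tumor/normal TCR-beta cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale: heavy-tailed clone abundances (Zipf or lognormal
law), partial clone sharing between a patient's two tissues, CDR3 amino-acid
lengths on 8-23 with a configurable peak (default 15), and skewed V/J segment
usage whose default profile follows the dominant segments reported for lung
tissue repertoires (TRBV11-2, TRBV29-1, TRBV20-1, TRBV6-5, TRBV12-3;
TRBJ2-1, TRBJ2-7, TRBJ2-3, TRBJ2-5).

CDR3 nucleotide sequences are sampled codon-wise from the 61 sense codons, so
every generated clonotype is productive by construction and the amino-acid
translation is consistent with the nucleotide sequence.

Under the default configuration the tumor abundance law is flatter than the
normal-tissue law (Zipf exponent 1.05 vs 1.25), which makes tumor diversity
higher and the normal highly-expanded-clone rate higher — the qualitative
paired contrast the pipeline is designed to detect.  Patients older than 60
get a steeper tumor law (lower diversity), and survival times are exponential
with a hazard ratio applied to the high-diversity half of the cohort.

Everything is deterministic given the config seed: the same config produces
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clonotype_io import Repertoire, write_metadata, write_repertoire

__all__ = [
    "AbundanceLaw",
    "SurvivalConfig",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_clone_pool",
    "assign_abundances",
    "generate_paired_cohort",
    "write_cohort",
    "DEFAULT_V_PROFILE",
    "DEFAULT_J_PROFILE",
    "TRBV_SEGMENTS",
    "TRBJ_SEGMENTS",
]

# ---------------------------------------------------------------------------
# genetic code: codon order TTT, TTC, ... (base order T, C, A, G)

_BASES = "TCAG"
_CODON_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_SENSE = [(cod, aa) for cod, aa in zip(_ALL_CODONS, _CODON_AA) if aa != "*"]
N_SENSE_CODONS = len(_SENSE)  # 61
_SENSE_NT = np.frombuffer("".join(c for c, _ in _SENSE).encode("ascii"), dtype=np.uint8).reshape(
    N_SENSE_CODONS, 3
)
_SENSE_AA = np.frombuffer("".join(a for _, a in _SENSE).encode("ascii"), dtype=np.uint8)

# ---------------------------------------------------------------------------
# default locus composition: 46 functional TRBV segments (23 families),
# 13 TRBJ segments (2 families)

TRBV_SEGMENTS: tuple[str, ...] = (
    "TRBV11-2", "TRBV29-1", "TRBV20-1", "TRBV6-5", "TRBV12-3",
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV4-2", "TRBV4-3",
    "TRBV5-1", "TRBV5-4", "TRBV5-5", "TRBV5-6",
    "TRBV6-1", "TRBV6-2", "TRBV6-3", "TRBV6-4", "TRBV6-6", "TRBV6-8",
    "TRBV7-2", "TRBV7-3", "TRBV7-4", "TRBV7-6", "TRBV7-7", "TRBV7-8", "TRBV7-9",
    "TRBV9", "TRBV10-1", "TRBV10-2", "TRBV10-3",
    "TRBV11-1", "TRBV11-3", "TRBV12-4", "TRBV12-5",
    "TRBV13", "TRBV14", "TRBV15", "TRBV16", "TRBV18", "TRBV19",
    "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28", "TRBV30",
)

TRBJ_SEGMENTS: tuple[str, ...] = (
    "TRBJ2-1", "TRBJ2-7", "TRBJ2-3", "TRBJ2-5",
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-2", "TRBJ2-4", "TRBJ2-6",
)


def _decaying_profile(named: dict[str, float], all_names: tuple[str, ...], decay: float) -> dict[str, float]:
    rest = [s for s in all_names if s not in named]
    leftover = 1.0 - sum(named.values())
    weights = np.array([decay**i for i in range(len(rest))])
    weights *= leftover / weights.sum()
    profile = dict(named)
    profile.update({s: float(w) for s, w in zip(rest, weights)})
    return {s: profile[s] for s in all_names}


#: default segment usage, anchored on the dominant lung-repertoire segments
DEFAULT_V_PROFILE: dict[str, float] = _decaying_profile(
    {"TRBV11-2": 0.1525, "TRBV29-1": 0.1008, "TRBV20-1": 0.0816, "TRBV6-5": 0.0707, "TRBV12-3": 0.0681},
    TRBV_SEGMENTS,
    decay=0.92,
)
DEFAULT_J_PROFILE: dict[str, float] = _decaying_profile(
    {"TRBJ2-1": 0.1878, "TRBJ2-7": 0.1758, "TRBJ2-3": 0.1167, "TRBJ2-5": 0.0995},
    TRBJ_SEGMENTS,
    decay=0.85,
)


@dataclass
class AbundanceLaw:
    """Clone-size law: ``zipf`` (p_r proportional to r^-alpha) or ``lognormal``."""

    kind: str = "zipf"
    alpha: float = 1.0
    mu: float = 0.0
    sigma: float = 1.0

    def probabilities(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "zipf":
            if self.alpha < 0:
                raise ValueError(f"zipf exponent must be >= 0, got {self.alpha}")
            w = np.arange(1, n + 1, dtype=float) ** -self.alpha
        elif self.kind == "lognormal":
            if self.sigma <= 0:
                raise ValueError(f"lognormal sigma must be > 0, got {self.sigma}")
            w = rng.lognormal(self.mu, self.sigma, size=n)
        else:
            raise ValueError(f"unknown abundance law {self.kind!r}")
        return w / w.sum()


@dataclass
class SurvivalConfig:
    """Exponential survival: baseline hazard for the low-diversity group, a
    hazard ratio for the high-diversity group, and exponential censoring."""

    baseline_hazard: float = 0.02  # events per month
    hazard_ratio_high_di: float = 3.0
    censoring_hazard: float = 0.01

    def validate(self) -> None:
        if self.baseline_hazard <= 0 or self.censoring_hazard <= 0:
            raise ValueError("hazards must be positive")
        if self.hazard_ratio_high_di <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class SyntheticCohortConfig:
    """All generator knobs for a paired tumor/normal cohort."""

    n_patients: int = 15
    clones_tumor: int = 50_000
    clones_normal: int = 40_000
    reads_per_sample: int = 500_000
    reads_jitter: float = 0.2  # per-sample depth ~ Uniform(1 +/- jitter) * reads_per_sample
    tumor_law: AbundanceLaw = field(default_factory=lambda: AbundanceLaw("zipf", alpha=1.05))
    normal_law: AbundanceLaw = field(default_factory=lambda: AbundanceLaw("zipf", alpha=1.25))
    shared_fraction: float = 0.25
    v_profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_V_PROFILE))
    j_profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_J_PROFILE))
    cdr3_length_peak: int = 15
    cdr3_length_sd: float = 2.5
    cdr3_length_min: int = 8
    cdr3_length_max: int = 23
    age_effect_on_di: float = 0.15  # relative steepening of the tumor law for age > 60
    tumor_v_boost: dict[str, float] = field(default_factory=dict)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if min(self.clones_tumor, self.clones_normal) < 1:
            raise ValueError("clone counts must be positive")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0.0 <= self.reads_jitter < 1.0:
            raise ValueError("reads_jitter must be in [0, 1)")
        for name, profile in (("v_profile", self.v_profile), ("j_profile", self.j_profile)):
            total = sum(profile.values())
            if abs(total - 1.0) > 1e-6 or min(profile.values()) < 0:
                raise ValueError(f"{name} must be a normalised probability map (sum={total})")
        if not 1 <= self.cdr3_length_min <= self.cdr3_length_peak <= self.cdr3_length_max:
            raise ValueError("require length_min <= length_peak <= length_max")
        self.survival.validate()

    def length_law(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete CDR3 aa length distribution peaking at ``cdr3_length_peak``."""
        lengths = np.arange(self.cdr3_length_min, self.cdr3_length_max + 1)
        w = np.exp(-0.5 * ((lengths - self.cdr3_length_peak) / self.cdr3_length_sd) ** 2)
        return lengths, w / w.sum()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("tumor_law", "normal_law"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = AbundanceLaw(**raw[key])
        if isinstance(raw.get("survival"), dict):
            raw["survival"] = SurvivalConfig(**raw["survival"])
        config = cls(**raw)
        config.validate()
        return config


def _random_cdr3(lengths: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised productive CDR3 generation for an array of aa lengths."""
    n = len(lengths)
    nt_out = np.empty(n, dtype=object)
    aa_out = np.empty(n, dtype=object)
    for length in np.unique(lengths):
        idx = np.flatnonzero(lengths == length)
        codons = rng.integers(0, N_SENSE_CODONS, size=(len(idx), length))
        nt_bytes = _SENSE_NT[codons].reshape(len(idx), 3 * length)
        aa_bytes = _SENSE_AA[codons]
        nt_out[idx] = np.char.decode(np.ascontiguousarray(nt_bytes).view(f"S{3 * length}")[:, 0], "ascii")
        aa_out[idx] = np.char.decode(np.ascontiguousarray(aa_bytes).view(f"S{length}")[:, 0], "ascii")
    return nt_out, aa_out


def generate_clone_pool(
    n_clones: int,
    v_profile: dict[str, float],
    j_profile: dict[str, float],
    length_law: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Sample ``n_clones`` unique productive clonotypes.

    Returns a frame with cdr3_nt, cdr3_aa (consistent translation), v_segment
    and j_segment; nucleotide sequences are unique within the pool and
    disjoint from ``exclude``.
    """
    lengths, length_probs = length_law
    if n_clones == 0:
        return pd.DataFrame(
            {c: pd.Series(dtype=object) for c in ("cdr3_nt", "cdr3_aa", "v_segment", "j_segment")}
        )
    capacity = float(sum(61.0**int(l) for l, p in zip(lengths, length_probs) if p > 0))
    if n_clones > capacity / 2:
        raise ValueError(f"requested {n_clones} clones exceeds sequence-space bound")
    taken: set[str] = set(exclude) if exclude else set()
    nt_parts: list[np.ndarray] = []
    aa_parts: list[np.ndarray] = []
    remaining = n_clones
    while remaining > 0:
        draw_lengths = rng.choice(lengths, size=remaining, p=length_probs)
        nt, aa = _random_cdr3(draw_lengths, rng)
        fresh = ~pd.Index(nt).isin(taken) & ~pd.Series(nt).duplicated().to_numpy()
        nt, aa = nt[fresh], aa[fresh]
        taken.update(nt.tolist())
        nt_parts.append(nt)
        aa_parts.append(aa)
        remaining -= len(nt)
    nt_all = np.concatenate(nt_parts)[:n_clones]
    aa_all = np.concatenate(aa_parts)[:n_clones]
    v_names, v_probs = zip(*v_profile.items())
    j_names, j_probs = zip(*j_profile.items())
    return pd.DataFrame(
        {
            "cdr3_nt": nt_all,
            "cdr3_aa": aa_all,
            "v_segment": rng.choice(np.array(v_names, dtype=object), size=n_clones, p=v_probs),
            "j_segment": rng.choice(np.array(j_names, dtype=object), size=n_clones, p=j_probs),
        }
    )


def assign_abundances(
    pool: pd.DataFrame,
    law: AbundanceLaw,
    reads: int,
    rng: np.random.Generator,
    *,
    sample_id: str = "sample",
    patient_id: str = "patient",
    tissue: str = "",
) -> Repertoire:
    """Give pool clones heavy-tailed abundances and draw multinomial reads.

    Law ranks are assigned to clones in random order, and clones drawn zero
    times are absent from the returned repertoire (as they would be unseen in
    sequencing).
    """
    if reads < 1:
        raise ValueError("reads must be >= 1")
    n = len(pool)
    probs = law.probabilities(n, rng)[rng.permutation(n)]
    counts = rng.multinomial(reads, probs)
    keep = counts > 0
    table = pool.loc[keep].copy()
    table["count"] = counts[keep]
    return Repertoire(
        sample_id=sample_id, patient_id=patient_id, tissue=tissue, table=table, key_level="nt+VJ"
    )


@dataclass
class SyntheticCohort:
    repertoires: list[Repertoire]
    metadata: pd.DataFrame
    config: SyntheticCohortConfig

    def repertoire(self, patient_id: str, tissue: str) -> Repertoire:
        for rep in self.repertoires:
            if rep.patient_id == patient_id and rep.tissue == tissue:
                return rep
        raise KeyError(f"no {tissue} repertoire for patient {patient_id}")


def _boosted(profile: dict[str, float], boost: dict[str, float]) -> dict[str, float]:
    if not boost:
        return profile
    out = {s: p * boost.get(s, 1.0) for s, p in profile.items()}
    z = sum(out.values())
    return {s: p / z for s, p in out.items()}


def generate_paired_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate the full paired cohort: 2 repertoires per patient plus metadata.

    Each tumor pool contains ``shared_fraction`` of the matched normal pool
    (identical nucleotide sequences and segment calls) topped up with private
    clones; abundances are drawn independently per tissue, so sharing is
    presence/absence only.  Survival times are tied to the tumor-diversity
    median split.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    length_law = config.length_law()
    tumor_v = _boosted(config.v_profile, config.tumor_v_boost)

    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    ages = rng.integers(31, 77, size=config.n_patients)
    sexes = rng.choice(np.array(["Male", "Female"], dtype=object), size=config.n_patients, p=[0.7, 0.3])
    path_types = rng.choice(
        np.array(["ADC", "SCC", "SCLC"], dtype=object), size=config.n_patients, p=[0.8, 0.13, 0.07]
    )
    diffs = rng.choice(
        np.array(["L", "M", "H", "unknown"], dtype=object), size=config.n_patients, p=[0.5, 0.3, 0.15, 0.05]
    )
    stages = rng.choice(np.array(["I", "II", "III"], dtype=object), size=config.n_patients, p=[0.5, 0.15, 0.35])

    repertoires: list[Repertoire] = []
    n_shared = int(round(config.shared_fraction * config.clones_normal))
    for i, pid in enumerate(patients):
        normal_pool = generate_clone_pool(
            config.clones_normal, config.v_profile, config.j_profile, length_law, rng
        )
        shared_idx = rng.choice(config.clones_normal, size=n_shared, replace=False)
        shared = normal_pool.iloc[np.sort(shared_idx)]
        private = generate_clone_pool(
            config.clones_tumor - n_shared,
            tumor_v,
            config.j_profile,
            length_law,
            rng,
            exclude=set(normal_pool["cdr3_nt"]),
        )
        tumor_pool = pd.concat([shared, private], ignore_index=True)

        tumor_law = config.tumor_law
        if ages[i] > 60 and config.age_effect_on_di != 0 and tumor_law.kind == "zipf":
            tumor_law = AbundanceLaw("zipf", alpha=tumor_law.alpha * (1 + config.age_effect_on_di))
        jitter = config.reads_jitter
        reads_t, reads_n = (
            max(1, int(round(config.reads_per_sample * rng.uniform(1 - jitter, 1 + jitter))))
            for _ in range(2)
        )
        repertoires.append(
            assign_abundances(
                tumor_pool, tumor_law, reads_t, rng,
                sample_id=f"{pid}_T", patient_id=pid, tissue="tumor",
            )
        )
        repertoires.append(
            assign_abundances(
                normal_pool, config.normal_law, reads_n, rng,
                sample_id=f"{pid}_N", patient_id=pid, tissue="normal",
            )
        )

    # survival tied to tumor diversity: high-DI half gets the hazard ratio
    from .repertoire_metrics import inverse_simpson
    from .cohort_stats import median_split

    tumor_di = pd.Series(
        [inverse_simpson(rep).inverse_simpson_di for rep in repertoires if rep.tissue == "tumor"],
        index=patients,
    )
    high = (median_split(tumor_di) == "high").to_numpy() if config.n_patients >= 2 else np.zeros(1, bool)
    surv = config.survival
    hazards = surv.baseline_hazard * np.where(high, surv.hazard_ratio_high_di, 1.0)
    t_event = rng.exponential(1.0 / hazards)
    t_censor = rng.exponential(1.0 / surv.censoring_hazard, size=config.n_patients)
    t_progress = rng.exponential(1.0 / (1.4 * hazards))
    os_time = np.maximum(np.round(np.minimum(t_event, t_censor), 1), 0.1)
    os_event = (t_event <= t_censor).astype(int)
    dfs_raw = np.minimum(t_progress, t_event)
    dfs_time = np.maximum(np.round(np.minimum(dfs_raw, t_censor), 1), 0.1)
    dfs_event = (dfs_raw <= t_censor).astype(int)

    metadata = pd.DataFrame(
        {
            "patient_id": patients,
            "age": ages.astype(float),
            "sex": sexes,
            "path_type": path_types,
            "differentiation": diffs,
            "tnm_stage": stages,
            "os_time": os_time,
            "os_event": os_event,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
        }
    )
    return SyntheticCohort(repertoires=repertoires, metadata=metadata, config=config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> list[Path]:
    """Write one clonotype TSV per sample plus metadata.tsv; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rep in cohort.repertoires:
        path = out_dir / f"{rep.sample_id}.tsv"
        write_repertoire(rep, path)
        paths.append(path)
    meta_path = out_dir / "metadata.tsv"
    write_metadata(cohort.metadata, meta_path)
    paths.append(meta_path)
    return paths
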