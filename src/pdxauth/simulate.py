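"""Synthetic-data generator for every authentication scenario.

Generates pure Hardy-Weinberg barcode cohorts, two- and three-source DNA
mixtures at arbitrary fractions, copy-number allelic imbalance, sex-linked
Y-assay dropout, and amplification-inefficiency noise — so the whole
authentication pipeline is testable without an instrument.

All genotype-level randomness is Hardy-Weinberg at per-locus allele-1
frequencies (default 0.5 everywhere, the maximum-entropy assumption for a
human-identification panel).  Mixtures operate on allele *template amounts*
(copies per diploid genome: HOM1=(2,0), HET=(1,1), HOM2=(0,2), hemizygous
male Y=(1,0)), which makes mixtures and copy-number variants composable:
the template of a mixture is the fraction-weighted sum of the contributors'
dosages.  DNA is mixed as purified template, not cells.

Determinism: identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .panel import (
    Category,
    GenotypeCall,
    Sex,
    SNPAssay,
    SNPProfile,
    default_panel,
    infer_sex,
)
from .signal import SignalTrace

#: Allele template copies per diploid genome for an autosomal call.
DOSAGE = {
    Category.HOM1: (2.0, 0.0),
    Category.HET: (1.0, 1.0),
    Category.HOM2: (0.0, 2.0),
    Category.NOAMP: (0.0, 0.0),
    Category.UNDET: (1.0, 1.0),  # best guess; contributors should be determined
}


@dataclass(frozen=True, slots=True)
class NoiseModel:
    """Amplification noise: multiplicative plateau scatter, additive baseline
    fluorescence, and Gaussian jitter on the threshold-crossing cycle."""

    plateau_cv: float = 0.05
    baseline_sd: float = 2.0
    ct_sd: float = 0.1


@dataclass(slots=True)
class SimulationConfig:
    """Study conditions for synthetic cohorts and traces.

    ``allele_freqs`` are per-locus allele-1 frequencies (length ``n_loci``;
    default 0.5 everywhere).  ``ct0`` is the threshold-crossing cycle of a
    full diploid template; ``plateau`` the endpoint fluorescence of a full
    template; ``anchor_threshold`` the instrument detection threshold that
    defines Ct.
    """

    n_loci: int = 32
    allele_freqs: tuple[float, ...] | None = None
    female_fraction: float = 0.5
    cycles: int = 40
    ct0: float = 24.0
    plateau: float = 1000.0
    growth_rate: float = math.log(2.0)
    anchor_threshold: float = 10.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.allele_freqs is not None:
            self.allele_freqs = tuple(float(f) for f in self.allele_freqs)
            if len(self.allele_freqs) != self.n_loci:
                raise ValueError("allele_freqs length must equal n_loci")
            if any(not 0.0 < f <= 1.0 for f in self.allele_freqs):
                raise ValueError("allele frequencies must be in (0, 1]")
        for name in ("cycles", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0,1]")

    @property
    def freqs(self) -> np.ndarray:
        if self.allele_freqs is None:
            return np.full(self.n_loci, 0.5)
        return np.asarray(self.allele_freqs, dtype=float)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        if d.get("allele_freqs") is not None:
            d["allele_freqs"] = tuple(d["allele_freqs"])
        return cls(**d)


@dataclass(frozen=True, slots=True)
class MixtureSpec:
    """Two- or three-contributor mixture; fractions must sum to one."""

    contributors: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.contributors) <= 3:
            raise ValueError("1-3 contributors required")
        if any(f <= 0 for _, f in self.contributors):
            raise ValueError("fractions must be > 0")
        total = sum(f for _, f in self.contributors)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    @property
    def fractions(self) -> dict[str, float]:
        return dict(self.contributors)


# --- genotype-level simulation ---------------------------------------------


def simulate_profiles(
    config: SimulationConfig,
    n_samples: int,
    assays: tuple[SNPAssay, ...] | None = None,
    rng: np.random.Generator | None = None,
    sexes: list[Sex] | None = None,
) -> list[SNPProfile]:
    """Draw pure barcode profiles under HWE at the configured allele frequencies.

    Autosomal genotypes are HOM1/HET/HOM2 with probabilities (p², 2pq, q²);
    Y-linked assays are hemizygous single-allele calls in males and NOAMP in
    females.  Sexes are drawn with ``config.female_fraction`` unless given.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if assays is None:
        assays = default_panel(config.n_loci)
    if len(assays) != config.n_loci:
        raise ValueError("panel size must equal config.n_loci")
    p = config.freqs
    y_mask = np.array([a.y_linked for a in assays])
    if sexes is None:
        female = rng.random(n_samples) < config.female_fraction
        sexes = [Sex.FEMALE if f else Sex.MALE for f in female]
    elif len(sexes) != n_samples:
        raise ValueError("sexes length must equal n_samples")

    u = rng.random((n_samples, config.n_loci))
    hom1 = u < p**2
    het = (~hom1) & (u < p**2 + 2 * p * (1 - p))
    codes = np.where(hom1, 0, np.where(het, 1, 2))  # 0=HOM1 1=HET 2=HOM2
    uy = rng.random((n_samples, config.n_loci))  # only Y columns consumed

    cat_by_code = {0: Category.HOM1, 1: Category.HET, 2: Category.HOM2}
    profiles = []
    for i in range(n_samples):
        calls: dict[str, GenotypeCall] = {}
        for j, assay in enumerate(assays):
            if y_mask[j]:
                if sexes[i] is Sex.FEMALE:
                    calls[assay.assay_id] = GenotypeCall(Category.NOAMP)
                else:
                    cat = Category.HOM1 if uy[i, j] < p[j] else Category.HOM2
                    calls[assay.assay_id] = GenotypeCall(cat)
            else:
                calls[assay.assay_id] = GenotypeCall(cat_by_code[int(codes[i, j])])
        prof = SNPProfile(sample_id=f"sim-{i:05d}", calls=calls)
        prof.inferred_sex = infer_sex(prof, [a.assay_id for a in assays if a.y_linked])
        profiles.append(prof)
    return profiles


def profile_dosage(
    profile: SNPProfile, assays: tuple[SNPAssay, ...]
) -> np.ndarray:
    """Allele template amounts (n_loci, 2) in copies per diploid genome.

    Y-linked loci in males are hemizygous (one copy of the called allele);
    copy-number variants are expressed by passing explicit dosages to
    :func:`simulate_traces` instead.
    """
    out = np.zeros((len(assays), 2))
    male = profile.inferred_sex is Sex.MALE
    for j, assay in enumerate(assays):
        d = DOSAGE[profile.category(assay.assay_id)]
        if assay.y_linked and male:
            d = (d[0] / 2.0, d[1] / 2.0)
        out[j] = d
    return out


# --- trace-level simulation -------------------------------------------------


def _logistic_traces(
    dosage: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Realize the per-channel logistic model for a dosage matrix (L, 2).

    Returns fluorescence of shape (L, 2, cycles).  Each channel with template
    amount a crosses ``config.anchor_threshold`` at ``ct0 - log2(a/2)``
    (plus Ct jitter) and plateaus at ``plateau * a/2`` (times plateau noise);
    channels whose plateau never reaches the threshold stay sub-threshold.
    """
    a = np.asarray(dosage, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or (a < 0).any():
        raise ValueError("dosage must be (n_loci, 2) and non-negative")
    L, C, k, T = a.shape[0], config.cycles, config.growth_rate, config.anchor_threshold
    nz = a > 0
    plateau = config.plateau * (a / 2.0)
    plateau = plateau * np.clip(rng.normal(1.0, config.noise.plateau_cv, a.shape), 0.0, None)
    ct = np.where(nz, config.ct0 - np.log2(np.where(nz, a, 1.0) / 2.0), 0.0)
    ct = ct + rng.normal(0.0, config.noise.ct_sd, a.shape)
    # anchor the sigmoid midpoint so the curve crosses T exactly at ct
    crossing_ok = plateau > T * 1.001
    mid = np.where(
        crossing_ok,
        ct + np.log(np.clip(plateau / T - 1.0, 1e-9, None)) / k,
        ct + 3.0,  # sub-threshold channel: rises around its Ct but never crosses
    )
    cyc = np.arange(1, C + 1, dtype=float)
    f = plateau[:, :, None] / (1.0 + np.exp(-k * (cyc[None, None, :] - mid[:, :, None])))
    f = np.where(nz[:, :, None], f, 0.0)
    f = f + rng.normal(0.0, config.noise.baseline_sd, f.shape)
    return np.clip(f, 0.0, None)


def simulate_traces(
    dosage: np.ndarray | dict[str, tuple[float, float]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    assays: tuple[SNPAssay, ...] | None = None,
) -> dict[str, SignalTrace]:
    """Generate one trace per locus from allele template amounts.

    *dosage* is either an (n_loci, 2) array aligned with *assays* or a map
    ``assay_id -> (a1, a2)``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if assays is None:
        assays = default_panel(config.n_loci)
    if isinstance(dosage, dict):
        dosage = np.array([dosage[a.assay_id] for a in assays])
    f = _logistic_traces(dosage, config, rng)
    return {
        assay.assay_id: SignalTrace(assay.assay_id, f[j, 0], f[j, 1])
        for j, assay in enumerate(assays)
    }


def traces_for_profile(
    profile: SNPProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    assays: tuple[SNPAssay, ...] | None = None,
) -> dict[str, SignalTrace]:
    """Pure-sample traces realizing a profile's genotype calls."""
    if assays is None:
        assays = default_panel(config.n_loci)
    return simulate_traces(profile_dosage(profile, assays), config, rng, assays)


def mixture_dosage(
    profiles: list[SNPProfile],
    spec: MixtureSpec,
    assays: tuple[SNPAssay, ...],
) -> np.ndarray:
    """Fraction-weighted allele template of a multi-contributor mixture (exact, pre-noise)."""
    by_id = {p.sample_id: p for p in profiles}
    total = np.zeros((len(assays), 2))
    for rid, frac in spec.contributors:
        if rid not in by_id:
            raise KeyError(f"contributor {rid!r} not among supplied profiles")
        total += frac * profile_dosage(by_id[rid], assays)
    return total


def simulate_mixture(
    profiles: list[SNPProfile],
    spec: MixtureSpec,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    assays: tuple[SNPAssay, ...] | None = None,
) -> dict[str, SignalTrace]:
    """Traces of a DNA mixture of 1-3 contributor profiles."""
    if assays is None:
        assays = default_panel(config.n_loci)
    return simulate_traces(mixture_dosage(profiles, spec, assays), config, rng, assays)


def simulate_inefficiency(
    traces: dict[str, SignalTrace],
    dropout_rate: float,
    attenuation: float,
    rng: np.random.Generator | None = None,
) -> dict[str, SignalTrace]:
    """Attenuate randomly selected loci without changing allele ratios.

    Each locus is attenuated with probability *dropout_rate*; both channels
    are scaled by *attenuation*, producing UNDET (weak) or NOAMP calls with
    near-canonical angles — contamination-free undetermined genotypes.
    """
    if not 0.0 <= dropout_rate <= 1.0 or not 0.0 <= attenuation <= 1.0:
        raise ValueError("rates must be in [0,1]")
    rng = rng if rng is not None else np.random.default_rng(0)
    out: dict[str, SignalTrace] = {}
    for aid, tr in traces.items():
        if rng.random() < dropout_rate:
            out[aid] = SignalTrace(aid, tr.f1 * attenuation, tr.f2 * attenuation)
        else:
            out[aid] = SignalTrace(aid, tr.f1.copy(), tr.f2.copy())
    return out


def attenuate_loci(
    traces: dict[str, SignalTrace], assay_ids: list[str], attenuation: float
) -> dict[str, SignalTrace]:
    """Deterministically attenuate the named loci (helper for staged scenarios)."""
    out = {}
    for aid, tr in traces.items():
        scale = attenuation if aid in assay_ids else 1.0
        out[aid] = SignalTrace(aid, tr.f1 * scale, tr.f2 * scale)
    return out
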