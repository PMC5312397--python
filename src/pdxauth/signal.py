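"""Two-channel biallelic amplification signals: summaries, calls, evidence.

Model
-----
Each biallelic assay reports two fluorescence channels, one per allele probe,
over ``cycles`` qPCR cycles.  Writing ``a = (a1, a2)`` for the allele template
amounts in copies per diploid genome-equivalent (a pure heterozygote is
(1, 1), a hemizygous male Y locus (1, 0), a 1/32 contaminant of an opposite
homozygote contributes 2/32 of a copy), each channel follows a logistic
curve that

* crosses the detection (rise) threshold at ``Ct_i = ct0 - log2(a_i / 2)``
  — the canonical one-cycle-per-doubling Ct law, and
* plateaus at a level proportional to its template amount,
  ``plateau_i = P * a_i / 2``.

Two consequences drive everything downstream: the endpoint of the allelic
discrimination trajectory sits at angle ``atan2(a2, a1)`` (homozygotes on the
axes, heterozygotes on the diagonal, copy-number imbalance in between), and a
minor contaminating allele at fraction f rises ``~log2(1/f)`` cycles after
the major allele — the "late amplification of the opposite allele" signature
that makes small mixtures detectable even when the endpoint looks canonical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .panel import Category, DETERMINED, GenotypeCall

#: Canonical allelic-discrimination angles (degrees) of the three genotypes.
CANONICAL_ANGLES = {Category.HOM1: 0.0, Category.HET: 45.0, Category.HOM2: 90.0}


@dataclass(slots=True)
class SignalTrace:
    """Per-cycle two-channel fluorescence of one sample x assay."""

    assay_id: str
    f1: np.ndarray  # allele-1 channel, arbitrary units >= 0
    f2: np.ndarray  # allele-2 channel

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        if self.f1.shape != self.f2.shape or self.f1.ndim != 1:
            raise ValueError("f1 and f2 must be 1-D arrays of equal length")
        if (self.f1 < 0).any() or (self.f2 < 0).any():
            raise ValueError("fluorescence must be non-negative")

    @property
    def cycles(self) -> int:
        return len(self.f1)


@dataclass(frozen=True, slots=True)
class EndpointSummary:
    """Endpoint geometry and rise cycles of one trace.

    Rise cycles are fractional (linearly interpolated at the threshold
    crossing of a lightly smoothed curve): sub-cycle Ct differences carry the
    template-ratio information (a factor of 2 per cycle).
    """

    angle_deg: float        # atan2(f2_end, f1_end) in [0, 90]
    magnitude: float        # f1_end + f2_end
    rise_cycle_allele1: float | None
    rise_cycle_allele2: float | None

    @property
    def minor_rise_cycle(self) -> float | None:
        """Rise cycle of the channel with the smaller endpoint signal."""
        return self.rise_cycle_allele2 if self.angle_deg <= 45.0 else self.rise_cycle_allele1

    @property
    def major_rise_cycle(self) -> float | None:
        return self.rise_cycle_allele1 if self.angle_deg <= 45.0 else self.rise_cycle_allele2


@dataclass(frozen=True, slots=True)
class CallThresholds:
    """Decision thresholds for genotype calling (units of the trace fluorescence).

    Angle bands default to HOM1 < 15°, HET in [35°, 55°], HOM2 > 75°; anything
    else with adequate signal is UNDET.  Magnitudes assume a full-template
    plateau around 1000: below ``noamp_magnitude`` nothing amplified, between
    ``noamp_magnitude`` and ``weak_magnitude`` the signal is too weak to call
    (hemizygous-chimera or inefficient-amplification territory).
    """

    noamp_magnitude: float = 50.0
    weak_magnitude: float = 300.0
    rise_threshold: float = 10.0
    hom1_max_deg: float = 15.0
    het_min_deg: float = 35.0
    het_max_deg: float = 55.0
    hom2_min_deg: float = 75.0


DEFAULT_THRESHOLDS = CallThresholds()


@dataclass(frozen=True, slots=True)
class LocusEvidence:
    """Per-locus contamination/imbalance evidence against an expected call."""

    assay_id: str
    call: GenotypeCall
    deviation_deg: float                 # angular distance to the nearest canonical angle
    expected_deviation_deg: float | None # distance to the *expected* call's canonical angle
    late_minor_amplification: bool
    weak_amplification: bool
    unexpected_amplification: bool       # signal rose where the reference expects NOAMP
    summary: EndpointSummary


def _first_crossing(y: np.ndarray, threshold: float) -> float | None:
    """Fractional cycle (1-based) at which *y* first crosses *threshold*.

    A 3-cycle moving average suppresses baseline noise spikes before the
    crossing search; the crossing itself is linearly interpolated.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        return 1.0 if len(y) == 1 and y[0] >= threshold else None
    s = np.convolve(y, np.full(3, 1.0 / 3.0), mode="same")
    s[0] = 0.5 * (y[0] + y[1])
    s[-1] = 0.5 * (y[-1] + y[-2])
    above = s >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 1.0
    frac = (threshold - s[i - 1]) / (s[i] - s[i - 1])
    return float(i + frac)  # cycle numbers are 1-based: s[i] is cycle i+1


def summarize_trace(
    trace: SignalTrace,
    rise_threshold: float = DEFAULT_THRESHOLDS.rise_threshold,
    noamp_threshold: float = DEFAULT_THRESHOLDS.noamp_magnitude,
) -> EndpointSummary:
    """Reduce a trace to its endpoint angle/magnitude and per-channel rise cycles."""
    if rise_threshold <= 0 or noamp_threshold <= 0:
        raise ValueError("thresholds must be positive")
    e1 = float(trace.f1[-1])
    e2 = float(trace.f2[-1])
    angle = math.degrees(math.atan2(e2, e1)) if (e1 > 0 or e2 > 0) else 0.0
    return EndpointSummary(
        angle_deg=angle,
        magnitude=e1 + e2,
        rise_cycle_allele1=_first_crossing(trace.f1, rise_threshold),
        rise_cycle_allele2=_first_crossing(trace.f2, rise_threshold),
    )


def nearest_canonical_deviation(angle_deg: float) -> float:
    """Angular distance from the nearest of the canonical angles {0, 45, 90}."""
    return min(abs(angle_deg - a) for a in CANONICAL_ANGLES.values())


def _band_quality(angle: float, magnitude: float, center: float, halfwidth: float,
                  thresholds: CallThresholds) -> float:
    angle_q = max(0.0, 1.0 - abs(angle - center) / halfwidth)
    mag_q = min(1.0, magnitude / (2.0 * thresholds.weak_magnitude))
    return max(0.0, min(1.0, angle_q * mag_q))


def call_genotype(summary: EndpointSummary,
                  thresholds: CallThresholds = DEFAULT_THRESHOLDS) -> GenotypeCall:
    """Call one genotype from an endpoint summary.

    Exactly one category is returned.  Quality decreases with angular
    distance from the band center and with low magnitude.
    """
    t = thresholds
    m = summary.magnitude
    if m < t.noamp_magnitude:
        return GenotypeCall(Category.NOAMP, quality=max(0.0, 1.0 - m / t.noamp_magnitude))
    if m < t.weak_magnitude:
        return GenotypeCall(Category.UNDET, quality=0.0)
    a = summary.angle_deg
    if a < t.hom1_max_deg:
        return GenotypeCall(Category.HOM1, _band_quality(a, m, 0.0, t.hom1_max_deg, t))
    if t.het_min_deg <= a <= t.het_max_deg:
        return GenotypeCall(Category.HET, _band_quality(a, m, 45.0, 45.0 - t.het_min_deg, t))
    if a > t.hom2_min_deg:
        return GenotypeCall(Category.HOM2, _band_quality(a, m, 90.0, 90.0 - t.hom2_min_deg, t))
    return GenotypeCall(Category.UNDET, quality=0.0)


def locus_evidence(
    trace: SignalTrace,
    expected_call: GenotypeCall | Category,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
) -> LocusEvidence:
    """Score one locus against the reference expectation.

    ``late_minor_amplification`` fires when the reference expects a homozygote
    and the opposite-allele channel nonetheless crosses the rise threshold
    within the cycle budget — the core small-mixture signature.
    ``weak_amplification`` marks signal above the no-amplification floor but
    too weak to call (the inefficient-amplification signature: weak but with
    a canonical angle).
    """
    expected = expected_call.category if isinstance(expected_call, GenotypeCall) else expected_call
    t = thresholds
    summary = summarize_trace(trace, t.rise_threshold, t.noamp_magnitude)
    call = call_genotype(summary, t)
    amplified = summary.magnitude >= t.noamp_magnitude
    deviation = nearest_canonical_deviation(summary.angle_deg) if amplified else 0.0
    expected_dev = None
    if expected in DETERMINED and amplified:
        expected_dev = abs(summary.angle_deg - CANONICAL_ANGLES[expected])
    late_minor = False
    if expected is Category.HOM1:
        late_minor = summary.rise_cycle_allele2 is not None
    elif expected is Category.HOM2:
        late_minor = summary.rise_cycle_allele1 is not None
    unexpected = expected is Category.NOAMP and (
        summary.rise_cycle_allele1 is not None or summary.rise_cycle_allele2 is not None
    )
    weak = t.noamp_magnitude <= summary.magnitude < t.weak_magnitude
    return LocusEvidence(
        assay_id=trace.assay_id,
        call=call,
        deviation_deg=deviation,
        expected_deviation_deg=expected_dev,
        late_minor_amplification=late_minor,
        weak_amplification=weak,
        unexpected_amplification=unexpected,
        summary=summary,
    )


def estimate_allele_fraction(
    trace: SignalTrace,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Estimate the allele-2 fraction of the template from rise-cycle offsets.

    The template ratio obeys ``a1/a2 = 2**(Ct2 - Ct1)``, so
    ``frac2 = 1 / (1 + 2**(Ct2 - Ct1))``.  Falls back to the endpoint ratio
    when neither channel crossing is measurable, and returns exactly 0 or 1
    for single-channel amplification.
    """
    t = thresholds
    summary = summarize_trace(trace, t.rise_threshold, t.noamp_magnitude)
    if summary.magnitude < t.noamp_magnitude:
        raise ValueError(
            f"no amplification on {trace.assay_id}: magnitude {summary.magnitude:.1f} "
            f"below {t.noamp_magnitude}"
        )
    r1, r2 = summary.rise_cycle_allele1, summary.rise_cycle_allele2
    if r1 is not None and r2 is None:
        return 0.0
    if r2 is not None and r1 is None:
        return 1.0
    if r1 is None and r2 is None:
        e1, e2 = float(trace.f1[-1]), float(trace.f2[-1])
        return e2 / (e1 + e2)
    return 1.0 / (1.0 + 2.0 ** (r2 - r1))
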