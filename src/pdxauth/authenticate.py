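"""The authentication decision layer.

Profile-against-registry validation verdicts, integrated multi-locus
contamination detection with the contamination / inefficient-amplification
triage, mixture-fraction estimation, and serial-passage drift reports.

A sample is VALIDATED when its barcode best matches the expected reference
with no opposite-homozygote (strong) mismatch and at most a couple of
hom-vs-het (weak) mismatches, which copy-number changes can legitimately
produce.  Undetermined-enriched barcodes are triaged with the signal-level
evidence: shifted or late-rising amplification curves at several loci mean
contamination; weak but canonically-angled curves mean inefficient
amplification.  Contamination always requires multi-locus corroboration —
it is the integrated analysis across the whole panel that is decisive, not
any single probe.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientEvidenceError, PanelMismatchError
from .panel import (
    Category,
    DETERMINED,
    ReferencePanel,
    SNPAssay,
    SNPProfile,
)
from .signal import (
    CallThresholds,
    DEFAULT_THRESHOLDS,
    LocusEvidence,
    SignalTrace,
    estimate_allele_fraction,
    locus_evidence,
)

logger = logging.getLogger(__name__)

_OPPOSITE = {Category.HOM1: Category.HOM2, Category.HOM2: Category.HOM1}


@dataclass(frozen=True, slots=True)
class ValidationThresholds:
    """Verdict thresholds.

    ``max_weak``: weak (hom-vs-het) mismatches tolerated in a match — CNV can
    produce a couple.  ``undet_trigger``: undetermined/no-amplification loci
    that trigger the contamination-vs-inefficiency triage (contaminated
    cohorts and high-white-square solid-tumor profiles both sit around 4+).
    """

    max_weak: int = 2
    undet_trigger: int = 4


@dataclass(frozen=True, slots=True)
class DetectionThresholds:
    """Contamination-detection thresholds.

    ``min_flagged``: loci of corroborating evidence required (single-probe
    artifacts never condemn a sample).  ``deviation_delta_deg``: angular
    shift from the expected canonical angle counted as evidence.
    ``contributor_margin``: consistency lead over the runner-up required to
    name the implied second contributor.
    """

    min_flagged: int = 3
    deviation_delta_deg: float = 10.0
    contributor_margin: float = 0.1
    max_missing_fraction: float = 0.25


DEFAULT_VALIDATION = ValidationThresholds()
DEFAULT_DETECTION = DetectionThresholds()


class Status(str, enum.Enum):
    VALIDATED = "VALIDATED"
    MISMATCHED = "MISMATCHED"
    CONTAMINATION_SUSPECT = "CONTAMINATION_SUSPECT"
    INCONCLUSIVE = "INCONCLUSIVE"


class Disposition(str, enum.Enum):
    CONTAMINATED = "CONTAMINATED"
    INEFFICIENT_AMPLIFICATION = "INEFFICIENT_AMPLIFICATION"
    CLEAN = "CLEAN"


@dataclass(frozen=True, slots=True)
class ProfileComparison:
    """Per-locus tallies of a pairwise barcode comparison."""

    n_informative: int       # both calls determined
    n_match: int
    n_strong_mismatch: int   # opposite homozygotes
    n_weak_mismatch: int     # homozygote vs heterozygote
    n_undetermined: int      # either call NOAMP/UNDET (concordant Y dropout excluded)
    n_excluded: int          # concordant-by-sex Y dropout and same-sex Y differences

    @property
    def concordance(self) -> float:
        return self.n_match / self.n_informative if self.n_informative else 0.0


@dataclass(slots=True)
class ValidationVerdict:
    sample_id: str
    expected_reference: str
    best_reference: str | None
    status: Status
    comparison: ProfileComparison
    notes: list[str] = field(default_factory=list)


@dataclass(slots=True)
class ContaminationReport:
    """Integrated panel-wide mixture evidence for one sample."""

    sample_id: str
    flagged_loci: list[LocusEvidence]
    n_flagged: int
    disposition: Disposition
    implied_second_contributor: str | None = None
    estimated_fraction: float | None = None
    notes: list[str] = field(default_factory=list)


def compare_profiles(
    a: SNPProfile,
    b: SNPProfile,
    assays: tuple[SNPAssay, ...] | None = None,
) -> ProfileComparison:
    """Compare two barcodes locus by locus (symmetric in its arguments).

    Y-linked loci are excluded when both samples lack Y amplification
    (concordant female dropout) and, between samples of identical inferred
    sex, Y differences are excluded from mismatch counts (hemizygous calls
    are treated as less reliable than autosomal ones).
    """
    if set(a.calls) != set(b.calls):
        raise PanelMismatchError(
            f"profiles {a.sample_id!r} and {b.sample_id!r} are on different panels"
        )
    y_ids = (
        {x.assay_id for x in assays if x.y_linked} if assays is not None else set()
    )
    informative = match = strong = weak = undet = excluded = 0
    for aid in a.calls:
        ca, cb = a.category(aid), b.category(aid)
        if aid in y_ids:
            if ca is Category.NOAMP and cb is Category.NOAMP:
                excluded += 1
                continue
            if a.inferred_sex == b.inferred_sex and ca != cb:
                excluded += 1
                continue
        if ca not in DETERMINED or cb not in DETERMINED:
            undet += 1
            continue
        informative += 1
        if ca == cb:
            match += 1
        elif _OPPOSITE.get(ca) == cb:
            strong += 1
        else:
            weak += 1
    return ProfileComparison(
        n_informative=informative,
        n_match=match,
        n_strong_mismatch=strong,
        n_weak_mismatch=weak,
        n_undetermined=undet,
        n_excluded=excluded,
    )


def validate_sample(
    profile: SNPProfile,
    expected: str,
    panel: ReferencePanel,
    thresholds: ValidationThresholds = DEFAULT_VALIDATION,
    traces: dict[str, SignalTrace] | None = None,
    call_thresholds: CallThresholds = DEFAULT_THRESHOLDS,
    detection: DetectionThresholds = DEFAULT_DETECTION,
) -> ValidationVerdict:
    """Match one sample against the whole registry and return a verdict.

    The best reference is the registry entry with maximal concordance.
    Undetermined-enriched samples are triaged with trace-level evidence
    when traces are supplied; ties for best reference are reported as
    INCONCLUSIVE, never silently broken.
    """
    if expected not in panel.references:
        raise KeyError(f"expected reference {expected!r} not in registry")
    comparisons = {
        rid: compare_profiles(profile, ref, panel.assays)
        for rid, ref in panel.references.items()
    }
    cmp_exp = comparisons[expected]
    best_conc = max(c.concordance for c in comparisons.values())
    best_ids = [rid for rid, c in comparisons.items() if c.concordance >= best_conc - 1e-12]
    best = best_ids[0] if len(best_ids) == 1 else None
    notes: list[str] = []

    # trace evidence, when available, overrides a clean-looking barcode:
    # small mixtures shift curves long before they flip categorical calls
    report = None
    if traces is not None:
        report = detect_contamination(
            traces, panel.references[expected], panel,
            call_thresholds=call_thresholds, thresholds=detection,
            reference_id=expected,
        )
        if report.disposition is Disposition.CONTAMINATED:
            notes.append(
                f"mixture evidence at {report.n_flagged} loci"
                + (
                    f"; implied second contributor {report.implied_second_contributor}"
                    if report.implied_second_contributor
                    else ""
                )
            )
            return ValidationVerdict(
                profile.sample_id, expected, best, Status.CONTAMINATION_SUSPECT,
                cmp_exp, notes,
            )

    if cmp_exp.n_undetermined >= thresholds.undet_trigger:
        notes.append(
            f"undetermined-enriched: {cmp_exp.n_undetermined} loci NOAMP/UNDET"
        )
        if report is not None:
            notes.append(f"signal-level triage: {report.disposition.value}")
        return ValidationVerdict(
            profile.sample_id, expected, best, Status.INCONCLUSIVE, cmp_exp, notes
        )

    if best is None:
        notes.append(f"ambiguous best reference: tie among {sorted(best_ids)}")
        return ValidationVerdict(
            profile.sample_id, expected, None, Status.INCONCLUSIVE, cmp_exp, notes
        )

    expected_fits = (
        cmp_exp.n_strong_mismatch == 0 and cmp_exp.n_weak_mismatch <= thresholds.max_weak
    )
    if best == expected and expected_fits:
        return ValidationVerdict(
            profile.sample_id, expected, best, Status.VALIDATED, cmp_exp, notes
        )
    if best != expected and comparisons[best].n_strong_mismatch == 0 and not expected_fits:
        notes.append(
            f"profile fits {best!r} (concordance {comparisons[best].concordance:.3f}) "
            f"but not expected {expected!r} "
            f"({cmp_exp.n_strong_mismatch} strong, {cmp_exp.n_weak_mismatch} weak mismatches)"
        )
        return ValidationVerdict(
            profile.sample_id, expected, best, Status.MISMATCHED, cmp_exp, notes
        )
    notes.append(
        "no registry entry fits cleanly"
        if not expected_fits
        else f"expected fits but {best!r} matches better"
    )
    return ValidationVerdict(
        profile.sample_id, expected, best,
        Status.MISMATCHED if not expected_fits else Status.INCONCLUSIVE,
        cmp_exp, notes,
    )


def _implied_minor_allele(ev: LocusEvidence, expected: Category) -> int | None:
    """Which allele (1 or 2) the evidence says was unexpectedly present."""
    if expected is Category.HOM1:
        return 2
    if expected is Category.HOM2:
        return 1
    if expected is Category.HET:
        return 2 if ev.summary.angle_deg > 45.0 else 1
    if expected is Category.NOAMP:
        s = ev.summary
        if s.rise_cycle_allele1 is not None and s.rise_cycle_allele2 is None:
            return 1
        if s.rise_cycle_allele2 is not None and s.rise_cycle_allele1 is None:
            return 2
    return None


def _carries(call: Category, allele: int) -> float:
    if call is Category.HET:
        return 1.0
    if call is (Category.HOM1 if allele == 1 else Category.HOM2):
        return 1.0
    if call is Category.UNDET:
        return 0.5
    return 0.0


def _allele_dosage(call: Category, allele: int) -> float | None:
    """Copies of *allele* a diploid contributor with this call would add."""
    if call is Category.HET:
        return 1.0
    if call is (Category.HOM1 if allele == 1 else Category.HOM2):
        return 2.0
    if call in (Category.HOM1, Category.HOM2):
        return 0.0
    return None


def detect_contamination(
    traces: dict[str, SignalTrace],
    expected_profile: SNPProfile,
    panel: ReferencePanel,
    call_thresholds: CallThresholds = DEFAULT_THRESHOLDS,
    thresholds: DetectionThresholds = DEFAULT_DETECTION,
    reference_id: str | None = None,
) -> ContaminationReport:
    """Integrated panel-wide contamination triage from raw traces.

    A locus with adequate signal counts as mixture evidence when the
    unexpected allele's channel rises within the cycle budget (expected
    homozygote or expected Y-dropout) or the endpoint angle has shifted more
    than ``deviation_delta_deg`` away from the expected genotype's canonical
    angle.  Assays inside a karyotype region annotated for the expected
    reference are exempt from angle-shift evidence (copy-number imbalance
    shifts angles reproducibly without any contamination).

    Dispositions: CONTAMINATED with >= ``min_flagged`` corroborating loci;
    INEFFICIENT_AMPLIFICATION when undetermined/weak loci exist but every
    measurable angle stays canonical; CLEAN otherwise.
    """
    assay_ids = panel.assay_ids
    missing = [aid for aid in assay_ids if aid not in traces]
    if len(missing) > thresholds.max_missing_fraction * len(assay_ids):
        raise InsufficientEvidenceError(
            f"traces missing for {len(missing)}/{len(assay_ids)} loci: {missing[:5]}..."
        )
    if reference_id is None and expected_profile.sample_id in panel.references:
        reference_id = expected_profile.sample_id
    cnv_exempt = panel.cnv_assay_ids(reference_id) if reference_id else set()

    flagged: list[LocusEvidence] = []
    inefficient = 0
    for aid in assay_ids:
        if aid not in traces:
            continue
        expected = expected_profile.category(aid)
        if expected is Category.UNDET:
            continue  # reference itself is uninformative here
        ev = locus_evidence(traces[aid], expected, call_thresholds)
        adequate = ev.summary.magnitude >= call_thresholds.weak_magnitude
        is_flagged = False
        if expected in DETERMINED and adequate:
            if ev.late_minor_amplification:
                is_flagged = True
            elif (
                aid not in cnv_exempt
                and ev.expected_deviation_deg is not None
                and ev.expected_deviation_deg > thresholds.deviation_delta_deg
            ):
                is_flagged = True
        elif expected is Category.NOAMP and ev.unexpected_amplification:
            is_flagged = True
        if is_flagged:
            flagged.append(ev)
        elif expected in DETERMINED and (
            ev.weak_amplification or ev.call.category in (Category.NOAMP, Category.UNDET)
        ):
            inefficient += 1

    notes: list[str] = []
    if len(flagged) >= thresholds.min_flagged:
        disposition = Disposition.CONTAMINATED
    elif flagged:
        disposition = (
            Disposition.INEFFICIENT_AMPLIFICATION if inefficient else Disposition.CLEAN
        )
        notes.append(
            f"{len(flagged)} flagged loci below the {thresholds.min_flagged}-locus "
            "corroboration threshold"
        )
    elif inefficient:
        disposition = Disposition.INEFFICIENT_AMPLIFICATION
        notes.append(f"{inefficient} weak/undetermined loci with canonical angles")
    else:
        disposition = Disposition.CLEAN

    implied = None
    fraction = None
    if disposition is Disposition.CONTAMINATED:
        implied = _implied_contributor(
            flagged, expected_profile, panel, reference_id, thresholds
        )
        fraction = _estimated_fraction(
            traces, flagged, expected_profile, panel, implied, call_thresholds
        )
    return ContaminationReport(
        sample_id=expected_profile.sample_id,
        flagged_loci=flagged,
        n_flagged=len(flagged),
        disposition=disposition,
        implied_second_contributor=implied,
        estimated_fraction=fraction,
        notes=notes,
    )


def _implied_contributor(
    flagged: list[LocusEvidence],
    expected_profile: SNPProfile,
    panel: ReferencePanel,
    reference_id: str | None,
    thresholds: DetectionThresholds,
) -> str | None:
    """Registry entry most consistent with the flagged minor alleles (confidence-gated)."""
    candidates = [rid for rid in panel.references if rid != reference_id]
    if not candidates or len(flagged) < 2:
        return None
    implied_alleles = {
        ev.assay_id: _implied_minor_allele(ev, expected_profile.category(ev.assay_id))
        for ev in flagged
    }
    implied_alleles = {k: v for k, v in implied_alleles.items() if v is not None}
    if not implied_alleles:
        return None
    scores = {
        rid: float(
            np.mean(
                [
                    _carries(panel.references[rid].category(aid), allele)
                    for aid, allele in implied_alleles.items()
                ]
            )
        )
        for rid in candidates
    }
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best_score = ranked[0]
    if best_score < 0.5:
        return None
    if len(ranked) > 1 and best_score - ranked[1][1] < thresholds.contributor_margin:
        return None
    return best_id


def _estimated_fraction(
    traces: dict[str, SignalTrace],
    flagged: list[LocusEvidence],
    expected_profile: SNPProfile,
    panel: ReferencePanel,
    implied: str | None,
    call_thresholds: CallThresholds,
) -> float | None:
    """Median per-locus contaminant fraction over flagged homozygous-expected loci."""
    contributor = panel.references.get(implied) if implied else None
    estimates = []
    for ev in flagged:
        expected = expected_profile.category(ev.assay_id)
        if expected not in _OPPOSITE:  # only homozygous expectations are quantitative
            continue
        minor_allele = 2 if expected is Category.HOM1 else 1
        frac2 = estimate_allele_fraction(traces[ev.assay_id], call_thresholds)
        minor_frac = frac2 if minor_allele == 2 else 1.0 - frac2
        dosage = 2.0
        if contributor is not None:
            d = _allele_dosage(contributor.category(ev.assay_id), minor_allele)
            if d is None or d == 0.0:
                continue
            dosage = d
        estimates.append(min(1.0, 2.0 * minor_frac / dosage))
    if not estimates:
        return None
    return float(np.median(estimates))


def estimate_mixture_fraction(
    traces: dict[str, SignalTrace],
    ref_a: SNPProfile,
    ref_b: SNPProfile,
    call_thresholds: CallThresholds = DEFAULT_THRESHOLDS,
) -> float | None:
    """Estimate the fraction of contributor *ref_b* in an a+b mixture.

    Uses the median contaminant-allele fraction over the informative loci —
    those where the two references are opposite homozygotes, so the whole
    minor-allele signal is attributable to *ref_b*.  Returns None (with a
    logged explanation) when no locus is informative.
    """
    estimates = []
    for aid in ref_a.calls:
        ca, cb = ref_a.category(aid), ref_b.category(aid)
        if _OPPOSITE.get(ca) != cb:
            continue
        frac2 = estimate_allele_fraction(traces[aid], call_thresholds)
        estimates.append(frac2 if cb is Category.HOM2 else 1.0 - frac2)
    if not estimates:
        logger.warning(
            "no informative (opposite-homozygote) locus between %s and %s; "
            "mixture fraction is not estimable",
            ref_a.sample_id, ref_b.sample_id,
        )
        return None
    return float(np.median(estimates))


# --- serial-passage drift ---------------------------------------------------

_DRIFT_SCORE = {
    Category.HOM1: 0.0,
    Category.HET: 0.5,
    Category.UNDET: 0.5,
    Category.HOM2: 1.0,
    Category.NOAMP: None,
}


@dataclass(slots=True)
class DriftReport:
    """Per-locus call trajectories across serial passages."""

    sample_ids: list[str]
    trajectories: dict[str, list[Category]]
    drifting_loci: list[str]
    drift_detected: bool
    toward_reference: str | None = None


def serial_drift_report(
    profiles_by_passage: list[SNPProfile],
    panel: ReferencePanel | None = None,
    min_loci: int = 3,
    min_step: float = 0.5,
) -> DriftReport:
    """Detect a contaminant out-competing the original PDX across passages.

    A locus drifts when its allele-dosage score (HOM1=0, HET/UNDET=0.5,
    HOM2=1) moves monotonically by at least *min_step* from first to last
    passage; the takeover flag requires *min_loci* drifting loci.  When a
    registry is supplied, the reference most consistent with the final calls
    at the drifting loci is reported as the apparent takeover target.
    """
    if len(profiles_by_passage) < 2:
        raise ValueError("need at least two passages")
    assay_ids = list(profiles_by_passage[0].calls)
    trajectories = {
        aid: [p.category(aid) for p in profiles_by_passage] for aid in assay_ids
    }
    drifting = []
    for aid, cats in trajectories.items():
        scores = [_DRIFT_SCORE[c] for c in cats]
        if any(s is None for s in scores):
            continue
        diffs = np.diff(scores)
        monotone = (diffs >= 0).all() or (diffs <= 0).all()
        if monotone and abs(scores[-1] - scores[0]) >= min_step:
            drifting.append(aid)
    toward = None
    if panel is not None and len(drifting) >= min_loci:
        final = profiles_by_passage[-1]
        scores = {
            rid: np.mean(
                [float(ref.category(a) == final.category(a)) for a in drifting]
            )
            for rid, ref in panel.references.items()
        }
        toward = max(sorted(scores), key=lambda r: scores[r])
    return DriftReport(
        sample_ids=[p.sample_id for p in profiles_by_passage],
        trajectories=trajectories,
        drifting_loci=drifting,
        drift_detected=len(drifting) >= min_loci,
        toward_reference=toward,
    )
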