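"""Verdicts, integrated contamination detection, fraction estimation, drift."""

import itertools

import numpy as np
import pytest

import pdxauth as px
from pdxauth.panel import DEFAULT_Y_ASSAYS

from conftest import make_profile

C = px.Category
DET = {C.HOM1, C.HET, C.HOM2}
OPP = {C.HOM1: C.HOM2, C.HOM2: C.HOM1}


def brute_force_comparison(cats_a, cats_b, y_flags=None, same_sex=False):
    """Independent per-locus recount over raw category pairs.

    Implements the documented contract directly: concordant Y dropout and
    same-sex Y differences are excluded; loci with any NOAMP/UNDET call are
    undetermined; determined pairs are match / strong / weak.
    """
    y_flags = y_flags or [False] * len(cats_a)
    informative = match = strong = weak = undet = 0
    for ca, cb, is_y in zip(cats_a, cats_b, y_flags):
        if is_y and ca is C.NOAMP and cb is C.NOAMP:
            continue
        if is_y and same_sex and ca != cb:
            continue
        if ca not in DET or cb not in DET:
            undet += 1
            continue
        informative += 1
        if ca == cb:
            match += 1
        elif OPP.get(ca) == cb:
            strong += 1
        else:
            weak += 1
    return informative, match, strong, weak, undet


class TestCompareProfiles:
    def test_identical_profiles_have_concordance_one(self, config, assays):
        (a,) = px.simulate_profiles(config, 1, assays=assays)
        c = px.compare_profiles(a, a, assays)
        assert c.n_strong_mismatch == 0 and c.n_weak_mismatch == 0
        assert c.concordance == 1.0

    def test_agrees_with_brute_force_oracle_on_all_25_call_pairs(self, assays):
        """Every (call, call) combination on an autosomal locus matches an
        exhaustive recount."""
        # a 32-locus autosomal-only panel avoids the Y-dropout special case
        autosomal = tuple(
            px.SNPAssay(f"A{i:02d}", chromosome="1", position=i + 1) for i in range(32)
        )
        for ca, cb in itertools.product(list(C), repeat=2):
            cats_a = [C.HET] * 31 + [ca]
            cats_b = [C.HET] * 31 + [cb]
            a = make_profile("a", cats_a, autosomal)
            b = make_profile("b", cats_b, autosomal)
            got = px.compare_profiles(a, b, autosomal)
            exp = brute_force_comparison(cats_a, cats_b)
            assert (
                got.n_informative, got.n_match, got.n_strong_mismatch,
                got.n_weak_mismatch, got.n_undetermined,
            ) == exp, (ca, cb)

    def test_random_profiles_match_oracle_and_are_symmetric(self, assays):
        cfg = px.SimulationConfig(seed=37, female_fraction=0.0)
        a, b = px.simulate_profiles(cfg, 2, assays=assays)
        got = px.compare_profiles(a, b, assays)
        rev = px.compare_profiles(b, a, assays)
        assert got == rev
        exp = brute_force_comparison(
            a.categories(), b.categories(),
            y_flags=[x.y_linked for x in assays],
            same_sex=a.inferred_sex == b.inferred_sex,
        )
        assert (
            got.n_informative, got.n_match, got.n_strong_mismatch,
            got.n_weak_mismatch, got.n_undetermined,
        ) == exp

    def test_concordant_female_y_dropout_is_excluded_not_undetermined(self, assays):
        cfg = px.SimulationConfig(seed=38)
        a, b = px.simulate_profiles(
            cfg, 2, assays=assays, sexes=[px.Sex.FEMALE] * 2
        )
        c = px.compare_profiles(a, b, assays)
        assert c.n_excluded == 3
        assert c.n_informative + c.n_undetermined + c.n_excluded == 32

    def test_panel_mismatch_rejected(self, assays, config):
        (a,) = px.simulate_profiles(config, 1, assays=assays)
        small = px.SimulationConfig(n_loci=8, seed=0)
        (b,) = px.simulate_profiles(small, 1, assays=px.default_panel(8))
        with pytest.raises(px.PanelMismatchError):
            px.compare_profiles(a, b)


class TestValidateSample:
    def test_matching_sample_is_validated(self, reference_pair, config):
        a, b, registry = reference_pair
        sample = make_profile("P3-1", a.categories(), registry.assays, a.inferred_sex)
        v = px.validate_sample(sample, "REF-A", registry)
        assert v.status is px.Status.VALIDATED
        assert v.best_reference == "REF-A"

    def test_mislabel_reports_mismatched_with_true_best_reference(self, reference_pair):
        a, b, registry = reference_pair
        # pure sample of B validated against A: the mis-identification scenario
        sample = make_profile("mislabeled", b.categories(), registry.assays, b.inferred_sex)
        v = px.validate_sample(sample, "REF-A", registry)
        assert v.status is px.Status.MISMATCHED
        assert v.best_reference == "REF-B"

    def test_undetermined_enriched_without_traces_is_inconclusive(self, reference_pair):
        a, b, registry = reference_pair
        cats = a.categories()
        for i in range(4):
            cats[i] = C.UNDET
        sample = make_profile("weak", cats, registry.assays, a.inferred_sex)
        v = px.validate_sample(sample, "REF-A", registry)
        assert v.status is px.Status.INCONCLUSIVE

    def test_undetermined_enriched_with_mixture_traces_is_contamination_suspect(
        self, reference_pair, config
    ):
        a, b, registry = reference_pair
        rng = np.random.default_rng(41)
        spec = px.MixtureSpec((("REF-A", 0.7), ("REF-B", 0.3)))
        traces = px.simulate_mixture([a, b], spec, config, rng)
        calls = {
            aid: px.call_genotype(px.summarize_trace(tr)) for aid, tr in traces.items()
        }
        sample = px.SNPProfile("P5-18", calls)
        sample.inferred_sex = px.infer_sex(sample, DEFAULT_Y_ASSAYS)
        v = px.validate_sample(sample, "REF-A", registry, traces=traces)
        assert v.comparison.n_undetermined >= 4  # 0.3 mixing shifts angles off-band
        assert v.status is px.Status.CONTAMINATION_SUSPECT

    def test_unknown_expected_reference_rejected(self, reference_pair):
        a, _, registry = reference_pair
        with pytest.raises(KeyError):
            px.validate_sample(a, "NOPE", registry)

    def test_adding_sex_concordant_noamp_never_breaks_validation(self, reference_pair):
        """A female sample's Y dropout is concordant with its female reference
        and leaves the verdict VALIDATED."""
        a, b, registry = reference_pair
        cfg = px.SimulationConfig(seed=43)
        (ref,) = px.simulate_profiles(cfg, 1, sexes=[px.Sex.FEMALE])
        ref.sample_id = "REF-F"
        registry = px.add_calls(registry, ref)
        sample = make_profile("f-sample", ref.categories(), registry.assays, px.Sex.FEMALE)
        v = px.validate_sample(sample, "REF-F", registry)
        assert v.status is px.Status.VALIDATED


class TestDetectContamination:
    def test_mixture_flags_contamination_and_names_the_contributor(
        self, reference_pair, config
    ):
        a, b, registry = reference_pair
        rng = np.random.default_rng(47)
        for f in (0.5, 1 / 8, 1 / 32):
            spec = px.MixtureSpec((("REF-A", 1 - f), ("REF-B", f)))
            traces = px.simulate_mixture([a, b], spec, config, rng)
            rep = px.detect_contamination(traces, a, registry, reference_id="REF-A")
            assert rep.disposition is px.Disposition.CONTAMINATED, f
            assert rep.implied_second_contributor == "REF-B"
            assert rep.estimated_fraction == pytest.approx(f, rel=0.5)

    def test_attenuated_pure_sample_is_inefficient_amplification(
        self, reference_pair, config
    ):
        from pdxauth.simulate import attenuate_loci

        a, _, registry = reference_pair
        rng = np.random.default_rng(53)
        traces = px.traces_for_profile(a, config, rng)
        determined = [
            aid for aid in registry.assay_ids if a.category(aid) in DET
        ]
        weak = attenuate_loci(traces, determined[:5], 0.1)
        rep = px.detect_contamination(weak, a, registry, reference_id="REF-A")
        assert rep.disposition is px.Disposition.INEFFICIENT_AMPLIFICATION

    def test_pure_samples_are_clean_in_99_percent_of_replicates(
        self, reference_pair, config
    ):
        a, _, registry = reference_pair
        rng = np.random.default_rng(59)
        n = 300
        clean = sum(
            px.detect_contamination(
                px.traces_for_profile(a, config, rng), a, registry, reference_id="REF-A"
            ).disposition
            is px.Disposition.CLEAN
            for _ in range(n)
        )
        assert clean / n >= 0.99

    def test_cnv_annotated_loci_are_exempt_from_deviation_evidence(self, config):
        """Reproducible copy-number imbalance at annotated loci must not read
        as contamination."""
        cfg = px.SimulationConfig(seed=61, female_fraction=0.0)
        rng = np.random.default_rng(61)
        assays = px.default_panel()
        (ref,) = px.simulate_profiles(cfg, 1, assays=assays, rng=rng)
        ref.sample_id = "ALL17"
        registry = px.assign_references([ref], assays=assays)
        px.attach_karyotypes(
            registry,
            {
                "ALL17": (
                    px.KaryotypeRegion("6", 30_466_936, 170_792_391, 3, allele2_copies=2),
                )
            },
        )
        dosage = px.profile_dosage(ref, assays)
        cnv_ids = {"C___7421900_10", "C__27402849_10"}
        for j, assay in enumerate(assays):
            if assay.assay_id in cnv_ids:
                dosage[j] = (1.0, 2.0)  # heterozygous amplification, CN 3
        traces = px.simulate_traces(dosage, cfg, rng, assays)
        rep = px.detect_contamination(traces, ref, registry, reference_id="ALL17")
        assert rep.disposition is not px.Disposition.CONTAMINATED
        assert all(ev.assay_id not in cnv_ids for ev in rep.flagged_loci)

    def test_missing_traces_for_a_quarter_of_loci_rejected(self, reference_pair, config):
        a, _, registry = reference_pair
        rng = np.random.default_rng(67)
        traces = px.traces_for_profile(a, config, rng)
        for aid in registry.assay_ids[:9]:
            del traces[aid]
        with pytest.raises(px.InsufficientEvidenceError):
            px.detect_contamination(traces, a, registry, reference_id="REF-A")


class TestMixtureFraction:
    @pytest.mark.parametrize("f,tol", [(0.5, 0.05), (0.0, 0.02)])
    def test_extreme_fractions(self, reference_pair, config, f, tol):
        a, b, registry = reference_pair
        rng = np.random.default_rng(71)
        if f > 0:
            spec = px.MixtureSpec((("REF-A", 1 - f), ("REF-B", f)))
            traces = px.simulate_mixture([a, b], spec, config, rng)
        else:
            traces = px.traces_for_profile(a, config, rng)
        est = px.estimate_mixture_fraction(traces, a, b)
        assert est == pytest.approx(f, abs=tol)

    def test_one_sixteenth_mixture_median_within_003(self, reference_pair, config):
        a, b, registry = reference_pair
        rng = np.random.default_rng(73)
        f = 1 / 16
        spec = px.MixtureSpec((("REF-A", 1 - f), ("REF-B", f)))
        ests = [
            px.estimate_mixture_fraction(
                px.simulate_mixture([a, b], spec, config, rng), a, b
            )
            for _ in range(100)
        ]
        assert np.median(ests) == pytest.approx(f, abs=0.03)

    def test_zero_informative_loci_returns_none(self, assays, config):
        a = make_profile("a", [C.HET] * 32, assays)
        b = make_profile("b", [C.HET] * 32, assays)
        rng = np.random.default_rng(79)
        traces = px.simulate_traces(
            np.array([[1.0, 1.0]] * 32), config, rng, assays
        )
        assert px.estimate_mixture_fraction(traces, a, b) is None


class TestSerialDrift:
    def test_takeover_across_passages_is_flagged_toward_the_contaminant(
        self, reference_pair, config
    ):
        a, b, registry = reference_pair
        rng = np.random.default_rng(83)
        passages = []
        for label, f in (("P2", 0.3), ("P3", 0.8)):
            spec = px.MixtureSpec((("REF-A", 1 - f), ("REF-B", f)))
            traces = px.simulate_mixture([a, b], spec, config, rng)
            calls = {
                aid: px.call_genotype(px.summarize_trace(tr))
                for aid, tr in traces.items()
            }
            prof = px.SNPProfile(f"ETP4-{label}", calls, passage_label=label)
            passages.append(prof)
        rep = px.serial_drift_report(passages, panel=registry)
        assert rep.drift_detected
        assert rep.toward_reference == "REF-B"

    def test_identical_passages_show_no_drift(self, reference_pair):
        a, _, registry = reference_pair
        p1 = make_profile("P1", a.categories(), registry.assays, a.inferred_sex)
        p2 = make_profile("P2", a.categories(), registry.assays, a.inferred_sex)
        rep = px.serial_drift_report([p1, p2])
        assert not rep.drift_detected and rep.drifting_loci == []

    def test_noise_only_passages_rarely_flag(self, reference_pair, config):
        a, _, registry = reference_pair
        rng = np.random.default_rng(89)
        flags = 0
        n = 100
        for _ in range(n):
            passages = []
            for label in ("P2", "P3"):
                traces = px.traces_for_profile(a, config, rng)
                calls = {
                    aid: px.call_genotype(px.summarize_trace(tr))
                    for aid, tr in traces.items()
                }
                passages.append(px.SNPProfile(label, calls, passage_label=label))
            flags += px.serial_drift_report(passages).drift_detected
        assert flags / n <= 0.01
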