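import numpy as np
import pytest

import editscan as es
from editscan.annotation import AnnotationSet, Transcript
from editscan.seq import ReferenceSequence
from editscan.targets import CandidateSite
from editscan.variants import VariantCall


def _call(pos, f, unit_ref="r"):
    depth = 1000
    alt = round(f * depth)
    return VariantCall(unit_ref, pos, "C", "U", depth, alt, alt / depth,
                       1e-9, "C>U")


def make_calls(design, freqs_by_site):
    """freqs_by_site: {pos: {(sample, rep): f or None (absent)}}"""
    calls = {unit: [] for unit in design.units()}
    for pos, by_unit in freqs_by_site.items():
        for unit, f in by_unit.items():
            if f is not None:
                calls[unit].append(_call(pos, f))
    return calls


class TestIntersectReplicates:
    def test_site_missing_in_one_replicate_excluded(self, design):
        units = design.units()
        freqs = {10: {u: 0.1 for u in units}}
        freqs[10][units[-1]] = None
        assert es.intersect_replicates(make_calls(design, freqs)) == []

    def test_site_in_all_replicates_kept_with_full_matrix(self, design):
        units = design.units()
        freqs = {10: {u: 0.1 for u in units}}
        sites = es.intersect_replicates(make_calls(design, freqs))
        assert len(sites) == 1
        assert len(sites[0].f_by_replicate) == len(units)

    def test_minimal_two_sample_design(self):
        design = es.StudyDesign(kd_labels=("kd",))
        units = design.units()
        assert len(units) == 4
        freqs = {3: {u: 0.2 for u in units}}
        sites = es.intersect_replicates(make_calls(design, freqs))
        assert len(sites) == 1

    def test_empty_call_set_gives_empty_output(self):
        assert es.intersect_replicates({}) == []


class TestPercentDifference:
    @pytest.mark.parametrize("fc, fkd, expected", [
        (0.10, 0.05, 50.0), (0.10, 0.10, 0.0), (0.10, 0.0, 100.0),
    ])
    def test_arithmetic(self, fc, fkd, expected):
        assert es.percent_difference(fc, fkd) == pytest.approx(expected)

    def test_zero_control_undefined(self):
        with pytest.raises(ValueError):
            es.percent_difference(0.0, 0.0)


class TestClassifyTargets:
    def _site(self, design, ctrl, kd):
        """ctrl: (f1, f2); kd: {label: (f1, f2)}"""
        f = {}
        for rep, fval in enumerate(ctrl, start=1):
            f[(design.control_label, rep)] = fval
        for label, reps in kd.items():
            for rep, fval in enumerate(reps, start=1):
                f[(label, rep)] = fval
        return CandidateSite("r", 1, "C>U", f)

    def test_one_increased_replicate_fails_strict_mode(self, design):
        site = self._site(design, (0.10, 0.10),
                          {"kd_pool": (0.12, 0.04), "kd_single": (0.05, 0.06)})
        strict = es.classify_targets([site], design, "all_replicates_decrease")
        assert strict == []

    def test_same_site_passes_mean_mode(self, design):
        site = self._site(design, (0.10, 0.10),
                          {"kd_pool": (0.12, 0.04), "kd_single": (0.05, 0.06)})
        kept = es.classify_targets([site], design, "mean_decrease")
        assert len(kept) == 1
        # kd means 0.08 and 0.055 -> summary 0.0675 -> 32.5% drop from 0.10
        assert kept[0].percent_difference == pytest.approx(32.5)

    def test_unknown_mode_rejected(self, design):
        with pytest.raises(ValueError):
            es.classify_targets([], design, "median_decrease")

    def test_matches_bruteforce_oracle_on_random_matrices(self, design):
        """Both concordance rules agree with an independent re-implementation
        on 200 random frequency matrices."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            ctrl = rng.uniform(0.01, 0.3, size=2)
            kd = {label: tuple(rng.uniform(0.0, 0.3, size=2))
                  for label in design.kd_labels}
            site = self._site(design, tuple(ctrl), kd)

            # independent oracle
            ctrl_mean = (ctrl[0] + ctrl[1]) / 2
            kd_means = [sum(v) / 2 for v in kd.values()]
            expect_strict = all(f < ctrl_mean for v in kd.values() for f in v)
            expect_mean = all(m < ctrl_mean for m in kd_means)
            expect_pd = 100 * (ctrl_mean - np.mean(kd_means)) / ctrl_mean

            for mode, expected in (("all_replicates_decrease", expect_strict),
                                   ("mean_decrease", expect_mean)):
                site_copy = self._site(design, tuple(ctrl), kd)
                kept = es.classify_targets([site_copy], design, mode)
                assert bool(kept) == expected
                if kept:
                    assert kept[0].percent_difference == pytest.approx(expect_pd)


class TestTierSites:
    @pytest.mark.parametrize("pd_, tier", [
        (66.0, "gt33"),   # strict >66 boundary
        (70.0, "gt66"),
        (33.0, "all"),    # strict >33 boundary
        (10.0, "all"),
    ])
    def test_strict_thresholds(self, pd_, tier):
        site = CandidateSite("r", 1, "C>U", {}, percent_difference=pd_)
        assert es.tier_sites([site])[0].tier == tier

    def test_tier_nesting(self):
        rng = np.random.default_rng(1)
        sites = [CandidateSite("r", i, "C>U", {},
                               percent_difference=float(rng.uniform(-50, 100)))
                 for i in range(100)]
        es.tier_sites(sites)
        n66 = sum(s.tier == "gt66" for s in sites)
        n33 = sum(s.tier in ("gt66", "gt33") for s in sites)
        assert n66 <= n33 <= len(sites)


class TestAnnotateContext:
    def test_uc_motif_flag(self):
        ref = ReferenceSequence("r", "AUCA")
        site = CandidateSite("r", 2, "C>U", {})
        assert es.annotate_context(site, ref).uc_motif is True

    def test_non_uc_context(self):
        ref = ReferenceSequence("r", "ACCA")
        site = CandidateSite("r", 2, "C>U", {})
        assert es.annotate_context(site, ref).uc_motif is False

    def test_sequence_start_is_padded_and_not_uc(self):
        ref = ReferenceSequence("r", "CAUA")
        site = es.annotate_context(CandidateSite("r", 0, "C>U", {}), ref)
        assert site.uc_motif is False
        assert site.context.startswith("-" * 10)
        assert len(site.context) == 21


class TestAnnotateRegion:
    @pytest.fixture()
    def annotation(self):
        coding = Transcript("geneA", "r", 0, 100, "+",
                            exons=[(0, 30), (60, 100)], coding=True,
                            utr5=(0, 10), utr3=(90, 100))
        noncoding = Transcript("geneB", "r", 120, 160, "+",
                               exons=[(120, 160)], coding=False)
        return AnnotationSet([coding, noncoding])

    @pytest.mark.parametrize("pos, region, gene", [
        (95, "3'UTR", "geneA"),
        (5, "5'UTR", "geneA"),
        (20, "coding exon", "geneA"),
        (45, "intron", "geneA"),
        (130, "non-coding exon", "geneB"),
        (110, "intergenic", None),
    ])
    def test_region_precedence(self, annotation, pos, region, gene):
        site = es.annotate_region(CandidateSite("r", pos, "C>U", {}), annotation)
        assert (site.region, site.gene) == (region, gene)


class TestSyntheticRecovery:
    def test_planted_sites_recovered_with_low_false_positives(self, design):
        """kd_reduction 0.5 at f=0.10, depth 1000, duplicates: >= 90%
        sensitivity, <= 5% false positives among non-planted Cs."""
        ref = es.generate_reference(4000, seed=33)
        planted = es.plant_edit_sites(ref, 20, f_control_range=(0.10, 0.10),
                                      kd_reduction=0.5, seed=33)
        pileups = es.simulate_pileups(ref, planted, design, depth=1000, seed=33)
        calls = {u: es.call_c_to_u(t, 0.001) for u, t in pileups.items()}
        consensus = es.intersect_replicates(calls)
        kept = es.classify_targets(consensus, design, "mean_decrease")
        found = {s.position for s in kept}
        truth = {s.position for s in planted}
        sensitivity = len(found & truth) / len(truth)
        non_planted_c = [p for p in ref.positions_of("C") if p not in truth]
        fp_rate = len(found - truth) / len(non_planted_c)
        assert sensitivity >= 0.9
        assert fp_rate <= 0.05
        # no site is invented: output within consensus within union of calls
        union = {(c.ref_name, c.position) for cs in calls.values() for c in cs}
        assert {( s.ref_name, s.position) for s in kept} <= \
               {(s.ref_name, s.position) for s in consensus} <= union


def test_sites_table_and_bed_layout(design):
    units = design.units()
    site = CandidateSite("r", 9, "C>U", {u: 0.1 for u in units},
                         f_control_mean=0.1, percent_difference=50.0,
                         tier="gt33")
    frame = es.sites_to_frame([site])
    assert frame.loc[0, "pos"] == 10           # 1-based in reports
    assert {f"f_{s}_r{r}" for s, r in units} <= set(frame.columns)
    bed = es.sites_to_bed([site])
    assert bed == "r\t9\t10\tC>U\n"            # 0-based half-open in BED
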