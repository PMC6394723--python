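"""Binding-site scans, amplicon prediction, assay calls, panel metrics."""

import numpy as np
import pytest

from mcptyper.insilico_pcr import (
    RELAXED,
    STRINGENT,
    AssayDefinition,
    MatchThresholds,
    check_multiplex_compatibility,
    cross_dimer_3prime,
    evaluate_panel,
    find_binding_sites,
    predict_amplicons,
    run_assay,
)
from mcptyper.seqcore import ConcreteTemplate, expand, revcomp
from mcptyper.synth import PanelConfig, PlantSpec, make_panel, plant_template

from helpers import (
    brute_force_amplicons,
    brute_force_sites,
    random_degenerate,
    random_dna,
)


def _site_tuples(sites):
    return [(s.strand, s.start, s.end, s.mismatches, s.clamp_mismatches) for s in sites]


class TestBindingSites:
    def test_simple_degenerate_match(self):
        template = ConcreteTemplate("t", "TAGGT")
        sites = find_binding_sites("ARG", template, clamp_len=1)
        plus = [s for s in sites if s.strand == "+"]
        assert [(s.start, s.end) for s in plus] == [(1, 4)]

    def test_every_expansion_member_is_found(self, panel_by_group, rng):
        primer = panel_by_group["Vi1"].fw
        for concrete in sorted(expand(primer.seq)):
            background = random_dna(rng, 200)
            template = ConcreteTemplate("t", background[:80] + concrete + background[80:])
            sites = find_binding_sites(primer, template)
            assert any(s.strand == "+" and s.mismatches == 0 for s in sites)

    def test_template_shorter_than_primer_is_empty_not_error(self):
        assert find_binding_sites("ACGTACGT", ConcreteTemplate("t", "ACG")) == []

    def test_site_sets_match_brute_force_oracle(self, rng):
        for _ in range(50):
            primer = random_degenerate(rng, int(rng.integers(4, 9)))
            template = ConcreteTemplate("t", random_dna(rng, int(rng.integers(20, 60))))
            max_mm = int(rng.integers(0, 3))
            sites = find_binding_sites(
                primer, template, max_mismatch=max_mm, clamp_len=2, clamp_max_mismatch=0
            )
            oracle = brute_force_sites(primer, template.seq, max_mm, 2, 0)
            assert _site_tuples(sites) == oracle

    def test_template_n_matches_nothing_by_default(self):
        template = ConcreteTemplate("t", "AANAA")
        assert find_binding_sites("AAAAA", template, clamp_len=1) == []
        relaxed = find_binding_sites(
            "AAAAA", template, clamp_len=1, n_as_wildcard=True
        )
        assert any(s.mismatches == 0 for s in relaxed)

    def test_raising_max_mismatch_never_removes_sites(self, rng):
        primer = random_degenerate(rng, 8)
        template = ConcreteTemplate("t", random_dna(rng, 100))
        previous: set = set()
        for max_mm in range(4):
            found = set(
                _site_tuples(
                    find_binding_sites(
                        primer, template, max_mismatch=max_mm,
                        clamp_len=3, clamp_max_mismatch=3,
                    )
                )
            )
            assert previous <= found
            previous = found


class TestAmplicons:
    def test_planted_product_has_exact_length(self, panel_by_group):
        pair = panel_by_group["T7"]
        template, truth = plant_template(PlantSpec(pair=pair, product_len=500, seed=9))
        amps = predict_amplicons(pair, template)
        assert [a.length for a in amps] == [500]
        assert amps[0].start == truth.fw_start and amps[0].end == truth.rev_end

    def test_divergent_orientation_yields_no_product(self, panel_by_group, rng):
        pair = panel_by_group["T4"]
        fw = sorted(expand(pair.fw.seq))[0]
        rev_site = revcomp(sorted(expand(pair.rev.seq))[0])
        background = random_dna(rng, 800)
        # reverse-primer site upstream of forward site: primers point apart
        seq = background[:100] + rev_site + background[100:300] + fw + background[300:]
        assert predict_amplicons(pair, ConcreteTemplate("t", seq)) == []

    def test_two_by_two_sites_match_combinatorial_oracle(self, panel_by_group, rng):
        pair = panel_by_group["GJ1"]
        fw = sorted(expand(pair.fw.seq))[0]
        rv = revcomp(sorted(expand(pair.rev.seq))[0])
        background = random_dna(rng, 2000)
        seq = (
            background[:50] + fw + background[50:300] + fw
            + background[300:600] + rv + background[600:900] + rv + background[900:]
        )
        template = ConcreteTemplate("t", seq)
        min_len = len(pair.fw) + len(pair.rev) + 10
        amps = predict_amplicons(pair, template, max_len=5000)
        fw_sites = brute_force_sites(str(pair.fw.seq), seq, 0, 3, 0)
        rev_sites = brute_force_sites(str(pair.rev.seq), seq, 0, 3, 0)
        oracle = brute_force_amplicons(fw_sites, rev_sites, min_len, 5000)
        assert sorted((a.start, a.end) for a in amps) == oracle
        assert len(amps) == 4

    def test_shrinking_length_window_never_adds_amplicons(self, panel_by_group):
        pair = panel_by_group["N4"]
        template, _ = plant_template(PlantSpec(pair=pair, product_len=400, seed=2))
        wide = {(a.start, a.end) for a in predict_amplicons(pair, template, max_len=5000)}
        narrow = {
            (a.start, a.end)
            for a in predict_amplicons(pair, template, min_len=390, max_len=410)
        }
        assert narrow <= wide


def _triplex(panel_by_group, groups, temp):
    return AssayDefinition(
        name="/".join(groups),
        pairs=tuple(panel_by_group[g] for g in groups),
        annealing_temp=temp,
    )


class TestRunAssay:
    def test_single_planted_group_called_cleanly(self, panel_by_group):
        assay = _triplex(panel_by_group, ("T4", "T7", "SP6"), 52.0)
        template, _ = plant_template(
            PlantSpec(pair=panel_by_group["T7"], product_len=400, seed=4)
        )
        result = run_assay(assay, template)
        assert result.calls == {"T7"} and result.flags == set()

    def test_no_sites_means_no_calls(self, panel_by_group, rng):
        assay = _triplex(panel_by_group, ("T4", "T7", "SP6"), 52.0)
        template = ConcreteTemplate("t", random_dna(rng, 1000))
        result = run_assay(assay, template)
        assert result.calls == set()

    def test_clamp_mismatch_is_rated_negative_with_nonspecific_flag(self, panel_by_group):
        pair = panel_by_group["FO1"]
        template, _ = plant_template(
            PlantSpec(pair=pair, product_len=450, fw_mismatches=1,
                      mismatch_in_clamp=True, seed=6)
        )
        assay = AssayDefinition("FO1", (pair,), 50.0)
        result = run_assay(assay, template)
        assert result.calls == set()
        # the relaxed tier still refuses a broken clamp entirely
        assert all(a.nonspecific for a in result.amplicons)

    def test_body_mismatch_band_seen_but_rated_negative(self, panel_by_group):
        pair = panel_by_group["SP6"]
        template, _ = plant_template(
            PlantSpec(pair=pair, product_len=500, fw_mismatches=2, seed=7)
        )
        assay = AssayDefinition("SP6", (pair,), 55.0)
        result = run_assay(assay, template)
        assert result.calls == set()
        assert "nonspecific_band" in result.flags
        assert any(a.nonspecific for a in result.amplicons)

    def test_close_bands_raise_collision_but_keep_calls(self, panel_by_group, rng):
        t4, sp6 = panel_by_group["T4"], panel_by_group["SP6"]
        a, _ = plant_template(PlantSpec(pair=t4, product_len=400, seed=11,
                                        background_len=600))
        b, _ = plant_template(PlantSpec(pair=sp6, product_len=430, seed=12,
                                        background_len=600))
        template = ConcreteTemplate("t", a.seq + b.seq)
        assay = _triplex(panel_by_group, ("T4", "T7", "SP6"), 52.0)
        result = run_assay(assay, template)
        assert result.calls == {"T4", "SP6"}
        assert "band_collision" in result.flags

    def test_strand_symmetry_of_calls_and_lengths(self, panel_by_group):
        assay = _triplex(panel_by_group, ("N4", "FO1", "GJ1"), 54.0)
        template, _ = plant_template(
            PlantSpec(pair=panel_by_group["GJ1"], product_len=600, seed=13)
        )
        fwd = run_assay(assay, template)
        rev = run_assay(assay, template.revcomp())
        assert fwd.calls == rev.calls
        assert sorted(a.length for a in fwd.amplicons) == sorted(
            a.length for a in rev.amplicons
        )

    def test_triplex_calls_equal_union_of_singleplex_calls(self, panel_by_group):
        result = make_panel(PanelConfig(positives_per_group=2, negatives=8, seed=21))
        groups = ("T4", "T7", "SP6")
        triplex = _triplex(panel_by_group, groups, 52.0)
        for template in result.templates:
            tri = run_assay(triplex, template)
            union = set()
            for g in groups:
                single = AssayDefinition(
                    g, (panel_by_group[g],), panel_by_group[g].annealing_temp
                )
                union |= run_assay(single, template).calls
            assert tri.calls == union


class TestEvaluatePanel:
    def test_perfect_panel_scores_perfectly(self, panel_by_group):
        result = make_panel(PanelConfig(positives_per_group=2, negatives=8, seed=3))
        assays = [
            AssayDefinition(g, (p,), p.annealing_temp)
            for g, p in panel_by_group.items()
        ]
        ev = evaluate_panel(assays, [(t, result.labels[t.id]) for t in result.templates])
        assert all(v == 1.0 for v in ev.sensitivity.values())
        assert all(v == 1.0 for v in ev.specificity.values())

    def test_all_negative_panel_has_nan_sensitivity(self, panel_by_group):
        result = make_panel(PanelConfig(positives_per_group=0, negatives=8, seed=5))
        assays = [
            AssayDefinition(g, (p,), p.annealing_temp)
            for g, p in panel_by_group.items()
        ]
        ev = evaluate_panel(assays, [(t, "negative") for t in result.templates])
        assert all(v == 1.0 for v in ev.specificity.values())
        assert all(np.isnan(v) for v in ev.sensitivity.values())

    def test_corrupted_clamp_counts_as_a_miss(self, panel_by_group):
        pair = panel_by_group["T4"]
        good, _ = plant_template(PlantSpec(pair=pair, product_len=300, seed=8,
                                           template_id="good"))
        bad, _ = plant_template(
            PlantSpec(pair=pair, product_len=300, fw_mismatches=1,
                      mismatch_in_clamp=True, seed=9, template_id="bad")
        )
        assay = AssayDefinition("T4", (pair,), 50.0)
        ev = evaluate_panel([assay], [(good, "T4"), (bad, "T4")])
        assert ev.sensitivity["T4"] == 0.5

    def test_unlabeled_template_is_an_error(self, panel_by_group):
        assay = AssayDefinition("T4", (panel_by_group["T4"],), 50.0)
        with pytest.raises(ValueError, match="label"):
            evaluate_panel([assay], [(ConcreteTemplate("t", "ACGT" * 30), "")])


class TestMultiplexCompatibility:
    def test_distinct_sizes_and_temps_are_compatible(self, panel_by_group):
        groups = ("T4", "T7", "SP6")
        refs = []
        for g, size in zip(groups, (200, 500, 900)):
            t, _ = plant_template(
                PlantSpec(pair=panel_by_group[g], product_len=size, seed=31,
                          template_id=f"ref_{g}")
            )
            refs.append(t)
        pairs = [panel_by_group[g] for g in groups]
        from dataclasses import replace

        pairs = [replace(p, annealing_temp=52.0) for p in pairs]
        report = check_multiplex_compatibility(pairs, refs)
        assert report.compatible
        assert report.temp_spread == 0.0

    def test_close_products_fail_with_named_groups(self, panel_by_group):
        groups = ("T4", "T7")
        refs = []
        for g, size in zip(groups, (300, 340)):
            t, _ = plant_template(
                PlantSpec(pair=panel_by_group[g], product_len=size, seed=33,
                          template_id=f"ref_{g}")
            )
            refs.append(t)
        report = check_multiplex_compatibility(
            [panel_by_group[g] for g in groups], refs, max_temp_spread=10.0
        )
        assert not report.compatible
        assert any("T4" in r and "T7" in r for r in report.reasons)

    def test_fewer_than_two_pairs_rejected(self, panel_by_group):
        with pytest.raises(ValueError):
            check_multiplex_compatibility([panel_by_group["T4"]], [])

    def test_three_prime_dimer_run_of_four(self):
        assert cross_dimer_3prime("GGCCAAAA", "GGCCTTTT") == 4

    def test_dimer_run_matches_exhaustive_overlap_oracle(self, rng):
        def oracle(a, b):
            from mcptyper.seqcore import COMPLEMENT, base_set

            best = 0
            for k in range(1, min(len(a), len(b)) + 1):
                if all(
                    base_set(COMPLEMENT[a[-j]]) & base_set(b[-(k + 1 - j)])
                    for j in range(1, k + 1)
                ):
                    best = k
            return best

        for _ in range(30):
            a = random_degenerate(rng, int(rng.integers(4, 12)))
            b = random_degenerate(rng, int(rng.integers(4, 12)))
            assert cross_dimer_3prime(a, b) == oracle(a, b)
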