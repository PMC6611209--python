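"""Panel aggregation, ranking, tier stratification and end-to-end scoring."""

import numpy as np
import pytest

import hanlon as h
from conftest import random_scenario


def make_panel(sheets: dict[str, dict[str, h.ComponentScores]]):
    return h.RaterPanel(raters=list(sheets), sheets=sheets)


def cs(a, b, c, e=3.0, f=1.0, **kw):
    return h.ComponentScores(size_a=a, seriousness=b, effectiveness=c,
                             inequity_e=e, positioning_f=f, **kw)


class TestAggregation:
    def test_mean_of_two_raters(self):
        panel = make_panel({
            "r1": {"X": cs(4, 10, 5)},
            "r2": {"X": cs(7, 12, 6)},
        })
        means = h.aggregate_panel(panel, "paho")
        assert means["X"].a == 5.5
        assert means["X"].b == 11.0
        assert means["X"].c == 5.5

    def test_identical_sheets_are_idempotent(self, pilot_panel):
        means = h.aggregate_panel(pilot_panel, "paho")
        assert means == h.PILOT_CONSENSUS

    def test_pilot_means_feed_through_to_published_bpr(self, pilot_panel):
        means = h.aggregate_panel(pilot_panel, "paho")
        assert round(h.bpr_paho(means["1.1"]).value, 1) == 27.3

    def test_factorwise_mean_when_all_raters_use_factors(self):
        panel = make_panel({
            "r1": {"X": h.ComponentScores(
                size_a=5, seriousness=h.SeriousnessFactors(1, 2, 3, 4),
                effectiveness=5, inequity_e=1, positioning_f=1)},
            "r2": {"X": h.ComponentScores(
                size_a=5, seriousness=h.SeriousnessFactors(3, 2, 1, 0),
                effectiveness=5, inequity_e=1, positioning_f=1)},
        })
        means = h.aggregate_panel(panel, "paho")
        assert means["X"].seriousness == h.SeriousnessFactors(2, 2, 2, 2)

    def test_strict_policy_names_rater_program_component(self):
        panel = make_panel({
            "r1": {"X": cs(4, 10, 5), "Y": cs(1, 1, 1)},
            "r2": {"X": cs(7, 12, 6)},  # never scored Y
        })
        with pytest.raises(h.ValidationError) as exc:
            h.aggregate_panel(panel, "paho", missing="strict")
        msg = str(exc.value)
        assert "r2" in msg and "'Y'" in msg

    def test_skip_policy_uses_contributing_raters(self):
        panel = make_panel({
            "r1": {"X": cs(4, 10, 5), "Y": cs(2, 2, 2)},
            "r2": {"X": cs(8, 12, 6)},
        })
        means = h.aggregate_panel(panel, "paho", missing="skip")
        assert means["X"].a == 6.0
        assert means["Y"].a == 2.0

    def test_empty_panel_rejected(self):
        with pytest.raises(h.ValidationError, match="empty"):
            h.aggregate_panel(h.RaterPanel([], {}), "paho")

    def test_median_statistic(self):
        panel = make_panel({
            "r1": {"X": cs(1, 10, 5)},
            "r2": {"X": cs(2, 10, 5)},
            "r3": {"X": cs(9, 10, 5)},
        })
        means = h.aggregate_panel(panel, "paho", statistic="median")
        assert means["X"].a == 2.0

    def test_pearl_unanimity(self):
        yes, no = h.PearlFlags(1, 1, 1, 1, 1), h.PearlFlags(1, 1, 1, 0, 1)
        panel = make_panel({
            "r1": {"X": cs(5, 10, 5, pearl=yes)},
            "r2": {"X": cs(5, 10, 5, pearl=no)},
        })
        means = h.aggregate_panel(panel, "neiger")
        assert means["X"].pearl == no

    def test_mean_components_stay_in_valid_ranges(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            panel = h.generate_panel(random_scenario(rng))
            means = h.aggregate_panel(panel, "paho")
            for m in means.values():
                assert 0 <= m.a <= 10 and 0 <= m.b <= 20
                assert 0 <= m.c <= 10 and 0 <= m.e <= 5
                assert 2 / 3 - 0.005 <= m.f <= 1.5


class TestRanking:
    def test_pilot_ranks(self):
        scores = {pid: h.bpr_paho(comps)
                  for pid, comps in h.PILOT_CONSENSUS.items()}
        ranks = {r.program.id: r.rank for r in h.rank_results(scores)}
        assert ranks == {"4.1": 1, "5.1": 2, "1.1": 3}

    def test_single_program(self):
        scores = {"X": h.bpr_neiger(cs(5, 10, 5))}
        [res] = h.rank_results(scores)
        assert res.rank == 1

    def test_competition_ranking_for_ties(self):
        def score(v):
            return h.BprScore("neiger", v, cs(5, 10, 5))
        ranks = {r.program.id: r.rank for r in h.rank_results(
            {"X": score(50.0), "Y": score(50.0), "Z": score(10.0)})}
        assert ranks == {"X": 1, "Y": 1, "Z": 3}

    def test_rank_bpr_consistency(self):
        rng = np.random.default_rng(11)
        panel = h.generate_panel(random_scenario(rng, n_programs=7))
        results = h.score_panel(panel, "paho")
        for p in results:
            for q in results:
                if p.rank < q.rank:
                    assert p.bpr.value >= q.bpr.value

    def test_empty_scores(self):
        assert h.rank_results({}) == []


class TestTiers:
    def test_tertile_on_24_catalog_programs(self):
        rng = np.random.default_rng(3)
        true = {p.id: cs(float(rng.uniform(0, 10)),
                         float(rng.uniform(0, 20)),
                         float(rng.uniform(0, 10)))
                for p in h.PROGRAM_CATALOG}
        panel = h.generate_panel(h.PanelScenario(
            true_components=true, n_raters=2, noise_sd=0.5, seed=1))
        results = h.score_panel(panel, "paho")
        counts = {t: sum(r.tier == t for r in results)
                  for t in ("high", "medium", "low")}
        assert counts == {"high": 8, "medium": 8, "low": 8}

    def test_tertile_on_three_pilot_programs(self, pilot_panel):
        results = h.score_panel(pilot_panel, "paho")
        tiers = {r.program.id: r.tier for r in results}
        assert tiers == {"4.1": "high", "5.1": "medium", "1.1": "low"}

    def test_explicit_thresholds(self, pilot_panel):
        results = h.score_panel(pilot_panel, "paho", tiers=(60.0, 30.0))
        tiers = {r.program.id: r.tier for r in results}
        assert tiers == {"4.1": "medium", "5.1": "medium", "1.1": "low"}

    def test_thresholds_must_decrease(self):
        with pytest.raises(h.ConfigError, match="strictly decreasing"):
            h.stratify_tiers([], cutoffs=(30.0, 60.0))
        with pytest.raises(h.ConfigError, match="unknown tier"):
            h.stratify_tiers([], cutoffs="quartile")

    def test_tier_monotone_in_bpr(self):
        rng = np.random.default_rng(5)
        panel = h.generate_panel(random_scenario(rng, n_programs=7))
        results = h.score_panel(panel, "paho")
        order = {"high": 0, "medium": 1, "low": 2}
        for p in results:
            for q in results:
                if order[p.tier] < order[q.tier]:
                    assert p.bpr.value >= q.bpr.value


class TestScorePanel:
    def test_pilot_end_to_end(self, pilot_panel):
        results = h.score_panel(pilot_panel, "paho")
        got = {r.program.id: (round(r.bpr.value, 1), r.rank)
               for r in results}
        assert got == {"1.1": (27.3, 3), "4.1": (38.4, 1),
                       "5.1": (37.7, 2)}

    def test_equals_composed_stages(self, pilot_panel):
        means = h.aggregate_panel(pilot_panel, "paho")
        scores = {pid: h.compute_bpr(m, "paho") for pid, m in means.items()}
        composed = h.stratify_tiers(
            h.rank_results(scores, mean_components=means))
        assert h.score_panel(pilot_panel, "paho") == composed

    def test_f_neutral_keeps_pilot_ranking(self, pilot_panel):
        # without F the PAHO scores are 34.9 / 34.3 / 27.3: same order
        neutral = {r: {pid: h.ComponentScores(
            size_a=cs_.size_a, seriousness=cs_.seriousness,
            effectiveness=cs_.effectiveness, inequity_e=cs_.inequity_e,
            positioning_f=1.0)
            for pid, cs_ in sheet.items()}
            for r, sheet in pilot_panel.sheets.items()}
        panel = h.RaterPanel(pilot_panel.raters, neutral)
        ranks = {r.program.id: r.rank
                 for r in h.score_panel(panel, "paho")}
        assert ranks == {"4.1": 1, "5.1": 2, "1.1": 3}

    def test_empty_program_list(self):
        assert h.score_panel(h.RaterPanel(["r1"], {"r1": {}}), "paho") == []

    def test_score_then_aggregate_variant(self):
        panel = make_panel({
            "r1": {"X": cs(2, 4, 2)},
            "r2": {"X": cs(8, 16, 8)},
        })
        canonical = h.score_panel(panel, "paho")[0].bpr.value
        variant = h.score_panel(panel, "paho",
                                aggregate_scores=True)[0].bpr.value
        per_rater = [h.bpr_paho(cs(2, 4, 2)).value,
                     h.bpr_paho(cs(8, 16, 8)).value]
        assert variant == pytest.approx(sum(per_rater) / 2)
        assert variant != canonical  # nonlinear equation


class TestOrderInvariance:
    def test_horizontal_vs_vertical_bit_identical(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            panel = h.generate_panel(random_scenario(rng))
            by_prog = h.aggregate_panel(panel, "paho",
                                        iteration="by_program")
            by_comp = h.aggregate_panel(panel, "paho",
                                        iteration="by_component")
            assert by_prog == by_comp

    def test_rater_and_program_permutation(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            panel = h.generate_panel(random_scenario(rng))
            results = h.score_panel(panel, "paho")
            perm_raters = list(rng.permutation(panel.raters))
            shuffled = h.RaterPanel(
                raters=perm_raters,
                sheets={r: dict(reversed(list(panel.sheets[r].items())))
                        for r in perm_raters})
            assert h.score_panel(shuffled, "paho") == results
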