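"""Generative observer model: percepts, decisions, full-table simulation."""

import math

import numpy as np
import pytest

import fovealbias as fb
from fovealbias.design import build_schedule
from fovealbias.observer import (
    ObserverParams,
    Percept,
    additive_cohort,
    decide_comparison,
    decide_selection,
    expected_proportion,
    perceive,
    report_appearance,
    simulate_experiment,
)


def sigma(x):
    return 1.0 / (1.0 + math.exp(-x))


def mc_binomial_margin(p, n, z=4.0):
    return z * math.sqrt(p * (1 - p) / n)


class TestPerceive:
    def test_certain_filling_in_hides_the_discontinuity(self, rng):
        p = ObserverParams.calibrated(p_fill=1.0)
        for _ in range(50):
            assert perceive(p, "scotopic", 0.0, "D", rng) is Percept.CONTINUOUS

    def test_gap_observer_sees_gap_only_at_the_scotopic_fovea(self, rng):
        p = ObserverParams.ideal("perceptual_gap")
        assert perceive(p, "scotopic", 0.0, "D", rng) is Percept.GAP
        assert perceive(p, "scotopic", 4.0, "D", rng) is Percept.DISCONTINUOUS
        assert perceive(p, "photopic", 0.0, "C", rng) is Percept.CONTINUOUS

    def test_veridical_limit(self, rng):
        p = ObserverParams.calibrated(
            accuracy={(l, e): 1.0 for l in ("scotopic", "photopic")
                      for e in (0.0, 4.0, 8.0)}
        )
        assert perceive(p, "photopic", 4.0, "C", rng) is Percept.CONTINUOUS
        assert perceive(p, "photopic", 8.0, "D", rng) is Percept.DISCONTINUOUS

    def test_half_accuracy_matches_truth_half_the_time(self, rng):
        p = ObserverParams.calibrated(
            accuracy={(l, e): 0.5 for l in ("scotopic", "photopic")
                      for e in (0.0, 4.0, 8.0)}
        )
        n = 10_000
        hits = sum(
            perceive(p, "scotopic", 4.0, "C", rng) is Percept.CONTINUOUS
            for _ in range(n)
        )
        assert abs(hits / n - 0.5) < mc_binomial_margin(0.5, n)

    def test_uncalibrated_eccentricity_rejected(self, rng):
        p = ObserverParams.calibrated()
        with pytest.raises(ValueError, match="eccentricity"):
            perceive(p, "photopic", 2.0, "C", rng)


class TestDecideComparison:
    def test_unique_match_wins(self, rng):
        p = ObserverParams.calibrated(lapse=0.0)
        pair = (Percept.CONTINUOUS, Percept.DISCONTINUOUS)
        assert decide_comparison(p, pair, (0.0, 4.0), "continuity", rng) == "first"
        assert decide_comparison(p, pair, (0.0, 4.0), "discontinuity", rng) == "second"

    def test_tie_with_equal_reliability_is_fair(self, rng):
        p = ObserverParams.ideal("filling_in")
        pair = (Percept.CONTINUOUS, Percept.CONTINUOUS)
        n = 10_000
        firsts = sum(
            decide_comparison(p, pair, (4.0, 4.0), "continuity", rng) == "first"
            for _ in range(n)
        )
        assert abs(firsts / n - 0.5) < mc_binomial_margin(0.5, n)

    def test_tie_bias_is_logistic_in_reliability_difference(self, rng):
        """A 1-logit reliability gap resolves ties at sigma(1) = 0.731."""
        rel = {("scotopic", 0.0): 1.0, ("scotopic", 4.0): 0.0,
               ("scotopic", 8.0): 0.0}
        p = ObserverParams.ideal("filling_in", reliability=rel)
        pair = (Percept.CONTINUOUS, Percept.CONTINUOUS)
        n = 20_000
        less = sum(
            decide_comparison(p, pair, (0.0, 4.0), "continuity", rng) == "first"
            for _ in range(n)
        )
        assert abs(less / n - sigma(1.0)) < mc_binomial_margin(sigma(1.0), n)

    def test_gap_decision_falls_to_the_other_interval(self, rng):
        p = ObserverParams.ideal("perceptual_gap")
        # peripheral continuous: never report the scotoma stimulus continuous
        pair = (Percept.GAP, Percept.CONTINUOUS)
        assert decide_comparison(p, pair, (0.0, 4.0), "continuity", rng) == "second"
        assert (
            decide_comparison(p, pair, (0.0, 4.0), "discontinuity", rng) == "first"
        )
        # peripheral discontinuous: the scotoma stimulus wins by elimination
        pair = (Percept.GAP, Percept.DISCONTINUOUS)
        assert decide_comparison(p, pair, (0.0, 4.0), "continuity", rng) == "first"
        assert (
            decide_comparison(p, pair, (0.0, 4.0), "discontinuity", rng) == "second"
        )

    def test_double_gap_flags_and_guesses(self, rng):
        p = ObserverParams.ideal("perceptual_gap")
        pair = (Percept.GAP, Percept.GAP)
        with pytest.warns(RuntimeWarning, match="GAP"):
            choice = decide_comparison(p, pair, (0.0, 0.0), "continuity", rng)
        assert choice in ("first", "second")


class TestDecideSelection:
    def test_no_preference_without_reliability_or_type_bias(self, rng):
        p = ObserverParams.ideal("filling_in")
        pair = (Percept.CONTINUOUS, Percept.DISCONTINUOUS)
        n = 10_000
        firsts = sum(
            decide_selection(p, pair, (0.0, 4.0), rng) == "first"
            for _ in range(n)
        )
        assert abs(firsts / n - 0.5) < mc_binomial_margin(0.5, n)

    def test_gap_stimulus_never_selected(self, rng):
        p = ObserverParams.ideal("perceptual_gap")
        pair = (Percept.GAP, Percept.CONTINUOUS)
        assert all(
            decide_selection(p, pair, (0.0, 4.0), rng) == "second"
            for _ in range(200)
        )

    def test_sequence_averaging_cancels_type_preference(self, rng):
        """Averaging the two type assignments removes the delta term."""
        dr, delta = 0.6, 1.2
        rel = {("scotopic", 0.0): dr, ("scotopic", 4.0): 0.0,
               ("scotopic", 8.0): 0.0}
        p = ObserverParams.ideal("filling_in", reliability=rel, type_pref=delta)
        n = 20_000
        # C at the fovea vs D at 4 deg, and the reverse assignment
        sel_c_low = sum(
            decide_selection(
                p, (Percept.CONTINUOUS, Percept.DISCONTINUOUS), (0.0, 4.0), rng
            ) == "first"
            for _ in range(n)
        ) / n
        sel_d_low = sum(
            decide_selection(
                p, (Percept.DISCONTINUOUS, Percept.CONTINUOUS), (0.0, 4.0), rng
            ) == "first"
            for _ in range(n)
        ) / n
        closed_form = 0.5 * (sigma(dr + delta) + sigma(dr - delta))
        averaged = 0.5 * (sel_c_low + sel_d_low)
        assert abs(sel_c_low - sigma(dr + delta)) < mc_binomial_margin(
            sigma(dr + delta), n
        )
        assert abs(averaged - closed_form) < mc_binomial_margin(closed_form, n)
        # the first-order delta effect is gone: the averaged preference sits
        # near sigma(dr), far from either single-assignment extreme
        assert abs(averaged - sigma(dr)) < 0.05
        assert abs(sel_c_low - sigma(dr)) > 0.15


class TestReportAppearance:
    def test_lapse_free_report_is_the_percept(self, rng):
        p = ObserverParams.calibrated(lapse=0.0)
        assert report_appearance(p, Percept.CONTINUOUS, rng) == "continuous"
        assert report_appearance(p, Percept.DISCONTINUOUS, rng) == "discontinuous"

    def test_lapse_rate_dilutes_the_report(self, rng):
        p = ObserverParams.calibrated(lapse=0.1)
        n = 20_000
        hits = sum(
            report_appearance(p, Percept.DISCONTINUOUS, rng) == "discontinuous"
            for _ in range(n)
        )
        assert abs(hits / n - 0.95) < mc_binomial_margin(0.95, n)

    def test_filled_in_discontinuity_reported_continuous(self, rng):
        """A foveal scotopic D stimulus reads continuous at rate
        p_fill*(1-lapse) + lapse/2 (closed form vs. simulation)."""
        p = ObserverParams.calibrated(p_fill=0.9, lapse=0.1, accuracy={
            (l, e): 1.0 for l in ("scotopic", "photopic")
            for e in (0.0, 4.0, 8.0)
        })
        # a(scotopic, 0) = 1: an unfilled foveal D reads veridically as D
        n = 20_000
        rate = sum(
            report_appearance(
                p, perceive(p, "scotopic", 0.0, "D", rng), rng
            ) == "continuous"
            for _ in range(n)
        ) / n
        closed = 0.9 * (1 - 0.1) + 0.1 / 2  # p_fill*(1-lapse) + lapse/2
        assert abs(rate - closed) < mc_binomial_margin(closed, n)


class TestSimulateExperiment:
    def test_perfect_photopic_observer_is_always_correct(self):
        schedule = build_schedule(1, seed=2, lighting="photopic")
        obs = ObserverParams.ideal("photopic_veridical", p_break=0.0)
        trials = simulate_experiment(schedule, [obs])
        same = trials[trials.ecc_first == trials.ecc_second]
        report = np.where(
            trials.loc[same.index, "response_comparison"] == "first",
            same.type_first, same.type_second,
        )
        assert (report == "C").all()

    def test_gap_observer_never_reports_the_scotoma_continuous(self):
        schedule = build_schedule(1, seed=2, lighting="scotopic")
        obs = ObserverParams.ideal("perceptual_gap", p_break=0.0)
        trials = simulate_experiment(schedule, [obs])
        df = fb.analysis.add_grouping(trials)
        cell = df[(df.group == "scotopic 0|4 D|C")]
        assert len(cell) == 24
        assert cell["chose_less_ecc"].mean() == 0.0

    def test_equal_weight_filling_in_observer_is_unbiased(self):
        obs = [
            ObserverParams.ideal("filling_in", observer_id=f"o{i}", rng_seed=i,
                                 p_break=0.0)
            for i in range(20)
        ]
        schedule = build_schedule(1, seed=2, lighting="scotopic")
        trials = simulate_experiment(schedule, obs)
        df = fb.analysis.add_grouping(trials)
        cell = df[df.group == "scotopic 0|4 D|C"]
        p = cell["chose_less_ecc"].mean()
        assert abs(p - 0.5) < mc_binomial_margin(0.5, len(cell))

    def test_empty_observer_list_rejected(self):
        schedule = build_schedule(1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            simulate_experiment(schedule, [])

    def test_reproducible_from_seeds(self):
        schedule = build_schedule(2, seed=4)
        obs = [ObserverParams.calibrated(2, observer_id="a", rng_seed=99)]
        t1 = simulate_experiment(schedule, obs)
        t2 = simulate_experiment(schedule, obs)
        assert t1.equals(t2)

    def test_validity_flag_matches_deviation(self, exp1_trials):
        assert (
            (exp1_trials["max_fixation_deviation"] <= 2.0)
            == exp1_trials["valid"]
        ).all()

    def test_instruction_symmetry(self):
        """Continuity- and discontinuity-instructed observers with identical
        parameters produce the same grouped proportions in expectation."""
        schedule = build_schedule(1, seed=6, lighting="scotopic")
        kw = dict(p_break=0.0, lapse=0.0)
        cont = [
            ObserverParams.calibrated(observer_id=f"c{i}", rng_seed=1000 + i,
                                      instruction="continuity", **kw)
            for i in range(12)
        ]
        disc = [
            ObserverParams.calibrated(observer_id=f"d{i}", rng_seed=2000 + i,
                                      instruction="discontinuity", **kw)
            for i in range(12)
        ]
        dfc = fb.analysis.add_grouping(simulate_experiment(schedule, cont))
        dfd = fb.analysis.add_grouping(simulate_experiment(schedule, disc))
        pc = dfc[~dfc.same_ecc].groupby("group")["chose_less_ecc"].mean()
        pd_ = dfd[~dfd.same_ecc].groupby("group")["chose_less_ecc"].mean()
        n_cell = dfc[~dfc.same_ecc].groupby("group").size().min()
        margin = 2 * mc_binomial_margin(0.5, n_cell)  # two independent MCs
        assert ((pc - pd_).abs() < margin).all()


class TestExpectedProportion:
    @pytest.mark.parametrize(
        "lighting, lo, hi, t_lo, t_hi, metric",
        [
            ("scotopic", 0.0, 4.0, "C", "C", "continuous"),
            ("scotopic", 0.0, 4.0, "D", "C", "continuous"),
            ("scotopic", 4.0, 8.0, "C", "C", "continuous"),
            ("photopic", 0.0, 8.0, "C", "D", "continuous"),
            ("scotopic", 0.0, 0.0, "C", "D", "correct"),
            ("scotopic", 4.0, 4.0, "C", "D", "correct"),
        ],
    )
    def test_closed_form_matches_simulation(
        self, exp1_trials, lighting, lo, hi, t_lo, t_hi, metric
    ):
        """The enumeration oracle agrees with the trial-level simulator."""
        params = ObserverParams.calibrated(1)
        want = expected_proportion(params, lighting, lo, hi, t_lo, t_hi, metric)
        df = fb.analysis.add_grouping(exp1_trials)
        types = "pooled" if lo == hi else f"{t_lo}|{t_hi}"
        cell = df[df.group == f"{lighting} {lo:g}|{hi:g} {types}"]
        col = "correct" if metric == "correct" else "chose_less_ecc"
        got = cell[col].mean()
        assert abs(got - want) < mc_binomial_margin(want, len(cell))

    def test_additive_observer_is_logit_additive_in_expectation(self):
        """logit p(0|8) equals logit p(0|4) + logit p(4|8) exactly."""
        obs = additive_cohort(1, 0, r0_minus_r4=0.6, r4_minus_r8=0.3)[0]
        p = {
            pair: expected_proportion(obs, "scotopic", *pair, "C", "C")
            for pair in [(0.0, 4.0), (4.0, 8.0), (0.0, 8.0)]
        }
        l = {k: math.log(v / (1 - v)) for k, v in p.items()}
        assert l[(0.0, 4.0)] + l[(4.0, 8.0)] == pytest.approx(l[(0.0, 8.0)])

    def test_uniform_foveal_bonus_cancels_in_the_additivity_sum(self):
        """A bonus applied to every pair containing the fovea shifts both
        the summed and the observed logit equally, leaving the data
        additive; only a pair-specific bonus breaks additivity."""
        uniform = additive_cohort(
            1, 0, pair_bonus={(0.0, 4.0): 0.5, (0.0, 8.0): 0.5}
        )[0]
        lopsided = additive_cohort(1, 0, pair_bonus={(0.0, 8.0): 0.5})[0]
        for obs, expected_gap in [(uniform, 0.0), (lopsided, -0.5)]:
            l = {}
            for pair in [(0.0, 4.0), (4.0, 8.0), (0.0, 8.0)]:
                v = expected_proportion(obs, "scotopic", *pair, "C", "C")
                l[pair] = math.log(v / (1 - v))
            gap = l[(0.0, 4.0)] + l[(4.0, 8.0)] - l[(0.0, 8.0)]
            assert gap == pytest.approx(expected_gap, abs=1e-12)
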