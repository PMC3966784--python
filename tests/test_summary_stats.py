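"""Individual/group summaries, hypothesis tests, diel budgets."""

import itertools

import numpy as np
import pytest

from divetag import dive_classification as dc
from divetag import diel_solar as ds
from divetag import sequence_analysis as sq
from divetag import summary_stats as ss
from divetag.synthetic_data import REFERENCE_INDIVIDUALS

from conftest import build_log, classify_by_depth


def summaries_from_reference():
    """IndividualSummary objects carrying the published per-individual
    medians/ranges/counts (the worked-example inputs)."""
    out = []
    for wid, ref in REFERENCE_INDIVIDUALS.items():
        s = ss.IndividualSummary(wid)
        for var, key, n_key in [
            ("deep_depth_m", "deep_depth_m", "n_deep"),
            ("deep_duration_min", "deep_duration_min", "n_deep"),
            ("shallow_depth_m", "shallow_depth_m", "n_shallow"),
            ("shallow_duration_min", "shallow_duration_min", "n_shallow"),
            ("surfacing_duration_min", "surfacing_duration_min", "n_surfacing"),
            ("iddi_duration_min", "iddi_duration_min", "n_iddi"),
            ("iddi_n_shallow", "iddi_n_shallow", "n_iddi"),
        ]:
            med, lo, hi = ref[key]
            s.variables[var] = ss.VariableSummary(float(med), float(lo), float(hi), ref[n_key])
        s.deep_dive_rate = ref["deep_dive_rate"]
        out.append(s)
    return out


class TestIndividualSummary:
    def test_single_value_class(self):
        log = build_log([("dive", 65.6, 1168), ("surf", 2), ("dive", 20, 300),
                         ("surf", 2), ("dive", 65.6, 1168)])
        classified = classify_by_depth(log)
        s = ss.individual_summary("w1", classified, [], [], log.total_hours)
        v = s.variables["deep_depth_m"]
        assert (v.median, v.min, v.max, v.n) == (1168.0, 1168.0, 1168.0, 2)

    def test_interpolated_median_of_two(self):
        log = build_log([("dive", 59.2, 1400), ("surf", 2), ("dive", 78.4, 1500)])
        s = ss.individual_summary("w1", classify_by_depth(log), [], [], log.total_hours)
        assert s.variables["deep_duration_min"].median == pytest.approx(68.8)


class TestGroupSummary:
    def test_reproduces_published_deep_depth_statistics(self):
        g = ss.group_summary(summaries_from_reference(), "deep_depth_m")
        assert round(g.group_mean) == 1401
        assert round(g.group_sd, 1) == 137.8
        assert g.pooled_n == 1142

    def test_reproduces_published_rate_statistics(self):
        g = ss.group_summary(summaries_from_reference(), "deep_dive_rate")
        assert round(g.group_mean, 2) == 0.30
        assert g.group_sd == pytest.approx(0.05, abs=0.01)

    def test_population_sd_convention(self):
        # the published 137.8 requires the n denominator; the n-1 form
        # gives 147.4 and cannot have produced the printed value
        medians = [v["deep_depth_m"][0] for v in REFERENCE_INDIVIDUALS.values()]
        assert round(float(np.std(medians, ddof=0)), 1) == 137.8
        assert round(float(np.std(medians, ddof=1)), 1) == 147.4

    def test_identical_values_zero_sd(self):
        subs = summaries_from_reference()[:3]
        for s in subs:
            s.deep_dive_rate = 0.3
        g = ss.group_summary(subs, "deep_dive_rate")
        assert g.group_sd == 0.0

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            ss.group_summary(summaries_from_reference()[:1], "deep_depth_m")


def typed_bouts(durations_by_type):
    log_spec = []
    for btype, durs in durations_by_type.items():
        for d in durs:
            log_spec.append(("surf", d))
    log = build_log(log_spec)
    out = []
    i = 0
    for btype, durs in durations_by_type.items():
        for _ in durs:
            out.append(sq.TypedSurfacing(log.events[i], btype))
            i += 1
    return out


class TestBoutTypeComparison:
    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(5)
        groups = {t: rng.lognormal(np.log(1.9), 0.8, 300).tolist() for t in ("FS", "IS", "TS", "SS")}
        rep = ss.bout_type_comparison(typed_bouts(groups))
        assert rep.p_value > 0.01
        assert not any(p.significant for p in rep.pairwise)

    def test_shifted_terminal_bouts_detected(self):
        rng = np.random.default_rng(6)
        groups = {
            "FS": rng.lognormal(np.log(1.9), 0.8, 500).tolist(),
            "IS": rng.lognormal(np.log(1.66), 0.8, 2000).tolist(),
            "TS": (rng.lognormal(np.log(1.66), 0.8, 500) + 1.5).tolist(),
            "SS": rng.lognormal(np.log(1.9), 0.8, 8).tolist(),
        }
        rep = ss.bout_type_comparison(typed_bouts(groups))
        assert rep.p_value < 1e-6
        ts_is = next(p for p in rep.pairwise if {p.group_a, p.group_b} == {"TS", "IS"})
        assert ts_is.significant and ts_is.z > 3

    def test_two_singleton_tied_groups_h_zero(self):
        rep = ss.bout_type_comparison(typed_bouts({"FS": [2.0], "IS": [2.0]}))
        assert rep.h_statistic == 0.0

    def test_empty_type_excluded_with_warning(self):
        groups = {"FS": [1.0, 2.0, 1.5], "IS": [1.2, 1.8, 2.1], "TS": [3.0, 3.5, 2.8]}
        with pytest.warns(UserWarning, match="SS"):
            rep = ss.bout_type_comparison(typed_bouts(dict(groups, SS=[])))
        assert set(rep.group_n) == {"FS", "IS", "TS"}


class TestSensorModeComparison:
    def test_identical_samples_p_one(self):
        rep = ss.sensor_mode_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.p_value == pytest.approx(1.0)

    def test_exact_small_sample_matches_enumeration(self):
        rep = ss.sensor_mode_comparison([1, 2, 3], [4, 5, 6])
        assert rep.u_statistic == 0.0
        assert rep.p_value == pytest.approx(0.1)
        # enumeration oracle over all 20 rank arrangements
        pooled = [1, 2, 3, 4, 5, 6]
        us = []
        for combo in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in combo]
            b = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in a for y in b if x > y)
            us.append(min(u, 9 - u))
        # us already folds both tails (min of U and its mirror), so the
        # two-sided p is the share of arrangements at least as extreme
        p_exact = sum(1 for u in us if u <= 0) / len(us)
        assert rep.p_value == pytest.approx(p_exact)

    def test_half_minute_offset_detected_at_study_scale(self):
        # wet/dry vs depth-threshold bout durations, n ~ 3400 per arm
        rng = np.random.default_rng(8)
        for rep_i in range(5):
            wet = rng.lognormal(np.log(1.83), 1.0, 3380)
            depth5 = rng.lognormal(np.log(1.83), 1.0, 3429) + 0.5
            rep = ss.sensor_mode_comparison(wet, depth5)
            assert rep.p_value < 0.001
            assert rep.median_b > rep.median_a


class TestPairedDielTests:
    def test_identical_day_night_t_zero(self):
        r = ss.paired_diel_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ss.paired_diel_test([2, 2, 2, 2], [1, 1, 1, 1])

    def test_night_deeper_one_tailed(self):
        day = [1345, 1300, 1380, 1320, 1350, 1330, 1310, 1360]
        night = [d + 142 + o for d, o in zip(day, [-30, 10, 25, -12, 3, 18, -22, 9])]
        r = ss.paired_diel_test(day, night, "deep_depth_m", "night_greater")
        assert r.p_value < 0.01
        assert r.t_statistic < 0  # day minus night is negative
        assert r.df == 7

    def test_diel_contrasts_uses_default_tails(self):
        per_whale = {
            "deep_depth_m": ([1345.0] * 4 + [1300.0] * 4, [1487.0] * 4 + [1440.0] * 4),
        }
        out = ss.diel_contrasts(per_whale)
        assert out["deep_depth_m"].alternative == "night_greater"


class TestDielBudget:
    def test_fractions_sum_to_one_per_class(self, sim_zc010):
        log = sim_zc010.log
        classified, _ = dc.classify_dives(log, seed=0)
        assignments = ds.assign_diel(log.events, sim_zc010.positions)
        budget = ss.compute_diel_budget(log, classified, assignments)
        for diel in ("day", "night"):
            assert sum(budget.fractions[diel].values()) == pytest.approx(1.0, abs=1e-9)
            assert budget.deep_dives_per_hour[diel] > 0
        assert budget.hours["day"] + budget.hours["night"] == pytest.approx(
            log.total_hours, abs=1e-6
        )
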