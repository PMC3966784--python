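"""Deep/shallow classification, tail flagging, contextual reclassification."""

import numpy as np
import pytest

from divetag import dive_classification as dc
from divetag.behavior_log import BehaviorLogEvent

from conftest import T0, build_log, classify_by_depth
from datetime import timedelta


def make_dives(pairs, whale_id="w1"):
    """Dive events from (depth_m, duration_min) pairs, contiguous."""
    events = []
    t = T0
    for depth, dur in pairs:
        e = BehaviorLogEvent(whale_id, "dive", t, t + timedelta(minutes=dur), float(depth), "U")
        events.append(e)
        t = e.end + timedelta(minutes=2)
    return events


class TestKMeansTwoClass:
    def test_trivial_separation_at_published_modes(self):
        # two point-clouds at the group-mean deep and shallow modes
        dives = make_dives([(1401, 67)] * 3 + [(275, 21)] * 3)
        classified, report = dc.kmeans_two_class(dives, seed=0)
        assert [c.dive_class for c in classified] == ["deep"] * 3 + ["shallow"] * 3
        assert report.n_deep == 3 and report.n_shallow == 3
        assert report.cluster_centers["deep"] == (1401.0, 67.0)
        assert report.cluster_centers["shallow"] == (275.0, 21.0)
        # zero within-cluster variance -> complete separation
        assert report.anova_p == 0.0

    def test_labeling_invariant_to_seed(self):
        rng = np.random.default_rng(3)
        dives = make_dives(
            [(d, u) for d, u in zip(rng.uniform(200, 2000, 10), rng.uniform(10, 90, 10))]
        )
        base = [c.dive_class for c in dc.kmeans_two_class(dives, seed=0)[0]]
        for seed in (1, 7, 123):
            assert [c.dive_class for c in dc.kmeans_two_class(dives, seed=seed)[0]] == base

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_wcss_minimization(self, n, seed):
        rng = np.random.default_rng(seed)
        depths = np.concatenate(
            [rng.lognormal(np.log(1400), 0.2, n // 2), rng.lognormal(np.log(300), 0.4, n - n // 2)]
        )
        durs = rng.uniform(5, 90, n)
        dives = make_dives(list(zip(depths, durs)))
        got = [c.dive_class for c in dc.kmeans_two_class(dives, seed=0)[0]]
        assert got == dc.brute_force_two_class(dives)

    def test_too_few_dives_errors(self):
        with pytest.raises(dc.ClassificationError, match="insufficient"):
            dc.kmeans_two_class(make_dives([(1400, 60)] * 3))

    def test_degenerate_identical_dives_error(self):
        with pytest.raises(dc.ClassificationError, match="degenerate"):
            dc.kmeans_two_class(make_dives([(1400, 60)] * 6))

    def test_anova_reported_for_separated_classes(self):
        rng = np.random.default_rng(0)
        dives = make_dives(
            [(d, 60) for d in rng.normal(1400, 100, 30)]
            + [(d, 20) for d in rng.normal(300, 40, 30)]
        )
        _, report = dc.kmeans_two_class(dives, seed=0)
        assert report.anova_p < 1e-4


class TestFlagBorderline:
    def test_deep_minimum_flagged_by_percentile_rule(self):
        depths = [1000, 1100, 1200, 1300, 1400, 1500, 1600, 1700, 1800, 1900]
        dives = make_dives([(d, 60) for d in depths])
        classified = [dc.ClassifiedDive(e, "deep") for e in dives]
        flagged = dc.flag_borderline(classified)
        # direct percentile-computation oracle (linear interpolation, strict <)
        d_cut = np.percentile(depths, 5)
        expect = [d < d_cut for d in depths]
        assert [c.borderline for c in flagged] == expect
        assert flagged[0].borderline  # the minimum is below the 5th percentile

    def test_identical_class_values_never_flagged(self):
        dives = make_dives([(1400, 60)] * 8)
        classified = [dc.ClassifiedDive(e, "deep") for e in dives]
        assert not any(c.borderline for c in dc.flag_borderline(classified))

    def test_shallow_upper_tail_flagged(self):
        # shallow dives are flagged in the *upper* tail: unusually deep/long
        depths = [200, 220, 240, 260, 280, 300, 320, 340, 360, 700]
        dives = make_dives([(d, 20) for d in depths])
        classified = [dc.ClassifiedDive(e, "shallow") for e in dives]
        flagged = dc.flag_borderline(classified)
        assert flagged[-1].borderline
        assert sum(c.borderline for c in flagged) == 1

    def test_long_shallow_duration_flagged_even_at_typical_depth(self):
        pairs = [(250, d) for d in [18, 19, 20, 21, 22, 23, 24, 25, 26, 45]]
        classified = [dc.ClassifiedDive(e, "shallow") for e in make_dives(pairs)]
        assert dc.flag_borderline(classified)[-1].borderline


def fig2_style_log():
    """A deep-dive context with four consecutive ~500 m, ~35 min dives:
    the first two carry a deep label (flagged), the last two shallow."""
    spec = [
        ("dive", 60, 1500), ("surf", 2),
        ("dive", 35, 500), ("surf", 2),
        ("dive", 35, 500), ("surf", 2),
        ("dive", 35, 500), ("surf", 2),
        ("dive", 35, 500), ("surf", 2),
        ("dive", 60, 1500), ("surf", 2),
        ("dive", 20, 280),
    ]
    log = build_log(spec)
    dives = log.dives()
    classes = ["deep", "deep", "deep", "shallow", "shallow", "deep", "shallow"]
    classified = [dc.ClassifiedDive(e, c) for e, c in zip(dives, classes)]
    for i in (1, 2, 3, 4):  # the four anomalous dives are borderline
        classified[i].borderline = True
    return log, classified


class TestContextualReclassify:
    def test_fig2_run_of_questionable_deep_dives_broken(self):
        log, classified = fig2_style_log()
        out = dc.contextual_reclassify(log, classified)
        # the two deep-labeled 500 m dives flip to shallow ...
        assert out[1].dive_class == "shallow" and out[1].reclassified
        assert out[2].dive_class == "shallow" and out[2].reclassified
        assert out[1].original_class == "deep"
        # ... the shallow-labeled ones and the true deep neighbors do not
        assert out[3].dive_class == "shallow" and not out[3].reclassified
        assert out[0].dive_class == "deep" and not out[0].reclassified
        assert out[5].dive_class == "deep"

    def test_gap_adjacent_flagged_dive_retains_class(self):
        spec = [
            ("dive", 60, 1500), ("surf", 2),
            ("dive", 60, 1500), ("surf", 2),
            ("gap", 180),
            ("dive", 35, 500), ("surf", 2),
            ("dive", 60, 1500), ("surf", 2),
            ("dive", 60, 1500),
        ]
        log = build_log(spec)
        classified = classify_by_depth(log, threshold=450, flags={2})
        out = dc.contextual_reclassify(log, classified)
        assert out[2].dive_class == "deep" and not out[2].reclassified

    def test_unflagged_dives_never_altered(self):
        log, classified = fig2_style_log()
        for c in classified:
            c.borderline = False
        out = dc.contextual_reclassify(log, classified)
        assert not any(c.reclassified for c in out)
        assert [c.dive_class for c in out] == [c.original_class for c in out]

    def test_idempotent(self):
        log, classified = fig2_style_log()
        once = dc.contextual_reclassify(log, classified)
        snapshot = [(c.dive_class, c.reclassified, c.original_class) for c in once]
        twice = dc.contextual_reclassify(log, once)
        assert [(c.dive_class, c.reclassified, c.original_class) for c in twice] == snapshot

    def test_lone_deep_like_shallow_between_deep_dives_promoted(self):
        spec = [
            ("dive", 60, 1500), ("surf", 2),
            ("dive", 50, 1400), ("surf", 2),
            ("dive", 45, 900), ("surf", 2),  # lone 'shallow' far above class median
            ("dive", 60, 1500), ("surf", 2),
            ("dive", 20, 280), ("surf", 2),
            ("dive", 20, 260), ("surf", 2),
            ("dive", 22, 300),
        ]
        log = build_log(spec)
        classified = classify_by_depth(log, threshold=1000, flags={2})
        out = dc.contextual_reclassify(log, classified)
        assert out[2].dive_class == "deep" and out[2].reclassified


class TestFullChain:
    def test_reclassification_implies_borderline_and_class_change(self, sim_zc010):
        classified, report = dc.classify_dives(sim_zc010.log, seed=0)
        for c in classified:
            if c.reclassified:
                assert c.borderline
                assert c.dive_class != c.original_class
        assert report.n_reclassified <= report.n_flagged
        assert report.cluster_centers["deep"][0] > report.cluster_centers["shallow"][0]
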