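"""Sibling ParA inheritance statistics and population size comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from parabtrack import inheritance, lineage, profiles
from parabtrack.inheritance import (
    classify_max_inheritor, compare_inheritor_groups, compare_size_distributions,
    dunn_test, predict_random_inheritance, sibling_attributes,
    simulate_random_inheritance, SiblingPair,
)


def _pair(parent, big, small, len_big=3.0, len_small=2.0,
          max_to_larger=True, rate_big=0.25, rate_small=0.25):
    return SiblingPair(
        parent_id=parent, daughter_a=big, daughter_b=small,
        total_parA={big: len_big * 100, small: len_small * 100},
        max_parA={big: 80.0, small: 60.0},
        birth_length={big: len_big, small: len_small},
        birth_area={big: len_big * 0.5, small: len_small * 0.5},
        growth_rate={big: rate_big, small: rate_small},
        high_total_inheritor=big,
        max_inheritor=big if max_to_larger else small,
        larger=big,
    )


class TestClassifyMaxInheritor:
    def test_maximum_on_new_pole_side(self):
        who, tie = classify_max_inheritor(0.3 * 5, 0.5 * 5, 10, 11, 10)
        assert who == 10 and not tie

    def test_maximum_on_old_pole_side(self):
        who, tie = classify_max_inheritor(0.8 * 5, 0.5 * 5, 10, 11, 10)
        assert who == 11 and not tie

    def test_tie_at_plane_goes_to_larger_flagged(self):
        who, tie = classify_max_inheritor(2.5, 2.5, 10, 11, 11)
        assert who == 11 and tie


class TestRandomInheritancePrediction:
    def test_single_division_ratio(self):
        pred = predict_random_inheritance([_pair(1, 2, 3, 6.0, 4.0)])
        assert pred.expected_larger_count == pytest.approx(0.6)
        assert pred.observed_larger_count == 1

    def test_symmetric_divisions_expected_half(self):
        pairs = [_pair(i, 2 * i, 2 * i + 1, 2.5, 2.5) for i in range(1, 45)]
        pred = predict_random_inheritance(pairs)
        assert pred.n_divisions == 44
        assert pred.expected_larger_count == pytest.approx(22.0)

    def test_probabilities_sum_to_one_per_division(self):
        # each division's two daughter probabilities are p and 1 - p exactly
        for a, b in [(3.1, 2.2), (4.0, 1.0), (2.5, 2.5)]:
            pa = a / (a + b)
            pb = b / (a + b)
            assert pa + pb == 1.0

    def test_scale_invariance(self):
        p1 = predict_random_inheritance([_pair(1, 2, 3, 3.0, 2.0)])
        p2 = predict_random_inheritance([_pair(1, 2, 3, 30.0, 20.0)])
        assert p1.expected_larger_count == pytest.approx(p2.expected_larger_count)

    def test_uniform_placement_observed_tends_to_expected(self):
        pred = simulate_random_inheritance(10_000, asymmetry=0.6, seed=0)
        ratio = pred.observed_larger_count / pred.expected_larger_count
        assert ratio == pytest.approx(1.0, abs=0.02)


class TestGroupComparisons:
    def test_identical_groups_t_zero_p_one(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0.2, 0.3, 10)
        pairs = [_pair(i, 2 * i, 2 * i + 1, rate_big=r, rate_small=r)
                 for i, r in enumerate(rates, start=1)]
        res = compare_inheritor_groups(pairs, "growth_rate", "total")
        assert res["welch_t"] == pytest.approx(0.0, abs=1e-12)
        assert res["welch_p"] == pytest.approx(1.0)
        assert "undefined" in res["note"]  # all-tied pairs: Wilcoxon undefined

    def test_constant_difference_smallest_attainable_wilcoxon_p(self):
        n = 8
        pairs = [_pair(i, 2 * i, 2 * i + 1,
                       rate_big=0.30 + 0.001 * i, rate_small=0.25 + 0.001 * i)
                 for i in range(1, n + 1)]
        res = compare_inheritor_groups(pairs, "growth_rate", "total")
        # exact null: all 2^n sign assignments equally likely; the observed
        # all-positive ranking is one of two extremes (two-sided)
        assert res["wilcoxon_p"] == pytest.approx(2 * 2.0 ** (-n))

    def test_growth_advantage_detected_at_n40(self):
        rng = np.random.default_rng(1)
        pairs = []
        for i in range(1, 41):
            base = rng.uniform(0.2, 0.3)
            pairs.append(_pair(i, 2 * i, 2 * i + 1,
                               rate_big=base * 1.2 + rng.normal(0, 0.01),
                               rate_small=base + rng.normal(0, 0.01)))
        res = compare_inheritor_groups(pairs, "growth_rate", "total")
        assert res["welch_p"] < 0.05
        assert res["wilcoxon_p"] < 0.05
        assert res["mean_high"] > res["mean_low"]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_inheritor_groups([_pair(1, 2, 3)] * 5)

    def test_size_grouping_uses_larger_sibling(self):
        pairs = [_pair(i, 2 * i, 2 * i + 1, 3.0, 2.0) for i in range(1, 11)]
        res = compare_inheritor_groups(pairs, "area", "size")
        assert res["mean_high"] == pytest.approx(1.5)
        assert res["mean_low"] == pytest.approx(1.0)


def kruskal_h_by_hand(groups):
    """Hand-ranked Kruskal-Wallis H with tie correction (oracle)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    i = 0
    sorted_vals = pooled[order]
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1  # average rank, 1-based
        i = j + 1
    n = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


class TestSizeDistributions:
    FIXTURE = {
        "wt": np.array([3.1, 2.8, 3.4, 2.9, 3.2, 3.0]),
        "mutA": np.array([2.1, 2.4, 2.0, 2.6, 2.2, 2.3]),
        "mutB": np.array([3.9, 4.2, 3.7, 4.0, 4.4, 4.1]),
    }

    def test_identical_groups_h_zero(self):
        g = np.array([2.0, 2.5, 3.0, 3.5, 4.0])
        res = compare_size_distributions({"a": g, "b": g.copy()})
        assert res["H"] == 0.0 and res["p"] == 1.0

    def test_h_matches_hand_ranked_oracle(self):
        res = compare_size_distributions(self.FIXTURE)
        oracle = kruskal_h_by_hand(list(self.FIXTURE.values()))
        assert res["H"] == pytest.approx(oracle, abs=1e-10)

    def test_shifted_groups_flagged_by_dunn(self):
        rng = np.random.default_rng(2)
        a = rng.normal(3.0, 0.2, 40)
        b = rng.normal(4.5, 0.2, 40)
        res = compare_size_distributions({"a": a, "b": b})
        row = res["dunn"].iloc[0]
        assert row.p_adj < 0.05
        assert res["letters"]["a"] != res["letters"]["b"]

    def test_letter_classes_cluster_non_different_groups(self):
        rng = np.random.default_rng(3)
        groups = {
            "x1": rng.normal(3.0, 0.2, 50),
            "x2": rng.normal(3.02, 0.2, 50),   # indistinguishable from x1
            "y": rng.normal(5.0, 0.2, 50),
        }
        res = compare_size_distributions(groups)
        assert res["letters"]["x1"] == res["letters"]["x2"]
        assert res["letters"]["y"] != res["letters"]["x1"]

    def test_small_group_excluded(self, caplog):
        import logging
        groups = dict(self.FIXTURE)
        groups["tiny"] = np.array([1.0, 2.0])
        with caplog.at_level(logging.WARNING):
            res = compare_size_distributions(groups)
        assert res["n_groups"] == 3
        assert "excluded" in caplog.text

    def test_dunn_z_symmetry(self):
        d1 = dunn_test({"a": self.FIXTURE["wt"], "b": self.FIXTURE["mutA"]})
        d2 = dunn_test({"b": self.FIXTURE["mutA"], "a": self.FIXTURE["wt"]})
        assert d1.iloc[0].z == pytest.approx(-d2.iloc[0].z)


class TestSiblingAttributesOnSyntheticMovie:
    def test_totals_track_size_and_max_follows_truth(self, pipeline_run):
        cells = pipeline_run["cells"]
        truth = pipeline_run["truth"]
        cfg = pipeline_run["config"]
        profs = pipeline_run["profiles"]
        tree = lineage.build_lineage(cells)
        parA = profiles.profiles_from_table(profs, cells, cfg.pixel_size_um, "parA")
        first, last = {}, {}
        for p in parA:
            if p.cell_id not in first or p.frame < first[p.cell_id].frame:
                first[p.cell_id] = p
            if p.cell_id not in last or p.frame > last[p.cell_id].frame:
                last[p.cell_id] = p
        true_inheritor = {
            int(d.parent_id): int(d.max_inheritor)
            for d in truth.divisions.itertuples()
        }
        n = hits = 0
        for parent_id in tree.children:
            pair = sibling_attributes(tree, parent_id, first, last[parent_id])
            if pair is None:
                continue
            # totals scale with size by construction
            assert pair.high_total_inheritor == pair.larger
            n += 1
            hits += pair.max_inheritor == true_inheritor[parent_id]
        assert n >= 5
        assert hits == n  # geometric inheritor matches the generator's truth
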