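"""Microarray background tagging, detection filter, DE and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from dcquant import expression, synthetic
from dcquant.datatypes import DomainError, ExpressionMatrix


def _matrix(values, probe_ids=None, n_per_group=None):
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    n_per_group = n_per_group or n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    groups = {s: ("group1" if i < n_per_group else "group2")
              for i, s in enumerate(samples)}
    probe_ids = probe_ids or [f"p{i:04d}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                      columns=samples)
    return ExpressionMatrix(values=df, groups=groups)


class TestTagBackground:
    def test_lowest_twenty_percent_tagged(self):
        m = _matrix(np.arange(1, 11, dtype=float).reshape(10, 1).repeat(4, axis=1))
        mask = expression.tag_background(m)
        for s in m.values.columns:
            assert list(m.values.index[mask[s]]) == ["p0000", "p0001"]

    def test_exact_count_per_array(self):
        m, _ = synthetic.gen_microarray(n_probes=1000, seed=1)
        mask = expression.tag_background(m)
        assert (mask.sum(axis=0) == 200).all()

    def test_stable_tie_break_on_equal_intensities(self):
        m = _matrix(np.full((10, 4), 5.0))
        mask = expression.tag_background(m)
        assert list(m.values.index[mask["s0"]]) == ["p0000", "p0001"]

    def test_invalid_fraction_rejected(self):
        m = _matrix(np.ones((10, 4)))
        with pytest.raises(DomainError):
            expression.tag_background(m, fraction=1.0)


class TestDetectionThresholds:
    def test_zero_spread_background(self):
        m = _matrix(np.vstack([np.full((4, 4), 10.0), np.full((16, 4), 100.0)]))
        mask = expression.tag_background(m)
        thr = expression.detection_thresholds(m, mask)
        assert (thr == 10.0).all()

    def test_hand_computed_sample_sd(self):
        # background {8, 12}: mean 10, sample SD sqrt(8) -> 10 + 2*2.8284...
        vals = np.vstack([[[8.0] * 4], [[12.0] * 4], np.full((8, 4), 100.0)])
        m = _matrix(vals.reshape(10, 4))
        mask = expression.tag_background(m)
        thr = expression.detection_thresholds(m, mask)
        assert thr["s0"] == pytest.approx(10.0 + 2.0 * np.sqrt(8.0))

    def test_population_sd_flag(self):
        vals = np.vstack([[[8.0] * 4], [[12.0] * 4], np.full((8, 4), 100.0)])
        m = _matrix(vals.reshape(10, 4))
        mask = expression.tag_background(m)
        thr = expression.detection_thresholds(m, mask, ddof=0)
        assert thr["s0"] == pytest.approx(10.0 + 2.0 * 2.0)

    def test_translation_equivariance(self):
        m, _ = synthetic.gen_microarray(n_probes=200, seed=2)
        mask = expression.tag_background(m)
        thr1 = expression.detection_thresholds(m, mask)
        shifted = ExpressionMatrix(values=m.values + 17.5, groups=m.groups)
        thr2 = expression.detection_thresholds(shifted, mask)
        np.testing.assert_allclose(thr2, thr1 + 17.5, rtol=1e-12)


class TestDetectionFilter:
    def _fixture(self):
        # 3 probes x 8 samples (4 per group); thresholds all 100
        vals = np.array(
            [[200] * 8,                      # above everywhere -> retained
             [200, 200, 200, 50] * 2,        # 3/4 in both groups -> dropped
             [50, 50, 50, 50, 200, 200, 200, 200]],  # 0/4 then 4/4 -> retained
            dtype=float,
        )
        m = _matrix(vals)
        thr = pd.Series(100.0, index=m.values.columns)
        return m, thr

    def test_group_rule(self):
        m, thr = self._fixture()
        retained = expression.detection_filter(m, thr)
        assert retained == ["p0000", "p0002"]

    def test_exceeded_is_strict(self):
        m = _matrix(np.full((5, 4), 100.0))
        thr = pd.Series(100.0, index=m.values.columns)
        assert expression.detection_filter(m, thr) == []


class TestDifferentialExpression:
    def test_textbook_pooled_t(self):
        m = _matrix(np.array([[1, 2, 3, 4, 5, 6]], dtype=float), n_per_group=3)
        de = expression.differential_expression(m, ["p0000"], alpha=0.05)
        assert len(de) == 1
        row = de.iloc[0]
        assert row["t_statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert row["p_value"] == pytest.approx(0.0213, abs=2e-4)
        assert row["fold_change"] == pytest.approx(5.0 / 2.0)
        assert row["direction"] == "up"

    def test_matches_scipy_ttest(self):
        m, _ = synthetic.gen_microarray(n_probes=300, fold=1.5, seed=4)
        retained = list(m.values.index[:100])
        de = expression.differential_expression(m, retained, alpha=1.0)
        g1 = m.values.loc[de["probe_id"], m.samples_in("group1")]
        g2 = m.values.loc[de["probe_id"], m.samples_in("group2")]
        ref = stats.ttest_ind(g1, g2, axis=1, equal_var=True)
        np.testing.assert_allclose(de["t_statistic"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(de["p_value"], ref.pvalue, rtol=1e-10)

    def test_welch_matches_scipy(self):
        m, _ = synthetic.gen_microarray(n_probes=100, fold=1.5, seed=5)
        retained = list(m.values.index[:50])
        de = expression.differential_expression(m, retained, alpha=1.0, test="welch")
        g1 = m.values.loc[de["probe_id"], m.samples_in("group1")]
        g2 = m.values.loc[de["probe_id"], m.samples_in("group2")]
        ref = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
        np.testing.assert_allclose(de["p_value"], ref.pvalue, rtol=1e-8)

    def test_zero_variance_probe_excluded_with_warning(self):
        vals = np.vstack([np.full((1, 8), 5.0),
                          np.arange(8, dtype=float).reshape(1, 8) + 1])
        m = _matrix(vals)
        with pytest.warns(UserWarning, match="zero variance"):
            de = expression.differential_expression(m, ["p0000", "p0001"], alpha=1.0)
        assert "p0000" not in set(de["probe_id"])

    def test_identical_groups_not_significant(self):
        vals = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        m = _matrix(vals, n_per_group=3)
        de = expression.differential_expression(m, ["p0000"], alpha=0.05)
        assert de.empty

    def test_probe_row_permutation_invariance(self):
        m, _ = synthetic.gen_microarray(n_probes=200, fold=3.0, seed=6)
        det = expression.detect(m)
        de1 = expression.differential_expression(m, det.retained_probes)
        perm = m.values.sample(frac=1.0, random_state=1)
        mp = ExpressionMatrix(values=perm, groups=m.groups)
        det2 = expression.detect(mp)
        de2 = expression.differential_expression(mp, det2.retained_probes)
        assert set(det.retained_probes) == set(det2.retained_probes)
        merged = de1.merge(de2, on="probe_id", suffixes=("_a", "_b"))
        assert len(merged) == len(de1) == len(de2)
        np.testing.assert_allclose(merged["p_value_a"], merged["p_value_b"])


def brute_force_upgma(dist: np.ndarray, labels: list) -> list:
    """Naive average-linkage oracle: at each step re-average the original
    pairwise distances over all cross-cluster member pairs."""
    clusters = {lab: frozenset([i]) for i, lab in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for la, lb in itertools.combinations(sorted(clusters), 2):
            members_a, members_b = clusters[la], clusters[lb]
            d = np.mean([dist[i, j] for i in members_a for j in members_b])
            key = tuple(sorted((la, lb)))
            if best is None or d < best[0] - 1e-15 or (
                abs(d - best[0]) <= 1e-15 and key < best[1]
            ):
                best = (d, key)
        d, (la, lb) = best
        merges.append((la, lb, d, len(clusters[la]) + len(clusters[lb])))
        clusters[min(la, lb)] = clusters.pop(la) | clusters.pop(lb)
    return merges


class TestClustering:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(100, 20, size=(20, 1))
        vals = np.hstack([base, base, rng.normal(100, 20, (20, 2))])
        m = _matrix(vals)
        dendro = expression.cluster_samples(m)
        first = dendro.merges[0]
        assert {first[0], first[1]} == {"s0", "s1"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(10, 1000, size=(30, 5))
        m1 = _matrix(vals, n_per_group=2)
        vals2 = vals.copy()
        vals2[:, 3] = np.exp(vals2[:, 3] / 500.0)  # strictly monotone transform
        m2 = _matrix(vals2, n_per_group=2)
        d1 = expression.cluster_samples(m1)
        d2 = expression.cluster_samples(m2)
        assert d1.merges == d2.merges
        assert d1.newick == d2.newick

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = rng.uniform(1, 1000, size=(15, 6))
            m = _matrix(vals)
            dist = expression._spearman_distance(m.values)
            expected = brute_force_upgma(dist, list(m.values.columns))
            got = expression.cluster_samples(m).merges
            for (la, lb, h, n), (ela, elb, eh, en) in zip(got, expected):
                assert {la, lb} == {ela, elb}
                assert h == pytest.approx(eh, abs=1e-10)
                assert n == en

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 1000, size=(25, 6))
        m = _matrix(vals)
        dist = expression._spearman_distance(m.values)
        z = linkage(squareform(dist, checks=False), method="average")
        got = expression.cluster_samples(m)
        np.testing.assert_allclose(
            sorted(h for _, _, h, _ in got.merges), np.sort(z[:, 2]), atol=1e-10
        )

    def test_constant_sample_errors_with_name(self):
        vals = np.random.default_rng(4).uniform(1, 100, (10, 4))
        vals[:, 2] = 7.0
        m = _matrix(vals)
        with pytest.raises(DomainError, match="s2"):
            expression.cluster_samples(m)

    def test_newick_parses_with_all_leaves(self):
        m, _ = synthetic.gen_microarray(n_probes=100, seed=7)
        dendro = expression.cluster_samples(m)
        assert dendro.newick.endswith(";")
        for s in m.values.columns:
            assert s in dendro.newick


class TestReport:
    def test_difference_and_fold_direction(self):
        vals = np.array([[10.0] * 4 + [20.0] * 4, [5.0] * 8])
        m = _matrix(vals)
        det = expression.DetectionResult(
            background_mask=pd.DataFrame(), thresholds=pd.Series(dtype=float),
            retained_probes=["p0000", "p0001"],
        )
        de = pd.DataFrame({"probe_id": ["p0000"], "t_statistic": [5.0],
                           "p_value": [0.001], "fold_change": [2.0],
                           "direction": ["up"]})
        report = expression.expression_report(m, det, de)
        row = report["by_absolute_difference"].iloc[0]
        assert row["abs_difference"] == pytest.approx(10.0)
        assert row["fold_change"] == pytest.approx(2.0)
        assert row["direction"] == "up"
        # equal-mean probe excluded from ranked lists
        assert "p0001" not in set(report["by_fold_change"]["probe_id"])

    def test_planted_de_probes_recovered_at_generous_effect(self):
        m, truth = synthetic.gen_microarray(
            n_probes=500, fold=4.0, de_fraction=0.1, seed=8
        )
        det = expression.detect(m)
        de = expression.differential_expression(m, det.retained_probes)
        report = expression.expression_report(m, det, de)
        assert set(truth.params["de_probe_ids"]) <= set(det.retained_probes)
        assert set(truth.params["de_probe_ids"]) <= set(de["probe_id"])
        assert report["n_significant"] == len(de)
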