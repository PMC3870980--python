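"""Tests of normalization, differential expression, heritability, kinetics,
correlation and clustering."""

import numpy as np
import pytest

from winemap import traits
from winemap.traits import (
    cluster_genes,
    correlate_with_trait,
    differential_expression,
    extract_kinetics,
    heritability,
    quantile_normalize,
)

from conftest import make_expression


class TestQuantileNormalize:
    def test_hand_example(self):
        em = make_expression(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(em)
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        em = make_expression(np.column_stack([col, col]))
        out = quantile_normalize(em)
        np.testing.assert_allclose(out.values, em.values)

    def test_columns_share_sorted_vector_and_ranks_preserved(self):
        rng = np.random.default_rng(1)
        em = make_expression(rng.normal(size=(30, 5)))
        out = quantile_normalize(em)
        ref = np.sort(out.values[:, 0])
        for j in range(5):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)
            assert np.array_equal(
                np.argsort(out.values[:, j]), np.argsort(em.values[:, j])
            )

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        em = make_expression(rng.normal(size=(25, 4)))
        once = quantile_normalize(em)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_missing_values_rejected(self):
        X = np.ones((5, 3)) * np.arange(5)[:, None]
        X[0, 0] = np.nan
        em = make_expression(np.where(np.isnan(X), 0, X))
        em.values[0, 0] = np.nan
        with pytest.raises(ValueError):
            quantile_normalize(em)


class TestDifferentialExpression:
    def _matrix(self, shift_rows, shift, noise, n_genes=50, n=5, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, noise, size=(n_genes, 2 * n))
        X[shift_rows, :n] += shift
        return make_expression(X)

    def test_overlapping_groups_rejected(self):
        em = self._matrix([], 0, 1)
        with pytest.raises(ValueError):
            differential_expression(em, em.sample_ids[:5], em.sample_ids[4:8])

    def test_significant_but_below_fold_change_filter(self):
        """A shift of 0.5 log2 is detectable yet fails the 0.7 logFC rule."""
        em = self._matrix([0], shift=0.5, noise=0.01, seed=3)
        de = differential_expression(em, em.sample_ids[:5], em.sample_ids[5:])
        assert de.iloc[0]["adjPv"] < 0.01
        assert not de.iloc[0]["passes_filter"]

    def test_full_shift_passes_filter(self):
        em = self._matrix([0], shift=1.0, noise=0.1, seed=4)
        de = differential_expression(em, em.sample_ids[:5], em.sample_ids[5:])
        assert de.iloc[0]["passes_filter"]
        assert de.iloc[0]["logFC"] == pytest.approx(1.0, abs=0.25)

    def test_null_false_positive_control(self):
        em = self._matrix([], shift=0, noise=1.0, n_genes=1000, seed=5)
        de = differential_expression(em, em.sample_ids[:5], em.sample_ids[5:])
        assert (de["adjPv"] < 0.01).sum() <= 10

    def test_bh_adjustment_monotone(self):
        em = self._matrix([0, 1, 2], shift=1.0, noise=0.5, n_genes=200, seed=6)
        de = differential_expression(em, em.sample_ids[:5], em.sample_ids[5:])
        assert (de["adjPv"] >= de["p"] - 1e-12).all()
        by_p = de.sort_values("p")["adjPv"].to_numpy()
        assert np.all(np.diff(by_p) >= -1e-12)

    def test_moderated_mode_agrees_on_strong_effects(self):
        em = self._matrix([0], shift=2.0, noise=0.2, seed=7)
        w = differential_expression(em, em.sample_ids[:5], em.sample_ids[5:], method="welch")
        m = differential_expression(em, em.sample_ids[:5], em.sample_ids[5:], method="moderated")
        assert w.iloc[0]["passes_filter"] and m.iloc[0]["passes_filter"]


class TestHeritability:
    def test_formula_arithmetic(self):
        # Var_seg = 100, Var_env = 20 -> 80%
        rng = np.random.default_rng(0)
        seg = rng.normal(0, 10, size=2000)
        seg = (seg - seg.mean()) / seg.std(ddof=1) * 10  # exact variance 100
        env = np.array([0.0, np.sqrt(2 * 20.0)])  # sample variance 20
        assert heritability(seg, env, env + 5) == pytest.approx(80.0)

    def test_env_equals_seg_gives_zero(self):
        seg = np.array([0.0, 2.0])  # variance 2
        par = np.array([0.0, 2.0])  # variance 2
        assert heritability(seg, par, par) == pytest.approx(0.0)

    def test_hand_example(self):
        # segregants {1,2,3,4}: variance 5/3; pooled parental variance 0.5 -> 70%
        assert heritability([1, 2, 3, 4], [0, 1], [10, 11]) == pytest.approx(70.0)

    def test_negative_estimate_warned_not_clipped(self):
        with pytest.warns(UserWarning, match="negative"):
            h = heritability([1.0, 1.1, 0.9, 1.05], [0, 10], [0, 10])
        assert h < 0

    def test_zero_segregant_variance_rejected(self):
        with pytest.raises(ValueError):
            heritability([1.0, 1.0, 1.0], [0, 1], [0, 1])


class TestKinetics:
    def test_linear_curve(self):
        t = np.linspace(0, 50, 101)
        k = extract_kinetics(t, 2.0 * t)
        assert k.Rmax == pytest.approx(2.0, rel=0.01)
        assert k.R70 == pytest.approx(2.0, rel=0.01)
        assert k.lag_time == pytest.approx(0.0, abs=0.5)

    def test_logistic_curve_closed_form(self):
        L, kk, t0 = 90.0, 0.15, 60.0
        t = np.linspace(0, 160, 400)
        y = L / (1 + np.exp(-kk * (t - t0)))
        k = extract_kinetics(t, y)
        assert k.Rmax == pytest.approx(L * kk / 4, rel=0.02)

    def test_r70_evaluated_at_seventy_percent_crossing(self):
        """A curve topping out at 94.3 g/l has its R70 read at the 66 g/l mark."""
        L, kk, t0 = 94.3, 0.1, 70.0
        t = np.linspace(0, 250, 600)
        y = L / (1 + np.exp(-kk * (t - t0)))
        k = extract_kinetics(t, y)
        total = k.total_CO2
        target = 0.7 * total
        assert target == pytest.approx(66.0, abs=0.15)
        t70 = t0 - np.log(L / target - 1) / kk
        expected_rate = L * kk * np.exp(-kk * (t70 - t0)) / (1 + np.exp(-kk * (t70 - t0))) ** 2
        assert k.R70 == pytest.approx(expected_rate, rel=0.02)

    def test_resampling_invariance(self):
        L, kk, t0 = 90.0, 0.12, 60.0
        t1 = np.linspace(0, 180, 300)
        t2 = np.linspace(0, 180, 900)
        k1 = extract_kinetics(t1, L / (1 + np.exp(-kk * (t1 - t0))))
        k2 = extract_kinetics(t2, L / (1 + np.exp(-kk * (t2 - t0))))
        assert k1.R70 == pytest.approx(k2.R70, rel=0.02)

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 10, 10)
        with pytest.raises(ValueError):
            extract_kinetics(t, t)

    def test_r70_never_exceeds_rmax(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 100, 200)
        y = np.cumsum(np.abs(rng.normal(1, 0.3, size=200)))
        k = extract_kinetics(t, y)
        assert k.R70 <= k.Rmax + 1e-9


class TestCorrelation:
    def test_perfect_correlations(self):
        trait = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        X = np.vstack([trait, -trait, np.array([1.0, 1.0, 2.0, 0.0, 1.5])])
        em = make_expression(X)
        out = correlate_with_trait(em, trait)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[1]["r"] == pytest.approx(-1.0)
        assert abs(out.iloc[2]["r"]) < 1.0

    def test_zero_variance_gene_reported_missing(self):
        X = np.vstack([np.ones(6), np.arange(6.0)])
        em = make_expression(X)
        out = correlate_with_trait(em, np.arange(6.0))
        assert np.isnan(out.iloc[0]["r"])
        assert out.iloc[1]["r"] == pytest.approx(1.0)

    def test_null_correlation_calibration(self):
        """At n=44 an independent gene stays below |r| = 0.3 with the
        probability the t transform of r predicts (about 95%)."""
        from scipy import stats as ss

        n, thr = 44, 0.3
        t = thr * np.sqrt((n - 2) / (1 - thr**2))
        expected = 1 - 2 * ss.t.sf(t, n - 2)
        rng = np.random.default_rng(7)
        n_runs = 400
        hits = sum(
            abs(np.corrcoef(rng.normal(size=n), rng.normal(size=n))[0, 1]) < thr
            for _ in range(n_runs)
        )
        assert hits / n_runs == pytest.approx(expected, abs=0.03)
        assert expected > 0.94


class TestClustering:
    def test_duplicated_pair_forms_single_cluster(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=20)
        X = np.vstack([base, base + rng.normal(0, 1e-3, 20), rng.normal(size=(18, 20))])
        em = make_expression(X)
        cs = cluster_genes(em, seed=8)
        pair = {em.gene_ids[0], em.gene_ids[1]}
        assert any(pair <= c for c in cs.clusters)

    def test_all_pairwise_rule_holds(self):
        rng = np.random.default_rng(9)
        block = rng.normal(size=20)
        X = np.vstack(
            [block + rng.normal(0, 0.1, 20) for _ in range(4)]
            + [rng.normal(size=(16, 20))]
        )
        em = make_expression(X)
        cs = cluster_genes(em, seed=9)
        for cluster in cs.clusters:
            rows = [em.gene_ids.index(g) for g in cluster]
            R = np.corrcoef(em.values[rows])
            off = R[~np.eye(len(rows), dtype=bool)]
            assert off.min() > cs.threshold_r

    def test_pure_noise_cluster_count_within_calibration(self):
        """The cutoff is chosen so that fewer than three chance clusters are
        expected; independent-noise data must respect that bound on
        average."""
        rng = np.random.default_rng(10)
        counts = []
        for s in range(6):
            em = make_expression(rng.normal(size=(30, 20)))
            cs = cluster_genes(em, seed=100 + s)
            counts.append(len(cs.clusters))
            assert cs.threshold_r >= 0.5
        assert np.mean(counts) < 3.0

    def test_too_few_genes_rejected(self):
        em = make_expression(np.random.default_rng(0).normal(size=(5, 10)))
        with pytest.raises(ValueError):
            cluster_genes(em)
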