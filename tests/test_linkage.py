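"""Tests of genotype probabilities, Haley-Knott scans, permutation
significance and linkage calling."""

import numpy as np
import pandas as pd
import pytest

from winemap import genome, linkage, simulate
from winemap.linkage import (
    GenotypeProbabilities,
    LODProfile,
    call_linkages,
    fdr_table,
    genotype_probabilities,
    hk_scan,
    lod_matrix,
    permutation_fdr_transcriptome,
    permutation_threshold_trait,
    threshold_at_fdr,
)
from winemap.simulate import MISSING, P1, P2, GenotypeMatrix, MarkerMap


def single_locus_probs(p1_indicator):
    grid = pd.DataFrame(
        {"chrom": [1], "pos_kbp": [10.0], "pos_cM": [10 / 3], "is_marker": [True]}
    )
    p = np.asarray(p1_indicator, dtype=float)[None, :]
    return GenotypeProbabilities(grid, p, [f"s{i}" for i in range(p.shape[1])])


class TestGenotypeProbabilities:
    def test_exact_at_typed_markers(self, two_marker_map):
        gm = GenotypeMatrix(two_marker_map, np.array([[P1], [P2]], dtype=np.int8), ["s1"])
        probs = genotype_probabilities(gm, step_cM=5.0)
        at_markers = probs.probs[probs.grid["is_marker"].to_numpy(), 0]
        np.testing.assert_allclose(at_markers, [1.0, 0.0])

    def test_midpoint_concordant_flanks_hand_value(self, two_marker_map):
        # 20 cM interval, both flanks P1: (1-r)^2 / ((1-r)^2 + r^2) with
        # r = (1 - e^-0.2)/2, i.e. about 0.990
        gm = GenotypeMatrix(two_marker_map, np.array([[P1], [P1]], dtype=np.int8), ["s1"])
        probs = genotype_probabilities(gm, step_cM=10.0)
        mid = probs.probs[~probs.grid["is_marker"].to_numpy(), 0]
        r = genome.haldane_r(10.0)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        assert mid[0] == pytest.approx(expected, abs=1e-9)
        assert mid[0] == pytest.approx(0.990, abs=0.001)

    def test_midpoint_discordant_flanks_is_half(self, two_marker_map):
        gm = GenotypeMatrix(two_marker_map, np.array([[P1], [P2]], dtype=np.int8), ["s1"])
        probs = genotype_probabilities(gm, step_cM=10.0)
        mid = probs.probs[~probs.grid["is_marker"].to_numpy(), 0]
        assert mid[0] == pytest.approx(0.5)

    def test_missing_marker_conditioned_on_flanks(self):
        table = pd.DataFrame(
            {
                "marker_id": ["a", "b", "c"],
                "chrom": [1, 1, 1],
                "pos_kbp": [3.0, 33.0, 63.0],
                "pos_cM": [1.0, 11.0, 21.0],
            }
        )
        mm = MarkerMap(table)
        gm = GenotypeMatrix(mm, np.array([[P1], [MISSING], [P1]], dtype=np.int8), ["s1"])
        probs = genotype_probabilities(gm, step_cM=50.0)
        # the missing middle marker behaves like a pseudo-marker between
        # concordant flanks: probability close to, but below, one
        mid = probs.probs[1, 0]
        assert 0.95 < mid < 1.0

    def test_uninformative_chromosome_gets_half(self, two_marker_map):
        gm = GenotypeMatrix(
            two_marker_map, np.array([[MISSING], [MISSING]], dtype=np.int8), ["s1"]
        )
        with pytest.warns(UserWarning, match="no informative"):
            probs = genotype_probabilities(gm)
        np.testing.assert_allclose(probs.probs, 0.5)

    def test_error_rate_shrinks_toward_half(self, two_marker_map):
        gm = GenotypeMatrix(two_marker_map, np.array([[P1], [P2]], dtype=np.int8), ["s1"])
        probs = genotype_probabilities(gm, error_rate=0.01)
        at_markers = probs.probs[probs.grid["is_marker"].to_numpy(), 0]
        np.testing.assert_allclose(at_markers, [0.99, 0.01])

    def test_grid_step(self, two_marker_map):
        gm = GenotypeMatrix(two_marker_map, np.array([[P1], [P2]], dtype=np.int8), ["s1"])
        probs = genotype_probabilities(gm, step_cM=2.5)
        cm = probs.grid["pos_cM"].to_numpy()
        assert np.all(np.diff(cm) <= 2.5 + 1e-9)


class TestHKScan:
    def test_constant_trait_gives_zero_profile(self):
        probs = single_locus_probs([0, 0, 1, 1, 0, 1, 0, 1])
        with pytest.warns(UserWarning, match="zero variance"):
            prof = hk_scan(probs, np.full(8, 3.0))
        np.testing.assert_allclose(prof.lod, 0.0)

    def test_hand_least_squares_example(self):
        # genotype [0,0,1,1], trait [0,1,1,2]: RSS0=2, RSS1=1, LOD = 2 log10 2
        probs = single_locus_probs([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="fewer than eight"):
            prof = hk_scan(probs, np.array([0.0, 1.0, 1.0, 2.0]))
        assert prof.lod[0] == pytest.approx(2 * np.log10(2.0), abs=1e-12)

    def test_matches_explicit_least_squares_oracle(self):
        """LOD from the correlation form equals (n/2) log10(RSS0/RSS1)
        computed by brute-force OLS, on random instances."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            x = rng.integers(0, 2, size=n).astype(float)
            if x.var() == 0:
                continue
            y = rng.normal(size=n) + x * rng.normal()
            probs = single_locus_probs(x)
            lod = lod_matrix(probs, y[None, :])[0, 0]
            X = np.column_stack([np.ones(n), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = float(((y - X @ beta) ** 2).sum())
            rss0 = float(((y - y.mean()) ** 2).sum())
            expected = (n / 2) * np.log10(rss0 / rss1)
            assert lod == pytest.approx(expected, abs=1e-9)

    def test_missing_trait_values_dropped(self):
        probs = single_locus_probs([0, 0, 0, 0, 1, 1, 1, 1, 0, 1])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, np.nan, np.nan])
        prof = hk_scan(probs, y)
        assert np.isfinite(prof.lod[0]) and prof.lod[0] > 1.0

    def test_lod_capped_on_perfect_fit(self):
        probs = single_locus_probs([0, 0, 0, 0, 1, 1, 1, 1])
        prof = hk_scan(probs, np.array([0.0, 0, 0, 0, 1, 1, 1, 1]))
        assert np.isfinite(prof.lod[0])
        assert prof.lod[0] == pytest.approx(4 * 12.0, rel=0.01)


class TestPermutationThreshold:
    def test_deterministic_for_fixed_seed(self, cross44):
        gm, _ = cross44
        probs = genotype_probabilities(gm)
        y = np.random.default_rng(1).normal(size=gm.n_segregants)
        a = permutation_threshold_trait(probs, y, n_perm=200, seed=3)
        b = permutation_threshold_trait(probs, y, n_perm=200, seed=3)
        assert a == b

    def test_planted_qtl_exceeds_threshold(self, cross44):
        gm, truth = cross44
        probs = genotype_probabilities(gm)
        tt = simulate.simulate_traits(gm, truth, target_H2=85.0, n_qtls=1, seed=13)
        y = tt.trait("polygenic")
        thr = permutation_threshold_trait(probs, y, n_perm=200, seed=13)
        prof = hk_scan(probs, y)
        assert prof.max_lod() > thr

    def test_null_trait_calibration(self, cross44):
        """Genome-wide false-positive rate near the nominal 5%."""
        gm, _ = cross44
        probs = genotype_probabilities(gm)
        rng = np.random.default_rng(14)
        y0 = rng.normal(size=gm.n_segregants)
        thr = permutation_threshold_trait(probs, y0, n_perm=400, fdr=0.05, seed=14)
        hits = 0
        n_rep = 120
        for _ in range(n_rep):
            y = rng.normal(size=gm.n_segregants)
            if lod_matrix(probs, y[None, :]).max() >= thr:
                hits += 1
        assert abs(hits / n_rep - 0.05) < 0.05


class TestTranscriptomeFdr:
    def test_fdr_arithmetic_from_counts(self):
        """1063 observed linkages at LOD 4 with a mean null count of 106.3
        corresponds to an FDR of 0.10."""
        rng = np.random.default_rng(15)
        observed = np.concatenate([np.full(1063, 4.5), np.full(937, 1.0)])
        null = np.vstack(
            [np.concatenate([np.full(k, 4.5), np.full(2000 - k, 1.0)])
             for k in (106, 107, 106, 106)]
        )
        null = null[:, rng.permutation(2000)]
        tab = fdr_table(observed, null, np.array([4.0]))
        assert tab["observed"].iloc[0] == 1063
        assert tab["null_mean"].iloc[0] == pytest.approx(106.25)
        assert tab["fdr"].iloc[0] == pytest.approx(0.10, abs=0.001)

    def test_counts_non_increasing_and_fdr_bounded(self, cross44):
        gm, truth = cross44
        em = simulate.simulate_expression(gm, truth, n_genes=120, seed=16)
        probs = genotype_probabilities(gm)
        tab = permutation_fdr_transcriptome(probs, em, n_perm=4, seed=16)
        assert (np.diff(tab["observed"]) <= 0).all()
        assert (np.diff(tab["null_mean"]) <= 1e-9).all()
        valid = tab["fdr"].dropna()
        assert ((valid >= 0) & (valid <= 1)).all()

    def test_pure_null_fdr_near_one_at_low_thresholds(self, cross44):
        gm, truth = cross44
        em = simulate.simulate_expression(
            gm, truth, n_genes=200, cis_frac=0, trans_frac=0, dosage_log2=0, seed=17
        )
        probs = genotype_probabilities(gm)
        tab = permutation_fdr_transcriptome(probs, em, n_perm=4, seed=17)
        low = tab[(tab["lod"] <= 2.5) & tab["fdr"].notna()]
        assert (low["fdr"] > 0.5).all()

    def test_threshold_selection(self):
        tab = pd.DataFrame(
            {"lod": [3.0, 4.0, 5.0], "observed": [50, 10, 1],
             "null_mean": [40.0, 1.0, 0.0], "fdr": [0.8, 0.1, 0.0]}
        )
        assert threshold_at_fdr(tab, 0.10) == 4.0
        assert threshold_at_fdr(tab, 0.01) == 5.0
        assert threshold_at_fdr(tab.assign(fdr=[0.9, 0.8, 0.7]), 0.05) == float("inf")


class TestCallLinkages:
    def _profile(self, lod_by_chrom):
        rows, lods = [], []
        for c, lod in lod_by_chrom.items():
            for i, v in enumerate(lod):
                rows.append((c, (i + 1) * 10.0, (i + 1) * 10.0 / 3, True))
                lods.append(v)
        grid = pd.DataFrame(rows, columns=["chrom", "pos_kbp", "pos_cM", "is_marker"])
        return LODProfile("t", grid, np.array(lods))

    def test_below_threshold_everywhere_is_empty(self):
        prof = self._profile({1: [0.5, 1.0, 0.4]})
        assert call_linkages(prof, threshold=3.0) == []

    def test_sharp_peak_and_interval(self):
        prof = self._profile({2: [1, 2, 10, 9.5, 5, 1]})
        recs = call_linkages(prof, threshold=3.0, drop=1.0)
        assert len(recs) == 1
        r = recs[0]
        assert (r.peak_chrom, r.peak_kbp, r.lod) == (2, 30.0, 10.0)
        assert r.ci_lo_kbp == 30.0 and r.ci_hi_kbp == 40.0

    def test_plateau_peaks_leftmost_and_interval_spans(self):
        prof = self._profile({1: [1, 6, 6, 6, 1]})
        recs = call_linkages(prof, threshold=3.0)
        assert recs[0].peak_kbp == 20.0
        assert recs[0].ci_lo_kbp == 20.0 and recs[0].ci_hi_kbp == 40.0

    def test_one_record_per_chromosome(self):
        prof = self._profile({1: [8, 1, 8], 2: [9, 1, 1]})
        recs = call_linkages(prof, threshold=3.0)
        assert len(recs) == 2
        assert sorted(r.peak_chrom for r in recs) == [1, 2]


class TestIntervalCoverage:
    def test_one_lod_interval_covers_planted_locus(self, sparse_map):
        """The 1-LOD support interval should bracket the true locus in most
        simulations at a 1-sd effect."""
        hits = trials = 0
        for s in range(25):
            gm, truth = simulate.simulate_cross(
                sparse_map, n_segregants=100, translocation=None, seed=300 + s
            )
            em = simulate.simulate_expression(
                gm, truth, n_genes=1, cis_frac=1.0, trans_frac=0.0,
                effect_size_log2=1.0, noise_sd=1.0, seed=300 + s,
            )
            gene, chrom, pos, _ = truth.planted_eqtls[0]
            probs = genotype_probabilities(gm)
            prof = hk_scan(probs, em.values[0], trait_id=gene)
            recs = [r for r in call_linkages(prof, threshold=2.0) if r.peak_chrom == chrom]
            if not recs:
                continue
            trials += 1
            r = max(recs, key=lambda r: r.lod)
            if r.ci_lo_kbp - 1e-9 <= pos <= r.ci_hi_kbp + 1e-9:
                hits += 1
        assert trials >= 15
        assert hits / trials >= 0.8
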