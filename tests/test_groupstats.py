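"""Two-sample t grids, max-t permutation correction, band clusters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qeegkit as qk


class TestTGrid:
    def test_identical_groups_zero_t(self):
        x = np.random.default_rng(0).normal(size=(4, 10))
        tg = qk.t_grid(x, x.copy())
        assert np.allclose(tg.t, 0.0)

    def test_matches_hand_worked_pooled_t(self):
        """3-vs-3 single-feature fixture worked by hand:
        A = (1, 2, 3), B = (2, 4, 6) -> meanA=2, meanB=4, ssA=2, ssB=8,
        sp2=(2+8)/4=2.5, se=sqrt(2.5*2/3), t=-2/se."""
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[2.0], [4.0], [6.0]])
        expected = -2.0 / np.sqrt(2.5 * (2.0 / 3.0))
        tg = qk.t_grid(a, b)
        assert tg.t[0] == pytest.approx(expected, abs=1e-12)

    def test_shape_contract(self):
        rng = np.random.default_rng(1)
        tg = qk.t_grid(rng.normal(size=(5, 912)), rng.normal(size=(7, 912)))
        assert tg.t.shape == (912,)

    def test_zero_variance_feature_flagged(self):
        a = np.ones((3, 2))
        b = np.ones((3, 2))
        a[:, 1] = [1.0, 2.0, 3.0]
        b[:, 1] = [4.0, 5.0, 6.0]
        tg = qk.t_grid(a, b)
        assert tg.t[0] == 0.0
        assert tg.zero_variance[0]
        assert not tg.zero_variance[1]


class TestMaxT:
    def test_defaults(self):
        x = np.random.default_rng(2).normal(size=(8, 5))
        m = qk.MaxTPermutation(x, np.array(["a"] * 4 + ["b"] * 4))
        assert m.n_perm == 10000
        assert m.alpha == 0.05

    def test_exact_enumeration_matches_montecarlo(self):
        """3 vs 3 has 20 distinct splits; exhaustive corrected p agrees
        with Monte Carlo within 2 binomial standard errors."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 15))
        x[3:, 0] += 2.0
        labels = np.array(["A"] * 3 + ["B"] * 3)
        exact = qk.maxt_test(x, labels, method="exact", n_perm=5000)
        mc = qk.maxt_test(x, labels, method="montecarlo", n_perm=5000, seed=4)
        se = np.sqrt(exact.p_corrected * (1 - exact.p_corrected) / 5000)
        assert np.all(
            np.abs(exact.p_corrected - mc.p_corrected) <= 2 * se + 1e-3
        )

    def test_auto_switches_to_exact_for_tiny_groups(self):
        x = np.random.default_rng(5).normal(size=(6, 4))
        rep = qk.maxt_test(x, np.array(["A"] * 3 + ["B"] * 3), n_perm=1000)
        assert rep.method == "exact"
        assert rep.n_perm == 20

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 40))
        labels = np.array(["A"] * 15 + ["B"] * 15)
        r1 = qk.maxt_test(x, labels, n_perm=300, seed=11)
        r2 = qk.maxt_test(x, labels, n_perm=300, seed=11)
        assert np.array_equal(r1.null_maxt, r2.null_maxt)
        assert np.array_equal(r1.p_corrected, r2.p_corrected)

    def test_corrected_p_in_unit_interval_and_mask_consistent(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(24, 60))
        x[12:, :3] += 1.5
        rep = qk.maxt_test(x, np.array(["A"] * 12 + ["B"] * 12),
                           n_perm=500, seed=8)
        assert np.all(rep.p_corrected > 0)
        assert np.all(rep.p_corrected <= 1)
        assert np.array_equal(rep.mask, np.abs(rep.t) > rep.threshold)

    def test_threshold_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(20, 30))
        labels = np.array(["A"] * 10 + ["B"] * 10)
        thresholds = [
            qk.maxt_test(x, labels, n_perm=400, alpha=a, seed=1).threshold
            for a in (0.01, 0.05, 0.10, 0.25)
        ]
        assert all(t1 >= t2 for t1, t2 in zip(thresholds, thresholds[1:]))

    def test_p_invariant_to_feature_order(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(20, 25))
        labels = np.array(["A"] * 10 + ["B"] * 10)
        perm = rng.permutation(25)
        r1 = qk.maxt_test(x, labels, n_perm=400, seed=2)
        r2 = qk.maxt_test(x[:, perm], labels, n_perm=400, seed=2)
        assert np.allclose(r1.p_corrected[perm], r2.p_corrected)

    def test_planted_single_cell_power(self):
        """A 1.5-z single-cell effect at n=50/50 is detected in most
        simulations despite max-t correction over 912 features."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 25
        for _ in range(n_sim):
            x = rng.standard_normal((100, 912))
            x[50:, 17] += 1.5
            rep = qk.maxt_test(
                x, np.array(["A"] * 50 + ["B"] * 50),
                n_perm=500, seed=int(rng.integers(2 ** 31)),
            )
            hits += bool(rep.mask[17])
        assert hits / n_sim > 0.8

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_null_maxt_positive_and_sorted(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(12, 8))
        rep = qk.maxt_test(x, np.array(["A"] * 6 + ["B"] * 6),
                           n_perm=200, seed=seed)
        assert np.all(rep.null_maxt >= 0)
        assert np.all(np.diff(rep.null_maxt) >= 0)


class TestBandSummary:
    def test_empty_mask_empty_summary(self, grid):
        rep = qk.SignificanceReport(
            t=np.zeros(912), threshold=5.0, mask=np.zeros(912, bool),
            p_corrected=np.ones(912), null_maxt=np.zeros(100),
            n_perm=100, alpha=0.05, seed=0, method="montecarlo",
            n_a=10, n_b=10,
        )
        summary = qk.summarize_bands(rep, grid, qk.MONTAGE_1020)
        assert summary.clusters.empty
        assert summary.bands.empty

    def test_four_cluster_mask_reproduced(self, grid):
        """A mask equal to the planted four-cluster cell set comes back as
        four labeled bands with the published frequency extents."""
        eff = qk.four_cluster_effects(1.0)
        mag = eff.magnitude_grid(qk.MONTAGE_1020, grid)
        mask = (mag != 0).ravel()
        t = np.sign(mag).ravel() * 6.0
        rep = qk.SignificanceReport(
            t=t, threshold=5.0, mask=mask, p_corrected=np.ones(912),
            null_maxt=np.zeros(100), n_perm=100, alpha=0.05, seed=0,
            method="montecarlo", n_a=10, n_b=10,
        )
        summary = qk.summarize_bands(rep, grid, qk.MONTAGE_1020)
        bands = summary.bands.set_index("band")
        assert set(bands.index) == {"theta", "alpha1", "alpha2", "beta1"}
        assert bands.loc["theta", ["f_lo", "f_hi"]].tolist() == [3.91, 5.86]
        assert bands.loc["alpha1", ["f_lo", "f_hi"]].tolist() == [8.59, 8.98]
        assert bands.loc["alpha2", ["f_lo", "f_hi"]].tolist() == [11.33, 12.5]
        assert bands.loc["beta1", ["f_lo", "f_hi"]].tolist() == [13.67, 18.36]
        assert bands.loc["theta", "sign"] == 1
        assert bands.loc["alpha1", "sign"] == -1

    def test_uncovered_bin_rejected(self, grid):
        rep = qk.SignificanceReport(
            t=np.zeros(912), threshold=5.0, mask=np.zeros(912, bool),
            p_corrected=np.ones(912), null_maxt=np.zeros(100),
            n_perm=100, alpha=0.05, seed=0, method="montecarlo",
            n_a=10, n_b=10,
        )
        with pytest.raises(ValueError, match="not covered"):
            qk.summarize_bands(rep, grid, qk.MONTAGE_1020,
                               band_definitions={"theta": (3.7, 7.6)})

    def test_planted_theta_effect_reported_with_positive_sign(
        self, model, normative_fit, grid
    ):
        """End to end: an increased-theta cohort yields a theta cluster
        whose t sign matches the direction of the planted change in the
        first group listed."""
        from conftest import extract_z

        eff = qk.EffectSpec([qk.EffectEntry(("T4",), 3.91, 5.86, 1.5)])
        cohort = qk.make_study_cohort(30, 30, model, eff, seed=20,
                                      reference=normative_fit)
        z = extract_z(cohort, normative_fit)
        rep = qk.maxt_test(z, cohort.table["group"].to_numpy(),
                           n_perm=800, seed=21)
        summary = qk.summarize_bands(rep, grid, qk.MONTAGE_1020)
        assert "theta" in summary.detected_bands
        # t = mean(A) - mean(B); the planted increase sits in group B
        assert summary.detected_bands["theta"] == -1
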