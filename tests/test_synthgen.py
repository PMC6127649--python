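"""Synthetic-cohort generator: closed-form spectra, determinism, effects."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency, mannwhitneyu

import qeegkit as qk


class TestSynthesizeRecording:
    def test_variance_matches_model_integral(self, model):
        """Parseval: realized signal variance equals the density integral
        (exactly per realization up to channel-gain factors)."""
        flat = qk.SpectralModel(
            bumps=(), background_exponent=0.0, background_age_exp=0.0,
            channel_gain_sd=0.0, global_gain_sd=0.0,
        )
        target = flat.total_power(8.0, n_samples=6000)
        ratios = []
        for seed in range(50):
            rec = qk.synthesize_recording(flat, 8.0, 60.0, seed=seed)
            ratios.append(rec.samples.var(axis=1).mean() / target)
        assert abs(np.mean(ratios) - 1.0) < 0.05
        assert np.allclose(ratios, 1.0, atol=0.02)  # exact-amplitude synthesis

    def test_bump_peak_at_construction_frequency(self):
        m = qk.SpectralModel(
            bumps=(qk.Bump(center=10.16, width=0.3, amplitude=50.0),),
            background_amplitude=0.1, channel_gain_sd=0.0, global_gain_sd=0.0,
        )
        grid = qk.band_grid(100.0)
        acc = np.zeros(48)
        for seed in range(10):
            rec = qk.synthesize_recording(m, 8.0, 60.0, seed=seed)
            spec = qk.subject_features(rec, geometric_correct=False)
            acc += spec.values.mean(axis=0)
        peak = grid.frequencies[np.argmax(acc)]
        assert peak == pytest.approx(10.15625)  # the 10.16 Hz bin

    def test_same_seed_bit_identical(self, model):
        r1 = qk.synthesize_recording(model, 7.0, 60.0, seed=123)
        r2 = qk.synthesize_recording(model, 7.0, 60.0, seed=123)
        assert np.array_equal(r1.samples, r2.samples)

    def test_duration_too_short(self, model):
        with pytest.raises(ValueError, match="duration"):
            qk.synthesize_recording(model, 8.0, 30.0, seed=0)

    def test_bump_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            qk.SpectralModel(bumps=(qk.Bump(center=60.0, width=1.0,
                                            amplitude=1.0),))

    def test_expected_periodogram_matches_closed_form(self):
        """Monte-Carlo averaged Bartlett periodogram equals the model's
        closed-form expected bin power (leakage-limited tolerance)."""
        m = qk.SpectralModel(channel_gain_sd=0.0, global_gain_sd=0.0)
        grid = qk.band_grid(100.0)
        expected = m.expected_bin_power(8.0, grid=grid)
        vals = []
        for seed in range(30):
            rec = qk.synthesize_recording(m, 8.0, 60.0, seed=seed)
            epochs = qk.segment_epochs(rec)
            cross = qk.bartlett_cross_spectrum(epochs, 100.0)
            vals.append(cross.diagonal_power()[:, grid.indices])
        ratio = np.mean(vals, axis=(0, 1)) / expected
        assert np.all(np.abs(ratio - 1.0) < 0.1)


class TestNormativeCohort:
    def test_sizes_and_age_range(self, model):
        cohort = qk.make_normative_cohort(50, (5, 11), model, seed=1)
        assert len(cohort) == 50
        ages = cohort.table["age"]
        assert ages.between(5, 11).all()
        assert {rec.age for rec in cohort} == set(ages)

    def test_fixed_seed_identical_cohort(self, model):
        c1 = qk.make_normative_cohort(5, (5, 11), model, seed=9)
        c2 = qk.make_normative_cohort(5, (5, 11), model, seed=9)
        assert c1.table.equals(c2.table)
        for r1, r2 in zip(c1, c2):
            assert np.array_equal(r1.samples, r2.samples)

    def test_too_small_cohort(self, model):
        with pytest.raises(ValueError):
            qk.make_normative_cohort(1, (5, 11), model, seed=0)


class TestStudyCohort:
    def test_unknown_electrode_rejected(self, model):
        eff = qk.EffectSpec([qk.EffectEntry(("Xz",), 4.0, 5.0, 1.0)])
        with pytest.raises(ValueError, match="montage"):
            qk.make_study_cohort(3, 3, model, eff, seed=0)

    def test_empty_effects_groups_exchangeable(self, model, normative_fit):
        from conftest import extract_z

        cohort = qk.make_study_cohort(
            20, 20, model, qk.EffectSpec([]), seed=3, reference=normative_fit
        )
        z = extract_z(cohort, normative_fit)
        g = cohort.table["group"].to_numpy()
        tg = qk.t_grid(z[g == "A"], z[g == "B"])
        assert abs(tg.t.mean()) < 0.15
        assert np.abs(tg.t).max() < 6.0

    def test_planted_z_shift_recovered(self, model, normative_fit):
        """A +1 z-unit planted shift produces an empirical group z
        difference of ~1 at the targeted cells (averaged over electrodes
        with independent gains and over two cohort draws)."""
        from conftest import extract_z

        eff = qk.EffectSpec([
            qk.EffectEntry(("T4", "O2", "F3", "Cz"), 3.91, 5.86, 1.0)
        ])
        grid = qk.band_grid(100.0)
        cells = eff.magnitude_grid(model.channel_labels, grid).ravel() != 0
        diffs = []
        for seed in (0, 1):
            cohort = qk.make_study_cohort(
                150, 150, model, eff, seed=seed, reference=normative_fit
            )
            z = extract_z(cohort, normative_fit)
            g = cohort.table["group"].to_numpy()
            d = z[g == "B"].mean(axis=0) - z[g == "A"].mean(axis=0)
            diffs.append(d[cells].mean())
        assert abs(np.mean(diffs) - 1.0) < 0.15

    def test_default_effects_match_four_cluster_table(self, grid):
        """The default effect spec plants exactly the four published
        band/electrode clusters (25 cells)."""
        expected = {
            ("T4", 3.91), ("Pz", 3.91), ("T4", 5.08), ("T4", 5.86),
            ("O2", 5.86),
            ("Fz", 8.59), ("C3", 8.59), ("Cz", 8.98), ("Fp1", 8.98),
            ("Fp2", 8.98), ("F3", 8.98), ("F4", 8.98),
            ("T4", 11.33), ("T4", 11.72), ("T5", 11.72), ("T4", 12.11),
            ("T5", 12.11), ("O1", 12.11), ("P3", 12.5), ("P4", 12.5),
            ("P4", 13.67), ("T5", 13.67), ("T4", 14.45), ("T4", 17.58),
            ("T4", 18.36),
        }
        eff = qk.four_cluster_effects()
        cells = eff.cells(qk.MONTAGE_1020, grid)
        assert len(cells) == 25
        assert cells == expected


class TestItemResponses:
    def test_zero_discrimination_item_independent_of_trait(self):
        spec = qk.default_item_spec(group_shift=2.0)
        table = qk.make_item_responses(spec, 300, seed=5)
        # item 0 has a ~ 0: responses carry no group information
        cont = (
            table.groupby(["group", spec.item_names[0]]).size()
            .unstack(fill_value=0)
        )
        _, p, *_ = chi2_contingency(cont)
        assert p > 0.01
        # a highly discriminating item clearly separates the groups
        cont2 = (
            table.groupby(["group", spec.item_names[1]]).size()
            .unstack(fill_value=0)
        )
        _, p2, *_ = chi2_contingency(cont2)
        assert p2 < 1e-6

    def test_null_shift_sum_scores_reject_at_alpha(self):
        """With no group shift the two-sample test on raw sum scores
        rejects at roughly its nominal rate, not more."""
        spec = qk.default_item_spec(group_shift=0.0)
        rejections = 0
        n_rep = 20
        for s in range(n_rep):
            table = qk.make_item_responses(spec, 150, seed=600 + s)
            items = list(spec.item_names)
            sums = table[items].sum(axis=1)
            a = sums[table["group"] == "A"]
            b = sums[table["group"] == "B"]
            rejections += mannwhitneyu(a, b).pvalue < 0.05
        assert rejections <= 4  # binomial(20, 0.05) upper tail

    def test_rows_per_subject_and_rater(self):
        spec = qk.default_item_spec(n_raters=2)
        table = qk.make_item_responses(spec, 10, seed=7)
        assert len(table) == 2 * 10 * 2
        assert set(table["rater"]) == {"R1", "R2"}

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            qk.ItemModelSpec(
                discriminations=np.array([1.0]),
                thresholds=[np.array([0.5, 0.5])],
            )


class TestLeadfield:
    def test_identity_option(self):
        lf = qk.make_leadfield(4, 4, kind="identity")
        assert np.array_equal(lf.matrix, np.eye(4))

    def test_fixed_seed_identical(self):
        l1 = qk.make_leadfield(5, 12, seed=3)
        l2 = qk.make_leadfield(5, 12, seed=3)
        assert np.array_equal(l1.matrix, l2.matrix)

    @pytest.mark.parametrize("seed", range(20))
    def test_full_rank_over_seeds(self, seed):
        lf = qk.make_leadfield(6, 15, seed=seed)
        assert np.linalg.matrix_rank(lf.matrix) == 6

    def test_degenerate_dimensions(self):
        with pytest.raises(ValueError):
            qk.make_leadfield(1, 5, seed=0)
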