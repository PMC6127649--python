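"""Graded-response IRT: EM fitting, EAP scores, latent group test."""

import numpy as np
import pandas as pd
import pytest

import qeegkit as qk


def _recovery_spec(shift=0.0, n_raters=1):
    return qk.ItemModelSpec(
        discriminations=np.array([1.8, 2.5, 1.2, 0.9, 1.5]),
        thresholds=[
            np.array([-1.0, 0.2, 1.3]),
            np.array([-0.5, 0.8, 2.0]),
            np.array([-1.5, 0.0, 1.5]),
            np.array([-0.8, 0.5, 1.8]),
            np.array([0.0, 1.0, 2.2]),
        ],
        group_shift=shift,
        n_raters=n_raters,
    )


@pytest.fixture(scope="module")
def recovery_fit():
    table = qk.make_item_responses(_recovery_spec(), 250, seed=3)
    return qk.fit_graded_model(table), table


class TestFitting:
    def test_loglik_monotone_nondecreasing(self, recovery_fit):
        fit, _ = recovery_fit
        assert np.all(np.diff(fit.ll_history) > -1e-6)

    def test_parameter_recovery(self, recovery_fit):
        fit, _ = recovery_fit
        spec = _recovery_spec()
        ok = 0
        total = 0
        for j in range(5):
            a_true = spec.discriminations[j]
            ok += abs(fit.discriminations[j, 0] - a_true) <= 0.25 * a_true
            total += 1
            for k, b_true in enumerate(spec.thresholds[j]):
                ok += abs(fit.thresholds[j][k] - b_true) <= 0.3
                total += 1
        assert ok / total >= 0.9

    def test_aic_formula(self, recovery_fit):
        fit, _ = recovery_fit
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_near_zero_discrimination_gives_tiny_loading(self):
        """An uninformative item fits with a near-zero standardized
        loading, mirroring the excluded background-frequency item."""
        spec = qk.default_item_spec(group_shift=0.0, n_raters=1)
        table = qk.make_item_responses(spec, 250, seed=4)
        fit = qk.fit_graded_model(table)
        loadings = np.abs(fit.loadings[:, 0])
        assert loadings[0] < 0.2       # the a ~ 0 item
        assert np.all(loadings[1:3] > 0.5)

    def test_loadings_invariant_to_reversed_categories_up_to_sign(
        self, recovery_fit
    ):
        """Reversing every item is the latent-axis flip, so only the
        loading magnitudes are identified; reversing a single item flips
        that item's sign relative to the rest."""
        fit, table = recovery_fit
        items = fit.model.items
        all_rev = table.copy()
        for item in items:
            all_rev[item] = table[item].max() - table[item]
        rfit = qk.fit_graded_model(all_rev)
        assert np.allclose(
            np.abs(rfit.loadings[:, 0]), np.abs(fit.loadings[:, 0]), atol=0.05
        )
        one_rev = table.copy()
        one_rev[items[0]] = table[items[0]].max() - table[items[0]]
        ofit = qk.fit_graded_model(one_rev)
        signs = np.sign(ofit.loadings[:, 0])
        assert signs[0] == -signs[1]
        assert np.all(signs[1:] == signs[1])

    def test_single_category_item_rejected(self):
        table = pd.DataFrame({
            "item_a": [0, 1, 2] * 20,
            "item_b": [1] * 60,
        })
        with pytest.raises(ValueError, match="single observed category"):
            qk.fit_graded_model(table)

    def test_too_few_observations(self):
        table = pd.DataFrame({"item_a": [0, 1] * 10})
        with pytest.raises(ValueError, match="at least 30"):
            qk.fit_graded_model(table)


class TestModelSelection:
    def test_aic_usually_prefers_one_factor_on_unidimensional_data(self):
        """The spurious two-factor likelihood gain is non-regular (the
        score of every extra loading vanishes identically at zero), so
        AIC prefers one factor typically but not uniformly; the median
        AIC margin over a handful of simulations is positive.  The full
        50-simulation calibration runs in the acceptance suite."""
        margins = []
        for s in range(4):
            table = qk.make_item_responses(_recovery_spec(), 125,
                                           seed=100 + s)
            f1 = qk.fit_graded_model(table, n_factors=1, tol=1e-3)
            f2 = qk.fit_graded_model(table, n_factors=2, tol=1e-3,
                                     n_quadrature=13)
            margins.append(f2.aic - f1.aic)
        assert np.median(margins) > 0


class TestEAP:
    def test_all_lowest_pattern_has_minimum_eap(self, recovery_fit):
        fit, table = recovery_fit
        items = fit.model.items
        patterns = table[items].drop_duplicates().to_numpy()
        scores = fit.eap_scores(patterns)
        lowest = np.zeros((1, 5), dtype=int)
        low_score = fit.eap_scores(lowest)[0]
        assert low_score <= scores.min() + 1e-9

    def test_modal_pattern_near_zero_on_symmetric_data(self):
        spec = qk.ItemModelSpec(
            discriminations=np.full(4, 1.5),
            thresholds=[np.array([-1.0, 1.0])] * 4,
        )
        table = qk.make_item_responses(spec, 400, seed=5)
        fit = qk.fit_graded_model(table)
        modal = np.ones((1, 4), dtype=int)  # middle category everywhere
        assert abs(fit.eap_scores(modal)[0]) < 0.25

    def test_eap_shrinks_relative_to_ml(self, recovery_fit):
        """|EAP| < |grid-search ML| for the extreme response patterns."""
        fit, _ = recovery_fit
        theta = fit.model.theta[:, 0]
        for pattern in (np.zeros((1, 5), int), np.full((1, 5), 3, int)):
            eap = fit.eap_scores(pattern)[0]
            from qeegkit.irt import _item_logprobs

            ll = np.zeros_like(theta)
            for j in range(5):
                lp = _item_logprobs(theta * fit.discriminations[j, 0],
                                    fit.thresholds[j])
                ll += lp[pattern[0, j]]
            ml = theta[np.argmax(ll)]
            assert abs(eap) < abs(ml)

    def test_unseen_category_rejected(self, recovery_fit):
        fit, _ = recovery_fit
        bad = np.array([[0, 0, 0, 0, 9]])
        with pytest.raises(ValueError, match="never seen"):
            fit.eap_scores(bad)

    def test_eap_deterministic(self, recovery_fit):
        fit, table = recovery_fit
        s1 = fit.eap_scores(table)
        s2 = fit.eap_scores(table)
        assert np.array_equal(s1, s2)


class TestLatentGroupTest:
    def test_planted_shift_detected_with_correct_sign(self):
        table = qk.make_item_responses(
            qk.default_item_spec(group_shift=1.0, n_raters=2), 50, seed=7
        )
        res = qk.latent_group_test(table)
        assert res.estimate > 0
        assert res.p_value < 0.05
        assert res.groups == ("A", "B")

    def test_result_schema(self):
        table = qk.make_item_responses(
            qk.default_item_spec(group_shift=0.8, n_raters=2), 40, seed=8
        )
        res = qk.latent_group_test(table)
        summary = res.summary()
        assert {"estimate", "se", "z", "p_value"} <= set(summary.columns)
        assert res.se > 0
        assert np.isfinite(res.z)

    def test_null_shift_usually_not_significant(self):
        rejections = 0
        for s in range(8):
            table = qk.make_item_responses(
                qk.default_item_spec(group_shift=0.0, n_raters=2),
                30, seed=600 + s,
            )
            res = qk.latent_group_test(table, max_iter=200)
            rejections += res.p_value < 0.05
        assert rejections <= 2

    def test_rater_offset_recovered(self):
        spec = qk.default_item_spec(group_shift=0.5, n_raters=2)
        spec.rater_offsets = np.array([0.0, 0.8])
        table = qk.make_item_responses(spec, 80, seed=9)
        res = qk.latent_group_test(table)
        assert res.rater_offsets["R2"] == pytest.approx(0.8, abs=0.45)

    def test_single_group_rejected(self):
        table = qk.make_item_responses(
            qk.default_item_spec(n_raters=2), 20, seed=10
        )
        table = table[table["group"] == "A"]
        with pytest.raises(ValueError, match="two groups"):
            qk.latent_group_test(table)
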