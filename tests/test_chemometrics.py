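"""Chemometrics against independent oracles: brute-force Kennard-Stone,
pseudoinverse least squares, scikit-learn PLS, and a naive LOOCV loop."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from kmnir import chemometrics as cm


# ---------------------------------------------------------------------------
# Kennard-Stone
# ---------------------------------------------------------------------------

def _kennard_stone_naive(x: np.ndarray, n_cal: int):
    """Plain-loop maximin selection (the algorithm's definition)."""
    n = x.shape[0]
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.sum((x[i] - x[j]) ** 2))
            if d > best[0]:
                best = (d, (i, j))
    selected = list(best[1])
    while len(selected) < n_cal:
        cand_best = (-1.0, None)
        for i in range(n):
            if i in selected:
                continue
            dmin = min(float(np.sum((x[i] - x[s]) ** 2)) for s in selected)
            if dmin > cand_best[0]:
                cand_best = (dmin, i)
        selected.append(cand_best[1])
    return selected


class TestKennardStone:
    def test_one_dimensional_example(self):
        x = np.array([[0.0], [1.0], [3.0], [10.0]])
        cal, val = cm.kennard_stone_split(x, 3)
        assert list(cal) == [0, 3, 2]
        assert list(val) == [1]

    def test_n_cal_two_is_max_distance_pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 4))
        cal, _ = cm.kennard_stone_split(x, 2)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        i, j = cal
        assert d[i, j] == pytest.approx(d.max())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_maximin(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        x = rng.normal(size=(n, 3))
        n_cal = int(rng.integers(2, n))
        cal, val = cm.kennard_stone_split(x, n_cal)
        assert list(cal) == _kennard_stone_naive(x, n_cal)
        assert sorted(list(cal) + list(val)) == list(range(n))

    def test_duplicate_rows_resolved_by_tie_rule(self):
        x = np.array([[0.0], [0.0], [5.0], [5.0]])
        cal, _ = cm.kennard_stone_split(x, 2)
        assert list(cal) == [0, 2]  # smallest-index pair among ties

    @pytest.mark.parametrize("bad", [1, 6, 7])
    def test_out_of_range_n_cal(self, bad):
        with pytest.raises(ValueError):
            cm.kennard_stone_split(np.random.default_rng(1).normal(size=(6, 2)), bad)

    def test_deterministic(self):
        x = np.random.default_rng(3).normal(size=(20, 5))
        a = cm.kennard_stone_split(x, 13)
        b = cm.kennard_stone_split(x, 13)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# NIPALS PLS
# ---------------------------------------------------------------------------

class TestPLS:
    def test_single_wavelength_equals_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 1))
        y = 2.5 * x[:, 0] + 1.0 + rng.normal(scale=0.1, size=15)
        model = cm.pls_fit(x, y, 1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        pred = cm.pls_predict(model, x)
        assert np.allclose(pred, slope * x[:, 0] + intercept, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_rank_equals_pseudoinverse(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        model = cm.pls_fit(x, y, 4)
        xc = x - x.mean(axis=0)
        beta = np.linalg.pinv(xc) @ (y - y.mean())
        pred_ls = y.mean() + xc @ beta
        assert np.allclose(cm.pls_predict(model, x), pred_ls, rtol=1e-8, atol=1e-8)

    @pytest.mark.parametrize("n_comp", [1, 2, 3])
    def test_matches_sklearn_predictions(self, n_comp):
        """Independent cross-check against scikit-learn's PLS (scale=False)."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 8))
        y = x @ rng.normal(size=8) + rng.normal(scale=0.2, size=20)
        model = cm.pls_fit(x, y, n_comp)
        sk = PLSRegression(n_components=n_comp, scale=False).fit(x, y[:, None])
        assert np.allclose(
            cm.pls_predict(model, x), sk.predict(x).ravel(), atol=1e-8
        )

    def test_exact_linear_response_gives_zero_rmsec(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 3))
        y = x @ np.array([1.0, -2.0, 0.5])
        model = cm.pls_fit(x, y, 3)
        assert np.sqrt(np.mean((cm.pls_predict(model, x) - y) ** 2)) < 1e-9

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        model = cm.pls_fit(x, y, 5)
        t = model.scores
        for i in range(5):
            for j in range(i + 1, 5):
                bound = 1e-8 * np.linalg.norm(t[:, i]) * np.linalg.norm(t[:, j])
                assert abs(t[:, i] @ t[:, j]) <= bound

    def test_calibration_predictions_centred(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(18, 10))
        y = rng.normal(size=18)
        model = cm.pls_fit(x, y, 3)
        assert cm.pls_predict(model, x).mean() == pytest.approx(model.y_mean, abs=1e-10)

    def test_prediction_is_affine(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = cm.pls_fit(x, y, 2)
        x1, x2 = rng.normal(size=(2, 6))
        alpha = 0.3
        mix = cm.pls_predict(model, (alpha * x1 + (1 - alpha) * x2)[None, :])
        parts = alpha * cm.pls_predict(model, x1[None, :]) + (
            1 - alpha
        ) * cm.pls_predict(model, x2[None, :])
        assert mix == pytest.approx(parts, rel=1e-10)

    def test_mean_spectrum_predicts_mean_response(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = cm.pls_fit(x, y, 2)
        assert cm.pls_predict(model, x.mean(axis=0))[0] == pytest.approx(model.y_mean)

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cm.pls_fit(np.random.default_rng(0).normal(size=(5, 3)), np.ones(5), 1)

    def test_too_many_components_rejected(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="n_latent"):
            cm.pls_fit(x, np.arange(5.0), 5)

    def test_shape_mismatch_on_predict(self):
        model = cm.pls_fit(
            np.random.default_rng(0).normal(size=(6, 4)), np.arange(6.0), 2
        )
        with pytest.raises(ValueError, match="wavelength"):
            cm.pls_predict(model, np.ones((2, 5)))


# ---------------------------------------------------------------------------
# LOOCV PRESS
# ---------------------------------------------------------------------------

def _press_naive(x, y, max_lv):
    """Double loop over held-out samples and LV counts using sklearn."""
    n = x.shape[0]
    press = np.zeros(max_lv)
    for a in range(1, max_lv + 1):
        for i in range(n):
            keep = np.arange(n) != i
            sk = PLSRegression(n_components=a, scale=False).fit(
                x[keep], y[keep, None]
            )
            press[a - 1] += float(
                (sk.predict(x[i : i + 1]).ravel()[0] - y[i]) ** 2
            )
    return press


class TestLOOCVPress:
    def test_exact_linear_single_column(self):
        x = np.linspace(0, 1, 10)[:, None]
        y = 3.0 * x[:, 0] + 0.5
        curve = cm.loocv_press(x, y, 1)
        assert curve.selected_lv == 1
        assert curve.press_value[0] < 1e-18

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(8, 5))
        y = x @ rng.normal(size=5) + rng.normal(scale=0.3, size=8)
        curve = cm.loocv_press(x, y, 3)
        naive = _press_naive(x, y, 3)
        assert np.allclose(curve.press_value, naive, rtol=1e-8)

    def test_selected_lv_stable_under_duplication(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(7, 4))
        y = x @ rng.normal(size=4) + rng.normal(scale=0.2, size=7)
        base = cm.loocv_press(x, y, 3)
        dup = cm.loocv_press(np.vstack([x, x]), np.concatenate([y, y]), 3)
        assert dup.selected_lv == base.selected_lv

    def test_tie_breaks_toward_fewer_lvs(self):
        # exact linear fit: PRESS is ~0 from LV 1 on; argmin must pick 1
        x = np.column_stack([np.linspace(0, 1, 12), np.linspace(0, 2, 12) ** 1.0])
        y = x[:, 0] * 2.0
        curve = cm.loocv_press(x, y, 3)
        assert curve.selected_lv == 1

    def test_infeasible_max_latent_rejected(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="max_latent"):
            cm.loocv_press(x, np.arange(5.0), 4)

    def test_rmsecv_from_selected_press(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(9, 4))
        y = x @ rng.normal(size=4) + rng.normal(scale=0.1, size=9)
        curve = cm.loocv_press(x, y, 3)
        expect = np.sqrt(curve.press_value[curve.selected_lv - 1] / 9)
        assert curve.rmsecv == pytest.approx(expect)


# ---------------------------------------------------------------------------
# Model evaluation metrics
# ---------------------------------------------------------------------------

class TestEvaluateModel:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(20, 6))
        y = x @ rng.normal(size=6) + 5.0 + rng.normal(scale=0.3, size=20)
        model = cm.pls_fit(x[:14], y[:14], 3)
        curve = cm.loocv_press(x[:14], y[:14], 3)
        return model, curve, x, y

    def test_direct_arithmetic_example(self):
        """y_val {1,2,3}, predictions {1.1,2.1,3.1}: RMSEP 0.1, SD 1, RPD 10."""
        y_val = np.array([1.0, 2.0, 3.0])
        pred = y_val + 0.1
        rmsep = np.sqrt(np.mean((pred - y_val) ** 2))
        sd = np.std(y_val, ddof=1)
        assert rmsep == pytest.approx(0.1)
        assert sd / rmsep == pytest.approx(10.0)
        # and via evaluate_model with a contrived exact model
        x = np.array([[1.0], [2.0], [3.0], [1.5], [2.5]])
        y = x[:, 0].copy()
        model = cm.pls_fit(x, y, 1)
        # shift validation references by -0.1 so predictions are off by +0.1
        rep = cm.evaluate_model(
            model, None, x[:2], y[:2], x[2:], y[2:] - 0.1, "f", "RAW"
        )
        assert rep.rmsep == pytest.approx(0.1, abs=1e-9)
        assert rep.rpd == pytest.approx(np.std(y[2:] - 0.1, ddof=1) / 0.1, rel=1e-6)

    def test_rpd_identity(self, fitted):
        model, curve, x, y = fitted
        rep = cm.evaluate_model(model, curve, x[:14], y[:14], x[14:], y[14:])
        sd = np.std(y[14:], ddof=1)
        assert rep.rpd == pytest.approx(sd / rep.rmsep, rel=1e-9)
        assert rep.rmsec >= 0 and rep.rmsecv >= 0 and rep.rmsep >= 0

    def test_perfect_predictions_give_infinite_rpd(self):
        x = np.linspace(0, 1, 8)[:, None]
        y = 2.0 * x[:, 0] + 1.0
        model = cm.pls_fit(x, y, 1)
        rep = cm.evaluate_model(model, None, x[:5], y[:5], x[5:], y[5:])
        assert rep.rmsep == pytest.approx(0.0, abs=1e-12)
        assert np.isinf(rep.rpd)

    def test_validation_order_invariance(self, fitted):
        model, curve, x, y = fitted
        rep = cm.evaluate_model(model, curve, x[:14], y[:14], x[14:], y[14:])
        perm = np.random.default_rng(1).permutation(6)
        rep_p = cm.evaluate_model(
            model, curve, x[:14], y[:14], x[14:][perm], y[14:][perm]
        )
        for f in ("rmsec", "rmsecv", "rmsep", "r2_cal", "r2_cv", "r2_pred", "rpd"):
            assert getattr(rep, f) == pytest.approx(getattr(rep_p, f), rel=1e-12)

    def test_constant_validation_reference_rejected(self, fitted):
        model, curve, x, y = fitted
        with pytest.raises(ValueError, match="RPD"):
            cm.evaluate_model(
                model, curve, x[:14], y[:14], x[14:], np.ones(6)
            )
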