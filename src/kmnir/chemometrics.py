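"""Calibration chemometrics: Kennard-Stone splitting, NIPALS PLS, PRESS.

The calibration workflow follows standard NIR practice: a deterministic
maximin-distance Kennard-Stone split into calibration and validation sets,
mean-centred (unscaled) NIPALS partial least squares, leave-one-out
cross-validated PRESS to pick the latent-variable count, and the usual
figures of merit (RMSEC/RMSECV/RMSEP, R², RPD).

RPD — the ratio of the validation set's reference-value standard deviation
to RMSEP — is the model-comparison statistic; values >= 3 conventionally
mark a usable quantitative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "PLSModel",
    "PressCurve",
    "ModelReport",
    "kennard_stone_split",
    "pls_fit",
    "pls_predict",
    "loocv_press",
    "evaluate_model",
]


# ---------------------------------------------------------------------------
# Kennard-Stone sample selection
# ---------------------------------------------------------------------------

def kennard_stone_split(
    spectra_matrix: ArrayLike, n_calibration: int
) -> tuple[NDArray[np.intp], NDArray[np.intp]]:
    """Deterministic Kennard-Stone maximin split.

    Seeds the calibration set with the two samples at maximal Euclidean
    distance, then repeatedly adds the sample whose minimum distance to the
    already-selected set is largest.  All ties break toward the smallest
    sample index, so the split is fully deterministic.  Unselected indices
    (in ascending order) form the validation set.

    Returns
    -------
    (calibration_indices, validation_indices)
        Calibration indices in selection order.
    """
    x = np.asarray(spectra_matrix, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if not (2 <= n_calibration < n):
        raise ValueError(
            f"n_calibration must be in [2, {n - 1}], got {n_calibration}"
        )

    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, -np.inf)
    # lexicographically smallest (i, j) among maximal-distance pairs
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    first = (min(i, j), max(i, j))
    np.fill_diagonal(d2, np.inf)

    selected = [first[0], first[1]]
    mask = np.ones(n, dtype=bool)
    mask[selected] = False
    # min squared distance from each remaining sample to the selected set
    min_d2 = np.minimum(d2[:, selected[0]], d2[:, selected[1]])
    while len(selected) < n_calibration:
        cand = np.where(mask, min_d2, -np.inf)
        nxt = int(np.argmax(cand))  # argmax takes the first (smallest) index on ties
        selected.append(nxt)
        mask[nxt] = False
        min_d2 = np.minimum(min_d2, d2[:, nxt])
    cal = np.asarray(selected, dtype=np.intp)
    val = np.nonzero(mask)[0].astype(np.intp)
    return cal, val


# ---------------------------------------------------------------------------
# NIPALS partial least squares
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSModel:
    """Mean-centred NIPALS PLS regression state.

    ``regression_vector`` maps a centred spectrum to the centred response:
    ``y_hat = y_mean + (x - x_mean) @ regression_vector``.
    """

    n_latent: int
    x_mean: NDArray[np.float64]
    y_mean: float
    weights: NDArray[np.float64]      # (n_wavelengths, n_latent)
    x_loadings: NDArray[np.float64]   # (n_wavelengths, n_latent)
    y_loadings: NDArray[np.float64]   # (n_latent,)
    regression_vector: NDArray[np.float64]
    scores: NDArray[np.float64] = field(repr=False, default=None)  # calibration T


_NIPALS_MAX_ITER = 500
_NIPALS_TOL = 1e-12


def _nipals(
    x0: NDArray[np.float64],
    y0: NDArray[np.float64],
    n_latent: int,
    allow_fewer: bool = False,
) -> tuple[NDArray, NDArray, NDArray, NDArray]:
    """NIPALS deflation on centred data; returns (W, P, q, T).

    When the deflated residual covariance vanishes (the response is
    exactly fitted or X is rank-exhausted) before ``n_latent`` components,
    the extraction stops there: with ``allow_fewer`` the truncated
    factorisation is returned, otherwise an error names the component.
    """
    n, p = x0.shape
    w_mat = np.empty((p, n_latent))
    p_mat = np.empty((p, n_latent))
    q_vec = np.empty(n_latent)
    t_mat = np.empty((n, n_latent))
    x, y = x0.copy(), y0.copy()
    scale = max(float(np.abs(x0).max(initial=0.0)), 1.0)
    done = 0
    for a in range(n_latent):
        w = x.T @ y
        nw = np.linalg.norm(w)
        if not np.isfinite(nw):
            raise ArithmeticError(
                f"NIPALS failed at component {a + 1}: non-finite weights"
            )
        if nw == 0.0:
            break
        # single-response PLS1: the weight vector is available in closed form,
        # so the power iteration converges in one pass
        w /= nw
        t = x @ w
        tt = float(t @ t)
        if tt < _NIPALS_TOL * scale**2:
            break
        p_load = x.T @ t / tt
        q = float(y @ t / tt)
        x = x - np.outer(t, p_load)
        y = y - q * t
        w_mat[:, a], p_mat[:, a], q_vec[a], t_mat[:, a] = w, p_load, q, t
        done += 1
    if done < n_latent and not allow_fewer:
        raise ArithmeticError(
            f"NIPALS residual exhausted at component {done + 1}: "
            f"only {done} latent variables are extractable"
        )
    return w_mat[:, :done], p_mat[:, :done], q_vec[:done], t_mat[:, :done]


def pls_fit(
    X: ArrayLike, y: ArrayLike, n_latent: int, allow_fewer: bool = False
) -> PLSModel:
    """Fit mean-centred NIPALS PLS1 with ``n_latent`` components.

    No variance scaling is applied (standard for absorbance spectra).  The
    regression vector ``B = W (PᵀW)⁻¹ q`` reproduces the sequential
    score/deflation model exactly.  With ``allow_fewer``, a response that
    is exactly fitted before ``n_latent`` components yields a model with
    the attainable component count instead of an error.
    """
    x = np.asarray(X, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[0] != yv.shape[0]:
        raise ValueError("X must be 2-D with one row per response value")
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 calibration samples")
    if not (1 <= n_latent <= min(n - 1, p)):
        raise ValueError(
            f"n_latent must be in [1, {min(n - 1, p)}], got {n_latent}"
        )
    if np.std(yv) == 0.0:
        raise ValueError("response y has zero variance")

    x_mean = x.mean(axis=0)
    y_mean = float(yv.mean())
    w_mat, p_mat, q_vec, t_mat = _nipals(
        x - x_mean, yv - y_mean, n_latent, allow_fewer=allow_fewer
    )
    beta = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_vec)
    return PLSModel(
        n_latent=w_mat.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=w_mat,
        x_loadings=p_mat,
        y_loadings=q_vec,
        regression_vector=beta,
        scores=t_mat,
    )


def pls_predict(model: PLSModel, X: ArrayLike) -> NDArray[np.float64]:
    """Predict responses: ``y_mean + (X - x_mean) @ B``."""
    x = np.asarray(X, dtype=np.float64)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"wavelength count {x.shape[1]} does not match model "
            f"({model.x_mean.shape[0]})"
        )
    return model.y_mean + (x - model.x_mean) @ model.regression_vector


# ---------------------------------------------------------------------------
# PRESS latent-variable selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PressCurve:
    """Leave-one-out PRESS per latent-variable count, with the argmin choice."""

    lv_index: NDArray[np.intp]
    press_value: NDArray[np.float64]
    selected_lv: int

    @property
    def rmsecv(self) -> float:
        """RMSECV at the selected latent-variable count."""
        n = getattr(self, "_n_samples", None)
        if n is None:
            raise AttributeError("PressCurve built without sample count")
        return float(np.sqrt(self.press_value[self.selected_lv - 1] / n))


def _press_predictions_per_lv(
    x0: NDArray, y0: NDArray, x_new: NDArray, max_latent: int
) -> NDArray[np.float64]:
    """Predictions of one held-out sample for every LV count 1..max_latent."""
    x_mean = x0.mean(axis=0)
    y_mean = float(y0.mean())
    w_mat, p_mat, q_vec, _ = _nipals(
        x0 - x_mean, y0 - y_mean, max_latent, allow_fewer=True
    )
    # sequential prediction: accumulate t_new_a * q_a with deflated x_new;
    # if the fold exhausted its residual early, later LV counts keep the
    # last attainable prediction
    x_res = x_new - x_mean
    pred = np.empty(max_latent)
    acc = y_mean
    for a in range(max_latent):
        if a < w_mat.shape[1]:
            t_new = float(x_res @ w_mat[:, a])
            acc += t_new * q_vec[a]
            x_res = x_res - t_new * p_mat[:, a]
        pred[a] = acc
    return pred


def loocv_press(X: ArrayLike, y: ArrayLike, max_latent: int) -> PressCurve:
    """Leave-one-out PRESS curve over latent-variable counts 1..``max_latent``.

    Each sample is held out in turn, the model refitted on the remainder and
    the held-out sample predicted at every LV count; ``PRESS(a) = Σᵢ
    (ŷ₋ᵢ(a) − yᵢ)²``.  The selected count attains the minimum, ties broken
    toward fewer latent variables.
    """
    x = np.asarray(X, dtype=np.float64)
    yv = np.asarray(y, dtype=np.float64).ravel()
    n = x.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if not (1 <= max_latent <= n - 2):
        raise ValueError(f"max_latent must be in [1, {n - 2}], got {max_latent}")
    max_latent = min(max_latent, x.shape[1])

    press = np.zeros(max_latent)
    for i in range(n):
        keep = np.arange(n) != i
        pred = _press_predictions_per_lv(x[keep], yv[keep], x[i], max_latent)
        press += (pred - yv[i]) ** 2
    selected = int(np.argmin(press)) + 1  # argmin returns first min: fewer LVs
    curve = PressCurve(
        lv_index=np.arange(1, max_latent + 1, dtype=np.intp),
        press_value=press,
        selected_lv=selected,
    )
    object.__setattr__(curve, "_n_samples", n)
    return curve


# ---------------------------------------------------------------------------
# Figures of merit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelReport:
    """Evaluation of one (fraction-set x preprocessing) calibration model."""

    fraction_set: str
    preprocess_name: str
    n_latent: int
    rmsec: float
    rmsecv: float
    rmsep: float
    r2_cal: float
    r2_cv: float
    r2_pred: float
    rpd: float
    n_calibration: int = 0
    n_validation: int = 0


def _rmse(y_true: NDArray, y_pred: NDArray) -> float:
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def _r2(y_true: NDArray, y_pred: NDArray) -> float:
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def evaluate_model(
    model: PLSModel,
    press_curve: PressCurve | None,
    X_cal: ArrayLike,
    y_cal: ArrayLike,
    X_val: ArrayLike,
    y_val: ArrayLike,
    fraction_set: str = "",
    preprocess_name: str = "RAW",
) -> ModelReport:
    """Compute RMSEC/RMSECV/RMSEP, R² values and RPD for a fitted model.

    R² is ``1 − SS_res/SS_tot`` against each set's own mean (not squared
    correlation).  RPD uses the validation reference SD with the n−1
    denominator; a perfect validation fit reports ``rpd = inf``.
    """
    yc = np.asarray(y_cal, dtype=np.float64).ravel()
    yv = np.asarray(y_val, dtype=np.float64).ravel()
    if yv.size == 0:
        raise ValueError("validation set is empty")
    sd_val = float(np.std(yv, ddof=1)) if yv.size > 1 else 0.0
    if sd_val == 0.0:
        raise ValueError("validation reference SD is zero: RPD undefined")

    pred_cal = pls_predict(model, X_cal)
    pred_val = pls_predict(model, X_val)
    rmsec = _rmse(yc, pred_cal)
    rmsep = _rmse(yv, pred_val)

    if press_curve is not None:
        n_cal = yc.size
        press_sel = float(press_curve.press_value[press_curve.selected_lv - 1])
        rmsecv = float(np.sqrt(press_sel / n_cal))
        # R²_cv against the calibration responses the CV predicted
        r2_cv = 1.0 - press_sel / float(np.sum((yc - yc.mean()) ** 2))
    else:
        rmsecv, r2_cv = float("nan"), float("nan")

    rpd = float("inf") if rmsep == 0.0 else sd_val / rmsep
    return ModelReport(
        fraction_set=fraction_set,
        preprocess_name=preprocess_name,
        n_latent=model.n_latent,
        rmsec=rmsec,
        rmsecv=rmsecv,
        rmsep=rmsep,
        r2_cal=_r2(yc, pred_cal),
        r2_cv=r2_cv,
        r2_pred=_r2(yv, pred_val),
        rpd=rpd,
        n_calibration=yc.size,
        n_validation=yv.size,
    )
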