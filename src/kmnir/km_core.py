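"""Kubelka-Munk physics for diffuse reflectance of optically thick powders.

The remission function ``f(R∞) = (1 - R∞)² / (2 R∞)`` maps the diffuse
reflectance ``R∞`` of an infinitely thick powder layer to the ratio of its
absorption and scatter coefficients ``k/s``.  Apparent absorbance is the
base-10 convention ``A = -log10(R∞)``, i.e. reflectance is measured against a
non-absorbing reference (air).  This module provides the forward and inverse
maps, scatter-coefficient estimation when ``k`` is known, the inverse
particle-size law for ``s``, and a sliding-window linearity profile of
``A`` versus ``k/s`` that locates the quasi-linear region exploited by
linear calibration models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "KMCurve",
    "LinearityProfile",
    "remission_function",
    "invert_remission",
    "absorbance_from_ratio",
    "ratio_from_absorbance",
    "estimate_scatter",
    "scatter_from_particle_size",
    "km_curve",
    "linearity_profile",
    "linear_region_onset",
]


def _as_float_array(x: ArrayLike) -> NDArray[np.float64]:
    return np.asarray(x, dtype=np.float64)


def _first_bad(arr: NDArray, bad: NDArray) -> tuple[tuple[int, ...], float]:
    """Index (as plain ints) and value of the first offending element."""
    idx = tuple(int(i) for i in np.argwhere(np.atleast_1d(bad))[0])
    val = float(np.atleast_1d(arr)[idx])
    return idx, val


def remission_function(reflectance: ArrayLike) -> NDArray[np.float64] | float:
    """Kubelka-Munk remission function ``f(R∞) = (1-R∞)²/(2R∞) = k/s``.

    Parameters
    ----------
    reflectance
        Diffuse reflectance ``R∞`` in ``(0, 1]``, scalar or array
        (applied elementwise with shape preserved).

    Returns
    -------
    The dimensionless ``k/s`` ratio, ``0`` at ``R∞ = 1`` and strictly
    decreasing in ``R∞``.
    """
    r = _as_float_array(reflectance)
    bad = (r <= 0.0) | (r > 1.0)
    if np.any(bad):
        idx, val = _first_bad(r, bad)
        raise ValueError(
            f"reflectance must lie in (0, 1]; got {val} at index {idx}"
        )
    out = (1.0 - r) ** 2 / (2.0 * r)
    return float(out) if np.isscalar(reflectance) or out.ndim == 0 else out


def invert_remission(ratio: ArrayLike) -> NDArray[np.float64] | float:
    """Reflectance ``R∞`` in ``(0, 1]`` for a given ``k/s`` ratio.

    Uses the root ``R∞ = 1 + x - √(x² + 2x)`` of the remission quadratic,
    evaluated as ``1 / (1 + x + √(x² + 2x))`` — algebraically identical and
    free of catastrophic cancellation at large ``x``.
    """
    x = _as_float_array(ratio)
    bad = x < 0.0
    if np.any(bad):
        idx, val = _first_bad(x, bad)
        raise ValueError(f"k/s ratio must be >= 0; got {val} at index {idx}")
    out = 1.0 / (1.0 + x + np.sqrt(x * x + 2.0 * x))
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


def absorbance_from_ratio(ratio: ArrayLike) -> NDArray[np.float64] | float:
    """Apparent absorbance ``A = -log10(1 + x - √(x² + 2x))`` for ``x = k/s``."""
    r_inf = invert_remission(ratio)
    out = -np.log10(r_inf)
    return float(out) if np.isscalar(ratio) else out


def ratio_from_absorbance(absorbance: ArrayLike) -> NDArray[np.float64] | float:
    """``k/s`` ratio corresponding to an apparent absorbance ``A >= 0``."""
    a = _as_float_array(absorbance)
    bad = a < 0.0
    if np.any(bad):
        idx, val = _first_bad(a, bad)
        raise ValueError(f"absorbance must be >= 0; got {val} at index {idx}")
    out = remission_function(np.power(10.0, -a))
    return float(out) if np.isscalar(absorbance) else out


def estimate_scatter(
    absorption_k: ArrayLike, reflectance: ArrayLike
) -> NDArray[np.float64]:
    """Scatter-coefficient spectrum ``s = k / f(R∞)``, elementwise.

    ``k`` and ``R∞`` must be congruent spectra; ``k >= 0`` and
    ``0 < R∞ < 1`` wherever ``k > 0`` (at ``R∞ = 1`` the remission function
    vanishes and ``s`` is undefined unless ``k = 0`` there too).
    """
    k = _as_float_array(absorption_k)
    r = _as_float_array(reflectance)
    if k.shape != r.shape:
        raise ValueError(f"shape mismatch: k {k.shape} vs reflectance {r.shape}")
    if np.any(k < 0.0):
        raise ValueError("absorption coefficient k must be >= 0")
    fr = np.asarray(remission_function(r), dtype=np.float64)
    zero_div = (fr == 0.0) & (k > 0.0)
    if np.any(zero_div):
        idx, _ = _first_bad(k, zero_div)
        raise ZeroDivisionError(
            f"R = 1 with k > 0 at index {idx}: scatter coefficient undefined"
        )
    s = np.zeros_like(k)
    nz = fr > 0.0
    s[nz] = k[nz] / fr[nz]
    return s


def scatter_from_particle_size(
    diameter: ArrayLike,
    reference_scatter: float,
    reference_diameter: float,
) -> NDArray[np.float64] | float:
    """Scatter coefficient under the inverse particle-size law ``s ∝ 1/d``.

    ``s(d) = s_ref · d_ref / d`` — the Kubelka-Munk scatter coefficient is
    inversely proportional to particle diameter.
    """
    d = _as_float_array(diameter)
    if np.any(d <= 0.0) or reference_scatter <= 0.0 or reference_diameter <= 0.0:
        raise ValueError("diameters and reference scatter must be positive")
    out = reference_scatter * reference_diameter / d
    return float(out) if np.isscalar(diameter) else out


@dataclass(frozen=True)
class KMCurve:
    """Tabulated Kubelka-Munk curve: ``k/s`` grid with matching ``R∞`` and ``A``."""

    ratio_grid: NDArray[np.float64]
    remission: NDArray[np.float64]
    absorbance: NDArray[np.float64]

    def __post_init__(self) -> None:
        if not (len(self.ratio_grid) == len(self.remission) == len(self.absorbance)):
            raise ValueError("KMCurve fields must have equal length")
        if np.any(np.diff(self.ratio_grid) <= 0):
            raise ValueError("ratio_grid must be strictly increasing")


def km_curve(ratio_grid: ArrayLike) -> KMCurve:
    """Evaluate the Kubelka-Munk curve on a strictly increasing ``k/s`` grid."""
    grid = _as_float_array(ratio_grid)
    r = np.asarray(invert_remission(grid))
    return KMCurve(ratio_grid=grid, remission=r, absorbance=-np.log10(r))


@dataclass(frozen=True)
class LinearityProfile:
    """Sliding-window straight-line quality of ``A`` versus ``k/s``.

    Each window ``[start, start + width]`` carries the coefficient of
    determination of the least-squares line of absorbance against ``k/s``
    on that window, and the largest absolute deviation from the line.
    """

    window_start: NDArray[np.float64]
    window_width: float
    fit_r2: NDArray[np.float64]
    max_abs_residual: NDArray[np.float64]
    r2_threshold: float = field(default=0.995)

    @property
    def window_end(self) -> NDArray[np.float64]:
        return self.window_start + self.window_width


def _window_line_fit(x: NDArray, y: NDArray) -> tuple[float, float]:
    """R² and max |residual| of the OLS line of y on x."""
    coef = np.polynomial.polynomial.polyfit(x, y, 1)
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return r2, float(np.max(np.abs(resid)))


def linearity_profile(
    ratio_range: tuple[float, float],
    window_width: float = 4.0,
    grid_step: float = 0.01,
    r2_threshold: float = 0.995,
) -> LinearityProfile:
    """Profile how linear ``A(k/s)`` is over sliding windows of ``k/s``.

    Windows of span ``window_width`` slide across ``ratio_range`` in steps
    of ``grid_step``; within each, absorbance is fitted by a straight line
    on a grid of spacing ``grid_step``.  The curvature of the
    Kubelka-Munk absorbance decays like ``1/x²`` at large ``k/s``, so
    later windows are flatter and ``fit_r2`` rises toward 1.
    """
    lo, hi = float(ratio_range[0]), float(ratio_range[1])
    if not (0.0 <= lo < hi):
        raise ValueError("ratio_range must satisfy 0 <= lo < hi")
    if not (0.0 < window_width < hi - lo):
        raise ValueError("window_width must be positive and smaller than the range")
    if grid_step <= 0.0:
        raise ValueError("grid_step must be positive")

    n_pts = int(round(window_width / grid_step)) + 1
    if n_pts < 3:
        raise ValueError(
            "grid_step too coarse: fewer than 3 points per window"
        )
    starts = np.arange(lo, hi - window_width + grid_step / 2, grid_step)
    r2 = np.empty_like(starts)
    max_resid = np.empty_like(starts)
    for i, s0 in enumerate(starts):
        x = s0 + grid_step * np.arange(n_pts)
        y = np.asarray(absorbance_from_ratio(x))
        r2[i], max_resid[i] = _window_line_fit(x, y)
    return LinearityProfile(
        window_start=starts,
        window_width=window_width,
        fit_r2=r2,
        max_abs_residual=max_resid,
        r2_threshold=r2_threshold,
    )


def linear_region_onset(
    profile: LinearityProfile, r2_threshold: float | None = None
) -> float | None:
    """Smallest window start whose line fit reaches the R² threshold.

    Returns ``None`` when no window qualifies.
    """
    thr = profile.r2_threshold if r2_threshold is None else r2_threshold
    ok = np.nonzero(profile.fit_r2 >= thr)[0]
    return float(profile.window_start[ok[0]]) if ok.size else None
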