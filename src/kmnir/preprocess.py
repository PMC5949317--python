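"""Spectral preprocessing operators for NIR calibration transfer.

Scatter-correction (MSC, EMSC, SNV), Savitzky-Golay smoothing and smoothed
derivatives, vector normalisation and baseline subtraction.  Operators that
need a reference (MSC, EMSC) are *fitted* on calibration spectra only and the
frozen state is then applied unchanged to validation spectra — validation
rows never influence the reference.

All operators take a 2-D absorbance matrix (samples x wavelengths) and
preserve its shape and wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessState",
    "Preprocessor",
    "METHOD_NAMES",
    "snv",
    "msc_fit",
    "msc_apply",
    "emsc_fit",
    "emsc_apply",
    "savitzky_golay",
    "normalize",
    "baseline_subtract",
    "fit_preprocessor",
]

#: Method labels accepted by :func:`fit_preprocessor` and the CLI.
METHOD_NAMES = (
    "RAW",
    "MSC",
    "SNV",
    "EMSC",
    "SG9",
    "1D+SG",
    "2D+SG",
    "NORM",
    "BASELINE",
)


def _as_matrix(spectra: ArrayLike) -> NDArray[np.float64]:
    x = np.asarray(spectra, dtype=np.float64)
    if x.ndim == 1:
        x = x[np.newaxis, :]
    if x.ndim != 2:
        raise ValueError(f"expected a 1-D spectrum or 2-D matrix, got ndim={x.ndim}")
    return x


@dataclass(frozen=True)
class PreprocessState:
    """Frozen state of a fitted preprocessing operator.

    ``reference_spectrum`` is the mean calibration spectrum and is present
    exactly for the methods that regress each spectrum on a reference
    (MSC, EMSC).
    """

    method_name: str
    reference_spectrum: NDArray[np.float64] | None = None
    wavelengths: NDArray[np.float64] | None = None
    polynomial_order: int = 2
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv: int = 0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and exceed sg_polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must not exceed sg_polyorder")
        needs_ref = self.method_name in ("MSC", "EMSC")
        if needs_ref != (self.reference_spectrum is not None):
            raise ValueError(
                "reference_spectrum must be present iff method is MSC or EMSC"
            )


def snv(spectra: ArrayLike) -> NDArray[np.float64]:
    """Standard normal variate: each row to mean 0, sample SD 1 (n-1).

    SNV is a per-row affine map, so it is invariant to per-spectrum
    additive offsets and positive multiplicative scaling — the classic
    particle-size scatter signature.
    """
    x = _as_matrix(spectra)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 points per spectrum")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0.0)[0]
    if flat.size:
        raise ValueError(f"constant spectrum (zero SD) at sample index {flat[0]}")
    return (x - mu) / sd


def msc_fit(calibration_spectra: ArrayLike) -> PreprocessState:
    """Fit multiplicative scatter correction: reference = mean calibration spectrum."""
    x = _as_matrix(calibration_spectra)
    if x.shape[0] < 2:
        raise ValueError("MSC needs at least 2 calibration spectra")
    return PreprocessState(method_name="MSC", reference_spectrum=x.mean(axis=0))


def msc_apply(state: PreprocessState, spectra: ArrayLike) -> NDArray[np.float64]:
    """Regress each spectrum on the reference (x = a + b*ref) and return (x-a)/b."""
    if state.reference_spectrum is None:
        raise ValueError("state has no reference spectrum; fit MSC first")
    x = _as_matrix(spectra)
    ref = state.reference_spectrum
    if x.shape[1] != ref.shape[0]:
        raise ValueError("wavelength count does not match fitted reference")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.nonzero(b == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"MSC slope is zero for sample index {bad[0]} "
            "(spectrum orthogonal to reference)"
        )
    a = x.mean(axis=1) - b * ref.mean()
    return (x - a[:, None]) / b[:, None]


def _emsc_design(
    wavelengths: NDArray[np.float64], order: int, reference: NDArray[np.float64]
) -> NDArray[np.float64]:
    lam = wavelengths.astype(np.float64)
    span = lam[-1] - lam[0]
    lam_t = 2.0 * (lam - lam[0]) / span - 1.0 if span != 0 else np.zeros_like(lam)
    cols = [lam_t**p for p in range(order + 1)]
    cols.append(reference)
    return np.column_stack(cols)


def emsc_fit(
    calibration_spectra: ArrayLike,
    wavelengths: ArrayLike,
    polynomial_order: int = 2,
) -> PreprocessState:
    """Fit extended MSC: wavelength polynomial (scaled to [-1, 1]) plus
    reference.  Order 0 (constant + reference) reduces to plain MSC."""
    if polynomial_order < 0:
        raise ValueError("polynomial_order must be >= 0")
    x = _as_matrix(calibration_spectra)
    if x.shape[0] < 2:
        raise ValueError("EMSC needs at least 2 calibration spectra")
    lam = np.asarray(wavelengths, dtype=np.float64)
    if lam.shape[0] != x.shape[1]:
        raise ValueError("wavelengths must match spectrum length")
    return PreprocessState(
        method_name="EMSC",
        reference_spectrum=x.mean(axis=0),
        wavelengths=lam,
        polynomial_order=polynomial_order,
    )


def emsc_apply(state: PreprocessState, spectra: ArrayLike) -> NDArray[np.float64]:
    """Remove the fitted polynomial baseline and divide by the reference loading."""
    if state.reference_spectrum is None or state.wavelengths is None:
        raise ValueError("state has no EMSC reference; fit EMSC first")
    x = _as_matrix(spectra)
    design = _emsc_design(
        state.wavelengths, state.polynomial_order, state.reference_spectrum
    )
    if x.shape[1] <= state.polynomial_order + 2:
        raise ValueError("too few wavelengths for the EMSC design (singular)")
    coef, _, rank, _ = np.linalg.lstsq(design, x.T, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("singular EMSC design matrix")
    b_ref = coef[-1]
    bad = np.nonzero(b_ref == 0.0)[0]
    if bad.size:
        raise ValueError(f"EMSC reference loading is zero for sample index {bad[0]}")
    poly_part = design[:, :-1] @ coef[:-1]
    return (x - poly_part.T) / b_ref[:, None]


def savitzky_golay(
    spectra: ArrayLike,
    window: int = 9,
    polyorder: int = 2,
    deriv_order: int = 0,
    spacing: float = 1.0,
) -> NDArray[np.float64]:
    """Savitzky-Golay smoothing / smoothed derivative along the wavelength axis.

    Derivatives are scaled by ``spacing**-deriv_order`` (per nm when
    ``spacing`` is the wavelength step in nm).  Edges are handled by
    evaluating the first/last window's fitted polynomial, so output length
    equals input length.
    """
    x = _as_matrix(spectra)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if deriv_order > polyorder:
        raise ValueError("deriv_order must not exceed polyorder")
    if x.shape[1] < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(
        x, window_length=window, polyorder=polyorder, deriv=deriv_order,
        delta=spacing, axis=1, mode="interp",
    )


def normalize(
    spectra: ArrayLike, mode: str = "unit-vector", spacing: float = 1.0
) -> NDArray[np.float64]:
    """Per-row normalisation: ``unit-vector`` (L2), ``max``, or ``area``.

    ``area`` divides by the row sum times ``spacing`` so the discrete
    integral of the output is 1.
    """
    x = _as_matrix(spectra)
    if mode == "unit-vector":
        norm = np.linalg.norm(x, axis=1)
    elif mode == "max":
        norm = np.max(np.abs(x), axis=1)
    elif mode == "area":
        norm = np.sum(x, axis=1) * spacing
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    bad = np.nonzero(norm == 0.0)[0]
    if bad.size:
        raise ValueError(f"zero-norm spectrum at sample index {bad[0]}")
    return x / norm[:, None]


def baseline_subtract(
    spectra: ArrayLike, mode: str = "linear", wavelengths: ArrayLike | None = None
) -> NDArray[np.float64]:
    """Per-row baseline removal: ``offset`` (row minimum) or ``linear`` detrend."""
    x = _as_matrix(spectra)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 points per spectrum")
    if mode == "offset":
        return x - x.min(axis=1, keepdims=True)
    if mode == "linear":
        lam = (
            np.arange(x.shape[1], dtype=np.float64)
            if wavelengths is None
            else np.asarray(wavelengths, dtype=np.float64)
        )
        design = np.column_stack([np.ones_like(lam), lam])
        coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
        return x - (design @ coef).T
    raise ValueError(f"unknown baseline mode {mode!r}")


@dataclass(frozen=True)
class Preprocessor:
    """A named preprocessing method with frozen fitted state.

    ``transform`` never mutates the state, so calibration and validation
    spectra are corrected identically.
    """

    state: PreprocessState
    _transform: Callable[[PreprocessState, NDArray], NDArray]

    @property
    def name(self) -> str:
        return self.state.method_name

    def transform(self, spectra: ArrayLike) -> NDArray[np.float64]:
        return self._transform(self.state, _as_matrix(spectra))


def fit_preprocessor(
    method: str,
    calibration_spectra: ArrayLike,
    wavelengths: ArrayLike | None = None,
    *,
    emsc_order: int = 2,
    sg_window: int = 9,
    norm_mode: str = "unit-vector",
    baseline_mode: str = "linear",
) -> Preprocessor:
    """Fit a preprocessing method by its conventional label.

    Labels: RAW, MSC, SNV, EMSC, SG9 (nine-point smoothing), 1D+SG and
    2D+SG (nine-point smoothed first/second derivative), NORM, BASELINE.
    Reference-based methods use only the calibration rows given here.
    """
    x = _as_matrix(calibration_spectra)
    lam = None if wavelengths is None else np.asarray(wavelengths, dtype=np.float64)
    spacing = 1.0 if lam is None or lam.size < 2 else float(lam[1] - lam[0])

    if method == "RAW":
        return Preprocessor(PreprocessState("RAW"), lambda st, m: m)
    if method == "SNV":
        return Preprocessor(PreprocessState("SNV"), lambda st, m: snv(m))
    if method == "MSC":
        return Preprocessor(msc_fit(x), msc_apply)
    if method == "EMSC":
        if lam is None:
            raise ValueError("EMSC requires the wavelength grid")
        return Preprocessor(emsc_fit(x, lam, emsc_order), emsc_apply)
    if method in ("SG9", "1D+SG", "2D+SG"):
        deriv = {"SG9": 0, "1D+SG": 1, "2D+SG": 2}[method]
        # second derivative needs a cubic local fit; smoothing uses quadratic
        polyorder = 2 if deriv < 2 else 3
        st = PreprocessState(
            method, sg_window=sg_window, sg_polyorder=polyorder, sg_deriv=deriv
        )
        return Preprocessor(
            st,
            lambda s, m: savitzky_golay(
                m, s.sg_window, s.sg_polyorder, s.sg_deriv, spacing
            ),
        )
    if method == "NORM":
        return Preprocessor(
            PreprocessState("NORM"), lambda st, m: normalize(m, norm_mode, spacing)
        )
    if method == "BASELINE":
        return Preprocessor(
            PreprocessState("BASELINE"),
            lambda st, m: baseline_subtract(m, baseline_mode, lam),
        )
    raise ValueError(f"unknown preprocessing method {method!r}; known: {METHOD_NAMES}")
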