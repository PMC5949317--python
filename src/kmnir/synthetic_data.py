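"""Synthetic NIR diffuse-reflectance spectra with particle-size structure.

The generator emulates a sieved-powder calibration study: a set of base
powder samples, each with a true analyte content, sieved into particle-size
fractions and measured in replicate.  Spectra follow Kubelka-Munk physics
exactly: the absorption coefficient ``k(λ)`` is the analyte absorptivity
scaled by concentration plus a smooth matrix background, the scatter
coefficient ``s(λ)`` is constant within a fraction and inversely
proportional to the representative particle diameter, reflectance is
``R∞ = f⁻¹(k/s)``, and measurement noise enters on the reflectance scale
(a per-spectrum multiplicative packing term and per-channel additive
detector noise).  Replicate absorbances are averaged, and reference values
carry an unbiased relative assay error.

Because spectra are generated from known ``k`` and ``s`` fields, every
downstream stage (scatter estimation, preprocessing, calibration) can be
tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.stats import truncnorm

from .km_core import invert_remission, scatter_from_particle_size

__all__ = [
    "ParticleFraction",
    "SimulationConfig",
    "SyntheticTruth",
    "SpectraSet",
    "DEFAULT_FRACTIONS",
    "make_absorptivity_profile",
    "simulate_dataset",
    "pure_scatter_dataset",
]


@dataclass(frozen=True)
class ParticleFraction:
    """A sieve fraction with μm bounds and a representative diameter."""

    label: str
    lower_um: float
    upper_um: float
    representative_um: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lower_um < self.upper_um):
            raise ValueError(f"invalid bounds for fraction {self.label!r}")
        if self.representative_um is None:
            # arithmetic mean of the sieve bounds
            object.__setattr__(
                self, "representative_um", 0.5 * (self.lower_um + self.upper_um)
            )
        if not (self.lower_um <= self.representative_um <= self.upper_um):
            raise ValueError(f"representative_um outside bounds for {self.label!r}")


#: The seven sieve fractions of a 24/50/65/80/100/120/150-mesh cascade.
#: "<90" uses bounds (0, 90) with representative diameter 45 μm.
DEFAULT_FRACTIONS: tuple[ParticleFraction, ...] = (
    ParticleFraction("355-850", 355.0, 850.0),
    ParticleFraction("250-355", 250.0, 355.0),
    ParticleFraction("180-250", 180.0, 250.0),
    ParticleFraction("150-180", 150.0, 180.0),
    ParticleFraction("125-150", 125.0, 150.0),
    ParticleFraction("90-125", 90.0, 125.0),
    ParticleFraction("<90", 0.0, 90.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; defaults mirror the emulated design.

    Concentrations are in mg·g⁻¹; wavelengths in nm; ``k`` and ``s`` share
    one arbitrary consistent inverse-length unit so only ``k/s`` matters
    optically.  Noise SDs act on the reflectance scale.
    """

    seed: int = 1
    n_base_samples: int = 30
    n_batches: int = 10
    fractions: tuple[ParticleFraction, ...] = DEFAULT_FRACTIONS
    n_replicates: int = 3
    wavelength_lo: float = 780.0
    wavelength_hi: float = 2500.0
    wavelength_step: float = 2.0
    concentration_mean: float = 1.5
    concentration_sd: float = 0.5
    concentration_floor: float = 0.2
    #: (center nm, Gaussian SD nm, absorptivity height per mg·g⁻¹) —
    #: peaks in the second-overtone, first-combination-overtone and
    #: combination regions of C-H stretching bands.
    analyte_peaks: tuple[tuple[float, float, float], ...] = (
        (1200.0, 50.0, 0.08),
        (1700.0, 60.0, 0.12),
        (2270.0, 70.0, 0.10),
    )
    #: matrix background k: offset + slope-term rising toward long
    #: wavelengths plus broad O-H matrix bands (water/cellulose) —
    #: (center nm, Gaussian SD nm, height)
    background_offset: float = 0.15
    background_rise: float = 0.45
    background_power: float = 1.7
    matrix_bands: tuple[tuple[float, float, float], ...] = (
        (1450.0, 90.0, 0.25),
        (1940.0, 110.0, 0.35),
    )
    reference_scatter: float = 1.5
    reference_diameter: float = 100.0
    additive_noise_sd: float = 5e-4
    multiplicative_noise_sd: float = 2e-3
    hplc_cv: float = 0.015

    def __post_init__(self) -> None:
        if self.wavelength_step <= 0 or self.wavelength_lo >= self.wavelength_hi:
            raise ValueError("invalid wavelength grid")
        if min(self.additive_noise_sd, self.multiplicative_noise_sd, self.hplc_cv) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_replicates < 1 or self.n_base_samples < 1:
            raise ValueError("need at least one sample and one replicate")

    @property
    def wavelengths(self) -> NDArray[np.float64]:
        return np.arange(
            self.wavelength_lo,
            self.wavelength_hi + self.wavelength_step / 2,
            self.wavelength_step,
        )

    def zero_noise(self) -> "SimulationConfig":
        """Copy with all stochastic measurement errors switched off."""
        return replace(
            self, additive_noise_sd=0.0, multiplicative_noise_sd=0.0, hplc_cv=0.0
        )


@dataclass(frozen=True)
class SpectraSet:
    """Wavelength grid plus per-sample spectra and metadata.

    ``values`` rows align with ``metadata`` rows; metadata carries
    ``sample_id``, ``base_sample``, ``batch`` and ``fraction`` columns.
    """

    wavelengths: NDArray[np.float64]
    values: NDArray[np.float64]
    metadata: pd.DataFrame
    kind: str = "absorbance"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.metadata), len(self.wavelengths)):
            raise ValueError("values shape must be (n_samples, n_wavelengths)")

    def subset(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(
            wavelengths=self.wavelengths,
            values=self.values[mask],
            metadata=self.metadata.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool or mask.dtype.kind in "iu"
            else self.metadata.loc[mask].reset_index(drop=True),
            kind=self.kind,
        )

    def for_fractions(self, labels) -> "SpectraSet":
        keep = self.metadata["fraction"].isin(list(labels)).to_numpy()
        return self.subset(keep)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated set: concentrations and k/s fields."""

    true_concentration: NDArray[np.float64]
    k_spectra: NDArray[np.float64]
    s_spectra: NDArray[np.float64]
    fraction_labels: tuple[str, ...]
    sample_ids: tuple[str, ...] = field(default=())


def make_absorptivity_profile(
    config: SimulationConfig,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Analyte absorptivity spectrum and matrix background ``k`` spectrum.

    The analyte profile is a sum of Gaussians (per-mg·g⁻¹ absorptivity);
    the background is a smooth positive curve rising toward long
    wavelengths, standing in for water/cellulose matrix absorption.
    """
    lam = config.wavelengths
    analyte = np.zeros_like(lam)
    for center, width, height in config.analyte_peaks:
        if not (lam[0] <= center <= lam[-1]):
            import warnings

            warnings.warn(
                f"analyte peak at {center} nm lies outside the grid "
                f"[{lam[0]}, {lam[-1]}] nm",
                stacklevel=2,
            )
        analyte += height * np.exp(-0.5 * ((lam - center) / width) ** 2)
    u = (lam - lam[0]) / (lam[-1] - lam[0])
    background = (
        config.background_offset
        + config.background_rise * u**config.background_power
    )
    for center, width, height in config.matrix_bands:
        background = background + height * np.exp(
            -0.5 * ((lam - center) / width) ** 2
        )
    return analyte, background


def _draw_concentrations(config: SimulationConfig, rng: np.random.Generator):
    a = (config.concentration_floor - config.concentration_mean) / config.concentration_sd
    return truncnorm.rvs(
        a,
        np.inf,
        loc=config.concentration_mean,
        scale=config.concentration_sd,
        size=config.n_base_samples,
        random_state=rng,
    )


def _simulate(
    config: SimulationConfig, concentrations: NDArray[np.float64]
) -> tuple[SpectraSet, pd.DataFrame, SyntheticTruth]:
    rng = np.random.default_rng(config.seed)
    lam = config.wavelengths
    analyte, background = make_absorptivity_profile(config)

    rows, meta_rows = [], []
    k_rows, s_rows, conc_rows, frac_rows, ids = [], [], [], [], []
    for b, frac in enumerate(config.fractions):
        s_val = scatter_from_particle_size(
            frac.representative_um, config.reference_scatter, config.reference_diameter
        )
        s_spec = np.full_like(lam, s_val)
        for i in range(config.n_base_samples):
            conc = float(concentrations[i])
            k_spec = conc * analyte + background
            r_inf = np.asarray(invert_remission(k_spec / s_spec))
            reps = np.empty((config.n_replicates, lam.size))
            for r in range(config.n_replicates):
                # packing/repack variation: one multiplicative factor per spectrum
                mult = 1.0 + rng.normal(0.0, config.multiplicative_noise_sd)
                add = rng.normal(0.0, config.additive_noise_sd, size=lam.size)
                r_meas = np.clip(r_inf * mult + add, 1e-6, 1.0)
                reps[r] = -np.log10(r_meas)
            sample_id = f"S{i + 1:02d}_{frac.label}"
            rows.append(reps.mean(axis=0))
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "base_sample": i + 1,
                    "batch": i // max(1, config.n_base_samples // config.n_batches) + 1,
                    "fraction": frac.label,
                }
            )
            k_rows.append(k_spec)
            s_rows.append(s_spec)
            conc_rows.append(conc)
            frac_rows.append(frac.label)
            ids.append(sample_id)

    spectra = SpectraSet(
        wavelengths=lam,
        values=np.asarray(rows),
        metadata=pd.DataFrame(meta_rows),
    )
    ref_err = rng.normal(0.0, config.hplc_cv, size=len(ids)) if config.hplc_cv > 0 else np.zeros(len(ids))
    references = pd.DataFrame(
        {
            "sample_id": ids,
            "content_mg_g": np.asarray(conc_rows) * (1.0 + ref_err),
        }
    )
    truth = SyntheticTruth(
        true_concentration=np.asarray(conc_rows),
        k_spectra=np.asarray(k_rows),
        s_spectra=np.asarray(s_rows),
        fraction_labels=tuple(frac_rows),
        sample_ids=tuple(ids),
    )
    return spectra, references, truth


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[SpectraSet, pd.DataFrame, SyntheticTruth]:
    """Generate the full sieved-powder study: absorbance spectra, reference
    table (``sample_id``, ``content_mg_g``) and the generating truth.

    Each base sample keeps one true concentration across all its sieve
    fractions (the same powder, sieved); replicate spectra are averaged on
    the absorbance scale.  Fully reproducible from ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(_draw_concentrations(config, rng), dtype=np.float64)
    return _simulate(config, conc)


def pure_scatter_dataset(
    config: SimulationConfig | None = None,
) -> tuple[SpectraSet, pd.DataFrame, SyntheticTruth]:
    """All samples share one concentration; only particle size and noise vary.

    Isolates the scatter signature of particle size — the fixture behind
    preprocessing-effectiveness checks.
    """
    config = config or SimulationConfig()
    conc = np.full(config.n_base_samples, config.concentration_mean)
    return _simulate(config, conc)
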