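"""Study orchestration: fraction-wise model comparison, mixed-fraction
models, cross-prediction, the Kubelka-Munk linear-region report, and
delimited-text I/O for spectra, reference tables and reports.

The computational study mirrors a sieved-powder NIR calibration campaign:

* per single sieve fraction, compare preprocessing methods on one shared
  Kennard-Stone split (RMSEC/RMSECV/RMSEP, R², RPD; best method = max RPD);
* pool three adjacent fractions into mixed-size sets and repeat;
* apply each fitted mixed-set model to its member fractions' validation
  samples (cross-prediction), pairing the results with the single-fraction
  models' own validation metrics;
* profile where absorbance is a nearly linear function of ``k/s``.

Everything downstream of the data is deterministic, so a fixed dataset
yields byte-identical report files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import km_core
from .chemometrics import (
    ModelReport,
    PLSModel,
    PressCurve,
    evaluate_model,
    kennard_stone_split,
    loocv_press,
    pls_fit,
    pls_predict,
)
from .preprocess import Preprocessor, fit_preprocessor
from .synthetic_data import SpectraSet

logger = logging.getLogger("kmnir")

__all__ = [
    "StudyDesign",
    "FittedEntry",
    "StudyReport",
    "run_single_fraction_study",
    "run_mixed_fraction_study",
    "cross_predict",
    "run_full_study",
    "km_linear_region_report",
    "read_spectra",
    "write_spectra",
    "read_references",
    "write_references",
    "write_report",
    "align_references",
]

_DEFAULT_SINGLE = (
    "355-850",
    "250-355",
    "180-250",
    "150-180",
    "125-150",
    "90-125",
    "<90",
)

_DEFAULT_MIXED = {
    "180-850": ("355-850", "250-355", "180-250"),
    "150-355": ("250-355", "180-250", "150-180"),
    "125-250": ("180-250", "150-180", "125-150"),
    "90-180": ("150-180", "125-150", "90-125"),
    "0-150": ("125-150", "90-125", "<90"),
}


@dataclass(frozen=True)
class StudyDesign:
    """What to model and compare.

    ``mixed_sets`` are unions of three adjacent sieve fractions;
    ``cross_prediction`` maps a mixed-set label to the member fractions
    whose validation samples the mixed model must predict.
    ``split_fraction`` is the calibration share of the Kennard-Stone split
    (default 2:1 calibration:validation).
    """

    single_fractions: tuple[str, ...] = _DEFAULT_SINGLE
    mixed_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_MIXED)
    )
    preprocess_methods: tuple[str, ...] = ("RAW", "MSC", "SNV", "EMSC", "SG9")
    cross_prediction: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"90-180": ("150-180", "125-150", "90-125")}
    )
    split_fraction: float = 2.0 / 3.0
    max_latent: int = 10
    min_fraction_samples: int = 6

    def __post_init__(self) -> None:
        for label, members in self.mixed_sets.items():
            unknown = set(members) - set(self.single_fractions)
            if unknown:
                raise ValueError(f"mixed set {label!r} has unknown members {unknown}")
        for label, targets in self.cross_prediction.items():
            if label not in self.mixed_sets:
                raise ValueError(f"cross-prediction set {label!r} is not a mixed set")
            outside = set(targets) - set(self.mixed_sets[label])
            if outside:
                raise ValueError(
                    f"cross-prediction targets {outside} not members of {label!r}"
                )


@dataclass(frozen=True)
class FittedEntry:
    """One fitted (fraction-set x preprocessing) model with its split."""

    fraction_set: str
    method: str
    preprocessor: Preprocessor
    model: PLSModel
    press: PressCurve
    report: ModelReport
    cal_ids: tuple[str, ...]
    val_ids: tuple[str, ...]


@dataclass
class StudyReport:
    """Collected tables of the full study."""

    single_table: pd.DataFrame | None = None
    mixed_table: pd.DataFrame | None = None
    cross_table: pd.DataFrame | None = None
    comparison_table: pd.DataFrame | None = None
    single_entries: list[FittedEntry] = field(default_factory=list)
    mixed_entries: list[FittedEntry] = field(default_factory=list)


def align_references(spectra: SpectraSet, references: pd.DataFrame) -> NDArray:
    """Reference contents (mg·g⁻¹) aligned to the spectra's sample order."""
    if not {"sample_id", "content_mg_g"} <= set(references.columns):
        raise ValueError("reference table needs sample_id and content_mg_g columns")
    lut = references.set_index("sample_id")["content_mg_g"]
    missing = [s for s in spectra.metadata["sample_id"] if s not in lut.index]
    if missing:
        raise KeyError(f"no reference value for sample id {missing[0]!r}")
    return lut.loc[spectra.metadata["sample_id"]].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# model comparison on one fraction set
# ---------------------------------------------------------------------------

def compare_methods(
    spectra: SpectraSet,
    y: NDArray,
    label: str,
    design: StudyDesign,
    split: tuple[NDArray, NDArray] | None = None,
) -> list[FittedEntry]:
    """Kennard-Stone split once on RAW spectra, then compare all methods.

    The split is computed in RAW absorbance space and shared by every
    preprocessing method, so method comparisons see identical
    calibration/validation membership.  A precomputed ``split``
    (calibration indices, validation indices) may be supplied instead.
    """
    n = spectra.values.shape[0]
    if split is None:
        n_cal = int(round(n * design.split_fraction))
        n_cal = min(max(n_cal, 2), n - 1)
        cal_idx, val_idx = kennard_stone_split(spectra.values, n_cal)
    else:
        cal_idx, val_idx = split
    ids = spectra.metadata["sample_id"].to_numpy()
    logger.info(
        "%s: %d samples -> %d calibration / %d validation",
        label, n, len(cal_idx), len(val_idx),
    )

    entries = []
    for method in design.preprocess_methods:
        prep = fit_preprocessor(method, spectra.values[cal_idx], spectra.wavelengths)
        x_cal = prep.transform(spectra.values[cal_idx])
        x_val = prep.transform(spectra.values[val_idx])
        max_lv = min(design.max_latent, len(cal_idx) - 2, x_cal.shape[1])
        press = loocv_press(x_cal, y[cal_idx], max_lv)
        model = pls_fit(x_cal, y[cal_idx], press.selected_lv, allow_fewer=True)
        report = evaluate_model(
            model, press, x_cal, y[cal_idx], x_val, y[val_idx],
            fraction_set=label, preprocess_name=method,
        )
        logger.info(
            "%s / %s: %d LV, RMSEP %.4f mg/g, RPD %.2f",
            label, method, model.n_latent, report.rmsep, report.rpd,
        )
        entries.append(
            FittedEntry(
                fraction_set=label,
                method=method,
                preprocessor=prep,
                model=model,
                press=press,
                report=report,
                cal_ids=tuple(ids[cal_idx]),
                val_ids=tuple(ids[val_idx]),
            )
        )
    return entries


def _best_flags(entries: list[FittedEntry]) -> list[bool]:
    """Best = max RPD; ties toward fewer latent variables, then method order."""
    key = [(-e.report.rpd, e.report.n_latent, i) for i, e in enumerate(entries)]
    best = min(range(len(entries)), key=lambda i: key[i])
    return [i == best for i in range(len(entries))]


def _entries_table(entries: list[FittedEntry]) -> pd.DataFrame:
    rows = []
    by_set: dict[str, list[FittedEntry]] = {}
    for e in entries:
        by_set.setdefault(e.fraction_set, []).append(e)
    for label, group in by_set.items():
        flags = _best_flags(group)
        for e, flag in zip(group, flags):
            r = e.report
            rows.append(
                {
                    "fraction_set": label,
                    "preprocessing": e.method,
                    "n_latent": r.n_latent,
                    "RMSEC": r.rmsec,
                    "R2_cal": r.r2_cal,
                    "RMSECV": r.rmsecv,
                    "R2_cv": r.r2_cv,
                    "RMSEP": r.rmsep,
                    "R2_pred": r.r2_pred,
                    "RPD": r.rpd,
                    "best": flag,
                }
            )
    return pd.DataFrame(rows)


def run_single_fraction_study(
    spectra: SpectraSet, references: pd.DataFrame, design: StudyDesign | None = None
) -> StudyReport:
    """Per-fraction preprocessing comparison (single particle-size models)."""
    design = design or StudyDesign()
    y_all = align_references(spectra, references)
    report = StudyReport()
    for label in design.single_fractions:
        mask = (spectra.metadata["fraction"] == label).to_numpy()
        if mask.sum() < design.min_fraction_samples:
            logger.warning(
                "fraction %s has only %d samples; skipped", label, int(mask.sum())
            )
            continue
        report.single_entries.extend(
            compare_methods(spectra.subset(mask), y_all[mask], label, design)
        )
    report.single_table = _entries_table(report.single_entries)
    return report


def run_mixed_fraction_study(
    spectra: SpectraSet, references: pd.DataFrame, design: StudyDesign | None = None
) -> StudyReport:
    """Pooled three-fraction (mixed particle-size) model comparison."""
    design = design or StudyDesign()
    y_all = align_references(spectra, references)
    report = StudyReport()
    for label, members in design.mixed_sets.items():
        mask = spectra.metadata["fraction"].isin(members).to_numpy()
        if mask.sum() < design.min_fraction_samples:
            logger.warning("mixed set %s has too few samples; skipped", label)
            continue
        report.mixed_entries.extend(
            compare_methods(spectra.subset(mask), y_all[mask], label, design)
        )
    report.mixed_table = _entries_table(report.mixed_entries)
    return report


def _predict_metrics(
    entry: FittedEntry, x_raw: NDArray, y: NDArray
) -> tuple[float, float, float]:
    """RMSEP, R² and RPD of an already-fitted entry on new raw spectra."""
    x = entry.preprocessor.transform(x_raw)
    pred = pls_predict(entry.model, x)
    rmsep = float(np.sqrt(np.mean((y - pred) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    sd = float(np.std(y, ddof=1))
    rpd = float("inf") if rmsep == 0.0 else sd / rmsep
    return rmsep, r2, rpd


def cross_predict(
    mixed_entries: list[FittedEntry],
    spectra: SpectraSet,
    references: pd.DataFrame,
    design: StudyDesign | None = None,
    single_entries: list[FittedEntry] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Apply fitted mixed-set models to member fractions' validation samples.

    Target samples are the member-fraction rows of the mixed split's own
    validation partition; asking the model to predict samples from its
    calibration partition raises (leakage guard).  When single-fraction
    entries are supplied, a comparison table pairs each target fraction's
    best single model with the best mixed-model cross-prediction.
    """
    design = design or StudyDesign()
    y_all = align_references(spectra, references)
    ids = spectra.metadata["sample_id"].to_numpy()
    rows = []
    for mixed_label, targets in design.cross_prediction.items():
        group = [e for e in mixed_entries if e.fraction_set == mixed_label]
        if not group:
            raise ValueError(f"no fitted mixed model for set {mixed_label!r}")
        for entry in group:
            cal_set = set(entry.cal_ids)
            for target in targets:
                frac_mask = (spectra.metadata["fraction"] == target).to_numpy()
                val_mask = frac_mask & np.isin(ids, list(entry.val_ids))
                leaked = frac_mask & np.isin(ids, list(cal_set))
                if not val_mask.any():
                    raise ValueError(
                        f"fraction {target!r} absent from the validation "
                        f"partition of mixed set {mixed_label!r}"
                    )
                rmsep, r2, rpd = _predict_metrics(
                    entry, spectra.values[val_mask], y_all[val_mask]
                )
                rows.append(
                    {
                        "mixed_set": mixed_label,
                        "preprocessing": entry.method,
                        "target_fraction": target,
                        "n_predicted": int(val_mask.sum()),
                        "n_excluded_calibration": int(leaked.sum()),
                        "RMSEP": rmsep,
                        "R2_pred": r2,
                        "RPD": rpd,
                    }
                )
    cross_table = pd.DataFrame(rows)

    comparison = None
    if single_entries:
        comparison = _comparison_table(cross_table, single_entries, design)
    return cross_table, comparison


def predict_samples(entry: FittedEntry, spectra: SpectraSet, y: NDArray):
    """Predict arbitrary samples with a fitted entry, refusing its own
    calibration samples (leakage guard)."""
    overlap = set(spectra.metadata["sample_id"]) & set(entry.cal_ids)
    if overlap:
        raise ValueError(
            f"samples {sorted(overlap)[:3]} were in the model's calibration "
            "partition; refusing to report them as predictions"
        )
    return _predict_metrics(entry, spectra.values, y)


def _comparison_table(
    cross_table: pd.DataFrame,
    single_entries: list[FittedEntry],
    design: StudyDesign,
) -> pd.DataFrame:
    """Single-vs-mixed comparison: per target fraction, the best single
    model's own validation metrics against the best mixed-model
    cross-prediction (best method = max mean RPD over the set's targets)."""
    rows = []
    for mixed_label, targets in design.cross_prediction.items():
        sub = cross_table[cross_table["mixed_set"] == mixed_label]
        mean_rpd = sub.groupby("preprocessing", sort=False)["RPD"].mean()
        best_method = mean_rpd.idxmax()
        for target in targets:
            singles = [e for e in single_entries if e.fraction_set == target]
            if not singles:
                continue
            flags = _best_flags(singles)
            best_single = [e for e, f in zip(singles, flags) if f][0]
            mrow = sub[
                (sub["preprocessing"] == best_method)
                & (sub["target_fraction"] == target)
            ].iloc[0]
            rows.append(
                {
                    "target_fraction": target,
                    "single_method": best_single.method,
                    "single_R2_pred": best_single.report.r2_pred,
                    "single_RMSEP": best_single.report.rmsep,
                    "single_RPD": best_single.report.rpd,
                    "mixed_set": mixed_label,
                    "mixed_method": best_method,
                    "mixed_R2_pred": mrow["R2_pred"],
                    "mixed_RMSEP": mrow["RMSEP"],
                    "mixed_RPD": mrow["RPD"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kubelka-Munk linear-region report
# ---------------------------------------------------------------------------

def km_linear_region_report(
    out_dir: str | Path,
    ratio_range: tuple[float, float] = (0.0, 20.0),
    window_width: float = 4.0,
    grid_step: float = 0.01,
    r2_threshold: float = 0.995,
) -> dict:
    """Write the Kubelka-Munk curve and linearity-profile tables.

    Returns the written paths and the linear-region onset (smallest window
    start whose straight-line R² reaches the threshold).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = ratio_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    grid = grid[grid >= 0]
    curve = km_core.km_curve(grid)
    curve_df = pd.DataFrame(
        {
            "ratio": grid,
            "remission": curve.remission,
            "absorbance": curve.absorbance,
        }
    )
    profile = km_core.linearity_profile(
        ratio_range, window_width, grid_step, r2_threshold
    )
    profile_df = pd.DataFrame(
        {
            "window_start": profile.window_start,
            "window_end": profile.window_end,
            "fit_r2": profile.fit_r2,
            "max_abs_residual": profile.max_abs_residual,
        }
    )
    curve_path = out_dir / "km_curve.tsv"
    profile_path = out_dir / "linearity_profile.tsv"
    write_report(curve_df, curve_path)
    write_report(profile_df, profile_path)
    onset = km_core.linear_region_onset(profile)
    logger.info(
        "linear-region onset (R2 >= %.4g, width %.3g): k/s = %s",
        r2_threshold, window_width, onset,
    )
    return {
        "km_curve": curve_path,
        "linearity_profile": profile_path,
        "onset": onset,
    }


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_META_COLS = ("sample_id", "base_sample", "batch", "fraction")
# shortest representation that round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    """Write a spectra set as wide tab-delimited text (metadata columns
    first, then one column per wavelength in nm)."""
    values = pd.DataFrame(
        spectra.values, columns=["%.12g" % wl for wl in spectra.wavelengths]
    )
    df = pd.concat([spectra.metadata.reset_index(drop=True), values], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a spectra set written by :func:`write_spectra`."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty spectra file: {path}")
    meta_cols = [c for c in _META_COLS if c in df.columns]
    if "sample_id" not in meta_cols or "fraction" not in meta_cols:
        missing = {"sample_id", "fraction"} - set(meta_cols)
        raise ValueError(f"spectra file missing metadata columns {missing}")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        wavelengths = np.asarray([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength columns must be strictly increasing")
    return SpectraSet(
        wavelengths=wavelengths,
        values=df[wl_cols].to_numpy(dtype=np.float64),
        metadata=df[meta_cols].reset_index(drop=True),
    )


def write_references(references: pd.DataFrame, path: str | Path) -> None:
    references.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_references(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty reference file: {path}")
    if not {"sample_id", "content_mg_g"} <= set(df.columns):
        raise ValueError("reference file needs sample_id and content_mg_g columns")
    return df


def write_report(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def run_full_study(
    spectra: SpectraSet,
    references: pd.DataFrame,
    design: StudyDesign | None = None,
    out_dir: str | Path | None = None,
    km_ratio_range: tuple[float, float] = (0.0, 20.0),
) -> StudyReport:
    """Run the complete computational study and (optionally) write all
    report tables to ``out_dir``."""
    design = design or StudyDesign()
    single = run_single_fraction_study(spectra, references, design)
    mixed = run_mixed_fraction_study(spectra, references, design)
    cross_table, comparison = cross_predict(
        mixed.mixed_entries, spectra, references, design, single.single_entries
    )
    report = StudyReport(
        single_table=single.single_table,
        mixed_table=mixed.mixed_table,
        cross_table=cross_table,
        comparison_table=comparison,
        single_entries=single.single_entries,
        mixed_entries=mixed.mixed_entries,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report.single_table, out_dir / "single_fraction_report.tsv")
        write_report(report.mixed_table, out_dir / "mixed_fraction_report.tsv")
        write_report(report.cross_table, out_dir / "cross_prediction_report.tsv")
        if report.comparison_table is not None:
            write_report(report.comparison_table, out_dir / "comparison_table.tsv")
        km_linear_region_report(out_dir, ratio_range=km_ratio_range)
    return report
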