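"""Release-rate estimation from zooplankton incubation time series.

Animals are incubated in 0.2-µm-filtered seawater (default 500 mL) and the
chamber water is sub-sampled on a fixed time grid; the dissolved free
taurine (Tau) and amino-acid (DFAA) concentrations rise roughly linearly
while release outpaces any loss, then plateau. The volumetric release rate
is the OLS slope of concentration on time over the rising limb only:

* the series is truncated at the last time point up to which *every*
  analyte tracked in the chamber still increased step over step
  (:func:`truncate_series`);
* a fit is rejected (``low_fit``) when r² < 0.60 or the slope's two-sided
  p-value exceeds 0.05, and flagged ``early_release_only`` when the rise is
  confined to the first sampling interval — the signature of a
  handling-stress pulse rather than sustained release;
* passing slopes are normalised to per-individual (pmol ind⁻¹ h⁻¹) and
  per-carbon-biomass (µmol g⁻¹ C h⁻¹) rates.

Controls (chambers without animals) are carried alongside; subtracting the
control series is available but off by default, so reported rates are net
rates with the control slope reported next to them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientPointsError,
    InvalidInputError,
    MissingDataError,
    PairingError,
    UndefinedStatisticError,
)

__all__ = [
    "IncubationSeries",
    "FitResult",
    "RateEstimate",
    "truncate_series",
    "fit_release_rate",
    "early_release_pattern",
    "apply_qc",
    "normalize_rates",
    "control_correct",
    "estimate_release_rate",
    "tau_dfaa_ratio",
    "summarize_rates",
    "rates_from_tables",
]

QC_PASS = "pass"
QC_LOW_FIT = "low_fit"
QC_EARLY_RELEASE = "early_release_only"
QC_INSUFFICIENT = "insufficient_points"


@dataclass(frozen=True)
class IncubationSeries:
    """One analyte's concentration time series from one incubation chamber."""

    station: str
    replicate: str
    analyte: str
    times_h: tuple[float, ...]
    concs_nM: tuple[float, ...]
    volume_L: float = 0.5
    n_individuals: int | None = None
    total_biomass_gC: float | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concs_nM, dtype=float)
        if t.size != c.size:
            raise InvalidInputError("times and concentrations differ in length")
        if t.size == 0 or t[0] != 0:
            raise InvalidInputError("time grid must start at 0 h")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(c < 0):
            raise InvalidInputError("concentrations must be nonnegative")
        if not self.is_control:
            if not self.n_individuals or self.n_individuals <= 0:
                raise InvalidInputError("non-control series need n_individuals > 0")
            if not self.total_biomass_gC or self.total_biomass_gC <= 0:
                raise InvalidInputError("non-control series need total_biomass_gC > 0")
        object.__setattr__(self, "times_h", tuple(float(x) for x in t))
        object.__setattr__(self, "concs_nM", tuple(float(x) for x in c))

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.times_h)

    @property
    def concs(self) -> np.ndarray:
        return np.asarray(self.concs_nM)


@dataclass(frozen=True)
class FitResult:
    """OLS outcome for one (possibly truncated) series."""

    slope_nM_per_h: float
    intercept_nM: float
    r_squared: float
    p_value: float
    n_points: int
    t_c_h: float
    slope_stderr: float

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t, n−2 df)."""
        half = stats.t.ppf(0.5 + level / 2, self.n_points - 2) * self.slope_stderr
        return self.slope_nM_per_h - half, self.slope_nM_per_h + half


@dataclass(frozen=True)
class RateEstimate:
    """Release-rate estimate with its QC verdict.

    Normalized rates are present iff ``qc_status == "pass"``.
    """

    station: str
    replicate: str
    analyte: str
    slope_nM_per_h: float | None
    r_squared: float | None
    p_value: float | None
    t_c_h: float
    t_i_h: float
    qc_status: str
    rate_per_individual_pmol_h: float | None = None
    rate_per_gC_umol_h: float | None = None


def _collapse_duplicate_times(t: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average concentrations sharing a time point (duplicate injections)."""
    ut, inv = np.unique(t, return_inverse=True)
    if ut.size == t.size:
        return t, c
    means = np.bincount(inv, weights=c) / np.bincount(inv)
    return ut, means


def truncate_series(
    series: IncubationSeries,
    companions: Sequence[IncubationSeries] = (),
    tol_nM: float = 0.0,
) -> float:
    """Time span t_c over which every tracked analyte still increases.

    Walks the shared time grid step by step; the first step at which any
    analyte (the series itself or a companion from the same chamber) fails
    to increase by more than ``tol_nM`` ends the usable span, and t_c is the
    last time point before that step. The default tolerance 0 is the strict
    reading of "did not further increase".
    """
    if tol_nM < 0:
        raise InvalidInputError("tol_nM must be >= 0")
    all_series = [series, *companions]
    t0 = series.times
    for s in companions:
        if not np.array_equal(s.times, t0):
            raise PairingError("companion series must share the time grid")
    t_c = t0[0]
    for k in range(1, t0.size):
        if all(s.concs[k] - s.concs[k - 1] > tol_nM for s in all_series):
            t_c = t0[k]
        else:
            break
    return float(t_c)


def fit_release_rate(series: IncubationSeries, t_c_h: float | None = None) -> FitResult:
    """OLS regression of concentration on time up to ``t_c_h``.

    The p-value is the two-sided t-test on the slope with n−2 degrees of
    freedom. A constant series yields slope 0 with r² = 0 and p = 1 rather
    than an error, so QC can flag it downstream.

    Raises
    ------
    InsufficientPointsError
        If fewer than 3 points remain after truncation.
    """
    t, c = _collapse_duplicate_times(series.times, series.concs)
    if t_c_h is None:
        t_c_h = float(t[-1])
    keep = t <= t_c_h + 1e-12
    t, c = t[keep], c[keep]
    if t.size < 3:
        raise InsufficientPointsError(
            f"only {t.size} points up to t_c = {t_c_h} h; need >= 3"
        )
    if np.ptp(c) == 0:
        return FitResult(0.0, float(c[0]), 0.0, 1.0, int(t.size), float(t_c_h), 0.0)
    res = stats.linregress(t, c)
    return FitResult(
        slope_nM_per_h=float(res.slope),
        intercept_nM=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=int(t.size),
        t_c_h=float(t_c_h),
        slope_stderr=float(res.stderr),
    )


def early_release_pattern(series: IncubationSeries) -> bool:
    """True when the rise is confined to the first sampling interval.

    The signature of a handling-stress pulse: the first interval carries
    more rise than everything after it combined, and the trend over the
    remaining points is flat or negative.
    """
    c = series.concs
    t = series.times
    if c.size < 3:
        return False
    first_rise = c[1] - c[0]
    later_rise = c[-1] - c[1]
    later_slope = stats.linregress(t[1:], c[1:]).slope if np.ptp(c[1:]) else 0.0
    return bool(first_rise > max(later_rise, 0.0) and first_rise > 0 and later_slope <= 0)


def apply_qc(
    fit: FitResult,
    series: IncubationSeries,
    r2_min: float = 0.60,
    p_max: float = 0.05,
    combine: str = "or",
) -> str:
    """QC verdict for a fitted series.

    ``early_release_only``: the first sampling interval carries more rise
    than everything after it combined, and the post-first-interval trend is
    flat or negative — a handling-stress pulse, not sustained release.
    ``low_fit``: r² < ``r2_min`` or p > ``p_max`` (``combine="or"``, the
    default, conservative reading) or both (``combine="and"``).
    """
    if combine not in ("or", "and"):
        raise InvalidInputError("combine must be 'or' or 'and'")
    if early_release_pattern(series):
        return QC_EARLY_RELEASE
    bad_r2 = fit.r_squared < r2_min
    bad_p = fit.p_value > p_max
    failed = (bad_r2 or bad_p) if combine == "or" else (bad_r2 and bad_p)
    return QC_LOW_FIT if failed else QC_PASS


def normalize_rates(
    slope_nM_per_h: float,
    volume_L: float,
    n_individuals: int,
    total_biomass_gC: float,
) -> tuple[float, float]:
    """Per-individual and per-biomass rates from a volumetric slope.

    Total chamber release is ``slope × volume`` in nmol h⁻¹ (nM ≡ nmol L⁻¹).
    Per individual: ×10³/n → pmol ind⁻¹ h⁻¹. Per biomass: ×10⁻³/biomass →
    µmol g⁻¹ C h⁻¹.
    """
    if volume_L <= 0:
        raise InvalidInputError("volume must be > 0")
    if n_individuals <= 0 or total_biomass_gC <= 0:
        raise InvalidInputError("chamber needs individuals and biomass > 0")
    total_nmol_h = slope_nM_per_h * volume_L
    per_ind_pmol_h = total_nmol_h / n_individuals * 1e3
    per_gC_umol_h = total_nmol_h / total_biomass_gC * 1e-3
    return per_ind_pmol_h, per_gC_umol_h


def control_correct(
    series: IncubationSeries, control: IncubationSeries
) -> IncubationSeries:
    """Subtract a control (no-animal) series point-wise, floored at 0.

    The control is linearly interpolated onto the sample's time grid when
    the grids differ. Off by default in the pipeline; reported rates are
    net rates.
    """
    if series.analyte != control.analyte:
        raise PairingError(
            f"analyte mismatch: {series.analyte!r} vs {control.analyte!r}"
        )
    ctrl = np.interp(series.times, control.times, control.concs)
    corrected = np.maximum(series.concs - ctrl, 0.0)
    return replace(series, concs_nM=tuple(float(x) for x in corrected))


def estimate_release_rate(
    series: IncubationSeries,
    companions: Sequence[IncubationSeries] = (),
    tol_nM: float = 0.0,
    control: IncubationSeries | None = None,
    r2_min: float = 0.60,
    p_max: float = 0.05,
    combine: str = "or",
) -> RateEstimate:
    """Full per-series pipeline: truncate, fit, QC, normalise."""
    if control is not None:
        series = control_correct(series, control)
    t_c = truncate_series(series, companions, tol_nM)
    t_i = float(series.times[-1])
    try:
        fit = fit_release_rate(series, t_c)
    except InsufficientPointsError:
        # an early stress pulse truncates to almost nothing; name the cause
        status = QC_EARLY_RELEASE if early_release_pattern(series) else QC_INSUFFICIENT
        return RateEstimate(
            series.station, series.replicate, series.analyte,
            None, None, None, t_c, t_i, status,
        )
    status = apply_qc(fit, series, r2_min, p_max, combine)
    per_ind = per_gc = None
    if status == QC_PASS:
        per_ind, per_gc = normalize_rates(
            fit.slope_nM_per_h,
            series.volume_L,
            series.n_individuals,
            series.total_biomass_gC,
        )
    return RateEstimate(
        series.station, series.replicate, series.analyte,
        fit.slope_nM_per_h, fit.r_squared, fit.p_value,
        fit.t_c_h, t_i, status, per_ind, per_gc,
    )


def tau_dfaa_ratio(
    estimates: Mapping[str, RateEstimate] | Iterable[RateEstimate],
    tau_analyte: str = "Tau",
) -> float:
    """Molar ratio of the taurine release rate to the summed DFAA rates.

    Only QC-passing rates enter; both sides use the same normalisation
    (per-individual rates).
    """
    if isinstance(estimates, Mapping):
        estimates = list(estimates.values())
    else:
        estimates = list(estimates)
    tau = [e for e in estimates if e.analyte == tau_analyte and e.qc_status == QC_PASS]
    dfaa = [e for e in estimates if e.analyte != tau_analyte and e.qc_status == QC_PASS]
    if not tau or tau[0].rate_per_individual_pmol_h in (None, 0.0):
        raise UndefinedStatisticError("no passing, nonzero taurine rate")
    if not dfaa:
        raise UndefinedStatisticError("no passing DFAA rates")
    total_dfaa = sum(e.rate_per_individual_pmol_h for e in dfaa)
    if total_dfaa <= 0:
        raise UndefinedStatisticError("summed DFAA rate is not positive")
    return tau[0].rate_per_individual_pmol_h / total_dfaa


def summarize_rates(
    rates: pd.DataFrame,
    by: str | Sequence[str] = "region",
    per_individual_col: str = "rate_pmol_ind_h",
    per_biomass_col: str = "rate_umol_gC_h",
) -> pd.DataFrame:
    """Group means ± sample sd of release rates, with daily conversion.

    One row per group: unweighted arithmetic mean and n−1 sd of the
    per-individual (pmol ind⁻¹ h⁻¹) and per-biomass (µmol g⁻¹ C h⁻¹) rates,
    plus the daily per-individual rate in nmol ind⁻¹ d⁻¹
    (hourly × 24 / 1000).
    """
    if isinstance(by, str):
        by = [by]
    if rates.empty:
        raise MissingDataError("no rates to summarise")
    out = []
    for key, grp in rates.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n"] = len(grp)
        for col, name in (
            (per_individual_col, "pmol_ind_h"),
            (per_biomass_col, "umol_gC_h"),
        ):
            if col in grp.columns and grp[col].notna().any():
                row[f"mean_{name}"] = float(grp[col].mean())
                row[f"sd_{name}"] = (
                    float(grp[col].std(ddof=1)) if len(grp) > 1 else float("nan")
                )
            else:
                row[f"mean_{name}"] = row[f"sd_{name}"] = float("nan")
        row["mean_nmol_ind_d"] = row["mean_pmol_ind_h"] * 24.0 / 1e3
        out.append(row)
    return pd.DataFrame(out)


def rates_from_tables(
    incubations: pd.DataFrame,
    chambers: pd.DataFrame,
    tol_nM: float = 0.0,
    control_correction: bool = False,
    **qc_kwargs,
) -> pd.DataFrame:
    """Estimate rates for every (station, replicate, analyte) in a long table.

    ``incubations`` columns: station, replicate, analyte, time_h, conc_nM,
    is_control. ``chambers`` columns: station, replicate, volume_L,
    n_individuals, total_biomass_gC. Controls are matched per station and
    analyte (replicate ignored). All analytes sharing a chamber act as
    truncation companions for each other.
    """
    meta = chambers.set_index(["station", "replicate"])
    results = []
    inc = incubations.sort_values("time_h")
    controls: dict[tuple[str, str], IncubationSeries] = {}
    chamber_series: dict[tuple[str, str], list[IncubationSeries]] = {}
    for (station, rep, analyte), grp in inc.groupby(
        ["station", "replicate", "analyte"], sort=False
    ):
        is_control = bool(grp["is_control"].iloc[0]) if "is_control" in grp else False
        # duplicate time points (repeat injections, pooled controls) averaged
        times, concs = _collapse_duplicate_times(
            grp["time_h"].to_numpy(dtype=float), grp["conc_nM"].to_numpy(dtype=float)
        )
        if is_control:
            s = IncubationSeries(
                str(station), str(rep), str(analyte),
                tuple(times), tuple(concs), is_control=True,
            )
            controls[(str(station), str(analyte))] = s
            continue
        try:
            m = meta.loc[(station, rep)]
        except KeyError:
            raise MissingDataError(
                f"no chamber metadata for station {station!r} replicate {rep!r}"
            ) from None
        s = IncubationSeries(
            str(station), str(rep), str(analyte),
            tuple(times), tuple(concs),
            volume_L=float(m["volume_L"]),
            n_individuals=int(m["n_individuals"]),
            total_biomass_gC=float(m["total_biomass_gC"]),
        )
        chamber_series.setdefault((str(station), str(rep)), []).append(s)
    for (station, rep), series_list in chamber_series.items():
        for s in series_list:
            companions = [c for c in series_list if c is not s]
            ctrl = controls.get((station, s.analyte)) if control_correction else None
            est = estimate_release_rate(
                s, companions, tol_nM=tol_nM, control=ctrl, **qc_kwargs
            )
            ctrl_slope = float("nan")
            ctrl_s = controls.get((station, s.analyte))
            if ctrl_s is not None and len(ctrl_s.times_h) >= 3:
                ctrl_slope = stats.linregress(ctrl_s.times, ctrl_s.concs).slope
            results.append(
                {
                    "station": station,
                    "replicate": rep,
                    "analyte": s.analyte,
                    "t_c_h": est.t_c_h,
                    "t_i_h": est.t_i_h,
                    "slope_nM_per_h": est.slope_nM_per_h,
                    "r_squared": est.r_squared,
                    "p_value": est.p_value,
                    "qc_status": est.qc_status,
                    "rate_pmol_ind_h": est.rate_per_individual_pmol_h,
                    "rate_umol_gC_h": est.rate_per_gC_umol_h,
                    "control_slope_nM_per_h": ctrl_slope,
                }
            )
    if not results:
        warnings.warn("no non-control incubation series found", stacklevel=2)
    return pd.DataFrame(results)
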