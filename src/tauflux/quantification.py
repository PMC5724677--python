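"""Analytical-QC mathematics for HPLC amino-acid / taurine quantification.

Covers the method-validation arithmetic used when measuring dissolved free
taurine and amino acids by HPLC with fluorescence detection: external
standard-curve linearity, single-point internal-standard quantification,
spike recovery, replicate precision (RSD), signal-to-noise based detection
and quantification limits, and the spike-confirmation check applied to
samples falling between LOD and LOQ.

Instrument-level work (peak integration, retention-time alignment) is out of
scope; every function here operates on already-integrated responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InternalStandardFailureError,
    InvalidInputError,
    LimitsNotReachedError,
    UndefinedStatisticError,
)

__all__ = [
    "StandardSeries",
    "CalibrationBundle",
    "QCMetrics",
    "fit_calibration",
    "quantify_internal_standard",
    "recovery",
    "rsd",
    "detect_limits",
    "confirm_by_spike",
    "qc_report",
]


@dataclass(frozen=True)
class StandardSeries:
    """An external standard series for one analyte.

    Parameters
    ----------
    analyte
        Analyte name, e.g. ``"Tau"`` or ``"Gly"``.
    levels
        Sequence of ``(concentration_nM, response)`` pairs. Replicate
        responses at the same nominal concentration are allowed as repeated
        pairs.
    """

    analyte: str
    levels: tuple[tuple[float, float], ...]

    def __init__(self, analyte: str, levels: Sequence[tuple[float, float]]):
        lv = tuple((float(c), float(r)) for c, r in levels)
        if any(c < 0 or r < 0 for c, r in lv):
            raise InvalidInputError(
                "standard concentrations and responses must be nonnegative"
            )
        if len({c for c, _ in lv}) < 2:
            raise InvalidInputError(
                "a standard series needs at least 2 distinct concentration levels"
            )
        object.__setattr__(self, "analyte", analyte)
        object.__setattr__(self, "levels", lv)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.levels])

    @property
    def responses(self) -> np.ndarray:
        return np.array([r for _, r in self.levels])


@dataclass(frozen=True)
class CalibrationBundle:
    """Fitted calibration line with optional detection limits.

    ``slope`` is in response units per nM, ``intercept`` in response units;
    ``r_squared`` is the squared Pearson correlation of the fit. ``lod_nM``
    and ``loq_nM`` are filled in by :func:`detect_limits` when a dilution
    series with noise estimates is available.
    """

    slope: float
    intercept: float
    r_squared: float
    lod_nM: float | None = None
    loq_nM: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidInputError("r_squared must lie in [0, 1]")
        if self.lod_nM is not None and self.lod_nM < 0:
            raise InvalidInputError("lod_nM must be >= 0")
        if (
            self.lod_nM is not None
            and self.loq_nM is not None
            and self.loq_nM < self.lod_nM
        ):
            raise InvalidInputError("loq_nM must be >= lod_nM")

    def concentration(self, response: float) -> float:
        """Invert the line: concentration (nM) for a detector response."""
        return (response - self.intercept) / self.slope


@dataclass(frozen=True)
class QCMetrics:
    """Recovery and precision for one analyte at one spike level."""

    recovery_pct: float
    rsd_pct: float
    n_replicates: int = field(default=2)

    def __post_init__(self) -> None:
        if self.rsd_pct < 0:
            raise InvalidInputError("rsd_pct must be >= 0")
        if self.n_replicates < 2:
            raise InvalidInputError("RSD requires at least 2 replicates")


def fit_calibration(series: StandardSeries) -> CalibrationBundle:
    """Fit an unweighted least-squares line of response on concentration.

    Returns a :class:`CalibrationBundle` with the OLS slope, intercept and
    the squared Pearson correlation. A validated run is expected to reach
    r² of at least about 0.997; this function does not enforce that — it is
    a property of good standards, not of the fit.

    Raises
    ------
    DegenerateDesignError
        If the concentrations have zero variance (all levels identical).
    """
    x = series.concentrations
    y = series.responses
    if np.ptp(x) == 0:
        raise DegenerateDesignError("concentration levels have zero variance")
    res = stats.linregress(x, y)
    # Constant responses: the line is flat and r is undefined; report r²=1
    # for an exactly collinear (flat) series, else use the Pearson r.
    if np.ptp(y) == 0:
        r2 = 1.0 if np.allclose(y, res.intercept + res.slope * x) else 0.0
    else:
        r2 = float(res.rvalue**2)
    return CalibrationBundle(
        slope=float(res.slope), intercept=float(res.intercept), r_squared=min(r2, 1.0)
    )


def quantify_internal_standard(
    sample_response: float,
    is_response: float,
    is_conc_nM: float,
    rrf: float = 1.0,
) -> float:
    """Single-point internal-standard quantification.

    The analyte concentration is ``(sample_response / is_response) *
    is_conc_nM / rrf`` where ``rrf`` is the relative response factor —
    (analyte response per nM) / (internal-standard response per nM) —
    measured from an external standard run. Because both responses are taken
    from the same injection, multiplying both by a common drift factor
    leaves the result unchanged, which is the point of adding the internal
    standard (here alpha-aminobutyric acid, AABA).

    Raises
    ------
    InternalStandardFailureError
        If ``is_response`` is not strictly positive (lost internal standard).
    InvalidInputError
        If ``rrf`` is not strictly positive.
    """
    if is_response <= 0:
        raise InternalStandardFailureError(
            "internal-standard response must be > 0 (internal standard lost?)"
        )
    if rrf <= 0:
        raise InvalidInputError("relative response factor must be > 0")
    return (sample_response / is_response) * is_conc_nM / rrf


def recovery(c_amended_nM: float, c_unamended_nM: float, c_spike_nM: float) -> float:
    """Spike recovery R in percent: ``R = (Ca - Cu) / Cs * 100``.

    ``Ca`` and ``Cu`` are the measured concentrations of the amended and
    unamended sample and ``Cs`` the nominal spike concentration. A perfectly
    returned spike gives exactly 100%.
    """
    if c_spike_nM <= 0:
        raise InvalidInputError("spike concentration must be > 0")
    return (c_amended_nM - c_unamended_nM) / c_spike_nM * 100.0


def rsd(replicate_concs: Sequence[float]) -> float:
    """Relative standard deviation of replicates, percent.

    Uses the n−1 sample standard deviation divided by the mean.
    """
    x = np.asarray(replicate_concs, dtype=float)
    if x.size < 2:
        raise InvalidInputError("RSD needs at least 2 replicates")
    m = x.mean()
    if m == 0:
        raise UndefinedStatisticError("RSD undefined for zero-mean replicates")
    return float(x.std(ddof=1) / m * 100.0)


def detect_limits(
    dilution_series: Sequence[tuple[float, float, float]],
    sn_lod: float = 3.0,
    sn_loq: float = 10.0,
) -> tuple[float, float]:
    """Detection and quantification limits from a dilution series.

    Each entry is ``(concentration_nM, signal, noise)``. LOD is the lowest
    concentration whose signal-to-noise ratio reaches ``sn_lod`` (default 3)
    and LOQ the lowest reaching ``sn_loq`` (default 10), so LOQ >= LOD.

    Raises
    ------
    LimitsNotReachedError
        If no level reaches the LOD threshold (or none the LOQ threshold).
    InvalidInputError
        If any noise estimate is not strictly positive.
    """
    rows = sorted((float(c), float(s), float(n)) for c, s, n in dilution_series)
    if any(n <= 0 for _, _, n in rows):
        raise InvalidInputError("noise estimates must be > 0")
    lod = next((c for c, s, n in rows if s / n >= sn_lod), None)
    loq = next((c for c, s, n in rows if s / n >= sn_loq), None)
    if lod is None:
        raise LimitsNotReachedError(f"no level reaches S/N >= {sn_lod}")
    if loq is None:
        raise LimitsNotReachedError(f"no level reaches S/N >= {sn_loq}")
    return lod, loq


def confirm_by_spike(
    measured_unspiked_nM: float,
    measured_spiked_nM: float,
    spike_nM: float,
    tol_pct: float = 15.0,
) -> bool:
    """Confirm a sub-LOQ identification by spike return.

    Samples measuring between LOD and LOQ are spiked (here with 1 nM
    taurine); the identification is confirmed when the measured increase
    matches the nominal spike within ``tol_pct`` percent.
    """
    if spike_nM <= 0:
        raise InvalidInputError("spike must be > 0")
    if tol_pct <= 0:
        raise InvalidInputError("tolerance must be > 0")
    err_pct = abs((measured_spiked_nM - measured_unspiked_nM) - spike_nM) / spike_nM * 100.0
    return err_pct <= tol_pct


def qc_report(
    standards: pd.DataFrame,
    replicates: pd.DataFrame | None = None,
    spikes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build a one-row-per-analyte QC report table.

    Parameters
    ----------
    standards
        Long table with columns ``analyte, conc_nM, response`` and optional
        ``noise``. Calibration is fit per analyte; when ``noise`` is present
        detection limits are computed from the same rows.
    replicates
        Optional table ``analyte, sample_id, conc_nM``; RSD is reported per
        analyte pooled over samples with >= 2 replicates (mean of per-sample
        RSDs).
    spikes
        Optional table ``analyte, c_amended_nM, c_unamended_nM, c_spike_nM``;
        recovery is averaged per analyte.

    Returns
    -------
    DataFrame with columns ``analyte, slope, intercept, r_squared, lod_nM,
    loq_nM, recovery_pct, rsd_pct`` (NaN where not computable).
    """
    rows = []
    for analyte, grp in standards.groupby("analyte"):
        series = StandardSeries(analyte, list(zip(grp["conc_nM"], grp["response"])))
        cal = fit_calibration(series)
        lod = loq = math.nan
        if "noise" in grp.columns and grp["noise"].notna().all():
            try:
                lod, loq = detect_limits(
                    list(zip(grp["conc_nM"], grp["response"], grp["noise"]))
                )
            except LimitsNotReachedError:
                pass
        rec = math.nan
        if spikes is not None:
            sp = spikes[spikes["analyte"] == analyte]
            if len(sp):
                rec = float(
                    np.mean(
                        [
                            recovery(a, u, s)
                            for a, u, s in zip(
                                sp["c_amended_nM"], sp["c_unamended_nM"], sp["c_spike_nM"]
                            )
                        ]
                    )
                )
        prec = math.nan
        if replicates is not None:
            rp = replicates[replicates["analyte"] == analyte]
            vals = [
                rsd(g["conc_nM"].to_numpy())
                for _, g in rp.groupby("sample_id")
                if len(g) >= 2 and g["conc_nM"].mean() != 0
            ]
            if vals:
                prec = float(np.mean(vals))
        rows.append(
            {
                "analyte": analyte,
                "slope": cal.slope,
                "intercept": cal.intercept,
                "r_squared": cal.r_squared,
                "lod_nM": lod,
                "loq_nM": loq,
                "recovery_pct": rec,
                "rsd_pct": prec,
            }
        )
    return pd.DataFrame(rows)
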