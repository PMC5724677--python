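"""Depth-profile bookkeeping and comparative statistics.

Bottle-level chemistry for dissolved free taurine profiles: DON by
difference (TDN minus inorganic N), the contribution of taurine carbon and
nitrogen to the bulk DOC and DON pools, depth-layer assignment
(epipelagic / mesopelagic / bathypelagic), layer means, and the two
comparison statistics used on layered data — the two-sided Mann–Whitney U
test and the Hedges g standardized mean difference with small-sample
correction.

Taurine is C₂H₇NO₃S: 2 carbon and 1 nitrogen atoms per molecule, so a
taurine concentration in nM carries 2·nM of carbon (nmol C L⁻¹) and 1·nM of
nitrogen against pools measured in µM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, MissingDataError, UndefinedStatisticError

__all__ = [
    "TAU_C_ATOMS",
    "TAU_N_ATOMS",
    "DEFAULT_LAYER_BOUNDARIES",
    "LayerComparison",
    "compute_don",
    "tau_carbon_fraction",
    "tau_nitrogen_fraction",
    "assign_layer",
    "annotate_profiles",
    "layer_mean_concentration",
    "mann_whitney",
    "hedges_g",
    "compare_layers",
]

TAU_C_ATOMS = 2
TAU_N_ATOMS = 1

#: (epi/meso boundary, meso/bathy boundary) in metres; intervals are
#: half-open [lo, hi), so a 200 m bottle is mesopelagic.
DEFAULT_LAYER_BOUNDARIES: tuple[float, float] = (200.0, 1000.0)

LAYERS = ("epipelagic", "mesopelagic", "bathypelagic")


@dataclass(frozen=True)
class LayerComparison:
    """Mann–Whitney comparison of one variable between two sample groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    hedges_g: float


def compute_don(tdn_uM: float, no3_uM: float, no2_uM: float, nh4_uM: float) -> float:
    """DON by difference: TDN − (NO₃ + NO₂ + NH₄), µM.

    A negative difference (measurement error) is returned as NaN with a
    warning rather than a negative concentration.
    """
    for name, v in (("tdn", tdn_uM), ("no3", no3_uM), ("no2", no2_uM), ("nh4", nh4_uM)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingDataError(f"cannot compute DON: {name} missing")
        if v < 0:
            raise InvalidInputError(f"{name} must be >= 0")
    don = tdn_uM - (no3_uM + no2_uM + nh4_uM)
    if don < 0:
        warnings.warn("negative DON by difference; flagged missing", stacklevel=2)
        return float("nan")
    return don


def tau_carbon_fraction(tau_nM: float, doc_uM: float) -> float:
    """Taurine carbon as a percentage of the DOC pool.

    ``2 × tau_nM`` nmol C L⁻¹ → ×10⁻³ µM C, against DOC in µM, ×100.
    """
    if doc_uM <= 0:
        raise InvalidInputError("DOC must be > 0")
    return TAU_C_ATOMS * tau_nM * 1e-3 / doc_uM * 100.0


def tau_nitrogen_fraction(tau_nM: float, don_uM: float) -> float:
    """Taurine nitrogen as a percentage of the DON pool (1 N per molecule)."""
    if don_uM <= 0:
        raise InvalidInputError("DON must be > 0")
    return TAU_N_ATOMS * tau_nM * 1e-3 / don_uM * 100.0


def assign_layer(
    depth_m: float, boundaries: tuple[float, float] = DEFAULT_LAYER_BOUNDARIES
) -> str:
    """Depth layer for a bottle depth; intervals are [lo, hi)."""
    if depth_m < 0:
        raise InvalidInputError("depth must be >= 0")
    epi_meso, meso_bathy = boundaries
    if not 0 < epi_meso < meso_bathy:
        raise InvalidInputError("boundaries must satisfy 0 < epi/meso < meso/bathy")
    if depth_m < epi_meso:
        return "epipelagic"
    if depth_m < meso_bathy:
        return "mesopelagic"
    return "bathypelagic"


def annotate_profiles(
    bottles: pd.DataFrame,
    boundaries: tuple[float, float] = DEFAULT_LAYER_BOUNDARIES,
) -> pd.DataFrame:
    """Add layer, DON and taurine pool fractions to a bottle table.

    Expects columns ``station, depth_m, tau_nM, doc_uM`` and optionally
    ``tdn_uM, no3_uM, no2_uM, nh4_uM``. DON and the N fraction stay NaN
    where any nitrogen species is missing (as for samples analysed without
    the inorganic N suite).
    """
    out = bottles.copy()
    out["layer"] = [assign_layer(d, boundaries) for d in out["depth_m"]]
    n_cols = ["tdn_uM", "no3_uM", "no2_uM", "nh4_uM"]
    if all(c in out.columns for c in n_cols):
        don = out["tdn_uM"] - (out["no3_uM"] + out["no2_uM"] + out["nh4_uM"])
        don = don.where(don >= 0)  # negative-by-difference flagged missing
    else:
        don = pd.Series(np.nan, index=out.index)
    out["don_uM"] = don
    out["tauC_pct_doc"] = TAU_C_ATOMS * out["tau_nM"] * 1e-3 / out["doc_uM"] * 100.0
    out["tauN_pct_don"] = TAU_N_ATOMS * out["tau_nM"] * 1e-3 / don * 100.0
    return out


def layer_mean_concentration(
    bottles: pd.DataFrame,
    layer: str | None = None,
    depth_window: tuple[float, float] | None = None,
    column: str = "tau_nM",
    boundaries: tuple[float, float] = DEFAULT_LAYER_BOUNDARIES,
) -> float:
    """Unweighted mean of one column over a layer or depth window.

    ``depth_window`` is half-open [lo, hi) in metres and takes precedence
    over ``layer``. All station-depth samples in the window enter with
    equal weight.
    """
    if depth_window is not None:
        lo, hi = depth_window
        sel = bottles[(bottles["depth_m"] >= lo) & (bottles["depth_m"] < hi)]
    elif layer is not None:
        layers = [assign_layer(d, boundaries) for d in bottles["depth_m"]]
        sel = bottles[np.asarray(layers) == layer]
    else:
        raise InvalidInputError("give either a layer or a depth window")
    vals = sel[column].dropna()
    if vals.empty:
        raise MissingDataError("no samples in the requested window")
    return float(vals.mean())


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when both samples are small
    (min n ≤ 8) and untied, and the normal approximation with tie
    correction otherwise. Two groups with all values identical carry no
    rank information: U is its null mean and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def hedges_g(a, b) -> float:
    """Hedges g: standardized mean difference with small-sample correction.

    The pooled n−1 standard deviation divides the mean difference and the
    result is multiplied by J = 1 − 3/(4(n_a+n_b)−9). Returned as a
    magnitude (absolute value), the usual convention when g is read purely
    as an effect size.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a + n_b < 3 or n_a < 1 or n_b < 1:
        raise InvalidInputError("need at least 3 observations across both groups")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * a.var(ddof=1) if n_a > 1 else 0.0) + (
        (n_b - 1) * b.var(ddof=1) if n_b > 1 else 0.0
    )
    pooled_sd = np.sqrt(pooled_var / df) if df > 0 else 0.0
    if pooled_sd == 0:
        if a.mean() == b.mean():
            return 0.0
        raise UndefinedStatisticError("zero pooled sd with unequal means")
    j = 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0)
    return float(abs(a.mean() - b.mean()) / pooled_sd * j)


def compare_layers(
    bottles: pd.DataFrame,
    layer_a: str,
    layer_b: str,
    column: str = "tau_nM",
    boundaries: tuple[float, float] = DEFAULT_LAYER_BOUNDARIES,
) -> LayerComparison:
    """Mann–Whitney + Hedges g comparison of one variable between layers."""
    layers = np.asarray([assign_layer(d, boundaries) for d in bottles["depth_m"]])
    va = bottles.loc[layers == layer_a, column].dropna().to_numpy()
    vb = bottles.loc[layers == layer_b, column].dropna().to_numpy()
    if va.size == 0 or vb.size == 0:
        raise MissingDataError(f"no samples in {layer_a!r} or {layer_b!r}")
    u, p = mann_whitney(va, vb)
    g = hedges_g(va, vb)
    return LayerComparison(layer_a, layer_b, va.size, vb.size, u, p, g)
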