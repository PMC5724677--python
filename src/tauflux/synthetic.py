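"""Synthetic data generators for every stage of the pipeline.

No raw cruise data ship with this package; instead each input the analysis
consumes can be simulated with known ground truth:

* incubation time series with a linear-rise-then-plateau kinetic, an
  optional exponentially decaying handling-stress spike, and Gaussian
  noise (:func:`simulate_incubation`);
* exponential-with-depth taurine profiles with paired DOC/TDN/inorganic-N
  chemistry (:func:`simulate_profiles`);
* log-normal specimen morphometrics per taxon group
  (:func:`simulate_specimens`);
* linear HPLC standard series with signal-to-noise columns
  (:func:`simulate_standard_series`).

The ``"goa"`` and ``"na"`` presets reproduce the two campaign designs: the
subarctic Pacific incubations sampled every 2 h to 12 h plus a final point
at 24 h with large mixed copepod–amphipod assemblages (~340 µg C per
individual), the Atlantic incubations every 0.5 h to 2 h then 3, 5, 8 h
with small copepods (~2.5 µg C per individual). All generators take a
mandatory seed and are bit-reproducible for a given scenario + seed.

The kinetic form (linear rise, hard plateau, exponential stress pulse) is
this package's modelling choice for chamber behaviour; real incubations
can curve smoothly into their plateau and the noise need not be
homoscedastic (a proportional-error option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .morphometry import Specimen, specimen_set_biomass
from .release_rates import IncubationSeries

__all__ = [
    "GOA_TIME_GRID_H",
    "NA_TIME_GRID_H",
    "IncubationScenario",
    "ProfileScenario",
    "simulate_incubation",
    "simulate_profiles",
    "simulate_specimens",
    "simulate_standard_series",
    "SPECIMEN_PRESETS",
]

#: Sampling grids of the two campaign designs (hours).
GOA_TIME_GRID_H: tuple[float, ...] = (0, 2, 4, 6, 8, 10, 12, 24)
NA_TIME_GRID_H: tuple[float, ...] = (0, 0.5, 1, 1.5, 2, 3, 5, 8)


@dataclass(frozen=True)
class IncubationScenario:
    """Ground truth for one simulated incubation chamber.

    ``true_rates_pmol_ind_h`` maps analyte name to the true per-individual
    release rate; the volumetric slope is
    ``rate × n_individuals / (volume_L × 10³)`` nM h⁻¹. Concentrations rise
    linearly until ``plateau_time_h`` (default: never within the grid) and
    stay flat after; an optional stress spike adds
    ``stress_spike_nM · exp(−t/stress_decay_h)``.
    """

    true_rates_pmol_ind_h: Mapping[str, float]
    n_individuals: int = 50
    volume_L: float = 0.5
    biomass_gC: float = 0.0168
    sampling_times_h: tuple[float, ...] = GOA_TIME_GRID_H
    plateau_time_h: float | None = None
    stress_spike_nM: float = 0.0
    stress_decay_h: float = 1.0
    noise_sd_nM: float = 10.0
    proportional_noise: bool = False
    baseline_nM: float = 1.0
    station: str = "synthetic"
    replicate: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_rates_pmol_ind_h:
            raise InvalidInputError("need at least one analyte rate")
        if any(r <= 0 for r in self.true_rates_pmol_ind_h.values()):
            raise InvalidInputError("true rates must be > 0")
        if self.volume_L <= 0 or self.n_individuals <= 0 or self.biomass_gC <= 0:
            raise InvalidInputError("volume, individuals and biomass must be > 0")
        if self.noise_sd_nM < 0:
            raise InvalidInputError("noise sd must be >= 0")

    @classmethod
    def preset(cls, name: str, seed: int, **overrides) -> "IncubationScenario":
        """Campaign presets ``"goa"`` and ``"na"`` with study-like defaults."""
        if name == "goa":
            base = cls(
                true_rates_pmol_ind_h={"Tau": 425.0, "Gly": 300.0},
                n_individuals=50,
                biomass_gC=50 * 3.4e-4,
                sampling_times_h=GOA_TIME_GRID_H,
                noise_sd_nM=10.0,
                station="goa-synthetic",
                seed=seed,
            )
        elif name == "na":
            base = cls(
                true_rates_pmol_ind_h={"Tau": 24.4, "Gly": 60.0},
                n_individuals=40,
                biomass_gC=40 * 2.8e-6,
                sampling_times_h=NA_TIME_GRID_H,
                noise_sd_nM=0.3,
                station="na-synthetic",
                seed=seed,
            )
        else:
            raise InvalidInputError(f"unknown preset {name!r}")
        return replace(base, **overrides) if overrides else base

    def volumetric_slope_nM_h(self, analyte: str) -> float:
        """True volumetric slope for one analyte, nM h⁻¹."""
        return (
            self.true_rates_pmol_ind_h[analyte]
            * self.n_individuals
            / (self.volume_L * 1e3)
        )


def simulate_incubation(scenario: IncubationScenario) -> list[IncubationSeries]:
    """Simulate one chamber: one series per analyte plus matched controls.

    Controls carry the same baseline and noise but zero release and no
    stress spike (no animals). Identical scenarios + seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    t = np.asarray(scenario.sampling_times_h, dtype=float)
    plateau = (
        float(t[-1]) if scenario.plateau_time_h is None else scenario.plateau_time_h
    )
    out: list[IncubationSeries] = []
    for analyte in scenario.true_rates_pmol_ind_h:
        r_v = scenario.volumetric_slope_nM_h(analyte)
        # the t=0 sample is drawn as the animals go in, before their
        # handling-stress pulse reaches the water; spike applies for t > 0
        spike = np.where(
            t > 0,
            scenario.stress_spike_nM * np.exp(-t / scenario.stress_decay_h),
            0.0,
        )
        mean = scenario.baseline_nM + spike + r_v * np.minimum(t, plateau)
        sd = (
            scenario.noise_sd_nM * np.maximum(mean, 0) / np.maximum(mean.max(), 1e-12)
            if scenario.proportional_noise
            else scenario.noise_sd_nM
        )
        concs = np.maximum(mean + rng.normal(0.0, sd, size=t.size), 0.0)
        out.append(
            IncubationSeries(
                scenario.station,
                scenario.replicate,
                analyte,
                tuple(t),
                tuple(concs),
                volume_L=scenario.volume_L,
                n_individuals=scenario.n_individuals,
                total_biomass_gC=scenario.biomass_gC,
            )
        )
    for analyte in scenario.true_rates_pmol_ind_h:
        ctrl_mean = np.full(t.size, scenario.baseline_nM)
        concs = np.maximum(
            ctrl_mean + rng.normal(0.0, scenario.noise_sd_nM, size=t.size), 0.0
        )
        out.append(
            IncubationSeries(
                scenario.station,
                "control",
                analyte,
                tuple(t),
                tuple(concs),
                volume_L=scenario.volume_L,
                is_control=True,
            )
        )
    return out


@dataclass(frozen=True)
class ProfileScenario:
    """Exponential-with-depth taurine profile with paired bulk chemistry.

    tau(z) = baseline + (surface − baseline)·exp(−z / e_folding) + noise,
    floored at zero. The defaults put ~1–5 nM in the epipelagic declining
    to ~0.15 nM at depth, with an upper-100-m mean near 2.5 nM on the
    default bottle grid. DOC, DON and the inorganic N species follow
    smooth open-ocean shapes so pool fractions are computable.
    """

    surface_conc_nM: float = 5.0
    e_folding_depth_m: float = 60.0
    deep_baseline_nM: float = 0.15
    n_stations: int = 6
    depths_m: tuple[float, ...] = (
        5, 25, 50, 75, 100, 150, 200, 300, 500, 750, 1000, 1500, 2000, 3000,
    )
    noise_sd_nM: float = 0.1
    with_nitrogen: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deep_baseline_nM >= self.surface_conc_nM:
            raise InvalidInputError("deep baseline must be below the surface value")
        if self.e_folding_depth_m <= 0 or self.n_stations < 1:
            raise InvalidInputError("invalid profile scenario")

    def mean_tau_nM(self, depth_m: np.ndarray | float) -> np.ndarray | float:
        """Noise-free taurine concentration at depth (closed form)."""
        return self.deep_baseline_nM + (
            self.surface_conc_nM - self.deep_baseline_nM
        ) * np.exp(-np.asarray(depth_m, dtype=float) / self.e_folding_depth_m)


def simulate_profiles(scenario: ProfileScenario) -> pd.DataFrame:
    """Bottle table: station, depth_m, tau_nM, doc_uM, tdn/no3/no2/nh4_uM."""
    rng = np.random.default_rng(scenario.seed)
    rows = []
    z = np.asarray(scenario.depths_m, dtype=float)
    for i in range(scenario.n_stations):
        tau = np.maximum(
            scenario.mean_tau_nM(z) + rng.normal(0, scenario.noise_sd_nM, z.size), 0.0
        )
        doc = 42.0 + 38.0 * np.exp(-z / 150.0) + rng.normal(0, 1.5, z.size)
        doc = np.maximum(doc, 35.0)
        row = {
            "station": f"S{i + 1}",
            "depth_m": z,
            "tau_nM": tau,
            "doc_uM": doc,
        }
        if scenario.with_nitrogen:
            don = 2.0 + 4.5 * np.exp(-z / 300.0) + rng.normal(0, 0.2, z.size)
            don = np.maximum(don, 1.0)
            no3 = np.maximum(1.0 + 30.0 * (1 - np.exp(-z / 400.0)) + rng.normal(0, 0.5, z.size), 0.0)
            no2 = np.maximum(0.1 + rng.normal(0, 0.02, z.size), 0.0)
            nh4 = np.maximum(0.05 + 0.3 * np.exp(-z / 100.0) + rng.normal(0, 0.02, z.size), 0.0)
            row.update(
                tdn_uM=don + no3 + no2 + nh4, no3_uM=no3, no2_uM=no2, nh4_uM=nh4
            )
        rows.append(pd.DataFrame(row))
    return pd.concat(rows, ignore_index=True)


#: Morphometric presets. Medians chosen so the implied per-individual
#: carbon biomass lands in the two observed regimes: large subarctic
#: Pacific assemblages (~3.4 × 10⁻⁴ g C ind⁻¹) and small Atlantic copepods
#: (~2.5 × 10⁻⁶ g C ind⁻¹).
SPECIMEN_PRESETS: dict[str, dict] = {
    "goa": {
        "group": "copepod",
        "taxon": "Neocalanus-like",
        "median_length_um": 4200.0,
        "diameter_ratio": 1 / 3,
        "sigma_log": 0.15,
    },
    "na": {
        "group": "copepod",
        "taxon": "Calanus-like",
        "median_length_um": 810.0,
        "diameter_ratio": 1 / 3,
        "sigma_log": 0.15,
    },
}


def simulate_specimens(
    group: str,
    n: int,
    median_length_um: float,
    seed: int,
    diameter_ratio: float = 1 / 3,
    sigma_log: float = 0.15,
    taxon: str | None = None,
) -> list[Specimen]:
    """Draw ``n`` specimens with log-normal lengths (and linked diameters).

    ``sigma_log`` is the log-scale sd; ``sigma_log = 0`` gives identical
    specimens. Diameters are ``diameter_ratio × length`` with small
    independent log-normal jitter.
    """
    if n < 1 or median_length_um <= 0 or sigma_log < 0 or diameter_ratio <= 0:
        raise InvalidInputError("invalid specimen distribution parameters")
    rng = np.random.default_rng(seed)
    lengths = median_length_um * np.exp(rng.normal(0.0, sigma_log, n))
    diam = lengths * diameter_ratio * np.exp(rng.normal(0.0, sigma_log / 3, n))
    return [
        Specimen(taxon or group, group, float(L), float(d))
        for L, d in zip(lengths, diam)
    ]


def simulate_specimens_preset(preset: str, n: int, seed: int) -> list[Specimen]:
    """Specimen set from a campaign preset (``"goa"`` or ``"na"``)."""
    try:
        p = SPECIMEN_PRESETS[preset]
    except KeyError:
        raise InvalidInputError(f"unknown specimen preset {preset!r}") from None
    return simulate_specimens(
        p["group"], n, p["median_length_um"], seed,
        diameter_ratio=p["diameter_ratio"], sigma_log=p["sigma_log"],
        taxon=p["taxon"],
    )


def simulate_standard_series(
    analyte: str,
    levels_nM: Sequence[float] = (1, 5, 10, 500, 1000, 1500),
    response_per_nM: float = 1000.0,
    noise_rel: float = 0.03,
    baseline_noise: float = 5.0,
    n_replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear standard series with proportional response noise and S/N.

    Response = ``response_per_nM × conc × (1 + ε)`` with
    ε ~ N(0, noise_rel); the ``noise`` column is the constant instrument
    baseline noise so S/N grows linearly with concentration. The default
    3% proportional noise puts the fitted r² in the high-0.99s expected of
    a validated run.
    """
    if any(c <= 0 for c in levels_nM):
        raise InvalidInputError("standard levels must be > 0")
    if baseline_noise <= 0:
        raise InvalidInputError("baseline noise must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for c in levels_nM:
        for _ in range(n_replicates):
            resp = response_per_nM * c * (1.0 + rng.normal(0.0, noise_rel))
            rows.append(
                {
                    "analyte": analyte,
                    "conc_nM": float(c),
                    "response": max(resp, 0.0),
                    "noise": baseline_noise,
                }
            )
    return pd.DataFrame(rows)
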