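"""Published incubation summary tables used as worked inputs.

Community- and species-specific taurine release rates from two shipboard
incubation campaigns: a Gulf of Alaska cruise (August 2013; mixed
copepod–amphipod assemblages, six stations, 24 h incubations) and a North
Atlantic cruise (August 2014; a mixed copepod community plus four
single-species experiments, 8–24 h incubations). Each row is one chamber's
already-fitted rate: the regression time span T_C, total incubation time
T_I, fit r², headcount and the per-individual and per-carbon-biomass
rates. These are literature values transcribed at printed precision — the
raw time series behind them are not distributed — and serve as inputs for
the summary statistics and turnover calculations.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "goa_community_rates",
    "na_community_rates",
    "na_species_rates",
]

_GOA_ROWS = [
    # station, replicate, t_c_h, t_i_h, r2, %large-copepod, %Themisto, %Vibilia,
    # n_total, rate_pmol_ind_h, rate_umol_gC_h
    ("5", "A", 24, 24, 0.970, 32, 26, 42, 50, 316.8, 0.9),
    ("5", "B", 24, 24, 0.907, 51, 22, 28, 83, 480.2, 0.5),
    ("8", "A", 8, 24, 0.984, 0, 63, 37, 38, 570.8, 1.7),
    ("12", "A", 8, 24, 0.955, 59, 35, 6, 51, 331.8, 0.5),
    ("17", "A", 10, 24, 0.977, 79, 19, 2, 53, 356.0, 0.7),
    ("20", "A", 8, 24, 0.998, 78, 19, 4, 54, 498.3, 0.6),
    ("29", "A", 8, 24, 0.856, 56, 18, 26, 39, 421.8, 0.6),
]

_NA_COMMUNITY_ROWS = [
    # station, replicate, t_c_h, t_i_h, r2, %Acartia, %Calanus, %Centropagus,
    # n_total, rate_pmol_ind_h, rate_umol_gC_h
    ("14", "A", 3, 24, 0.814, 14, 45, 41, 44, 24.7, 8.9),
    ("14", "B", 3, 24, 0.851, 20, 32, 49, 41, 24.5, 7.7),
    ("14", "C", 3, 24, 0.970, 20, 20, 59, 49, 24.1, 11.8),
]

_NA_SPECIES_ROWS = [
    # station, species, replicate, t_c_h, t_i_h, r2, n_total,
    # rate_pmol_ind_h, rate_umol_gC_h
    ("111", "Calanus", "A", 8, 8, 0.807, 30, 17.9, 7.6),
    ("111", "Calanus", "B", 8, 8, 0.772, 30, 6.9, 4.4),
    ("111", "Calanus", "C", 8, 8, 0.851, 35, 16.7, 7.0),
    ("59", "Acartia", "A", 5, 8, 0.877, 37, 7.9, 3.4),
    ("59", "Acartia", "B", 5, 8, 0.878, 35, 7.2, 4.6),
    ("59", "Acartia", "C", 5, 8, 0.949, 35, 7.9, 3.2),
    ("115", "Clausocalanus", "A", 5, 8, 0.616, 35, 5.5, 3.8),
    ("115", "Clausocalanus", "B", 5, 8, 0.817, 35, 4.7, 3.3),
    ("115", "Clausocalanus", "C", 5, 8, 0.740, 35, 7.1, 5.1),
    ("111", "Centropagus", "A", 8, 8, 0.868, 30, 3.8, 1.1),
    ("111", "Centropagus", "B", 8, 8, 0.841, 30, 4.5, 1.8),
    ("111", "Centropagus", "C", 8, 8, 0.915, 30, 3.8, 1.1),
]


def goa_community_rates() -> pd.DataFrame:
    """Gulf of Alaska mixed-assemblage community rates (7 chambers)."""
    df = pd.DataFrame(
        _GOA_ROWS,
        columns=[
            "station", "replicate", "t_c_h", "t_i_h", "r_squared",
            "pct_neocalanus", "pct_themisto", "pct_vibilia", "n_total",
            "rate_pmol_ind_h", "rate_umol_gC_h",
        ],
    )
    df["region"] = "goa"
    df["pct_amphipod"] = df["pct_themisto"] + df["pct_vibilia"]
    return df


def na_community_rates() -> pd.DataFrame:
    """North Atlantic mixed copepod community rates (3 replicates)."""
    df = pd.DataFrame(
        _NA_COMMUNITY_ROWS,
        columns=[
            "station", "replicate", "t_c_h", "t_i_h", "r_squared",
            "pct_acartia", "pct_calanus", "pct_centropagus", "n_total",
            "rate_pmol_ind_h", "rate_umol_gC_h",
        ],
    )
    df["region"] = "na"
    return df


def na_species_rates() -> pd.DataFrame:
    """North Atlantic single-species rates (4 species × 3 replicates)."""
    df = pd.DataFrame(
        _NA_SPECIES_ROWS,
        columns=[
            "station", "species", "replicate", "t_c_h", "t_i_h", "r_squared",
            "n_total", "rate_pmol_ind_h", "rate_umol_gC_h",
        ],
    )
    df["region"] = "na"
    return df
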