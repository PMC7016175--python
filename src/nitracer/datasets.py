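"""Reference values from a published two-soil DMPP microcosm study.

These are the printed summary tables of the study the package's
synthetic design emulates: gross N transformation rates (mean +/- sd,
ug N/g soil/day), soil pools and microbial biomass (ug/g soil), and
cumulative 48 h gas emissions (ug/g soil).  They serve as inputs for
derived-quantity arithmetic (effect sizes, contributions, product
ratios) and as regime anchors for the synthetic generator; the raw
time series behind them were not published.

Keys: soil in {"sandy_cl", "loam"}; treatment in {"fertilizer", "dmpp"}.
"""

from __future__ import annotations

# Gross N transformation rates: (mean, sd)
GROSS_RATES = {
    "sandy_cl": {
        "fertilizer": {
            "M_Nrec": (0.12, 0.04), "I_NH4_Nrec": (0.16, 0.04),
            "M_Nlab": (0.10, 0.03), "I_NH4_Nlab": (0.81, 0.26),
            "O_Nrec": (0.38, 0.11), "I_NO3": (9.48, 0.12),
            "O_NH4": (5.44, 0.28), "D_NO3": (0.026, 0.003),
            "A_NH4": (1.18, 0.22), "R_NH4a": (0.08, 0.02),
        },
        "dmpp": {
            "M_Nrec": (1.03, 0.11), "I_NH4_Nrec": (0.79, 0.22),
            "M_Nlab": (0.25, 0.05), "I_NH4_Nlab": (2.59, 0.50),
            "O_Nrec": (0.34, 0.22), "I_NO3": (6.55, 0.31),
            "O_NH4": (2.04, 0.20), "D_NO3": (0.14, 0.01),
            "A_NH4": (0.87, 0.75), "R_NH4a": (0.68, 0.07),
        },
    },
    "loam": {
        "fertilizer": {
            "M_Nrec": (2.59, 0.09), "I_NH4_Nrec": (0.002, 0.0005),
            "M_Nlab": (5.80, 0.28), "I_NH4_Nlab": (0.002, 0.0002),
            "O_Nrec": (0.0, 0.0), "I_NO3": (0.017, 0.0005),
            "O_NH4": (18.64, 0.24), "D_NO3": (2.14, 0.05),
            "A_NH4": (0.0, 0.0), "R_NH4a": (0.0, 0.0),
        },
        "dmpp": {
            "M_Nrec": (2.50, 0.11), "I_NH4_Nrec": (0.0020, 0.00005),
            "M_Nlab": (5.37, 0.07), "I_NH4_Nlab": (0.002, 0.0002),
            "O_Nrec": (0.0, 0.0), "I_NO3": (0.016, 0.0005),
            "O_NH4": (17.46, 0.37), "D_NO3": (2.02, 0.08),
            "A_NH4": (0.0, 0.0), "R_NH4a": (0.0, 0.0),
        },
    },
}

# Soil pools and biomass: variable -> soil -> {condition: (mean, se)}
SOIL_POOLS = {
    "nh4": {
        "sandy_cl": {"t0": (17.0, 0.1), "fertilizer_48h": (9.9, 0.5),
                     "dmpp_48h": (14.4, 0.2)},
        "loam": {"t0": (18.2, 0.2), "fertilizer_48h": (2.1, 0.1),
                 "dmpp_48h": (7.1, 0.8)},
    },
    "no3": {
        "sandy_cl": {"t0": (70.9, 2.2), "fertilizer_48h": (70.2, 2.1),
                     "dmpp_48h": (61.9, 1.4)},
        "loam": {"t0": (135.2, 1.4), "fertilizer_48h": (175.0, 3.3),
                 "dmpp_48h": (171.0, 4.0)},
    },
    "doc": {
        "sandy_cl": {"prior": (37.7, 1.3), "fertilizer_48h": (71.3, 4.1),
                     "dmpp_48h": (107.3, 12.0)},
        "loam": {"prior": (146.1, 2.0), "fertilizer_48h": (197.9, 9.4),
                 "dmpp_48h": (261.3, 6.5)},
    },
    "c_mic": {
        "sandy_cl": {"prior": (93.6, 18.7), "fertilizer_48h": (61.5, 13.9),
                     "dmpp_48h": (66.3, 7.4)},
        "loam": {"prior": (433.0, 34.4), "fertilizer_48h": (471.8, 13.5),
                 "dmpp_48h": (480.3, 7.5)},
    },
    "n_mic": {
        "sandy_cl": {"prior": (11.9, 0.6), "fertilizer_48h": (13.9, 1.9),
                     "dmpp_48h": (11.9, 0.8)},
        "loam": {"prior": (89.1, 16.8), "fertilizer_48h": (82.3, 2.5),
                 "dmpp_48h": (92.7, 4.3)},
    },
}

# Cumulative 48 h emissions: variable -> soil -> treatment -> (mean, se)
EMISSIONS = {
    "denitrification": {   # N2 + N2O_d
        "sandy_cl": {"fertilizer": (0.73, 0.13), "dmpp": (0.58, 0.05)},
        "loam": {"fertilizer": (3.08, 0.87), "dmpp": (2.83, 1.02)},
    },
    "n2": {
        "sandy_cl": {"fertilizer": (0.47, 0.09), "dmpp": (0.46, 0.04)},
        "loam": {"fertilizer": (0.87, 0.11), "dmpp": (1.20, 0.20)},
    },
    "n2o": {
        "sandy_cl": {"fertilizer": (0.24, 0.03), "dmpp": (0.14, 0.02)},
        "loam": {"fertilizer": (1.46, 0.38), "dmpp": (1.80, 0.52)},
    },
    "co2": {
        "sandy_cl": {"fertilizer": (6.55, 0.52), "dmpp": (5.99, 0.18)},
        "loam": {"fertilizer": (44.66, 1.73), "dmpp": (46.27, 1.35)},
    },
}

# Reported method detection limits for N2 (ug N2-N / g soil) at two
# assumed enrichments of the denitrifying pool
N2_DETECTION_LIMITS = {0.50: 0.005, 0.20: 0.014}
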