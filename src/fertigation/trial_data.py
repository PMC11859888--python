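"""Published summary data from a 2020-2022 drip-fertigated sugar-beet trial.

The reference study (Wulanchabu, Inner Mongolia) ran a split-plot trial
with four fertilization levels (main plots F1-F4, total N+P2O5+K2O of
336-462 kg/ha) crossed with three irrigation levels (subplots W1-W3,
945-1350 m3/ha) in three replicates, with F3W3 as the conventional-dose
control (CK) and unfertilized checks at every irrigation level.  Only
treatment means (+/- SD, with LSD letters) were published, not the
plot-level raw data; this module packages those summaries as tidy
DataFrames for tests, demos and the desk-scale re-analysis.

All loaders return fresh copies, so callers may mutate freely.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "FERT_LEVELS",
    "IRR_LEVELS",
    "CK_FERT",
    "CK_IRR",
    "MEAN_GROWTH_PRECIP_MM",
    "PUBLISHED_TWI_WINDOW_M3HA",
    "PUBLISHED_FERT_WINDOW_KGHA",
    "PUBLISHED_IRRIGATION_WINDOW_M3HA",
    "load_dose_table",
    "load_yield_means",
    "load_quality_means",
    "load_surface_summary",
    "load_reference_trial",
]

# (N, P2O5, K2O) doses in kg/ha per fertilization level; irrigation in m3/ha.
_DOSES = {
    "F1": (96.0, 120.0, 120.0),
    "F2": (108.0, 135.0, 135.0),
    "F3": (120.0, 150.0, 150.0),
    "F4": (132.0, 165.0, 165.0),
}
_IRRIGATION = {"W1": 945.0, "W2": 1147.5, "W3": 1350.0}

FERT_LEVELS = {k: sum(v) for k, v in _DOSES.items()}   # totals: 336..462
IRR_LEVELS = dict(_IRRIGATION)
CK_FERT = "F3"
CK_IRR = "W3"

#: Mean effective precipitation over the beet growth period, 2020-2022 (mm).
MEAN_GROWTH_PRECIP_MM = 309.46

#: Reported optimal windows from the pooled multi-criterion analysis.
#: The pooled plot-level data behind them were not published, so these are
#: documented reference outputs, not reproducible targets.
PUBLISHED_TWI_WINDOW_M3HA = (4136.46, 4380.82)
PUBLISHED_FERT_WINDOW_KGHA = (394.04, 408.03)
PUBLISHED_IRRIGATION_WINDOW_M3HA = (1041.91, 1286.27)

# Root yield, t/ha: mean, SD, LSD letters (per year).
_YIELD = {
    2020: {
        ("F1", "W1"): (55.21, 0.93, "c"),   ("F2", "W1"): (57.25, 2.23, "bc"),
        ("F3", "W1"): (55.55, 1.38, "c"),   ("F4", "W1"): (55.52, 1.23, "c"),
        ("F1", "W2"): (57.11, 1.46, "bc"),  ("F2", "W2"): (59.07, 0.41, "ab"),
        ("F3", "W2"): (60.07, 0.88, "a"),   ("F4", "W2"): (56.32, 1.68, "c"),
        ("F1", "W3"): (56.22, 1.73, "c"),   ("F2", "W3"): (61.12, 1.70, "a"),
        ("F3", "W3"): (60.81, 1.21, "a"),   ("F4", "W3"): (60.39, 0.21, "a"),
    },
    2021: {
        ("F1", "W1"): (61.36, 0.81, "f"),   ("F2", "W1"): (63.05, 1.35, "ef"),
        ("F3", "W1"): (68.60, 4.84, "bcd"), ("F4", "W1"): (62.25, 0.60, "f"),
        ("F1", "W2"): (65.28, 2.93, "def"), ("F2", "W2"): (72.01, 2.43, "bc"),
        ("F3", "W2"): (72.14, 4.57, "bc"),  ("F4", "W2"): (70.20, 1.46, "bc"),
        ("F1", "W3"): (67.50, 5.52, "cde"), ("F2", "W3"): (79.36, 2.36, "a"),
        ("F3", "W3"): (73.47, 1.06, "b"),   ("F4", "W3"): (71.38, 0.88, "bc"),
    },
    2022: {
        ("F1", "W1"): (65.90, 1.85, "de"),    ("F2", "W1"): (67.46, 1.88, "bcde"),
        ("F3", "W1"): (66.61, 0.31, "cde"),   ("F4", "W1"): (65.35, 3.57, "e"),
        ("F1", "W2"): (68.84, 1.43, "abcd"),  ("F2", "W2"): (69.11, 0.34, "abcd"),
        ("F3", "W2"): (67.21, 2.03, "bcde"),  ("F4", "W2"): (66.87, 0.09, "bcde"),
        ("F1", "W3"): (69.59, 0.87, "abc"),   ("F2", "W3"): (70.70, 1.34, "a"),
        ("F3", "W3"): (69.95, 1.48, "ab"),    ("F4", "W3"): (67.63, 0.70, "abcde"),
    },
}

# ANOVA significance codes per year for the yield table: F, W, FxW.
_YIELD_STARS = {2020: ("**", "**", "*"), 2021: ("**", "**", "*"),
                2022: ("*", "**", "ns")}

# Root sugar content (%) and sugar yield (t/ha): mean, SD, letters.
_SUGAR_CONTENT = {
    2020: {
        ("F1", "W1"): (16.23, 0.18, "a"),   ("F1", "W2"): (15.79, 0.24, "bc"),
        ("F1", "W3"): (15.78, 0.16, "bc"),  ("F2", "W1"): (15.69, 0.35, "bcd"),
        ("F2", "W2"): (15.48, 0.09, "cde"), ("F2", "W3"): (15.20, 0.34, "ef"),
        ("F3", "W1"): (15.99, 0.28, "ab"),  ("F3", "W2"): (15.28, 0.05, "def"),
        ("F3", "W3"): (15.19, 0.25, "ef"),  ("F4", "W1"): (15.91, 0.20, "abc"),
        ("F4", "W2"): (15.90, 0.22, "abc"), ("F4", "W3"): (15.00, 0.15, "f"),
    },
    2021: {
        ("F1", "W1"): (20.63, 0.31, "a"),   ("F1", "W2"): (19.73, 0.40, "ab"),
        ("F1", "W3"): (19.18, 1.02, "bc"),  ("F2", "W1"): (20.39, 0.40, "a"),
        ("F2", "W2"): (18.47, 0.14, "c"),   ("F2", "W3"): (17.18, 0.43, "d"),
        ("F3", "W1"): (19.29, 0.86, "bc"),  ("F3", "W2"): (18.66, 0.71, "c"),
        ("F3", "W3"): (18.47, 0.30, "c"),   ("F4", "W1"): (20.34, 0.50, "a"),
        ("F4", "W2"): (18.74, 0.60, "bc"),  ("F4", "W3"): (18.58, 0.26, "c"),
    },
    2022: {
        ("F1", "W1"): (16.28, 0.04, "a"),   ("F1", "W2"): (15.96, 0.10, "cd"),
        ("F1", "W3"): (15.92, 0.06, "d"),   ("F2", "W1"): (16.10, 0.11, "bc"),
        ("F2", "W2"): (16.04, 0.13, "cd"),  ("F2", "W3"): (15.92, 0.06, "d"),
        ("F3", "W1"): (16.09, 0.04, "bcd"), ("F3", "W2"): (16.06, 0.11, "bcd"),
        ("F3", "W3"): (15.70, 0.08, "e"),   ("F4", "W1"): (16.21, 0.11, "ab"),
        ("F4", "W2"): (16.13, 0.08, "abc"), ("F4", "W3"): (15.99, 0.11, "cd"),
    },
}
_SUGAR_YIELD = {
    2020: {
        ("F1", "W1"): (8.96, 0.05, "def"),  ("F1", "W2"): (9.02, 0.14, "cdef"),
        ("F1", "W3"): (8.87, 0.19, "ef"),   ("F2", "W1"): (8.98, 0.16, "cdef"),
        ("F2", "W2"): (9.15, 0.04, "abcd"), ("F2", "W3"): (9.29, 0.07, "a"),
        ("F3", "W1"): (8.88, 0.07, "ef"),   ("F3", "W2"): (9.18, 0.12, "abc"),
        ("F3", "W3"): (9.24, 0.07, "ab"),   ("F4", "W1"): (8.83, 0.10, "f"),
        ("F4", "W2"): (8.95, 0.15, "def"),  ("F4", "W3"): (9.06, 0.10, "bcde"),
    },
    2021: {
        ("F1", "W1"): (12.66, 0.32, "d"),    ("F1", "W2"): (12.87, 0.31, "bcd"),
        ("F1", "W3"): (12.91, 0.56, "bcd"),  ("F2", "W1"): (12.86, 0.40, "cd"),
        ("F2", "W2"): (13.30, 0.55, "abc"),  ("F2", "W3"): (13.63, 0.19, "a"),
        ("F3", "W1"): (13.21, 0.33, "abcd"), ("F3", "W2"): (13.44, 0.43, "ab"),
        ("F3", "W3"): (13.57, 0.24, "a"),    ("F4", "W1"): (12.66, 0.23, "d"),
        ("F4", "W2"): (13.15, 0.21, "abcd"), ("F4", "W3"): (13.26, 0.35, "abc"),
    },
    2022: {
        ("F1", "W1"): (10.63, 0.24, "ab"),  ("F1", "W2"): (10.97, 0.15, "ab"),
        ("F1", "W3"): (11.08, 0.09, "ab"),  ("F2", "W1"): (10.86, 0.01, "ab"),
        ("F2", "W2"): (11.08, 0.16, "ab"),  ("F2", "W3"): (11.21, 0.08, "a"),
        ("F3", "W1"): (10.60, 0.18, "ab"),  ("F3", "W2"): (10.81, 0.08, "ab"),
        ("F3", "W3"): (10.99, 0.18, "ab"),  ("F4", "W1"): (10.43, 0.23, "b"),
        ("F4", "W2"): (10.78, 0.21, "ab"),  ("F4", "W3"): (10.81, 0.32, "ab"),
    },
}
_SC_STARS = {2020: ("**", "**", "*"), 2021: ("**", "**", "*"), 2022: ("*", "**", "*")}
_SY_STARS = {2020: ("**", "**", "*"), 2021: ("*", "**", "ns"), 2022: ("**", "**", "ns")}

# Published quadratic response surfaces R = b0 + b1 F + b2 F^2 + b3 I + b4 F I + b5 I^2
# with F = total nutrient (kg/ha) and I = irrigation (m3/ha); published R^2,
# significance code, maximum value and its (F, I) location.
_SURFACES = [
    ("yield", 2020, (-30.206, 0.414, -6.194e-4, 1.471e-4, 7.633e-5, -9.298e-6),
     0.872, "*", 61.752, 420.30, 1433.61),
    ("yield", 2021, (-248.365, 1.195, -1.44e-3, 0.114, -1.44e-5, -3.748e-5),
     0.857, "*", 76.537, 405.43, 1446.28),
    ("yield", 2022, (-1.035, 0.273, -3.244e-4, 0.023, -2.428e-5, -2.63e-6),
     0.924, "**", 71.711, 312.20, 1646.73),
    ("sugar_yield", 2020, (1.695, 0.032, -4.857e-5, 1.510e-3, 5.894e-6, -1.468e-6),
     0.800, "*", 9.208, 406.26, 1298.06),
    ("sugar_yield", 2021, (-8.781, 0.091, -1.176e-4, 5.138e-3, 3.816e-6, -2.370e-6),
     0.965, "**", 13.625, 411.14, 1414.63),
    ("sugar_yield", 2022, (1.242, 0.030, -3.931e-5, 6.205e-3, -1.045e-6, -2.101e-6),
     0.904, "**", 11.146, 368.53, 1385.17),
]


def load_dose_table() -> pd.DataFrame:
    """Per-treatment N, P2O5, K2O and irrigation doses, with nutrient totals."""
    rows = []
    for f, (n, p, k) in _DOSES.items():
        for w, irr in _IRRIGATION.items():
            rows.append({"treatment": f + w, "fert_level": f, "irr_level": w,
                         "N_kg_ha": n, "P2O5_kg_ha": p, "K2O_kg_ha": k,
                         "F_total_kg_ha": n + p + k, "irrigation_m3_ha": irr})
    return pd.DataFrame(rows)


def _melt(table: dict, stars: dict, value_name: str) -> pd.DataFrame:
    rows = []
    for year, cells in table.items():
        fstar, wstar, fwstar = stars[year]
        for (f, w), (mean, sd, letters) in cells.items():
            rows.append({"year": year, "fert_level": f, "irr_level": w,
                         "F_total_kg_ha": FERT_LEVELS[f],
                         "irrigation_m3_ha": IRR_LEVELS[w],
                         value_name: mean, "sd": sd, "letters": letters,
                         "sig_F": fstar, "sig_W": wstar, "sig_FxW": fwstar})
    return pd.DataFrame(rows).sort_values(
        ["year", "fert_level", "irr_level"]).reset_index(drop=True)


def load_yield_means() -> pd.DataFrame:
    """Treatment-mean root yield (t/ha) with SD, LSD letters and ANOVA codes."""
    return _melt(_YIELD, _YIELD_STARS, "yield_t_ha")


def load_quality_means() -> pd.DataFrame:
    """Treatment-mean sugar content (%) and sugar yield (t/ha) per year."""
    sc = _melt(_SUGAR_CONTENT, _SC_STARS, "sugar_content_pct")
    sy = _melt(_SUGAR_YIELD, _SY_STARS, "sugar_yield_t_ha")
    keys = ["year", "fert_level", "irr_level", "F_total_kg_ha", "irrigation_m3_ha"]
    sc = sc.rename(columns={"sd": "sc_sd", "letters": "sc_letters",
                            "sig_F": "sc_sig_F", "sig_W": "sc_sig_W",
                            "sig_FxW": "sc_sig_FxW"})
    sy = sy.rename(columns={"sd": "sy_sd", "letters": "sy_letters",
                            "sig_F": "sy_sig_F", "sig_W": "sy_sig_W",
                            "sig_FxW": "sy_sig_FxW"})
    return sc.merge(sy, on=keys, validate="one_to_one")


def load_surface_summary() -> pd.DataFrame:
    """Published quadratic surfaces: coefficients, R2, maxima and locations."""
    rows = []
    for resp, year, b, r2, sig, ymax, fmax, imax in _SURFACES:
        rows.append({"response": resp, "year": year,
                     "b0": b[0], "b1": b[1], "b2": b[2],
                     "b3": b[3], "b4": b[4], "b5": b[5],
                     "r_squared": r2, "sig": sig,
                     "max_value": ymax, "max_F_kg_ha": fmax,
                     "max_I_m3_ha": imax})
    return pd.DataFrame(rows)


def load_reference_trial() -> dict[str, pd.DataFrame]:
    """All published summaries keyed by table name."""
    return {"doses": load_dose_table(), "yield": load_yield_means(),
            "quality": load_quality_means(), "surfaces": load_surface_summary()}
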