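"""Yield-quality and water/fertilizer use-efficiency indices.

Scalar formulas (all vectorized over numpy arrays / pandas Series):

* sugar content  SC = 0.8 x brix (%)
* sugar yield    SY = Y x SC/100 (t/ha)
* WUE  = Y / ET          (kg of root per m3 of water consumed)
* WUEi = Y / I           (kg per m3 of irrigation water)
* FAE  = (Y - Y0) / F    (kg of extra root per kg of nutrient applied,
  with Y0 the unfertilized-check mean at the same irrigation level and year)
* PFP  = Y / F           (kg of root per kg of nutrient)

and the sugar-yield variants SWUE, SWUEi, SFAE, SPFP with SY in place of
Y (and the check's sugar yield in place of Y0).  Yields enter in t/ha and
are converted to kg/ha internally; ET in mm is bridged to m3/ha by the
exact factor 10.

:func:`build_index_table` assembles the whole per-treatment table from a
tidy plot-observation table, the dose table and the seasonal water
records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import ZERO_FERT_LEVEL
from .water import SeasonWater, evapotranspiration, mm_to_m3ha

__all__ = [
    "MissingControlError",
    "sugar_content",
    "sugar_yield",
    "wue",
    "wuei",
    "fae",
    "pfp",
    "relative_change",
    "build_index_table",
    "sugar_variants",
    "summarize_index_table",
]


class MissingControlError(KeyError):
    """No zero-fertilizer control exists for the requested (year, irr_level)."""

    def __init__(self, year, irr_level):
        super().__init__(f"no zero-fertilizer control for year={year!r}, "
                         f"irr_level={irr_level!r}")
        self.year = year
        self.irr_level = irr_level


def _check(cond, msg):
    if not np.all(cond):
        raise ValueError(msg)


def sugar_content(brix):
    """Root sugar content (%) from the refractometer brix reading."""
    brix = np.asarray(brix, dtype=float)
    _check(brix >= 0, "brix must be >= 0")
    _check(brix <= 35, "brix above 35 is outside the instrument range")
    return 0.8 * brix


def sugar_yield(yield_t_ha, sc_pct):
    """Sugar yield (t/ha) = root yield x sugar content."""
    y = np.asarray(yield_t_ha, dtype=float)
    sc = np.asarray(sc_pct, dtype=float)
    _check(y >= 0, "yield must be >= 0")
    _check((sc >= 0) & (sc <= 100), "sugar content must be in [0, 100]%")
    return y * sc / 100.0


def wue(yield_t_ha, et_mm):
    """Water use efficiency (kg/m3): yield per unit water consumed."""
    et = np.asarray(et_mm, dtype=float)
    _check(et > 0, "ET must be > 0")
    return np.asarray(yield_t_ha, dtype=float) * 1000.0 / mm_to_m3ha(et)


def wuei(yield_t_ha, irrigation_m3_ha):
    """Irrigation water use efficiency (kg/m3): yield per unit irrigation."""
    irr = np.asarray(irrigation_m3_ha, dtype=float)
    _check(irr > 0, "irrigation must be > 0")
    return np.asarray(yield_t_ha, dtype=float) * 1000.0 / irr


def fae(yield_t_ha, y0_t_ha, fert_total_kg_ha):
    """Fertilizer agronomic efficiency (kg/kg); negative when Y < Y0."""
    F = np.asarray(fert_total_kg_ha, dtype=float)
    _check(F > 0, "total nutrient dose must be > 0")
    y = np.asarray(yield_t_ha, dtype=float)
    y0 = np.asarray(y0_t_ha, dtype=float)
    return (y - y0) * 1000.0 / F


def pfp(yield_t_ha, fert_total_kg_ha):
    """Partial factor productivity of fertilizer (kg/kg)."""
    F = np.asarray(fert_total_kg_ha, dtype=float)
    _check(F > 0, "total nutrient dose must be > 0")
    return np.asarray(yield_t_ha, dtype=float) * 1000.0 / F


def relative_change(value, reference):
    """Signed percent change of ``value`` relative to ``reference``."""
    ref = np.asarray(reference, dtype=float)
    _check(ref != 0, "reference must be nonzero")
    return 100.0 * (np.asarray(value, dtype=float) - ref) / ref


def _control_means(obs: pd.DataFrame, value_col: str) -> dict:
    ctrl = obs[obs["fert_level"] == ZERO_FERT_LEVEL]
    return ctrl.groupby(["year", "irr_level"])[value_col].mean().to_dict()


def build_index_table(observations: pd.DataFrame,
                      water: dict | list[SeasonWater],
                      fert_totals: dict[str, float],
                      irr_doses: dict[str, float]) -> pd.DataFrame:
    """Replicate-level index table from plot observations.

    Parameters
    ----------
    observations
        Tidy table with columns ``year, rep, fert_level, irr_level,
        yield_t_ha, brix_pct``; zero-fertilizer plots carry the level id
        ``"F0"`` and feed FAE/SFAE only.
    water
        Seasonal water records.  Either a list of :class:`SeasonWater`
        keyed internally by ``(year, irr_level)`` via an ``irr_level``
        attribute set on each record, or a mapping
        ``(year, irr_level) -> SeasonWater``.  All fertilization levels
        under one irrigation level share the same ET.
    fert_totals, irr_doses
        Level id -> total nutrient dose (kg/ha) and irrigation dose (m3/ha).

    Returns a replicate-level DataFrame with the full index set; aggregate
    with :func:`summarize_index_table`.
    """
    if isinstance(water, dict):
        wmap = water
    else:
        wmap = {(w.year, getattr(w, "irr_level")): w for w in water}

    obs = observations.copy()
    fert = obs[obs["fert_level"] != ZERO_FERT_LEVEL].copy()

    y0_yield = _control_means(obs, "yield_t_ha")
    sc_all = sugar_content(obs["brix_pct"])
    obs["_sy"] = sugar_yield(obs["yield_t_ha"], sc_all)
    y0_sugar = _control_means(obs, "_sy")

    fert["F_total_kg_ha"] = fert["fert_level"].map(fert_totals)
    fert["irrigation_m3_ha"] = fert["irr_level"].map(irr_doses)
    if fert["F_total_kg_ha"].isna().any():
        bad = sorted(set(fert.loc[fert["F_total_kg_ha"].isna(), "fert_level"]))
        raise KeyError(f"no dose entry for fertilization level(s) {bad}")
    if fert["irrigation_m3_ha"].isna().any():
        bad = sorted(set(fert.loc[fert["irrigation_m3_ha"].isna(), "irr_level"]))
        raise KeyError(f"no dose entry for irrigation level(s) {bad}")

    et, twi = [], []
    for _, r in fert.iterrows():
        key = (r["year"], r["irr_level"])
        if key not in wmap:
            raise KeyError(f"no seasonal water record for (year, irr_level)={key}")
        w = wmap[key]
        et.append(evapotranspiration(w))
        twi.append(mm_to_m3ha(w.irrigation_mm + w.precip_mm))
    fert["ET_mm"] = et
    fert["TWI_m3_ha"] = twi

    fert["sugar_content_pct"] = sugar_content(fert["brix_pct"])
    fert["sugar_yield_t_ha"] = sugar_yield(fert["yield_t_ha"],
                                           fert["sugar_content_pct"])

    def lookup_control(table):
        out = []
        for _, r in fert.iterrows():
            key = (r["year"], r["irr_level"])
            if key not in table:
                raise MissingControlError(*key)
            out.append(table[key])
        return np.array(out)

    if len(y0_yield) == 0 and len(fert):
        # no controls at all: FAE columns stay NaN rather than failing the
        # whole table; fae() itself raises when called explicitly
        fert["Y0_t_ha"] = np.nan
        fert["FAE_kg_kg"] = np.nan
        fert["SFAE_kg_kg"] = np.nan
    else:
        y0 = lookup_control(y0_yield)
        fert["Y0_t_ha"] = y0
        fert["FAE_kg_kg"] = fae(fert["yield_t_ha"], y0, fert["F_total_kg_ha"])
        sy0 = lookup_control(y0_sugar)
        fert["SFAE_kg_kg"] = fae(fert["sugar_yield_t_ha"], sy0,
                                 fert["F_total_kg_ha"])

    fert["WUE_kg_m3"] = wue(fert["yield_t_ha"], fert["ET_mm"])
    fert["WUEi_kg_m3"] = wuei(fert["yield_t_ha"], fert["irrigation_m3_ha"])
    fert["PFP_kg_kg"] = pfp(fert["yield_t_ha"], fert["F_total_kg_ha"])
    fert["SWUE_kg_m3"] = wue(fert["sugar_yield_t_ha"], fert["ET_mm"])
    fert["SWUEi_kg_m3"] = wuei(fert["sugar_yield_t_ha"], fert["irrigation_m3_ha"])
    fert["SPFP_kg_kg"] = pfp(fert["sugar_yield_t_ha"], fert["F_total_kg_ha"])
    return fert.drop(columns=["brix_pct"]).reset_index(drop=True)


def sugar_variants(table: pd.DataFrame) -> pd.DataFrame:
    """Sugar-yield efficiency columns of an index table (view by name)."""
    cols = ["year", "rep", "fert_level", "irr_level", "sugar_yield_t_ha",
            "SWUE_kg_m3", "SWUEi_kg_m3", "SFAE_kg_kg", "SPFP_kg_kg"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"index table missing column(s): {missing}")
    return table.loc[:, cols]


INDEX_COLUMNS = ["yield_t_ha", "sugar_content_pct", "sugar_yield_t_ha",
                 "ET_mm", "TWI_m3_ha", "WUE_kg_m3", "WUEi_kg_m3",
                 "FAE_kg_kg", "PFP_kg_kg", "SWUE_kg_m3", "SWUEi_kg_m3",
                 "SFAE_kg_kg", "SPFP_kg_kg"]


def summarize_index_table(table: pd.DataFrame) -> pd.DataFrame:
    """Treatment means and SDs over replicates, one row per
    (year, fert_level, irr_level)."""
    keys = ["year", "fert_level", "irr_level"]
    cols = [c for c in INDEX_COLUMNS if c in table.columns]
    g = table.groupby(keys, sort=True)[cols]
    mean = g.mean()
    sd = g.std(ddof=1)
    out = mean.join(sd, lsuffix="", rsuffix="_sd").reset_index()
    carry = [c for c in ("F_total_kg_ha", "irrigation_m3_ha") if c in table.columns]
    if carry:
        first = table.groupby(keys, sort=True)[carry].first().reset_index()
        out = out.merge(first, on=keys)
    return out
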