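"""End-to-end analysis pipeline: trial table -> indices -> statistics ->
response surfaces -> optimal dose window.

The stages mirror how a fertigation trial is analysed in practice:

1. load (or simulate) the plot-observation table and the seasonal water
   records;
2. compute the index table (sugar content/yield, ET, WUE, WUEi, FAE, PFP
   and sugar variants) at replicate level, then treatment means +/- SD;
3. per year: split-plot ANOVA per response and an LSD compact letter
   display across the fertilized treatments, plus a Pearson screen of the
   indices;
4. per year: quadratic surfaces of yield and sugar yield over (F, I) with
   stationary points;
5. pooled over years on the total-water-input axis: surfaces for yield,
   sugar content and FAE, their CK-relative admissible region, the
   bounding window and its conversion to irrigation doses.

Every output table is plain CSV with a header comment carrying the seed
and a hash of the configuration, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indices as idx
from . import optimize, stats, surface, synthetic
from .water import SeasonWater

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline",
           "read_water_table", "write_water_table"]

WATER_COLUMNS = ["year", "irr_level", "irrigation_mm", "precip_mm",
                 "delta_storage_mm"]

#: Default growth-period precipitation (mm) used when simulating water
#: records: the reference trial's three-year mean.
DEFAULT_PRECIP_MM = 309.46


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run depends on (pure function of this + files)."""

    out_dir: str = "fertigation_out"
    trial_path: str | None = None      # None -> simulate
    water_path: str | None = None      # None -> constant-precip records
    emulate_reference: bool = True
    n_reps: int = 3
    n_years: int = 3
    seed: int = 0
    alpha: float = 0.05
    fit_unit: str = "treatment-means"  # or "replicates"
    criteria: tuple[str, ...] = ("yield", "sugar_content", "FAE")
    F_range: tuple[float, float] = (300.0, 500.0)
    F_step: float = 0.5
    TWI_range: tuple[float, float] = (3500.0, 5000.0)
    TWI_step: float = 1.0
    precip_mm: float = DEFAULT_PRECIP_MM

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("criteria",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        for key in ("F_range", "TWI_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so re-runs into different directories compare equal)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def grid(self) -> optimize.GridSpec:
        return optimize.GridSpec(self.F_range, self.F_step,
                                 self.TWI_range, self.TWI_step)


@dataclass
class RunReport:
    """In-memory results of a pipeline run, mirroring the written files."""

    config: RunConfig
    observations: pd.DataFrame
    index_table: pd.DataFrame
    index_summary: pd.DataFrame
    anova: pd.DataFrame
    letters: pd.DataFrame
    correlations: pd.DataFrame
    surfaces: pd.DataFrame
    window: dict
    warnings: list[str] = field(default_factory=list)
    paths: dict[str, Path] = field(default_factory=dict)


def write_water_table(path, records: list[SeasonWater],
                      irr_levels: list[str]) -> None:
    rows = [{"year": w.year, "irr_level": lvl, "irrigation_mm": w.irrigation_mm,
             "precip_mm": w.precip_mm, "delta_storage_mm": w.delta_storage_mm}
            for w, lvl in zip(records, irr_levels)]
    pd.DataFrame(rows, columns=WATER_COLUMNS).to_csv(path, index=False)


def read_water_table(path) -> dict[tuple, SeasonWater]:
    """Read seasonal water records keyed by (year, irr_level)."""
    df = pd.read_csv(path)
    missing = [c for c in WATER_COLUMNS if c not in df.columns]
    if missing:
        raise synthetic.SchemaError(
            f"water table missing column(s): {', '.join(missing)}")
    out = {}
    for _, r in df.iterrows():
        out[(r["year"], r["irr_level"])] = SeasonWater(
            year=str(r["year"]), irrigation_mm=float(r["irrigation_mm"]),
            precip_mm=float(r["precip_mm"]),
            delta_storage_mm=float(r["delta_storage_mm"]))
    return out


def _default_water(years, design: synthetic.DesignSpec,
                   precip_mm: float) -> dict[tuple, SeasonWater]:
    out = {}
    for year in years:
        for lvl, dose in design.irr_levels.items():
            out[(year, lvl)] = SeasonWater(year=str(year),
                                           irrigation_mm=dose / 10.0,
                                           precip_mm=precip_mm)
    return out


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


_CRITERION_COLUMN = {"yield": "yield_t_ha", "sugar_content": "sugar_content_pct",
                     "sugar_yield": "sugar_yield_t_ha", "FAE": "FAE_kg_kg",
                     "WUE": "WUE_kg_m3"}


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis; see the module docstring for the stages."""
    cfg = config
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # ---- stage: inputs -------------------------------------------------
    try:
        design = synthetic.make_design(emulate_reference=cfg.emulate_reference,
                                       n_reps=cfg.n_reps, seed=cfg.seed)
        if cfg.trial_path is not None:
            if not Path(cfg.trial_path).exists():
                raise FileNotFoundError(f"trial table not found: {cfg.trial_path}")
            obs = synthetic.read_trial(cfg.trial_path)
        else:
            truth = synthetic.SyntheticTruth(seed=cfg.seed)
            obs = synthetic.simulate_trial(design, truth, n_years=cfg.n_years)
        years = sorted(obs["year"].unique())
        if cfg.water_path is not None:
            if not Path(cfg.water_path).exists():
                raise FileNotFoundError(f"water table not found: {cfg.water_path}")
            water = read_water_table(cfg.water_path)
        else:
            water = _default_water(years, design, cfg.precip_mm)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("inputs", str(e)) from e

    fert_totals = {lvl: design.fert_total(lvl) for lvl in design.fert_levels}

    # ---- stage: indices ------------------------------------------------
    try:
        table = idx.build_index_table(obs, water, fert_totals,
                                      dict(design.irr_levels))
        summary = idx.summarize_index_table(table)
    except Exception as e:
        raise PipelineError("indices", str(e)) from e

    # ---- stage: statistics --------------------------------------------
    anova_rows, letter_rows, corr_frames = [], [], []
    responses = ["yield_t_ha", "sugar_content_pct", "sugar_yield_t_ha"]
    try:
        for year in years:
            sub = table[table["year"] == year]
            for resp in responses:
                at = stats.splitplot_anova(sub, resp)
                t = at.table.copy()
                t.insert(0, "response", resp)
                t.insert(0, "year", year)
                anova_rows.append(t)
                means = sub.groupby(["fert_level", "irr_level"])[resp].agg(
                    ["mean", "std"])
                n_rep = int(sub.groupby(["fert_level", "irr_level"]).size().iloc[0])
                disp = stats.lsd_letters(
                    means["mean"], at.ms_error_b, at.df_error_b,
                    n_per_mean=n_rep, alpha=cfg.alpha, sds=means["std"])
                for (f, w), m in disp.means.items():
                    letter_rows.append({
                        "year": year, "response": resp, "fert_level": f,
                        "irr_level": w, "mean": m,
                        "sd": float(means.loc[(f, w), "std"]),
                        "letters": disp.letters[(f, w)], "lsd": disp.lsd})
            variables = [c for c in idx.INDEX_COLUMNS
                         if c in sub.columns and sub[c].notna().all()
                         and c not in ("ET_mm", "TWI_m3_ha")]
            cm = stats.pearson_matrix(
                sub.groupby(["fert_level", "irr_level"])[variables].mean(),
                variables)
            cm.insert(0, "year", year)
            corr_frames.append(cm)
        anova = pd.concat(anova_rows, ignore_index=True)
        letters = pd.DataFrame(letter_rows)
        correlations = pd.concat(corr_frames, ignore_index=True)
    except Exception as e:
        raise PipelineError("statistics", str(e)) from e

    # ---- stage: per-year response surfaces over (F, I) -----------------
    surf_rows = []
    try:
        for year in years:
            sub = summary[summary["year"] == year]
            src = table[table["year"] == year] if cfg.fit_unit == "replicates" else sub
            for resp in ("yield_t_ha", "sugar_yield_t_ha"):
                m = surface.fit_bqrm(src["F_total_kg_ha"],
                                     src["irrigation_m3_ha"], src[resp],
                                     name=resp, fit_unit=cfg.fit_unit)
                Fs, Is, val, cls = surface.stationary_point(m)
                fmax, imax, vmax = surface.constrained_max(
                    m, (min(fert_totals.values()), max(fert_totals.values())),
                    (min(design.irr_levels.values()), max(design.irr_levels.values())))
                b = m.coeffs
                surf_rows.append({
                    "year": year, "response": resp, "covariates": "F,I",
                    "b0": b[0], "b1": b[1], "b2": b[2], "b3": b[3],
                    "b4": b[4], "b5": b[5], "r_squared": m.r_squared,
                    "p_value": m.p_value, "n_points": m.n_points,
                    "stat_F": Fs, "stat_I": Is, "stat_value": val,
                    "classification": cls, "box_F": fmax, "box_I": imax,
                    "box_value": vmax})
    except Exception as e:
        raise PipelineError("surfaces", str(e)) from e

    # ---- stage: pooled TWI surfaces and the dose window -----------------
    try:
        pooled = summary.copy()
        models = {}
        for crit in cfg.criteria:
            col = _CRITERION_COLUMN.get(crit)
            if col is None or col not in pooled.columns:
                raise KeyError(f"unknown or unavailable criterion {crit!r}")
            src = pooled.dropna(subset=[col])
            m = surface.fit_bqrm(src["F_total_kg_ha"], src["TWI_m3_ha"],
                                 src[col], name=crit, fit_unit="pooled-means")
            models[crit] = m
            b = m.coeffs
            surf_rows.append({
                "year": "pooled", "response": crit, "covariates": "F,TWI",
                "b0": b[0], "b1": b[1], "b2": b[2], "b3": b[3], "b4": b[4],
                "b5": b[5], "r_squared": m.r_squared, "p_value": m.p_value,
                "n_points": m.n_points, "stat_F": np.nan, "stat_I": np.nan,
                "stat_value": np.nan, "classification": "",
                "box_F": np.nan, "box_I": np.nan, "box_value": np.nan})
        F_ck = fert_totals[design.control_fert_level]
        ck_rows = pooled[(pooled["fert_level"] == design.control_fert_level)
                         & (pooled["irr_level"] == design.control_irr_level)]
        TWI_ck = float(ck_rows["TWI_m3_ha"].mean())
        region = optimize.admissible_region(models, (F_ck, TWI_ck), cfg.grid())
        if region.empty:
            warnings.append(
                "empty admissible region: last criterion eliminating cells "
                f"was {region.diagnostics.get('eliminated_last_by')!r}")
            window_report = {"empty": True, **region.diagnostics}
        else:
            bounds = optimize.boundary_intersections(region)
            for bname, b in bounds.items():
                if b.box_limited:
                    warnings.append(f"window bound {bname} is grid-box limited")
            twi_lo, twi_hi = bounds["TWI_min"].value, bounds["TWI_max"].value
            window_report = {
                "empty": False, "F_ck": F_ck, "TWI_ck": TWI_ck,
                "F_min": bounds["F_min"].value, "F_max": bounds["F_max"].value,
                "TWI_min": twi_lo, "TWI_max": twi_hi,
                "irrigation_min_m3_ha": optimize.irrigation_from_twi(
                    twi_lo, cfg.precip_mm),
                "irrigation_max_m3_ha": optimize.irrigation_from_twi(
                    twi_hi, cfg.precip_mm),
                "bounds": {k: {"value": v.value, "criteria": list(v.criteria),
                               "box_limited": v.box_limited,
                               "intersection_point": v.intersection_point}
                           for k, v in bounds.items()},
            }
        surfaces_df = pd.DataFrame(surf_rows)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("window", str(e)) from e

    # ---- stage: reports -------------------------------------------------
    try:
        paths = {}
        for name, df in [("indices", table), ("index_summary", summary),
                         ("anova", anova), ("letters", letters),
                         ("correlations", correlations),
                         ("surfaces", surfaces_df)]:
            p = out_dir / f"{name}.csv"
            _write_csv(df, p, cfg)
            paths[name] = p
        wpath = out_dir / "window.json"
        with open(wpath, "w") as fh:
            json.dump({"config_hash": cfg.config_hash(), "seed": cfg.seed,
                       "window": window_report, "warnings": warnings},
                      fh, indent=2, default=float)
        paths["window"] = wpath
    except Exception as e:
        raise PipelineError("reports", str(e)) from e

    for w in warnings:
        logger.warning("%s", w)
    return RunReport(config=cfg, observations=obs, index_table=table,
                     index_summary=summary, anova=anova, letters=letters,
                     correlations=correlations, surfaces=surfaces_df,
                     window=window_report, warnings=warnings, paths=paths)
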