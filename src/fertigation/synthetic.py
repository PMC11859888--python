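"""Synthetic split-plot fertigation trials with known ground truth.

The generator emulates the reference trial's layout: fertilization levels
are randomized to large main plots, irrigation levels to subplots within
them, and unfertilized checks are carried at every irrigation level.  Each
response (root yield, brix) follows a full quadratic surface in the total
nutrient dose F (kg/ha) and the irrigation dose I (m3/ha),

    R(F, I) = b0 + b1 F + b2 F^2 + b3 I + b4 F I + b5 I^2,

plus a two-level error: one normal draw shared by all subplots of a
(year, replicate, main plot) — the main-plot stratum — and an independent
normal draw per plot — the subplot stratum.  Because the truth is known,
every downstream stage (indices, split-plot ANOVA, surface fitting, the
optimization window) can be tested for recovery without any field data.

Random streams are derived from one root seed per (year, rep, fert, irr)
cell, so adding years or replicates never changes the values already
generated for earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trial_data import CK_FERT, CK_IRR, _DOSES, _IRRIGATION

__all__ = [
    "DesignSpec",
    "SyntheticTruth",
    "InvalidDesignError",
    "SchemaError",
    "NegativeYieldError",
    "TRIAL_COLUMNS",
    "surface_from_vertex",
    "make_design",
    "simulate_trial",
    "write_trial",
    "read_trial",
]

ZERO_FERT_LEVEL = "F0"

#: Column schema of the plot-observation table (delimited text I/O).
TRIAL_COLUMNS = ["year", "rep", "fert_level", "irr_level", "yield_t_ha", "brix_pct"]


class InvalidDesignError(ValueError):
    """The requested design cannot support the split-plot analysis."""


class SchemaError(ValueError):
    """A trial table is missing a required column."""


class NegativeYieldError(RuntimeError):
    """The truth surface predicts persistently negative yields."""


@dataclass(frozen=True)
class DesignSpec:
    """Treatment structure of a split-plot fertigation trial.

    ``fert_levels`` maps level id to (N, P2O5, K2O) doses in kg/ha;
    ``irr_levels`` maps level id to the irrigation dose in m3/ha.
    """

    fert_levels: dict[str, tuple[float, float, float]]
    irr_levels: dict[str, float]
    n_reps: int
    control_fert_level: str
    control_irr_level: str
    include_zero_fert_controls: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise InvalidDesignError(
                f"n_reps={self.n_reps}: at least 2 replicates are needed to "
                "estimate the error strata")
        for lvl, doses in self.fert_levels.items():
            if any(d < 0 for d in doses):
                raise InvalidDesignError(f"negative dose in fert level {lvl!r}")
        for lvl, dose in self.irr_levels.items():
            if dose < 0:
                raise InvalidDesignError(f"negative irrigation in level {lvl!r}")
        if self.control_fert_level not in self.fert_levels:
            raise InvalidDesignError(
                f"control fert level {self.control_fert_level!r} not in design")
        if self.control_irr_level not in self.irr_levels:
            raise InvalidDesignError(
                f"control irrigation level {self.control_irr_level!r} not in design")

    def fert_total(self, level: str) -> float:
        """Total nutrient dose N + P2O5 + K2O (kg/ha) for a level."""
        if level == ZERO_FERT_LEVEL:
            return 0.0
        return float(sum(self.fert_levels[level]))

    @property
    def n_plots_per_year(self) -> int:
        n = len(self.fert_levels) * len(self.irr_levels) * self.n_reps
        if self.include_zero_fert_controls:
            n += len(self.irr_levels) * self.n_reps
        return n


def surface_from_vertex(peak_value: float, f_peak: float, i_peak: float,
                        b2: float, b4: float, b5: float) -> tuple[float, ...]:
    """Coefficients of R = peak + b2 (F-f0)^2 + b4 (F-f0)(I-i0) + b5 (I-i0)^2.

    Convenient for writing concave truths whose maximum location is known
    exactly; the returned tuple is in the (b0..b5) convention.
    """
    b0 = (peak_value + b2 * f_peak**2 + b4 * f_peak * i_peak + b5 * i_peak**2)
    b1 = -2.0 * b2 * f_peak - b4 * i_peak
    b3 = -2.0 * b5 * i_peak - b4 * f_peak
    return (b0, b1, b2, b3, b4, b5)


# Default yield truth: concave, peaking at 62 t/ha near the conventional
# dose, with unfertilized checks around 48 t/ha at full irrigation —
# the magnitudes of the reference trial.
DEFAULT_YIELD_SURFACE = surface_from_vertex(62.0, 420.0, 1430.0,
                                            -7.5e-5, 1.0e-5, -1.7e-5)
# Default brix truth: decreasing in both doses across the design range
# (quality rises when inputs are cut), with a mild convexity.
DEFAULT_BRIX_SURFACE = (27.5, -8.0e-3, 3.0e-6, -3.0e-3, 0.0, 1.0e-6)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth surfaces and error SDs for a simulated trial.

    ``sigma_mainplot``/``sigma_subplot`` are the yield error SDs (t/ha) of
    the two strata; brix gets its own, smaller, pair (percentage points).
    """

    yield_surface: tuple[float, ...] = DEFAULT_YIELD_SURFACE
    brix_surface: tuple[float, ...] = DEFAULT_BRIX_SURFACE
    sigma_mainplot: float = 0.8
    sigma_subplot: float = 1.5
    sigma_mainplot_brix: float = 0.15
    sigma_subplot_brix: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_mainplot", "sigma_subplot",
                     "sigma_mainplot_brix", "sigma_subplot_brix"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.yield_surface) != 6 or len(self.brix_surface) != 6:
            raise ValueError("surfaces need exactly 6 coefficients (b0..b5)")

    def with_seed(self, seed: int) -> "SyntheticTruth":
        return replace(self, seed=seed)


def evaluate_surface(coeffs, F, I):
    """Evaluate b0 + b1 F + b2 F^2 + b3 I + b4 F I + b5 I^2 (vectorized)."""
    b0, b1, b2, b3, b4, b5 = coeffs
    F = np.asarray(F, dtype=float)
    I = np.asarray(I, dtype=float)
    return b0 + b1 * F + b2 * F**2 + b3 * I + b4 * F * I + b5 * I**2


def make_design(emulate_reference: bool = True, n_reps: int = 3,
                seed: int = 0, include_zero_fert_controls: bool = True,
                n_fert_levels: int = 4, n_irr_levels: int = 3) -> DesignSpec:
    """Build a split-plot design, either the reference grid or a random one.

    With ``emulate_reference`` the four fertilization levels total
    {336, 378, 420, 462} kg/ha and irrigation is {945, 1147.5, 1350} m3/ha,
    with F3W3 as the control.  Otherwise dose grids are drawn at random
    (seeded) but kept strictly increasing in total nutrient.
    """
    if n_reps < 2:
        raise InvalidDesignError(
            f"n_reps={n_reps}: at least 2 replicates are needed")
    if emulate_reference:
        return DesignSpec(fert_levels={k: tuple(v) for k, v in _DOSES.items()},
                          irr_levels=dict(_IRRIGATION), n_reps=n_reps,
                          control_fert_level=CK_FERT, control_irr_level=CK_IRR,
                          include_zero_fert_controls=include_zero_fert_controls)
    rng = np.random.default_rng(seed)
    base = rng.uniform(250.0, 400.0)
    steps = np.sort(rng.uniform(20.0, 60.0, size=n_fert_levels - 1))
    totals = base + np.concatenate([[0.0], np.cumsum(steps)])
    fert = {}
    for i, tot in enumerate(totals, start=1):
        # keep the reference trial's rough N:P:K proportions
        fert[f"F{i}"] = (round(tot * 0.29, 1), round(tot * 0.355, 1),
                         round(tot * 0.355, 1))
    irr_lo = rng.uniform(700.0, 1000.0)
    irr = np.linspace(irr_lo, irr_lo * rng.uniform(1.3, 1.6), n_irr_levels)
    irr_levels = {f"W{j}": round(v, 1) for j, v in enumerate(irr, start=1)}
    return DesignSpec(fert_levels=fert, irr_levels=irr_levels, n_reps=n_reps,
                      control_fert_level=f"F{n_fert_levels}",
                      control_irr_level=f"W{n_irr_levels}",
                      include_zero_fert_controls=include_zero_fert_controls)


def _cell_rng(seed: int, year_idx: int, rep: int, fert_idx: int,
              irr_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, year_idx, rep, fert_idx, irr_idx]))


_MAX_RESAMPLE = 100


def simulate_trial(design: DesignSpec, truth: SyntheticTruth,
                   n_years: int = 1, start_year: int = 2020,
                   negative_yield: str = "resample") -> pd.DataFrame:
    """Simulate plot observations for ``n_years`` seasons.

    Each plot's expected yield/brix is its truth surface at the plot's
    (F_total, I); the main-plot error draw is shared by all subplots of a
    (year, rep, fert) group.  ``negative_yield`` is ``"resample"`` (redraw
    the subplot error, up to a cap), ``"clamp"`` (truncate at 0) or
    ``"fail"``.

    Returns a tidy DataFrame with columns ``year, rep, fert_level,
    irr_level, yield_t_ha, brix_pct``.
    """
    if negative_yield not in ("resample", "clamp", "fail"):
        raise ValueError(f"unknown negative_yield policy {negative_yield!r}")
    fert_ids = list(design.fert_levels)
    if design.include_zero_fert_controls:
        fert_ids = fert_ids + [ZERO_FERT_LEVEL]
    irr_ids = list(design.irr_levels)
    rows = []
    for year_idx in range(n_years):
        year = start_year + year_idx
        for rep in range(1, design.n_reps + 1):
            for fert_idx, fert in enumerate(fert_ids):
                F = design.fert_total(fert)
                # main-plot draw: stream index 0 in the irrigation axis
                main_rng = _cell_rng(truth.seed, year_idx, rep, fert_idx, 0)
                e_main = main_rng.normal(0.0, truth.sigma_mainplot)
                e_main_brix = main_rng.normal(0.0, truth.sigma_mainplot_brix)
                for irr_idx, irr in enumerate(irr_ids, start=1):
                    I = design.irr_levels[irr]
                    mu_y = float(evaluate_surface(truth.yield_surface, F, I))
                    mu_b = float(evaluate_surface(truth.brix_surface, F, I))
                    rng = _cell_rng(truth.seed, year_idx, rep, fert_idx, irr_idx)
                    y = mu_y + e_main + rng.normal(0.0, truth.sigma_subplot)
                    if y < 0:
                        if negative_yield == "fail":
                            raise NegativeYieldError(
                                f"negative yield {y:.2f} t/ha at (F={F}, I={I})")
                        if negative_yield == "clamp":
                            y = 0.0
                        else:
                            for _ in range(_MAX_RESAMPLE):
                                y = mu_y + e_main + rng.normal(0.0, truth.sigma_subplot)
                                if y >= 0:
                                    break
                            else:
                                raise NegativeYieldError(
                                    f"could not draw a non-negative yield at "
                                    f"(F={F}, I={I}): surface mean {mu_y:.2f} t/ha")
                    b = mu_b + e_main_brix + rng.normal(0.0, truth.sigma_subplot_brix)
                    b = float(np.clip(b, 0.0, 35.0))
                    rows.append({"year": year, "rep": rep, "fert_level": fert,
                                 "irr_level": irr, "yield_t_ha": y,
                                 "brix_pct": b})
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trial(path, observations: pd.DataFrame) -> None:
    """Write a plot-observation table as CSV (UTF-8, '.' decimal)."""
    missing = [c for c in TRIAL_COLUMNS if c not in observations.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
    observations.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial(path) -> pd.DataFrame:
    """Read a plot-observation table written by :func:`write_trial`."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
    df["rep"] = df["rep"].astype(int)
    return df.loc[:, TRIAL_COLUMNS]
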