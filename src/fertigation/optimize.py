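"""Multi-criterion dose window: CK-relative admissible regions.

Given fitted quadratic surfaces for several indices over (F, TWI) — total
nutrient dose and total water input — a dose pair is *admissible* for a
criterion when its predicted value is at least the prediction at the
control (CK) dose.  Intersecting the admissible sets of all criteria
(by default: root yield, sugar content and fertilizer agronomic
efficiency) yields the region where none of them falls below conventional
practice; its bounding box is the recommended water/fertilizer window.

The region is evaluated on a dose grid.  Each extreme of the window
(lowest/highest TWI, lowest/highest F) is then attributed to the
criterion iso-curves (prediction = CK reference) that bind there; when
two curves cross at an extreme, the crossing is refined off-grid by
bisection along each curve.  Extremes that sit on the grid boundary are
flagged box-limited instead.

Total water input converts to an irrigation dose by subtracting the mean
growth-period precipitation: I (m3/ha) = TWI - 10 x Pr (mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from .surface import SurfaceModel, predict

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "AdmissibleRegion",
    "WindowBound",
    "admissible_region",
    "boundary_intersections",
    "irrigation_from_twi",
]


@dataclass(frozen=True)
class GridSpec:
    """Dose grid for region evaluation (natural units: kg/ha, m3/ha)."""

    F_range: tuple[float, float] = (300.0, 500.0)
    F_step: float = 0.5
    TWI_range: tuple[float, float] = (3500.0, 5000.0)
    TWI_step: float = 1.0

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        f = np.arange(self.F_range[0], self.F_range[1] + self.F_step / 2,
                      self.F_step)
        t = np.arange(self.TWI_range[0], self.TWI_range[1] + self.TWI_step / 2,
                      self.TWI_step)
        return f, t


@dataclass
class WindowBound:
    """One edge of the dose window with its provenance."""

    value: float                      # refined coordinate of the bound
    grid_value: float                 # coordinate read off the grid mask
    criteria: tuple[str, ...]         # criteria binding at this extreme
    box_limited: bool = False
    intersection_point: tuple[float, float] | None = None  # (F, TWI)


@dataclass
class AdmissibleRegion:
    """Gridded CK-relative feasibility masks and their intersection."""

    F_axis: np.ndarray
    TWI_axis: np.ndarray
    masks: dict[str, np.ndarray]              # (nF, nTWI) boolean per criterion
    intersection: np.ndarray
    references: dict[str, float]              # CK prediction per criterion
    ck: tuple[float, float]                   # (F_ck, TWI_ck)
    models: dict[str, SurfaceModel]
    diagnostics: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not bool(self.intersection.any())

    def window(self) -> dict[str, float] | None:
        """Bounding box of the intersection mask, or None when empty."""
        if self.empty:
            return None
        fi, ti = np.nonzero(self.intersection)
        return {"F_min": float(self.F_axis[fi.min()]),
                "F_max": float(self.F_axis[fi.max()]),
                "TWI_min": float(self.TWI_axis[ti.min()]),
                "TWI_max": float(self.TWI_axis[ti.max()])}


def admissible_region(models: dict[str, SurfaceModel],
                      ck: tuple[float, float],
                      grid: GridSpec = GridSpec()) -> AdmissibleRegion:
    """Build per-criterion masks (prediction >= CK prediction) and intersect.

    ``models`` maps criterion name to a surface over (F, TWI); ``ck`` is
    the control dose pair.  The CK cell is admissible for every criterion
    by construction (weak inequality).  An empty intersection is returned
    with diagnostics naming the criterion that eliminated the last cells,
    never raised.
    """
    F_ck, TWI_ck = ck
    f_ax, t_ax = grid.axes()
    if not (f_ax[0] <= F_ck <= f_ax[-1] and t_ax[0] <= TWI_ck <= t_ax[-1]):
        raise ValueError(f"CK dose {ck} lies outside the grid {grid}")
    FF, TT = np.meshgrid(f_ax, t_ax, indexing="ij")
    masks, refs = {}, {}
    for name, model in models.items():
        ref = float(predict(model, F_ck, TWI_ck))
        refs[name] = ref
        masks[name] = np.asarray(predict(model, FF, TT)) >= ref
    inter = np.ones(FF.shape, dtype=bool)
    diagnostics: dict = {}
    for name in models:
        before = int(inter.sum())
        inter &= masks[name]
        after = int(inter.sum())
        if after == 0 and before > 0:
            diagnostics["eliminated_last_by"] = name
            diagnostics["cells_before_elimination"] = before
    return AdmissibleRegion(F_axis=f_ax, TWI_axis=t_ax, masks=masks,
                            intersection=inter, references=refs, ck=ck,
                            models=models, diagnostics=diagnostics)


def _binding_criteria(region: AdmissibleRegion, cells, neighbor) -> tuple[str, ...]:
    """Criteria whose mask turns False one step outward from the extreme."""
    binding: list[str] = []
    for name, mask in region.masks.items():
        for (fi, ti) in cells:
            nf, nt = neighbor(fi, ti)
            if 0 <= nf < mask.shape[0] and 0 <= nt < mask.shape[1]:
                if not mask[nf, nt]:
                    if name not in binding:
                        binding.append(name)
                    break
    return tuple(binding)


def _iso(model: SurfaceModel, ref: float):
    return lambda F, T: float(predict(model, F, T)) - ref


def _root_along(g, fixed: float, lo: float, hi: float, axis: str,
                tol: float, n_scan: int = 129) -> float | None:
    """Bisection root of a 1-D slice of an iso-curve function."""
    xs = np.linspace(lo, hi, n_scan)
    vals = [g(fixed, x) if axis == "T" else g(x, fixed) for x in xs]
    for a, b, va, vb in zip(xs[:-1], xs[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            return float(a)
        if va * vb < 0:
            fn = (lambda x: g(fixed, x)) if axis == "T" else (lambda x: g(x, fixed))
            return float(brentq(fn, a, b, xtol=tol / 10))
    return None


def _refine_crossing(g1, g2, F0: float, T0: float, F_span: float,
                     T_span: float, tol: float = 0.01) -> tuple[float, float] | None:
    """Crossing of two iso-curves near (F0, T0), by nested bisection.

    Walks criterion 1's curve T1(F) (inner bisection in TWI) and bisects
    the outer function g2(F, T1(F)) in F.  Falls back to a damped Newton
    solve if no outer bracket is found; returns None when neither method
    lands within ``tol`` of both curves.
    """

    def t_on_curve1(F):
        return _root_along(g1, F, T0 - T_span, T0 + T_span, "T", tol)

    fs = np.linspace(F0 - F_span, F0 + F_span, 65)
    prev = None
    for F in fs:
        t = t_on_curve1(F)
        if t is None:
            prev = None
            continue
        val = g2(F, t)
        if prev is not None and prev[1] * val < 0:

            def outer(x):
                tx = t_on_curve1(x)
                if tx is None:
                    raise RuntimeError("lost the inner curve while bisecting")
                return g2(x, tx)

            try:
                Fr = brentq(outer, prev[0], F, xtol=tol / 10)
                Tr = t_on_curve1(Fr)
                if Tr is not None:
                    return float(Fr), float(Tr)
            except RuntimeError:
                break
        if val == 0.0:
            return float(F), float(t)
        prev = (F, val)
    # fallback: simultaneous solve of the two conics
    sol, info, ier, _ = fsolve(lambda p: [g1(*p), g2(*p)], x0=[F0, T0],
                               full_output=True)
    if ier == 1 and abs(g1(*sol)) < tol and abs(g2(*sol)) < tol:
        return float(sol[0]), float(sol[1])
    return None


def boundary_intersections(region: AdmissibleRegion,
                           tol: float = 0.01) -> dict[str, WindowBound]:
    """Attribute each window extreme to its binding iso-curves and refine.

    For each of TWI_min, TWI_max, F_min, F_max: locate the extreme cells
    of the intersection mask, identify the criteria whose masks fail one
    step outward, and — when exactly two criteria cross there — refine
    the crossing off-grid.  Extremes on the grid boundary are flagged
    ``box_limited`` with no intersection point.
    """
    if region.empty:
        raise ValueError("admissible region is empty; no window to bound")
    fi, ti = np.nonzero(region.intersection)
    f_ax, t_ax = region.F_axis, region.TWI_axis
    gfuncs = {name: _iso(region.models[name], region.references[name])
              for name in region.models}
    f_span = 10 * (f_ax[1] - f_ax[0]) if len(f_ax) > 1 else 1.0
    t_span = 10 * (t_ax[1] - t_ax[0]) if len(t_ax) > 1 else 1.0
    span = {"F": max(f_span, 5.0), "T": max(t_span, 25.0)}

    out: dict[str, WindowBound] = {}
    specs = [
        ("TWI_min", ti, t_ax, lambda fi_, ti_: (fi_, ti_ - 1), ti == ti.min()),
        ("TWI_max", ti, t_ax, lambda fi_, ti_: (fi_, ti_ + 1), ti == ti.max()),
        ("F_min", fi, f_ax, lambda fi_, ti_: (fi_ - 1, ti_), fi == fi.min()),
        ("F_max", fi, f_ax, lambda fi_, ti_: (fi_ + 1, ti_), fi == fi.max()),
    ]
    for name, idx, axis, neighbor, attain in specs:
        ext_idx = idx[attain][0]
        grid_value = float(axis[ext_idx])
        cells = list(zip(fi[attain], ti[attain]))
        on_edge = ext_idx in (0, len(axis) - 1)
        if on_edge:
            out[name] = WindowBound(value=grid_value, grid_value=grid_value,
                                    criteria=(), box_limited=True)
            continue
        binding = _binding_criteria(region, cells, neighbor)
        point = None
        value = grid_value
        if len(binding) == 2:
            # use the middle attaining cell as the refinement seed
            mid = cells[len(cells) // 2]
            F0, T0 = float(f_ax[mid[0]]), float(t_ax[mid[1]])
            point = _refine_crossing(gfuncs[binding[0]], gfuncs[binding[1]],
                                     F0, T0, span["F"], span["T"], tol)
            if point is not None:
                value = point[1] if name.startswith("TWI") else point[0]
        out[name] = WindowBound(value=value, grid_value=grid_value,
                                criteria=binding, box_limited=False,
                                intersection_point=point)
    return out


def irrigation_from_twi(twi_m3ha: float, mean_precip_mm: float) -> float:
    """Irrigation dose (m3/ha) implied by a total-water-input dose.

    ``I = TWI - 10 x Pr``.  A negative result means the precipitation
    alone exceeds the requested total water input; it is returned as-is
    but logged, since irrigation cannot be negative in practice.
    """
    irr = twi_m3ha - 10.0 * mean_precip_mm
    if irr < 0:
        logger.warning("TWI %.2f m3/ha is below the precipitation "
                       "contribution %.2f m3/ha: implied irrigation %.2f "
                       "is negative", twi_m3ha, 10 * mean_precip_mm, irr)
    return irr
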