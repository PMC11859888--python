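"""Quadratic water-fertilizer response surfaces.

Each response (root yield, sugar yield, an efficiency index, ...) is
modelled as a full second-order polynomial in the total nutrient dose F
(kg/ha) and a water covariate x (irrigation dose or total water input,
m3/ha):

    R(F, x) = b0 + b1 F + b2 F^2 + b3 x + b4 F x + b5 x^2 .

Fitting is ordinary least squares.  The raw columns F^2 and x^2 are
severely ill-conditioned on agronomic dose scales, so the fit runs on
centred/scaled covariates and the coefficients are expanded back to the
natural units; the two parameterizations are algebraically identical, and
R^2 is invariant to the affine change of variables.

The stationary point solves the 2x2 gradient system; the Hessian
[[2 b2, b4], [b4, 2 b5]] classifies it (maximum iff b2 < 0 and
4 b2 b5 - b4^2 > 0).  Because the printed-precision coefficients of a
published equation can place the stationary point several units away from
the full-precision one, a grid+Newton constrained maximum over a stated
dose box is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SurfaceModel",
    "SingularDesignError",
    "UnderdeterminedError",
    "fit_bqrm",
    "predict",
    "stationary_point",
    "constrained_max",
]

TERMS = ("1", "F", "F^2", "I", "F*I", "I^2")


class SingularDesignError(ValueError):
    """The (F, x) support cannot identify all six quadratic terms."""


class UnderdeterminedError(ValueError):
    """Fewer points than the six coefficients plus one residual df."""


def _design_matrix(F, I):
    F = np.asarray(F, dtype=float)
    I = np.asarray(I, dtype=float)
    return np.column_stack([np.ones_like(F), F, F**2, I, F * I, I**2])


@dataclass
class SurfaceModel:
    """A fitted (or published) quadratic response surface."""

    response: str
    coeffs: tuple[float, float, float, float, float, float]
    r_squared: float | None = None
    p_value: float | None = None
    n_points: int | None = None
    fit_unit: str = "treatment-means"

    def __call__(self, F, I):
        return predict(self, F, I)

    @property
    def hessian(self) -> np.ndarray:
        _, _, b2, _, b4, b5 = self.coeffs
        return np.array([[2 * b2, b4], [b4, 2 * b5]])


def predict(model: SurfaceModel, F, I):
    """Evaluate the surface (vectorized over grids)."""
    b = np.asarray(model.coeffs)
    F = np.asarray(F, dtype=float)
    I = np.asarray(I, dtype=float)
    return b[0] + b[1] * F + b[2] * F**2 + b[3] * I + b[4] * F * I + b[5] * I**2


def fit_bqrm(F, I, response, name: str = "response",
             fit_unit: str = "treatment-means") -> SurfaceModel:
    """Least-squares fit of the full quadratic surface.

    Parameters are point arrays (same length): nutrient totals ``F``,
    water doses ``I`` and the measured ``response``.  Needs at least 7
    points spanning >= 3 distinct levels on each axis (otherwise the
    quadratic terms are not identifiable).
    """
    F = np.asarray(F, dtype=float)
    I = np.asarray(I, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    if len(F) != n or len(I) != n:
        raise ValueError("F, I and response must have equal length")
    if n <= 6:
        raise UnderdeterminedError(
            f"{n} points cannot determine 6 coefficients with a residual df")
    if len(np.unique(F)) < 3 or len(np.unique(I)) < 3:
        raise SingularDesignError(
            "need >= 3 distinct levels on each axis to identify the "
            "quadratic terms")

    # centre/scale to tame the conditioning of the squared columns
    mF, sF = F.mean(), F.std() or 1.0
    mI, sI = I.mean(), I.std() or 1.0
    u, v = (F - mF) / sF, (I - mI) / sI
    X = np.column_stack([np.ones(n), u, u**2, v, u * v, v**2])
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        raise SingularDesignError(
            f"design matrix rank {rank} < 6: the point layout does not "
            "separate all quadratic terms")
    c, *_ = np.linalg.lstsq(X, y, rcond=None)

    # expand back to natural units: substitute u=(F-mF)/sF, v=(I-mI)/sI
    c0, c1, c2, c3, c4, c5 = c
    b2 = c2 / sF**2
    b5 = c5 / sI**2
    b4 = c4 / (sF * sI)
    b1 = c1 / sF - 2 * c2 * mF / sF**2 - c4 * mI / (sF * sI)
    b3 = c3 / sI - 2 * c5 * mI / sI**2 - c4 * mF / (sF * sI)
    b0 = (c0 - c1 * mF / sF + c2 * mF**2 / sF**2 - c3 * mI / sI
          + c4 * mF * mI / (sF * sI) + c5 * mI**2 / sI**2)

    yhat = X @ c
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    df_model, df_resid = 5, n - 6
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        p = 0.0
    else:
        f_stat = (ss_tot - ss_res) / df_model / (ss_res / df_resid)
        p = float(sps.f.sf(f_stat, df_model, df_resid))
    return SurfaceModel(response=name,
                        coeffs=(b0, b1, b2, b3, b4, b5),
                        r_squared=r2, p_value=p, n_points=n,
                        fit_unit=fit_unit)


def stationary_point(model: SurfaceModel):
    """Solve the gradient system and classify the stationary point.

    Returns ``(F*, I*, value, classification)`` where classification is
    one of ``"maximum"``, ``"minimum"``, ``"saddle"`` or ``"degenerate"``
    (singular Hessian; location is then NaN, never guessed).
    """
    b0, b1, b2, b3, b4, b5 = model.coeffs
    if b2 == 0 and b4 == 0 and b5 == 0:
        raise ValueError("surface has no quadratic part; no stationary point")
    H = model.hessian
    det = 4 * b2 * b5 - b4**2
    if abs(det) < 1e-300 or np.linalg.cond(H) > 1e12:
        return (np.nan, np.nan, np.nan, "degenerate")
    Fs, Is = np.linalg.solve(H, [-b1, -b3])
    value = float(predict(model, Fs, Is))
    if det > 0:
        cls = "maximum" if b2 < 0 else "minimum"
    else:
        cls = "saddle"
    return (float(Fs), float(Is), value, cls)


def constrained_max(model: SurfaceModel, F_box, I_box, step: float = 1.0):
    """Maximum of the surface over a dose box, by grid search + refinement.

    When the analytic stationary point is a maximum and lies inside the
    box it is returned directly.  Otherwise a ``step``-spaced grid argmax
    is refined by one Newton step (projected back into the box), which for
    a quadratic lands on the exact optimum whenever the argmax is interior.
    Returns ``(F, I, value)``.
    """
    f_lo, f_hi = map(float, F_box)
    i_lo, i_hi = map(float, I_box)
    if not (f_lo < f_hi and i_lo < i_hi):
        raise ValueError("boxes must be non-empty intervals")
    if step <= 0:
        raise ValueError("step must be > 0")
    try:
        Fs, Is, val, cls = stationary_point(model)
    except ValueError:
        Fs, Is, val, cls = np.nan, np.nan, np.nan, "degenerate"
    if cls == "maximum" and f_lo <= Fs <= f_hi and i_lo <= Is <= i_hi:
        return (Fs, Is, val)
    fg = np.arange(f_lo, f_hi + step / 2, step)
    ig = np.arange(i_lo, i_hi + step / 2, step)
    FF, II = np.meshgrid(fg, ig, indexing="ij")
    Z = predict(model, FF, II)
    k = np.unravel_index(np.argmax(Z), Z.shape)
    f_best, i_best = float(FF[k]), float(II[k])
    # one Newton step from the grid argmax, projected into the box
    b0, b1, b2, b3, b4, b5 = model.coeffs
    g = np.array([b1 + 2 * b2 * f_best + b4 * i_best,
                  b3 + b4 * f_best + 2 * b5 * i_best])
    H = model.hessian
    if np.linalg.cond(H) < 1e12:
        stepvec = np.linalg.solve(H, -g)
        f_new = min(max(f_best + stepvec[0], f_lo), f_hi)
        i_new = min(max(i_best + stepvec[1], i_lo), i_hi)
        if predict(model, f_new, i_new) >= predict(model, f_best, i_best):
            f_best, i_best = f_new, i_new
    # the Newton step may leave one coordinate clamped at a box edge; polish
    # the free coordinate analytically (1-D quadratic)
    for _ in range(2):
        if f_best in (f_lo, f_hi) and b5 < 0:
            i_opt = -(b3 + b4 * f_best) / (2 * b5)
            i_best = min(max(i_opt, i_lo), i_hi)
        if i_best in (i_lo, i_hi) and b2 < 0:
            f_opt = -(b1 + b4 * i_best) / (2 * b2)
            f_best = min(max(f_opt, f_lo), f_hi)
    return (f_best, i_best, float(predict(model, f_best, i_best)))
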