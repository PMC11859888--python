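"""Quadratic response surfaces on the published treatment means.

Fits the six-coefficient quadratic R = b0 + b1 F + b2 F^2 + b3 I + b4 F I
+ b5 I^2 to the 12 published 2020 yield means, reports the fit quality,
and locates/classifies the stationary point.
"""

import numpy as np

from fertigation import (fit_bqrm, load_yield_means, predict,
                         stationary_point)

means = load_yield_means()
sub = means[means.year == 2020]
model = fit_bqrm(sub["F_total_kg_ha"], sub["irrigation_m3_ha"],
                 sub["yield_t_ha"], name="yield 2020")

print("coefficients (b0, b1, b2, b3, b4, b5):")
print(" ", np.array2string(np.array(model.coeffs), precision=6))
print(f"R^2 = {model.r_squared:.3f}   overall-F p = {model.p_value:.4f}"
      f"   (n = {model.n_points} treatment means)")

Fs, Is, val, cls = stationary_point(model)
print(f"\nstationary point: F* = {Fs:.1f} kg/ha, I* = {Is:.1f} m3/ha,"
      f" predicted yield {val:.2f} t/ha ({cls})")
print("note: with quadratic fits the stationary point is very sensitive to"
      "\ncoefficient rounding, so it is always reported with its Hessian"
      "\nclassification rather than taken at face value.")

ck = float(predict(model, 420.0, 1350.0))
print(f"\npredicted yield at the conventional dose (420, 1350): {ck:.2f} t/ha"
      f" (published mean 60.81)")
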