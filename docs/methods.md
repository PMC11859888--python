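# Methods

## The trial structure and its statistical model

The reference experiment is a split-plot factorial repeated over three
seasons: four fertilization levels (main plots; total nutrient
F ∈ {336, 378, 420, 462} kg·ha⁻¹, split N : P₂O₅ : K₂O ≈ 0.29 : 0.355 :
0.355) crossed with three drip-irrigation levels (subplots;
I ∈ {945, 1147.5, 1350} m³·ha⁻¹) in r = 3 replicate blocks, with the
conventional dose (F3W3) as control and an unfertilized check at every
irrigation level. Because irrigation is randomized *within* main plots,
observations share a main-plot error and carry an independent subplot
error:

    y_ijk = μ + ρ_i + α_j + (ρα)_ij + β_k + (αβ)_jk + ε_ijk ,

with replicate ρ, fertilization α, irrigation β, main-plot error (ρα) of
variance σ²ₐ and subplot error ε of variance σ²_b. The ANOVA therefore
tests fertilization against the Rep×F stratum ((r−1)(f−1) df) and
irrigation and the interaction against the residual stratum
(f(w−1)(r−1) df). The partition is computed directly from cell means and
is checked in the tests against (a) the SS identity, (b) a
main-plot-means interaction oracle, and (c) a fixed-effects OLS ANOVA
(statsmodels) in which each main plot enters as a block — the latter
reproduces the subplot-stratum F tests exactly.

Mean separation uses Fisher's protected LSD,
LSD = t₁₋α/2(df_e)·√(2·MS_e/n), summarized as a compact letter display by
insert-and-absorb on descending means. Letters are computed per year
across the twelve fertilized treatments using the subplot (error-b)
stratum; a mixed main-plot/subplot standard error for cross-stratum
contrasts would be a refinement, but all published comparisons are
reproduced with the single-stratum convention, so it is the default and
no alternative is currently implemented. Unfertilized checks are excluded
from the ANOVA (they would break factorial balance) and enter only the
agronomic-efficiency index.

## Water budget and indices

Seasonal crop water use is estimated by water balance,
ET = I + Pr + U − D − R − ΔW (all mm), simplified to ET = I + Pr − ΔW on
flat ground with deep groundwater. ΔW is storage at harvest minus storage
at planting over 0–80 cm, so drawdown (ΔW < 0) adds to ET. "Effective"
precipitation is, by default, the raw growth-period total; an optional
per-event threshold (default 0 mm) implements the convention that small
events evaporate before infiltrating. The water budget is resolved per
(year × irrigation level): all fertilization levels under one irrigation
level share one ET, since no plot-level soil moisture is available at the
summary level. The mm ↔ m³·ha⁻¹ bridge is exactly ×10.

Indices (yields in t·ha⁻¹ internally converted to kg·ha⁻¹):

| index | definition | units |
|---|---|---|
| SC  | 0.8 × brix | % |
| SY  | Y × SC/100 | t·ha⁻¹ |
| WUE | Y / ET | kg·m⁻³ |
| WUEi | Y / I | kg·m⁻³ |
| FAE | (Y − Y₀) / F | kg·kg⁻¹ |
| PFP | Y / F | kg·kg⁻¹ |

Y₀ is the *mean* of the unfertilized-check replicates at the same
irrigation level and year (checks are unreplicated per fertilized plot);
replicate-level FAE uses the replicate yield against that mean, and FAE
may legitimately be negative. The sugar variants (SWUE, SWUEi, SFAE,
SPFP) substitute sugar yield (and the check's sugar yield in SFAE), which
yields the exact identities SPFP = PFP·SC/100 and SWUEi = WUEi·SC/100
used as tests. The published index formulas carry two label slips (the
irrigation-efficiency formula is printed with the WUE label, the
agronomic-efficiency one without parentheses around Y − Y₀); both are
implemented per their symbol definitions. The published text also reports
*identical* percentage ranges for WUEi and SWUEi gains, which cannot both
be right since sugar content varies across treatments; this package
always computes SWUEi independently. CK-relative percent changes,
100·(x − x_CK)/x_CK, are computed on treatment means, which is the
convention under which the published deltas reproduce to 2 d.p.

## Response surfaces

Each response is fitted by OLS to the full quadratic
R(F, x) = b₀ + b₁F + b₂F² + b₃x + b₄Fx + b₅x² with x either the
irrigation dose (per-year fits) or the total water input (pooled fits).
Raw F²/x² columns have condition numbers ~10¹⁰ on agronomic scales, so
the solve runs on centred/scaled covariates and coefficients are expanded
back; R² is invariant under this affine change (tested to 1e−8). Fits
need ≥ 7 points spanning ≥ 3 levels per axis; rank deficiency and
underdetermination raise typed errors rather than silently regularizing.

The default fitting unit is the 12 treatment means per year.
Back-evaluation of the published equations against the published means
shows sub-1 t·ha⁻¹ residuals, consistent with a means-level fit, and the
means-level convention reproduces the published yield R² (0.872, 0.857,
0.924-vs-0.925) to the printed precision. Replicate-level fitting is
available via `fit_unit="replicates"`. Two of the published sugar-yield
R² values (0.800 and 0.965) are *not* reproducible from the published
means under either convention (this package obtains 0.821 and 0.928,
while the third, 0.904-vs-0.907, agrees); since the refitted coefficients
match the corresponding published equation to ~0.1 %, those two printed
R² values appear to be errata, and the recomputed values are reported
as-is.

The stationary point solves the 2×2 gradient system; the Hessian
[[2b₂, b₄], [b₄, 2b₅]] classifies it (maximum iff b₂ < 0 and
4b₂b₅ − b₄² > 0), with singular Hessians flagged degenerate rather than
guessed. Stationary points of quadratics are ill-conditioned in the
coefficients: re-deriving them from published *rounded* coefficients can
move the optimum by tens of kg·ha⁻¹ or hundreds of m³·ha⁻¹ (for the 2022
yield equation the rounded coefficients place it far outside the tested
irrigation range). Optima are therefore always reported with the
classification and an in-box flag, and `constrained_max` (grid argmax
plus one Newton step, plus 1-D polish on clamped edges) gives the maximum
over the tested dose box. Along a strongly F×I-correlated ridge a grid
argmax can sit several cells from the analytic point in one axis while
agreeing per-axis conditionally; the tests encode exactly that provable
form of agreement.

## Multi-criterion dose window

For the pooled analysis, per-year treatment means are stacked on the
(F, TWI) plane and one quadratic is fitted per criterion — by default
yield, sugar content and FAE, the set that bounds the published window;
WUE can be added by configuration. Sugar content is fitted with the same
quadratic family (its published interaction is described qualitatively as
a broken surface, but no alternative functional form is given, and the
quadratic is retained deliberately). A dose pair is admissible for a
criterion when its prediction is ≥ the prediction at the CK dose (weak
inequality, so the exact CK point is always admissible; a CK *between*
grid nodes can make near-CK cells inadmissible, which matters only at
grid resolution). The intersection mask is the logical AND; emptiness is
a diagnosed result (naming the criterion that eliminated the last cells),
not an exception.

Default grid: F ∈ [300, 500] step 0.5 kg·ha⁻¹, TWI ∈ [3500, 5000] step
1 m³·ha⁻¹. Each window extreme is attributed to the criteria whose masks
fail one step outward; when exactly two criteria bind, the iso-curve
crossing is refined off-grid by nested bisection (inner bisection along
one curve, outer bisection of the second criterion's residual) to 0.01 in
each axis, with a damped simultaneous solve as fallback; extremes on the
grid boundary are flagged box-limited. Irrigation doses follow from
I = TWI − 10·P̄r with P̄r the mean growth-period precipitation
(309.46 mm for the reference seasons). The published window itself
(TWI 4136.46–4380.82 m³·ha⁻¹, F 394.04–408.03 kg·ha⁻¹, irrigation
1041.91–1286.27 m³·ha⁻¹) derives from pooled fits whose underlying data
were never published; it is packaged as documented reference output, and
the tests verify its internal consistency under the conversion identity
plus full window recovery on synthetic data.

## The synthetic generator

The generator emulates the reference layout (12 fertilized treatments ×
3 replicates + 3 unfertilized checks × 3 replicates = 45 plots/year) or
seeded random dose grids. Responses follow user-specified quadratic truth
surfaces; errors are Gaussian with one main-plot draw shared by all
subplots of a (year, rep, fertilization) group and independent subplot
draws. Streams are derived per (year, rep, main plot, subplot) from one
root seed, so extending a trial never changes existing observations.

Defaults are chosen to look like the reference trial: a concave yield
truth peaking at 62 t·ha⁻¹ near (F = 420 kg·ha⁻¹, I = 1430 m³·ha⁻¹) with
unfertilized checks near 48 t·ha⁻¹ — the published 2020 equation is *not*
used as the default truth because it extrapolates to strongly negative
yields at F = 0 and cannot generate the checks; it remains available for
recovery tests with checks disabled. The brix truth decreases in both
doses across the design range (quality rises under input reduction) with
a mild convexity; σ defaults are 0.8/1.5 t·ha⁻¹ (main/subplot, yield) and
0.15/0.35 percentage points (brix), the scale of the published replicate
SDs. Negative simulated yields are redrawn by default (capped at 100
attempts), with clamp-to-zero and fail modes for stress tests.

What the generator does *not* emulate: growth-stage time courses,
year-to-year weather structure beyond a seasonal precipitation total,
spatial correlation between neighbouring plots, non-Gaussian errors, and
any non-quadratic dose response. Passing recovery tests therefore shows
the machinery is correct under the stated model, not that real trials
satisfy it.

## Problem sizes and numerical tolerances in the test suite

Monte-Carlo checks use 60 simulated trials per condition (effect
detection; optimum recovery at subplot σ = 1.5 → 0.75 → 0.375 t·ha⁻¹,
where the median stationary-point error must shrink monotonically), 100
random fixtures for the SS-partition and letter-display oracles, and
2000 replicates for the variance-component convergence check (10 %
tolerance). Noiseless coefficient recovery is asserted at 1e−8 relative;
the SS partition at 1e−8 relative; iso-curve refinement at 0.01 per axis.
The detection-rate check simulates from the published 2020 yield equation
with σ = 0.5/1.2 t·ha⁻¹, matching the published replicate SDs (~0.2–2.2);
at those noise levels the irrigation effect is detected at p < 0.01
essentially always and the fertilization effect at p < 0.05 in well over
half of runs, which mirrors the published significance pattern
(irrigation stronger than fertilization in the weakest year).

## Known limitations

* Means-level fits leave only 6 residual df; R² is accordingly optimistic
  and the overall F-test weak. Replicate-level fitting is one flag away.
* The admissible region inherits all quadratic-extrapolation risk; bounds
  flagged box-limited mean the grid, not the biology, stopped the search.
* FAE requires unfertilized checks; trials without them get NaN FAE
  columns and cannot use the default criterion set.
* The LSD display controls pairwise, not familywise, error — the
  convention of the reference analysis, kept deliberately.
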