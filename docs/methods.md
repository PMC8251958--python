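# Methods

## Coupled-equilibrium model

The transglycosylation is modeled as two reversible phosphorolysis
reactions sharing one pentose-1-phosphate / phosphate pool, with
concentration-based, dimensionless equilibrium constants in the
phosphorolysis direction, `K = [S][base] / ([nucleoside][Pi])`.  Activity
coefficients, ionic strength and buffer effects are not modeled; the
constants are condition-specific inputs (temperature and pH are carried as
metadata only).  Four pools are conserved: pentose moieties
(`[N_d]+[S]+[N_p]`), donor base (`[N_d]+[B_d]`), acceptor
(`[B_p]+[N_p]`) and phosphate (`[Pi]+[S]`).

### Forward solve

The state is parameterized by the acceptor conversion `x`.  The product
constraint fixes the sugar phosphate in closed form,
`[S]/(P0-[S]) = K_p * x/(1-x)`, after which every species follows from the
pools and the donor constraint leaves a single residual
`f(x) = K_d [N_d][Pi] - [S][B_d]`.  As `x` grows, `[S]` and `[B_d]` grow
while `[N_d]` and `[Pi]` shrink, so `f` is strictly decreasing: the root is
unique and is found by Brent bracketed search on `(0, 1)` (bisection with
secant/inverse-quadratic refinement, relative convergence at machine
precision, no random initialization).  Default constraint tolerance is a
relative residual of 1e-9 on both constants.

One numerical subtlety: when nearly all donor is consumed,
`[N_d] = D0 - xB0 - [S]` loses precision to cancellation.  At the solved
root the code re-evaluates `[N_d]` from the donor constraint itself
(`[S][B_d]/(K_d[Pi])`, all multiplicative), accepting the substitution only
when it moves the sugar balance by less than 1e-12 relative.  Mass
balances therefore hold to 1e-12 relative on every output.

Degenerate systems (no donor, no acceptor, no phosphate) return the `x=0`
boundary state flagged `degenerate` rather than raising: a zero-donor scan
point is an answer.

### Inversion

Given an observed equilibrium conversion and one constant, the other
follows in closed form.  For the donor constant the product constraint
gives `[S]` directly (same elimination as the forward solve).  For the
product constant the donor constraint
`K_d (D0-xB0-S)(P0-S) = S(xB0+S)` is a quadratic in `S`,
`(K_d-1)S^2 - [K_d(D0-xB0+P0)+xB0]S + K_d(D0-xB0)P0 = 0`, solved with the
numerically stable form of the quadratic formula; `K_d = 1` degenerates to
the linear branch and is handled explicitly.  The admissible root lies in
`(0, min(P0, D0-xB0))`; its absence signals a conversion thermodynamically
incompatible with the inputs (e.g. `xB0 >= D0`, violating the sugar
balance), reported as a typed exception.

### Excess scans

`conversion_curve` scans the donor:acceptor ratio at fixed acceptor and
phosphate loadings.  Phosphate stays at its absolute concentration by
default ("fixed" policy); a "proportional" policy scales it with the donor
instead.  The published working point — 0.09 equivalents of phosphate — is
interpreted relative to the acceptor nucleobase (0.09 mM at 1 mM base) and
held fixed across scans; both the referent and the scaling policy are
exposed as configuration because the source protocols leave them implicit.
`required_excess` exploits strict monotonicity of conversion in the excess
and brackets the target; an unattainable target (conversion at the excess
cap still short) returns a flagged result rather than raising, since
practical excess ceilings are part of the design space.  Under the
proportional policy the system becomes self-similar in the excess and
strongly unfavorable product constants genuinely cap the conversion.

### Brute-force oracle

`gibbs_grid_oracle` is an independent cross-check used only in tests: an
exhaustive scan over the two reaction extents minimizing the summed
squared log-residuals of both constraints.  Equilibrium species can sit
orders of magnitude below their pool bounds, so a single uniform grid
cannot resolve all regimes: the scan uses two-sided logarithmic axes
(dense near both boundaries), runs in both (extent-2, S) and
(extent-2, extent-1) parameterizations — each resolves a different corner
species — and refines the best cell with two zoomed linear passes.  The
refinement windows (±20 cells) absorb the discrete minimum's slide along
the constraint valley.  Agreement with the root-search solver is
verified to 1e-3 absolute in conversion over randomized systems with
constants log-uniform in [0.01, 100] and loadings in [0.1, 10] mM.

## Spectral analytics

Unmixing solves a nonnegative least-squares problem against the reference
matrix and normalizes the coefficients to fractions; nonnegativity is
imposed because the coefficients are physical state populations, and the
reference matrix is rejected when its column-normalized condition number
exceeds 1e8.  No baseline or scatter term is included by default (assay
protocols quench into fixed buffer); a constant-offset reference can be
added through the reference set.  Spectra on a different grid are linearly
resampled with a warning.

The pKa fit converts each titration spectrum to a deprotonated fraction by
unmixing and fits the monoprotic law with pKa as the sole parameter
(Levenberg–Marquardt, midpoint-nearest pH as start).  The reported
standard error is the asymptotic one from the least-squares curvature.  A
series whose fractions never cross the transition raises a no-transition
error; a series spanning less than one pH unit on either side of the
fitted midpoint carries a wide-stderr warning.  By construction the fitted
pKa is the pH at which the fitted fraction crosses 0.5.

Initial rates use the points where product has not exceeded 15 % of the
initial substrate (common enzymology practice; configurable), require at
least three such points, and fit an ordinary least-squares line with free
intercept.  Units follow from rate (mM/min = µmol/mL/min) × volume (mL);
specific activity U/mg is volume-invariant at fixed enzyme concentration.
The OLS slope over a finite window systematically underestimates the true
initial slope of a curving progress curve by roughly half the relative
rate decline across the window — narrow the window fraction when curvature
is visible.

## HPLC quantification

Peaks are assigned by non-overlapping retention-time windows; the packaged
typical retention times contain pairs that co-elute across different
reaction series (the two 12-min nucleosides) or sit closer than the
default ±0.3 min tolerance (3.4 vs. 3.6 min), so windows are built per
reaction series with tolerances shrunk below the smallest gap.  Conversion
is a peak-area ratio at the 307 nm quantification wavelength.  The
denominator defaults to the selenium-containing pair (free base + product
nucleoside) — the sugar donors absorb only weakly at 307 nm — and can be
widened to any label set; per-compound response factors (default equal,
both selenium species having their absorption maximum at 307 nm) convert
area ratios to mole ratios.

## Synthetic data

The generators emulate the *structure* of the study's raw data, not its
instrument physics:

* Reference spectra are sums of Gaussian bands on the 250–350 nm, 1 nm
  grid.  The default pair mimics a protonated form absorbing near 260 nm
  and a red-shifted deprotonated form peaking at 307 nm.
* Titrations mix the two references by the monoprotic law and add Gaussian
  noise (default sd 0.002 AU, additive, i.i.d. per wavelength).
* Kinetic time courses integrate generic reversible mass action,
  `r1 = kf1([N_d][Pi] - [S][B_d]/K_d)`,
  `r2 = kf2([S][B_p] - K_p[N_p][Pi])` (LSODA, rtol 1e-10, atol 1e-12,
  nonnegativity clamped in the rate evaluation).  Both rates vanish
  exactly on the equilibrium constraints, so endpoints provably coincide
  with the equilibrium solver — the cross-module consistency the tests
  rely on.  Mass-action (not Michaelis–Menten) is deliberate: the artifact
  needs thermodynamically consistent trajectories, not enzymological
  realism.  The default rate coefficients kf1 = kf2 = 5 mM⁻¹min⁻¹ bring
  the analytical fivefold-excess system to ≥99 % of its equilibrium
  conversion within a 30-minute horizon, matching the reported reaction
  times of the analytical runs.
* Peak tables set area = response factor × concentration with optional
  multiplicative Gaussian noise (default 2 % relative); sugar phosphates
  are omitted (not UV-active).

Real measurements additionally contain correlated baseline drift,
wavelength-dependent noise, detector nonlinearity, pipetting error and
chemical degradation channels (oxidative deselenation, sugar-phosphate
hydrolysis at 80 °C); passing the synthetic-recovery tests shows the
estimators are correct and well-conditioned, not that they are robust to
those effects.  Every generator draws from one seeded generator per call
and is bitwise reproducible under a fixed seed.

## Problem sizes and numerical defaults

Randomized test batches use 100–200 systems (constants log-uniform in
[0.01, 100], loadings log-uniform in [0.01, 100] mM — [0.1, 10] mM for
oracle comparisons), oracle grids of 2000 points per axis, titrations of
13 pH points, and 50-titration recovery sweeps; these sizes give stable
worst-case statistics while keeping the full suite around a minute on one
core.  Key tolerances: solver constraint residual 1e-9 (relative), mass
balances 1e-12 (relative), inversion round trips 1e-6 (relative),
solver–oracle agreement 1e-3 (absolute in conversion), kinetics endpoint
1e-4 (absolute in conversion).

## Known limitations

* No activity-coefficient or ionic-strength corrections; constants must be
  measured under the conditions they are used for, and no temperature
  extrapolation is provided.
* The pentose-1-phosphate hydrolysis side reaction (relevant at 80 °C) is
  not modeled; predicted conversions are upper bounds when it matters.
* Single-pKa (monoprotic) protonation model only.
* HPLC inputs are integrated peak tables; no chromatogram signal
  processing.
* The calibrate-and-predict workflow inherits the rounding of its printed
  inputs; predictions from rounded conversions and constants carry a
  percentage-point-scale uncertainty.
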