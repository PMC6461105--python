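# Methods

## The two-state model

The activation loop of the Aurora-A kinase domain interconverts between one
active and one inactive conformation.  We model this as a continuous-time
two-state Markov chain with rate constants

- `k_active` (s⁻¹): inactive → active (exit rate of the inactive state), and
- `k_inactive` (s⁻¹): active → inactive,

so dwell times in each state are exponential, the stationary inactive
occupancy is `k_inactive / (k_active + k_inactive)`, and the equilibrium
constant is `K_eq = [inactive]/[active] = k_inactive / k_active` (detailed
balance).  A quenching dye pair reports the conformation as a binary intensity
level: for the K224C/S283C reporter the inactive loop is quenched (low), for
the inverted M373C/S283C reporter it is fluorescent (high).

Free energies use `ΔG = −RT ln K_eq` with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and
T = 298.15 K (25 °C) unless overridden.  Ligand binding and phosphorylation
each shift the equilibrium by a characteristic free energy,
`ΔΔG_ligand = ΔG_apo − ΔG_ligand` (within one phosphorylation state) and
`ΔΔG_phosphorylation = ΔG_unphos − ΔG_phos` (within one ligand state), and any
condition composes as
`ΔG = ΔG_apo,unphos − ΔΔG_phosphorylation − ΔΔG_ligand`.

## Synthetic traces: what the generator emulates

`simulate.simulate_ensemble` draws, per molecule, a telegraph path (initial
state from the stationary distribution, since tethered molecules are imaged at
equilibrium) and integrates it into camera frames:

- frame interval 0.08 s (80 ms), 500 frames per molecule, ensembles of
  10²–10³ molecules — the acquisition conditions of the assay being modelled;
- the noiseless level of a frame is the exact time-weighted mixture of the two
  state intensities within that frame (transitions happen "within a single
  frame", never between samples);
- per-frame log-normal scatter around the level, parameterized so the *mode*
  of the scattered intensity equals the noiseless level.  Defaults: modes 1.0
  and 3.0 a.u. (3:1 contrast), shapes 0.15 (the peaks are ~7 shape-widths
  apart, comfortably resolved), no baseline.  Peak widths are not published
  for the real data; these were fixed once as a realistic resolved-peak regime
  and all recovery benchmarks run against them.

Not emulated: photobleaching and blinking (suppressed in the real experiment
by an oxygen-scavenger/Trolox buffer), camera EM gain and pixelation,
surface-tethering artefacts, and any third conformation (two states is the
model being tested).  Passing recovery tests therefore demonstrate correctness
of the estimators under the stated noise model, not robustness to bleaching or
drift.

Randomness: one `numpy` `SeedSequence` per ensemble, spawning one child
generator per molecule; the seed is recorded in every output.

## Population estimation from pooled histograms

Framewise intensities are pooled across molecules and fit with a sum of two
log-normal components, each written in mode/shape form
(`μ = ln mode + shape²`; median = mode·e^(shape²)).  Two routes:

- `fit_two_lognormals` — unweighted least squares of bin-integrated component
  mass (CDF differences, not density-at-center, so coarse bins over narrow
  peaks do not distort areas) against binned counts; Freedman–Diaconis
  binning by default; initial modes at the 20th/80th weighted percentiles
  with equal areas.  Component areas are free parameters and are *not*
  renormalized to sum to one.
- `fit_two_lognormals_mle` — maximum likelihood on the raw pooled
  intensities (one mixture weight, areas sum to one exactly).

At 80 ms frames and ~2 s⁻¹ switching, roughly 17% of frames contain a
transition and carry intermediate time-averaged intensities that neither
two-component model describes.  In log-intensity space these frames pile up
toward the high peak, so both estimators under-count the low peak: measured
on ground-truth simulations, the binned fit is low by ≈4 pp and the MLE by
≈2–2.5 pp on a 53% population.  The MLE is therefore the recommended
estimator and the pipeline default; the binned fit is retained for
comparability with conventional graphing-software fits.  The same bias is
*antisymmetric* under reporter-polarity inversion, so the mean of the two
constructs' populations cancels it — a quantitative rationale for the
two-construct design, asserted in the tests.

Populations map from areas by polarity (`pct_inactive = 100·area_low` for
inactive-low reporters, `100·area_high` for inverted ones), with standard
errors from the fit covariance (binned) or the binomial weight variance (MLE).

## Dwell-time kinetics

Framewise states are assigned by a single threshold placed where the two
fitted component densities cross (root of
`area_low·f_low(x) = area_high·f_high(x)` between the modes; geometric mean of
the modes as fallback when no crossing exists).  This replaces by-eye boundary
setting with a reproducible rule; at this assay's contrast any sensible
threshold gives the same assignment for >98% of transition-free frames.

Maximal runs of one state become dwells (minimum one frame); runs touching
either end of a trace are censored and excluded from rate fits (for an
exponential process this exclusion is the standard unbiased treatment).
`k_active` is fit from the complete quenched-state dwells two ways:

- `binned_lsq` (default) — least squares of `A·exp(−kt)` on the dwell
  histogram with one-frame bins, the classical procedure for such data; and
- `mle` — `1/mean` with standard error `k/√n`.

No dead-time/missed-event correction is applied.  Events shorter than about
half a frame are invisible: a sub-frame excursion merges the dwells on either
side, inflating the mean.  Measured on ground truth, `binned_lsq` recovers
`k_active` within −8…−10% and `1/mean` within −13…−15% at
(k_active, k_inactive) = (2.1, 2.4) s⁻¹, which is why the histogram fit is the
default; on clean exponential samples the two agree within their joint
standard errors (asserted in tests).  `k_inactive` is derived as
`k_active·K_eq` with errors combined in quadrature of relative errors;
residence times are the reciprocal rates.

## Thermodynamics display conventions

`K_eq` is always computed from unrounded population ratios and rounded only
for display (1 d.p.), with a 0.1 floor on displayed `K_eq` errors.  Reference
occupancy pairs are used exactly as printed, without renormalizing to 100%.
Three published reference values (K_eq for phosphorylated MLN8054 and
unphosphorylated CD532, ΔG for phosphorylated CD532) differ by one display
unit from what the printed integer populations give, because they were
published from unrounded fitted areas; the regression tests pin these three
offsets explicitly.

## Conformational-selection binding model

With conformation-specific dissociation constants `K_d,active` and
`K_d,inactive` and ligand-free equilibrium `K_eq,free`, trace-ligand mass
balance over {active, inactive, active·L, inactive·L} gives

    K_d,overall = (1 + K_eq,free) / (1/K_d,active + K_eq,free/K_d,inactive)

which is exact in both single-conformer limits and always lies between the
two conformation-specific constants.  The closed form is verified against an
independent numerical oracle that solves the four-species balance by root
finding and locates the half-bound ligand concentration (relative agreement
1e−6 on random triples).  A ligand at saturation shifts the equilibrium to
`K_eq,ligand = K_eq,apo/D` where `D = K_d,inactive/K_d,active` is the ligand
discrimination; the discrimination required to reach a target inactive
fraction f is `D = K_eq,start·(1−f)/f`.

Display convention for required-discrimination tables: fold preference is
rounded to the nearest integer and the displayed discrimination is the
reciprocal of that rounded fold (3 d.p.).  This reproduces published entries
such as 0.125 = 1/8 that direct rounding of the raw ratio does not.

Surface geometry (concentrations in nM; default axes 1 nM–10 µM, 50
log-spaced points):

- *Gap distances.*  The axis-parallel distance from an uphill point to a
  contour `c` follows from closed-form inversion,
  `K_d,active* = 1/((1+K_eq)/c − K_eq/K_d,inactive)` (and symmetrically);
  each is cross-checked against bisection.  For any point uphill of the
  contour both distances are finite — the uphill condition caps `c` below
  both axis asymptotes — so the infinite-distance flag can only trigger for
  contours above an asymptote.
- *Equidistant line.*  The locus where the two gap distances are equal
  (linear metric in K_d units by default; a log metric is available and the
  choice is recorded on the curve).  Because `K_d,overall` is homogeneous of
  degree one in (K_d,active, K_d,inactive, c), the locus is scale-invariant:
  a whole-domain maximum deviation from the diagonal does not shrink as `c`
  decreases.  The "approaches the diagonal as affinity increases" behaviour
  is pointwise, and is quantified as `|log(K_d,inactive/K_d,active)|` of the
  locus at a fixed `K_d,active` — e.g. at 3 µM and K_eq = 23/77 it falls
  0.200 → 0.018 → 0.002 over contours 1 µM → 100 nM → 10 nM.
- *Plateaus.*  The two logarithmic sensitivities
  `∂ln K_d,overall/∂ln K_d,axis` are analytic and sum to one, so a point can
  be flat with respect to at most one axis; the plateau mask flags, per axis,
  where that axis' sensitivity falls below a threshold (default 0.25), and
  "combined" means insensitive to at least one axis.

## Problem sizes and numerical tolerances

Recovery benchmarks use 500 molecules × 500 frames per condition (≈2.5×10⁵
pooled frames, ~10⁴–2×10⁴ complete dwells), matching the scale of the real
ensembles; unit tests use 150–250 molecules.  Root finding uses Brent's
method at relative tolerance ≤1e−12; mixture fits use Levenberg–Marquardt
(binned) and Nelder–Mead (MLE, tolerance 1e−8).  Fits must be stable to
within 1 pp of population under ±25% bin-width perturbation (asserted in
tests).  Degenerate single-peak data produce a flagged, not silent, result
with one area < 0.02.

## Known limitations

- No hidden-Markov inference: thresholding is adequate at this contrast but
  would fail at low signal-to-noise.
- No missed-event correction: rate estimates carry a documented −5…−10%
  (binned fit) systematic bias at 80 ms frames and ~2 s⁻¹ rates.
- Population estimates carry a −2…−4 pp transition-frame bias (see above);
  single-construct populations should be read with that in mind, and
  two-construct averaging is the recommended mitigation.
- The binding layer treats saturating-ligand and trace-ligand limits only; no
  finite-depletion isotherms, no kinetic (on/off-rate) binding model, and no
  transition-state energetics.
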