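# Methods

This note documents the models, conventions and numerical choices behind
`tauflux`, and what the synthetic-data generators do and do not emulate.

## Release-rate model

An incubation chamber holds N animals in volume V (default 0.5 L) of
0.2-µm-filtered seawater. While release outpaces losses, the dissolved
concentration of each analyte rises approximately linearly; the volumetric
release rate is the ordinary-least-squares slope of concentration (nM) on
time (h). Inference on the slope is the standard OLS t-test with n − 2
degrees of freedom, two-sided.

**Truncation.** Chambers plateau once uptake by carapace-attached bacteria
or re-ingestion balances release. The usable span T_C ends at the last
time point up to which *every* analyte tracked in the chamber still
increased step over step. "Still increased" means an increase greater than
`tol_nM`, default 0 (strict). The strict default matches integer T_C
values on the sampling grids used in practice; a small positive tolerance
guards against calling noise-level wiggles "increases" in noisy data.
Duplicate time points (repeat injections, pooled controls) are averaged
before any regression.

**QC rules.** A fit is rejected as `low_fit` when r² < 0.60 **or** the
slope p-value exceeds 0.05. The disjunctive reading is the conservative
one — it rejects at least as much as the conjunction — and is consistent
with retaining small-n fits with r² just above 0.60. The conjunction is
available via `combine="and"`. A series whose first sampling interval
carries more rise than all later intervals combined, with a flat or
negative trend afterwards, is flagged `early_release_only`: that pattern
is the signature of a handling-stress pulse (net tow, sorting) rather than
sustained release, and no rate is reported for it.

**Controls.** A no-animal control accompanies each experiment. Published
practice monitors controls without stating a subtraction, so by default
rates are *net* rates with the control's own slope reported alongside;
point-wise control subtraction (floored at zero, with linear interpolation
onto the sample grid) is available behind an explicit flag.

**Normalisation.** Total release is slope × V (nmol h⁻¹). Per individual:
× 10³ / N → pmol ind⁻¹ h⁻¹. Per biomass: × 10⁻³ / (g C) → µmol g⁻¹ C h⁻¹.
The identity (per-individual)/(per-biomass) = 10⁶ × g C ind⁻¹ holds
exactly and is used as a cross-module consistency check against the
morphometry results. Daily rates are hourly × 24.

## Morphometry

Copepod biovolume uses an ellipsoid V = 4/3 π a b c. The formula only
yields an ellipsoid volume when a, b, c are *semi*-axes, so a = length/2
and b = c = diameter/2; a full-axis reading would inflate volumes
eight-fold. Amphipods use a cone V = 1/3 π r² h with r = diameter/2 and
h = length (the body tapers along its length); orientation is a
convention and configurable. Carbon factors default to 0.08 pg C µm⁻³
(copepods) and 0.05 pg C µm⁻³ (amphipods) and are configurable because
such factors depend on fixation and instrument. No shrinkage correction
is applied.

## Bulk release and turnover

RRt = RRc × A scales the mean per-individual community rate
(nmol ind⁻¹ d⁻¹) by copepod abundance (ind L⁻¹) to a volumetric supply
rate; T = C/RRt is the steady-state turnover time of the ambient pool.
Steady state is an assumption, not a result: no consumption kinetics,
temperature scaling or depth structure is modelled, and abundance is a
user input (literature values). The regional example configurations in
`flux_turnover.REGION_EXAMPLES` carry abundance ranges back-derived from
published bulk-rate ranges divided by the corresponding mean rates; they
are reconstructions, certain only up to the rounding of the published
figures (the subarctic Pacific mean daily rate rounds to 10.2, while the
Atlantic figure is used unrounded as 0.58 nmol ind⁻¹ d⁻¹ for the same
reason). Reported values are conventionally rounded to three significant
figures for RRt and two for T.

## Analytical QC

Calibration lines are fit unweighted (no 1/x or 1/x² weighting).
Internal-standard quantification is single-point with a relative response
factor taken from the external standard run; the working formula is
conc = (sample response / IS response) × IS conc / RRF, which is invariant
to injection-to-injection drift by construction. RSD uses the n−1 sample
standard deviation, the conventional method-validation statistic. LOD and
LOQ operate on supplied (concentration, signal, noise) triples — peak
integration is instrument-side and out of scope. Spike confirmation for
samples between LOD and LOQ accepts when the measured increase is within
15% of the nominal spike by default; the window is a package choice wide
enough to contain the 99–111% recovery band a validated method exhibits.

## Water-column statistics

DON = TDN − (NO₃ + NO₂ + NH₄); negative differences are flagged missing
rather than clipped to zero. Pool fractions use taurine's elemental
composition (2 C, 1 N): Tau-C% = 2·Tau·10⁻³/DOC × 100 and
Tau-N% = Tau·10⁻³/DON × 100, so their ratio is exactly DOC/(2·DON). Depth
layers default to epipelagic [0, 200), mesopelagic [200, 1000) and
bathypelagic [1000, ∞) metres, half-open. Layer means are unweighted
across station-depth samples; trapezoidal depth-weighting is deliberately
not the default because bottle grids are irregular across stations.

Mann–Whitney U is two-sided, exact when both samples are small
(min n ≤ 8) and untied, otherwise normal-approximated with tie
correction. Hedges g divides the mean difference by the pooled n−1
standard deviation and applies the small-sample correction
J = 1 − 3/(4(n₁+n₂) − 9); it is reported as a magnitude, the usual
convention when g is read purely as an effect size. (Statements elsewhere
that g ranges 0–1 do not match the statistic's unbounded definition; no
bounded variant is implemented.)

## Synthetic data

The generators define the study conditions for every test:

* **Incubations** follow c(t) = c₀ + s·exp(−t/τ)·[t > 0] + r_v·min(t, t_p) + ε
  with volumetric slope r_v = rate × N/(V·10³), hard plateau at t_p, an
  optional exponentially decaying stress spike that appears after the t = 0
  sample, and homoscedastic Gaussian noise ε (a proportional-error option
  exists). Negative draws are floored at zero. The `"goa"` preset uses the
  0, 2, …, 12, 24 h grid, 50 individuals, 425 pmol ind⁻¹ h⁻¹ true taurine
  rate, ~340 µg C individuals and 10 nM noise (≈1% of the 24 h rise); the
  `"na"` preset uses the 0, 0.5, …, 2, 3, 5, 8 h grid, 40 individuals,
  24.4 pmol ind⁻¹ h⁻¹, ~2.8 µg C individuals and 0.3 nM noise. The linear
  rise/hard plateau form is a modelling choice: real chambers curve
  smoothly into their plateau, animals vary individually, and bacterial
  uptake is dynamic — so passing closure tests validate the estimator
  under the stated kinetics, not chamber biology.
* **Profiles** are exponential in depth, tau(z) = 0.15 + 4.85·exp(−z/60) nM
  by default (surface ≈ 5 nM, ≈0.15 nM at depth, upper-100-m mean ≈ 2.5 nM
  on the default bottle grid), with smooth open-ocean DOC/DON/inorganic-N
  shapes so pool fractions are computable and surface DOC:DON lands near
  10–14.
* **Specimens** have log-normal lengths (default log-sd 0.15) with
  diameters at a fixed ratio (1/3) plus small jitter; the presets bracket
  the two observed biomass regimes (~3.4 × 10⁻⁴ vs ~2.5 × 10⁻⁶ g C ind⁻¹).
* **Standard series** are linear with 3% proportional response noise and a
  constant instrument baseline noise, putting fitted r² in the high-0.99s
  and making S/N linear in concentration.

Every generator takes a mandatory seed (NumPy `default_rng`) and a given
scenario + seed is bit-reproducible.

## Problem sizes

The test suite and the reproduction script use 40–500 simulated chambers
per check and 6–20 stations per profile set; these sizes give Monte-Carlo
error comfortably below the asserted tolerances (e.g. the 95%-CI coverage
estimate over 500 chambers has a binomial standard error of ≈1 point)
while the whole suite runs in seconds.

## Known limitations

* Gross vs net release is not separable: carapace-attached bacterial
  uptake biases rates low, and starved animals release less.
* No temperature dependence of excretion; incubations at a single
  temperature are taken at face value.
* Turnover times inherit the uncertainty of literature abundances and the
  steady-state assumption; they are order-of-magnitude estimates.
* The QC disjunction/conjunction ambiguity and the control-subtraction
  question are resolved by configurable defaults, not by evidence.
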