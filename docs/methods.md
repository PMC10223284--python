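# Methods

## Scope and data model

The package analyses two in vitro toxicokinetic assays read out by mass
spectrometry as analyte:internal-standard response ratios, and carries the
results through in vitro–in vivo extrapolation (IVIVE). Concentrations are
expressed *at instrument* (nM in the injected solution). Work-up dilution
factors (a 1:3 acetonitrile crash then 1:10 for plasma samples; 1:1 then
1:9 for hepatocyte samples) are treated as metadata and never applied to
outputs: fraction unbound and depletion slopes are ratios of
concentrations diluted identically, so carrying dilutions through would
only create a silent unit-error class. One `batch_id` corresponds to one
measurement day and one calibration; when a chemical was measured on
several days each day gets its own curve, but a single f_up (or Cl_int)
is estimated per chemical.

Below-detection responses are kept as left-censored records (flagged, with
the batch eMDL as the threshold) rather than zeroed or dropped. The
Bayesian models use the censoring term directly; the point estimators
treat censored values as missing.

## Calibration

Curves are linear or quadratic in concentration, fitted by weighted least
squares with weights 1, 1/x or 1/x². Model selection is deterministic:
linear before quadratic, and within each form unweighted, then 1/x, then
1/x², accepting the first candidate whose back-calculation accuracy table
passes. Accuracy is judged per calibration level — replicate injections of
a level are averaged before comparison with nominal — and a curve is
accepted when every level's back-calculated mean lies within ±30% of
nominal and the slope is positive. Quadratic inversion takes the root in
[0, 1.2 × top level]; zero or two admissible roots yield an invalid (NaN)
result rather than an exception, since a validated curve is monotone over
its range.

The estimated method detection limit is sd(seven replicate back-calculated
low-level concentrations) × t(0.99, 6 df). The t value is computed from
the t distribution at run time; the conventional 3.14 figure is its
2-decimal rounding and appears only in tests. The estimated limit of
quantitation is the lowest level at which all seven replicates fall within
±30% of nominal; when that level sits below the eMDL it is floored at the
eMDL, since a level that cannot be detected cannot quantify.

## Plasma protein binding (ultracentrifugation)

f_up = mean(AF concentration) / mean(T5hr concentration). Means are taken
before the ratio because AF and T5hr aliquots are unpaired in the assay
design. Noise can push the raw ratio above 1; the reported point estimate
is capped at 1 (its physical maximum) with the raw ratio retained.
Stability is screened with mean(T5hr)/mean(T1hr): loss strictly greater
than 60% excludes the chemical. A missing T1hr yields "stability unknown"
rather than assuming the nominal spike concentration. A designated
reference compound (4-nitrotoluene) can be summarised per batch against a
configured historical band to flag drifting assay performance.

## Hepatocyte clearance (substrate depletion)

All replicate points enter an ordinary least-squares fit of
ln(concentration) on time — using every point rather than replicate means
maximises the F-test's degrees of freedom. Significance requires both
p < α (default α = 0.05, configurable; with one regressor the F-test
equals the two-sided t-test on the slope) and a negative slope; a
significantly positive slope is flagged as an anomaly and reported as no
detectable clearance. For significant fits k = −slope, T½ = ln 2/k and
Cl_int = 2000·k, where 2000 µL is the assay volume containing one million
cells at 50,000 cells/100 µL — an exact algebraic identity that the test
suite asserts on every fit.

Censored points are dropped and the whole-cell series is truncated at the
last timepoint with at least two quantifiable replicates; the cell-free
control is truncated to the same final timepoint so background subtraction
compares matched windows. Background adjustment subtracts rate constants
(k_met = max(0, k_cells − k_cellfree)) because both compartments follow
first-order loss; the cell-free rate enters only when itself significant.
Chemicals showing 50% or more cell-free loss at 120 min (inclusive
boundary) are excluded as abiotically unstable. Inactivated-hepatocyte
controls are generated, screened and reported identically, but only the
cell-free rate is subtracted: it isolates abiotic loss without cellular
protein binding. The design time grid is {0, 15, 30, 60, 120, 240} min
(the generator parameterises it).

## Bayesian uncertainty model

A joint model per chemical propagates calibration noise into the assay
parameters.

*Calibration sub-model* (per batch): y ~ Normal(μ, σ(μ)) with
μ = b0 + b1·C (optionally + b2·C²) and σ(μ) = sqrt(σ0² + (ν·μ)²) — a
constant floor plus proportional component. Responses flagged below
detection contribute P(y < threshold) via the Normal CDF.

*Ultracentrifugation sub-model*: each replicate experiment carries a
latent T1hr concentration, lognormal around the nominal at-instrument
level (250 nM for the 10 µM assay); a shared degradation factor
D ∈ (0, 1] gives C_T5 = D·C_T1 and C_AF = f_up·C_T5 with a single
f_up ~ Uniform(0, 1) across batches.

*Depletion sub-model*: C_cells(t) = C0·exp(−(k_met + k_bg)t),
C_cellfree(t) = C0'·exp(−k_bg t); Cl_int = 2000·k_met is derived. One
latent initial concentration per condition keeps the parameter count
small; well-to-well pipetting scatter is absorbed by the response noise.

*Priors* (all configurable, `invitrotk.bayes.Priors`): f_up and D uniform
via logit transforms; latent log-concentrations Normal(log nominal, 0.3);
σ0 ~ half-Cauchy(0.005) and ν ~ half-Cauchy(0.2); rate constants
half-Normal(0.05 min⁻¹); calibration intercepts Normal(0, 1) and
log-slopes Normal centred on the per-batch least-squares value (sd 3).
The heteroscedastic error form and these scales are this package's
choices; a prior-sensitivity test in the suite checks that informative
data dominate them.

*Sampling protocol*: n independent chains (default 5) of blockwise
adaptive random-walk Metropolis on transformed (unconstrained)
parameters. Blocks: calibration coefficients, noise parameters, latent
concentrations, assay parameters. Proposal scales adapt by Robbins–Monro
toward ~30% acceptance during burn-in, with per-component widths
refreshed from the second half of burn-in. Each extension runs a 50,000
iteration burn-in followed by 50,000 iterations thinned to 2,000 draws
per chain (defaults; tests use shorter chains), after which the
Brooks–Gelman multivariate shrink factor over the monitored parameters
(f_up, D, σ0, ν — or Cl_int, k_bg, σ0, ν) is evaluated; chains extend
until it is below 1.05 or a configured cap, reporting `converged`
accordingly. Summaries (median, central 95% credible interval) come from
the pooled final-extension draws (5 × 2,000 = 10,000 at defaults).
PSRF convention: the diagnostic is floored at 1, so identical chains give
exactly 1; parameters with zero total variance are dropped from the
multivariate statistic. Estimates whose 95% interval spans more than
three orders of magnitude are flagged `uncertain` (lower bounds at or
below zero are evaluated at a 10⁻⁶ floor).

## IVIVE

f_ub = min(1, f_up/Rb). The default blood:plasma ratio Rb = 0.55 applies
to ionized chemicals; neutral chemicals must supply a chemical-specific
Rb (partitioning is not predicted). Renal clearance is GFR·f_ub
(glomerular filtration of unbound chemical, no secretion/reabsorption).
Cl_int scales to whole liver by hepatocellularity (110×10⁶ cells/g) ×
liver mass (1596 g) × 60 × 10⁻⁶ and enters the well-stirred model
Cl_hep = Q_h·f_ub·CL_u/(Q_h + f_ub·CL_u) with Q_h = 90 L/h. Steady state
treats the daily dose (default 1 mg/kg/day, 70 kg) as a continuous
equivalent infusion: C_ss = μmol/h dose rate ÷ total clearance, in µM.
AED = LOEC/C_ss × dose. Zero total clearance yields an infinite C_ss
flag, not an error.

The bundled worked-example table reproduces its published outputs with
these scalars: clearances agree within 1%; C_ss and AED sit a consistent
~0.8% from the printed values, which are 2–3-digit roundings of a source
computation whose internal scalars evidently differed in the third
decimal. The regression test therefore allows 2% relative plus half a
unit in the last printed decimal, i.e. agreement at printed precision.

## Synthetic data: what it emulates and what it does not

The generator reproduces the stated designs — 15-point calibrations
(1.75–1250 nM plasma, 7–5000 nM hepatocyte) with 7-injection low-level
sets and blanks, the 10 µM / 3-replicate ultracentrifugation layout, the
1 µM / triplicate depletion grid with cell-free and inactivated
controls — with a measurement model matching the Bayesian likelihood
(heteroscedastic Normal response noise; defaults σ0 = 5×10⁻⁴ response
units, ν = 10%, chosen to put the implied eMDL near but below the lowest
calibration level, consistent with a validated bioanalytical method) and
lognormal pipetting noise (5%) on latent assay concentrations. A
`lognormal_errors` switch misspecifies the response noise for robustness
testing. Censoring applies the truth-implied detection threshold, so a
noiseless generator censors nothing and every estimator collapses onto
truth exactly — the suite asserts this closed loop at machine precision.
Cohort sampling draws f_up from a lognormal capped at 1 (median 0.094,
log-sd 1.3, matching a highly bound, right-skewed cohort) and Cl_int from
a zero-inflated lognormal.

Synthetic data do not emulate matrix interference, chromatographic drift,
carryover, instrument saturation, or chemical-specific response-factor
nonlinearity beyond an optional quadratic term; passing recovery tests
therefore demonstrates correctness of the estimation chain under the
stated noise model, not robustness to every laboratory failure mode.

## Numerical choices and test problem sizes

Stochastic tests use fixed seeds throughout; the acceptance-scale checks
run 100-seed recovery ensembles, a 1,000-replicate null simulation for
the F-test, and 100 simulated datasets × 4 chains × 5,000 iterations for
interval coverage — sizes chosen to keep Monte-Carlo error a small
fraction of each tolerance while the full suite stays lightweight on a
single CPU. Under the study noise conditions (10% proportional cv,
triplicates), first-order error propagation puts the f_up ratio
estimator's relative sd at cv·√(2/3) ≈ 8% — a useful yardstick when
interpreting recovery rates at tight tolerances.

## Known limitations

- The well-stirred IVIVE chain is a steady-state, single-compartment
  summary: no PBTK simulation, population variability, or tissue
  partitioning.
- Renal clearance assumes pure glomerular filtration; transporters are
  out of scope, as they are for the source assays.
- The depletion analysis is single-concentration (1 µM) first-order; no
  Michaelis–Menten saturation or metabolite identification.
- The Bayesian depletion model shares one latent initial concentration
  per condition rather than one per well; with triplicate wells this
  slightly understates between-well variability.
- Quadratic calibration inversion refuses ambiguous (two-root) cases
  instead of guessing.
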