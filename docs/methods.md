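# Methods

This note documents the models implemented in `ritdose`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Physical decay model

²¹³Bi (T½ = 45.59 min, standard nuclear data) decays through a short chain
whose alpha emissions are collapsed onto the parent: 97.86 % of decays pass
through ²¹³Po (T½ ≈ 4.2 μs), whose 8.376 MeV alpha is scored at the ²¹³Bi
decay site and time (secular-equilibrium collapse), and 2.14 % emit a
5.87 MeV alpha directly.  The branch-weighted mean alpha energy per nuclear
transformation is 1.3334 × 10⁻¹² J; the canonical nuclide object carries the
conventional rounded constant Δ = 1.33 × 10⁻¹² J, and the two are required to
agree within 1 %.  This distinction is visible at one decimal place in the
9 MBq/mL peritoneal dose (23.6 Gy with the conventional Δ, 23.7 Gy with the
unrounded sum).  Beta and gamma components and full Bateman chain solving
are out of scope: alpha energy dominates the absorbed dose at these scales.

Internal units are Bq, s, kg, J, Gy; MBq/mL, minutes and MeV are converted
at the interfaces, with fluid density 1 kg/L so 1 MBq/mL = 10⁹ Bq/kg.

## Organ dosimetry

Absorbed dose is D = (Ã/m)·Δ·Φ with Φ = 1 at organ scale.  Ã/m for a sampled
time–activity curve is the trapezoidal area plus a single-exponential tail
beyond the last sample (tail rate = physical λ by default, a fitted rate if
supplied; the analytic pure-decay case is C₀/λ).  The peritoneal surface is
treated as a plane bounding a half-space of uniformly radioactive fluid and
receives half the equilibrium dose — an assumption validated independently
by the microdosimetry module's vanishing-target half-space limit.  Bone
marrow uses a fixed marrow-to-blood dose ratio of 0.58 measured for i.p.
antibody conjugates; applying it to blood doses of 1.3 and 3.9 Gy gives 0.75
and 2.26 Gy (reported as 0.8 and 2.3 at one decimal).  Report output is
rounded to one decimal in Gy; full precision is kept internally.

## Biokinetics

The fluid/blood system is linear,

    dF/dt = −(k_t + λ) F,      dB/dt = k_t F − (k_c + λ) B,

so it is solved in closed form (exact and trivially stiff-safe) and
evaluated on a fixed grid (1 s steps for the first 10 min, then 60 s); a
numeric ODE solution serves only as a cross-check in the tests.  Defaults:

| parameter | default | unit | rationale |
|---|---|---|---|
| k_t (fluid→blood) | 3.744 × 10⁻⁵ | s⁻¹ | closed-form calibration so 3 MBq/mL gives a 1.3 Gy blood dose (≈5 h transfer half-time, plausible for i.p. IgG in mice) |
| k_c (blood elimination) | 10⁻⁵ | s⁻¹ | slow IgG clearance relative to the 46 min half-life |
| k_on | 10⁵ | M⁻¹s⁻¹ | typical IgG association |
| k_off | 10⁻⁵ | s⁻¹ | typical IgG dissociation (K_d = 0.1 nM) |
| antibody molar mass | 150 000 | g/mol | IgG |
| fluid / blood volume | 1.0 / 1.5 | mL | injected volume; mouse blood volume |

The study's own mouse transfer and clearance rates are unpublished; these
defaults are constrained only by the printed blood dose, and all are
overridable in the config.  Human-scenario peritoneal doses deliberately use
the no-clearance assumption instead of this model (peritoneal clearance in
patients is slow compared with the ²¹³Bi half-life).

Antigen occupancy is pseudo-first-order,
θ(t) = θ_eq·(1 − e^−(k_on C + k_off) t); at 10 μg/mL antibody the time to
95 % of equilibrium is ≈7.5 min, consistent with saturation "within minutes".
The fraction of decays occurring after binding (decay-weighted occupancy,
θ_eq·k/(k+λ) ≈ 0.96 at study concentrations) converts antigen counts into
bound decays.

## Microdosimetry

Alpha tracks are straight; energy deposited along a chord is
E(R_residual at entry) − E(R_residual at exit), the residual-range inversion
that reproduces Bragg-peak weighting without a transport code.  The
range–energy relation is a 20-node log-log table generated from
R = 2.47·E^1.664 μm, calibrated to commonly cited CSDA ranges of alphas in
unit-density tissue (47 μm at 5.87 MeV, 85 μm at 8.376 MeV).  Published
stopping-power tabulations deviate from this power law below ~1 MeV; that
region only shifts where the final fraction of a track's energy lands and is
immaterial at the tolerance of every quantity computed here.

Two bath geometries are exposed:

- **full**: the target sphere is a probe region of an infinite uniformly
  radioactive medium (activity also inside the sphere).  Limit check: at
  radius ≫ alpha range the dose converges to the equilibrium dose
  (C₀/λ)·Δ within MC error (charged-particle equilibrium).
- **half-space** (default): the cluster is tumor tissue tangent to the
  peritoneal wall and displaces fluid; activity fills the half-space above
  the wall minus the sphere.  Limit check: a vanishing cluster at the
  interface receives 50 % of the equilibrium dose, the classical surface
  rule.

Sources are sampled uniformly within one maximum range of the sphere (their
contribution is otherwise zero), and emission directions are importance-
sampled in the cone subtending the target with weight equal to the cone's
solid-angle fraction.  This makes micrometre targets estimable at 10⁶
histories (the default; seed 20170424) in about a second per radius, with
standard errors ≲0.5 %.  Estimates are bit-for-bit reproducible given (seed,
histories), the standard error scales as 1/√N, and per-track deposits never
exceed the emitted energy.

The bath time-integrated concentration for the mouse scenarios is the
two-compartment model's fluid integral C₀/(k_t + λ) — about 87 % of the
no-clearance value with the calibrated k_t — times an optional retention
multiplier (default 1).  With the default half-space geometry this yields
unspecific doses of ≈8.0 / 8.5 / 7.7 Gy at radii 9 / 30 / 50 μm for
3 MBq/mL, bracketing the half-equilibrium value of 7.87 Gy; at 9 MBq/mL they
are exactly 3× larger, since the geometry factor per radius is computed once
and scaled.

**Specific (cell-bound) dose.**  Bound decays per cluster are
(accessible antigens) × (decay-weighted occupancy) × (immunoreactive
fraction) / (antibody molecules per nuclide atom).  A single cell exposes
all 700 000 antigens; for a multicellular cluster antibody penetrates
poorly, so only the membrane area exposed at the cluster surface binds —
antigens_per_cell scaled by the cluster-to-cell surface-area ratio — and the
activity is placed on the sphere's surface shell (whole-cell uniform
placement for single cells).  With the default affinity and specific
activity this yields specific doses of ~11–14 Gy for 9–50 μm clusters,
higher than the few-Gy values a fuller kinetic model of this setting
reports; the discrepancy is expected, since the binding kinetics, effective
antigen accessibility and fluid depletion of that model are unpublished, and
no parameter here was adjusted to match it.  The robust qualitative features
are preserved and tested: specific dose is nearly invariant to activity
concentration once antigens saturate, rises slowly with cluster radius, and
total = specific + unspecific exactly.  The radius of the smallest tabulated
cluster is ambiguous in the source convention (9 μm could denote a
single-cell diameter); radius is exposed directly, with cell radius 4.5 μm
as the single-cell scale.

## Binding assay (Lindmo)

Bound/applied follows IRF·qc/(1 + qc); the double-reciprocal transform makes
applied/bound linear in 1/c, and IRF = 1/intercept by unweighted OLS on the
replicate-averaged transformed values (classical Lindmo; weighted variants
out of scope).  The transform is exactly invertible on noiseless data
(machine-precision IRF recovery), the estimate is invariant to the units of
applied activity, and a non-positive intercept raises a degenerate-fit
error.  Decay correction of counts within the incubation is off by default.

## Efficacy statistics

Tumor-free fraction = (n − tumor-bearing)/n with the nesting convention:
macroscopic-tumor animals are contained in the microscopic count and ascites
animals are assumed tumor-bearing (the tumor-bearing count is
max(n_micro, n_ascites)).  This is the only reading of the study's count
table that reproduces all three reported fractions (0.55, 0.78, 0.15); the
9 MBq/mL group uses n = 18 because two exclusions are input data, not
computed.

Fisher's exact test is implemented from first principles: hypergeometric
point probabilities via exact integer binomials, two-sided p as the sum over
all tables with the observed margins whose probability is ≤ the observed
table's probability × (1 + 10⁻⁷) (minimum-likelihood rule; the guard
protects against float ties).  Degenerate margins return p = 1.  The
implementation agrees with an exact rational-arithmetic enumeration for
every 2×2 table with N ≤ 40 and with `scipy.stats.fisher_exact` on random
tables.  No multiplicity adjustment is applied.

Hematology summaries report per-group/day mean, SEM = sd/√n with the
population standard deviation, and the day-6→14 percent change of the group
mean.

## Synthetic-data generators

All generators are pure functions of their seed (numpy `default_rng`);
noise is multiplicative log-normal with unit mean, the simplest
positive-support model for counts and assay data.

- **Blood TAC**: A·(e^−k_out·t − e^−k_in·t)·e^−λt with k_in = 10⁻² s⁻¹,
  k_out = 2 × 10⁻⁴ s⁻¹ and amplitude solved in closed form so the noiseless
  curve integrates to the target blood dose (1.3 Gy at 3 MBq/mL, 3.9 Gy at
  9 MBq/mL); 600 samples over 6 h keep the trapezoid + tail pipeline within
  0.5 % of the target.  A shape whose implied blood peak exceeds the
  injected fluid concentration is rejected as infeasible.
- **Lindmo assay**: six two-fold dilutions from 5 × 10⁶ cells/mL, duplicates,
  3 % CV; the default per-cell affinity (q = 2.075 × 10⁻⁶ per cells/mL) puts
  the noiseless top-concentration bound fraction at 0.83 when IRF = 0.91,
  matching the assay's reported operating point.
- **Outcomes**: Bernoulli tumor status at the stated tumor-free fraction;
  macroscopic and ascites flags drawn only among tumor-bearing animals, so
  the nesting invariant holds by construction.
- **Hematology**: log-normal counts around the reported day-6 WBC group
  means (4.3/3.9/3.4 × 10⁹/L) with a +22 % mean rise by day 14; only one
  platelet group mean is reported (777 × 10⁹/L), the others default to
  unremarkable values.

What passing tests on these generators show — and do not show: they verify
the estimators and dose pipeline against data with the *assumed* structure
(log-normal noise, exact biexponential shapes, independent Bernoulli
outcomes).  Real biodistributions have inter-animal variability, non-ideal
mixing of the i.p. fluid, and tumor-burden heterogeneity that none of the
generators emulate, so recovery here bounds estimator correctness, not field
performance.

## Problem sizes and determinism

Default Monte-Carlo runs use 10⁶ histories per radius/geometry (standard
error well under 1 % of the dose); the Lindmo calibration uses 1000 seeded
replicates; the exact-test validation sweeps all 135 751 tables with N ≤ 40.
Every seeded stage writes byte-identical output across repeated invocations
with the same configuration, and report CSVs embed the tool version and a
config digest in a `#` comment line.

## Known limitations

- Organ doses other than blood/marrow/peritoneum require a supplied organ
  TAC; kidney doses are supported only through that generic pathway (their
  source biodistribution is unpublished, so only linearity in administered
  activity is asserted).
- The specific-dose scale depends on unpublished binding/kinetic parameters
  (see above); treat the specific column as model output, not a reproduced
  measurement.
- No relative biological effectiveness weighting, stochastic single-cell hit
  statistics, multi-dose fractionation, or tumor-growth modelling.
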