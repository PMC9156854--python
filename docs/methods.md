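# Methods

## Model

`craydeb` implements the standard Dynamic Energy Budget (DEB) model for
four freshwater crayfish. An individual is a pair of energy pools —
reserve `E` (J) and structure `V` (cm³) — plus two bookkeeping states:
cumulative maturity `E_H` (J), which triggers the life-stage switches, and
a post-puberty reproduction buffer `E_R` (J). Assimilated energy
(`p_A = {p_Am} f L²`, zero before birth) enters the reserve; the mobilized
flux `p_C` is split by the κ-rule: a fraction κ pays volume-linked somatic
maintenance `[p_M]L³` first and growth with the remainder, while 1−κ pays
maturity maintenance `k_J E_H` and funds maturation (or, after `E_H`
reaches the puberty threshold, reproduction). The standard model is
appropriate here because freshwater crayfish hatch as miniature adults:
there is no larval metamorphosis and hence no need for a metabolic-
acceleration extension. No starvation-specific rules are included; at the
constant food levels the package simulates, reserve density equilibrates
at `e = f` and the standard equations remain valid.

Freshwater crayfish are ectotherms, so every rate parameter ({p_Am}, v,
[p_M], k_J, and the ageing acceleration, see below) is multiplied by an
Arrhenius correction `c_T`. Two forms are provided:

* **1-parameter**: `exp(T_A/T_ref − T_A/T)`, valid inside the thermal
  optimum; `T_A` = 8000 K for all four species.
* **5-parameter**: adds boundary temperatures `T_L`, `T_H` and boundary
  Arrhenius temperatures `T_AL` = 18000 K, `T_AH` = 21000 K so that rates
  collapse outside the tolerance range. Two algebraic conventions exist in
  the literature and they disagree by a few percent between the boundaries:
  a *piecewise* form that applies the low-boundary ratio for `T ≤ T_ref`
  and the high-boundary ratio above, and a *combined* single-ratio form
  with both boundary terms in one denominator. Both are implemented and
  selectable everywhere (`ct5_form`); **combined is the default** because
  it reproduces the reference warming-scenario reproduction outputs most
  closely. Note one behavioural difference: in the combined form a species
  whose upper boundary `T_H` sits close to `T_ref` (the noble crayfish)
  gets a numerator boost that can raise `c_T` above the 1-parameter value
  below `T_ref`; the piecewise form is bounded by it.

Food is a scaled functional response `f = X/(X+K_X) ∈ [0,1)`, with the
half-saturation density `K_X = {p_Am}/(κ_X {F_m})`. Values `f > 1` (up to
1.1) are allowed to represent food of above-reference quality. Since κ_X
and {F_m} are not estimable from the available data, they take the
standard defaults 0.8 and 6.5; every cross-species comparison that uses a
shared food density depends only on the {p_Am} *ratio*, which is verified
by a scale-invariance test.

## Parameters

The four species parameter sets (rates at `T_ref` = 293.15 K) ship as YAML
files and load through `load_species`. Males differ from females only in
the assimilation rate and the puberty threshold; the marbled crayfish is
obligately parthenogenetic and has no male set. Auxiliary parameters not
part of the estimated sets take standard DEB defaults: `k_J` = 0.002 1/d,
`κ_R` = 0.95, `s_G` = 0. These defaults are load-bearing for the
reproduction predictions (the published maximum reproduction rates are
reproduced only with exactly these values), so they are fixed defaults
rather than guesses.

The two maturity-at-hatching vs maturity-at-birth thresholds are stored as
`EHh` and `EHb`; the source parameter table prints both under the same
symbol, which we treat as typographical (the first is the hatching
threshold).

Wet weight uses `Ww = d_V V + (w_E/μ_E)(E + E_R)` with `d_V` = 1 g/cm³,
`w_E` = 23.9 g/mol and an *effective* `μ_E` = 93 500 J/mol (the standard
reserve chemical potential 550 kJ/mol times the standard dry structural
density 0.17 g/cm³). This back-derived composition reproduces the
reference ultimate wet weights of all four females to three digits, but
composition was never part of the parameter estimation, so all weight
outputs are flagged composition-dependent.

## Numerics

* **Integration.** `scipy.integrate.solve_ivp` with LSODA, relative
  tolerance 1e-8 (configurable). Birth and puberty switch the right-hand
  side discontinuously (feeding on; maturation rerouted to the buffer), so
  the life cycle is integrated in stage segments: a terminal event stops
  the solver exactly at each maturity threshold and the next segment
  restarts with `E_H` clamped onto it. This keeps every segment smooth —
  integrating across the puberty switch in one pass can stall LSODA in
  micro-steps. A derivative-evaluation budget turns any remaining
  pathological case (reachable from degenerate candidate parameters during
  calibration) into a clean failure.
* **Embryo start.** Structure starts at 1e-9 cm³ instead of 0; the embryo
  equations are regular there (`dL/dt → v/3`) and results are insensitive
  to the epsilon far below 1e-6 cm³.
* **Development delay.** The parameter `t0` is a pre-development delay
  appended before the embryo dynamics and temperature-corrected with the
  same `c_T` as the rates (configurable to uncorrected). All reported ages
  run from egg laying and include it.
* **Egg energy.** `initial_reserve` solves the maternal-effect condition
  (reserve density `f·[E_m]` at the birth threshold) by bracketed `brentq`
  shooting over the embryo system, relative tolerance 1e-8. A brute-force
  bisection oracle over an independent RK45 integration agrees to 1e-6.
* **Constant environments.** Lengths at maturity thresholds are
  temperature-independent and times scale exactly as `1/c_T`, so
  life-history traits are computed once at `T_ref` and rescaled; the
  ageing acceleration is corrected by `c_T²` to keep this rescaling exact.
* **Reproduction rate.** `R_max = c_T κ_R((1−κ)p_C^∞ − k_J E_H^p)/E_0`
  with `p_C^∞` evaluated analytically at the ultimate state (where
  `p_C = p_A`), avoiding integration error at the asymptote; clamped at 0.
* **Puberty-enabling food.** `fp_min` is defined as the smallest constant
  `f` whose maturity asymptote `(1−κ){p_Am} f³ L_m²/k_J` reaches `E_H^p`
  (temperature-independent). The closed form brackets a bisection on
  long-horizon integrations (tolerance 1e-4). A finite-lifespan definition
  (puberty before death) would give somewhat higher values, noticeably so
  for the short-lived marbled crayfish.
* **Lifespan.** The ageing pair `dq/dt = (q(V/V_m)s_G + ḧ_a c_T²) e (v c_T/L − r) − rq`,
  `dh/dt = q − rh` runs from birth (embryonic damage neglected), and the
  reported lifespan is the mean of the death-age distribution, `∫S dt`.
  With `s_G = 0` this gives 9473 d for the stone crayfish at 11 °C — about
  30% above the published 7300 d, which instead matches the thin
  approximation that accumulates damage at the ultimate size from age
  zero. We keep the survival-curve mean as the honest model quantity and
  treat lifespans as indicative only (they also depend on the unestimated
  `s_G`).

## Scenarios

All scenario work uses an average female per species at constant forcing;
the baseline temperature is 12.5 °C (representative of continental
European rivers where all four species occur) and warming increments of
+1.5/+3.0/+4.5 °C span the RCP 2.6–8.5 projections, applied with the
5-parameter correction. Annual reproductive output uses the continuous
convention 365·R_max; the clutch decomposition (stone crayfish: one clutch
every second year; marbled crayfish: five clutches per year; one per year
otherwise) is presentation only and never changes the annual total. The
competition comparison back-solves the shared food density from the
native's `f` = 0.8, translates it through the invader's `K_X` (pure
{p_Am}-ratio effect), and evaluates four scenarios: control, −20% food,
+2 °C, and both. Sweep grids default to 25 points; conditions where
puberty is not reached within the integration horizon are retained with an
explicit flag, and `f` > 1 rows are flagged as extrapolation.

## Synthetic data and calibration

`generate_observations` produces pseudo-observation sets with the
structure of real DEB calibration data — zero-variate traits and
uni-variate curves (time–length, time–weight, length–weight,
length–fecundity), each carrying its own temperature, food level and
weight — from a known parameter set, perturbed by unit-mean multiplicative
lognormal noise of chosen CV (positivity preserved; CV configurable; a
noise-free set equals the model predictions exactly). The default design
mirrors the richest real layout (growth at two temperatures and two food
levels, length–weight, length–fecundity). What the generator does *not*
emulate: serial correlation along growth curves, heteroscedastic
measurement error, size-truncated sampling, or between-individual
parameter variation — so passing recovery tests demonstrate identifiability
under idealized noise, not robustness to real-data pathologies.

`fit_parameters` minimizes the weighted squared relative error with
Nelder–Mead in log/logit-transformed coordinates (bounds enforced by the
transform; unstated bounds default to a factor of 10 around the start
point; one seeded restart). Default weights: 1 per zero-variate record and
1/n per point of an n-point curve, so each dataset counts comparably.
Goodness of fit is reported as MRE (weighted mean |pred−obs|/|obs|;
reported as defined, without clamping, although its nominal description in
the estimation literature is a [0,1] range) and SMSE (weighted mean
(pred−obs)²/(pred²+obs²), genuinely bounded in [0,1]). This is an
intentionally simplified stand-in for the covariation method (no
pseudo-data, augmented loss or parameter filters) meant for recovery
experiments, and the recovery tests use a single-food-level design with
six traits and one growth curve.

## Known limitations

* Individual-level only; no population upscaling, no seasonal phenology
  beyond the development delay, no crayfish-plague dynamics.
* Published stage *ages* (hatch/birth/puberty) for the three Astacidae
  were evidently evaluated at dataset-specific incubation temperatures
  that are not part of the shipped parameter sets; at the species' typical
  temperatures our ages differ from the published ones by 10–45% while all
  lengths, egg energies and reproduction rates agree. The marbled-crayfish
  ages, which are free of this ambiguity, reproduce to three digits.
* The two 5-parameter correction conventions disagree by ~4% at 17 °C for
  the marbled crayfish; outputs that depend on the choice report it.
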