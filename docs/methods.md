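# Methods

## Model structure

Each myosin head interacts with the nearest actin site through a strain
variable `x` (nm), the distance to the site's reference position; heads
are assumed uniformly distributed over one 36 nm site spacing.  Strongly
bound states are Hookean springs of stiffness `k_s = 2.8 pN/nm`; the
weakly (non-stereospecifically) bound state bears no stiffness.  Free
energies are measured in units of `kBT ≈ 4 pN·nm`; every free-energy
difference parameter is stored as `(G_initial − G_final)/kBT`, so a
positive value favours the forward transition.

### Rate laws

* **Weak binding** — `K_w = exp(ΔG_w)` inside the attachment window
  `(−2.8, 18.2)` nm and exactly 0 outside; the window also gates
  attachment and its reversal.
* **Attachment** into the first stereospecifically bound state —
  `k_on(x) = k_on′ exp(ΔG − k_s(x−x1)²/4kBT)` with the half-stiffness
  (single-head) Gaussian penalty; reverse
  `k_on,rev(x) = k_on′ exp(+k_s(x−x1)²/4kBT)`.
* **Pi exchange** with a binding site of dissociation constant `K` —
  strain independent, first-order off-rate `k_p+`, pseudo-first-order
  rebinding `k_p+·[Pi]/K`.
* **Power-stroke** — constant reverse rate `k_LH− = 2000 s⁻¹`; the forward
  rate carries the full free-energy difference between the parabolas at
  `x1` and `x2` (detailed balance by construction).
* **Active-site → secondary-site Pi shift** — a symmetric Boltzmann
  split: half of `ΔG_PiR` and half of the strain-energy difference
  between the parabolas at `x_w` (pre-power-stroke state) and `x1`
  (Pi-release state) enter the forward and backward exponents with
  opposite signs, so the ratio equals the full free-energy drop.
* **ADP release** — `k_5(x) = k_5′ exp(ΔG_AMDH-AM + k_s(x−x2)²/2kBT −
  G_AM(x))`, irreversible (MgADP ≈ 0; AM and AMD lumped).
* **Rigor force law** — `F_AM` is continuous piecewise linear in
  `ξ = x − x3` with configurable breakpoints/slopes and `F_AM(0) = 0`;
  `G_AM(x)` is its stored elastic energy `∫₀^ξ F_AM dξ′ / kBT`, the
  orientation that makes `G_AM ≥ 0` with minimum 0 at `x3`.
* **ATP-induced detachment** — Michaelis-type in [MgATP] with
  `k_2(x) = k_2(0)·exp(|F_AM|·x_crit/kBT)`.

After formula evaluation every rate is clamped into
`[r_min, r_max]` (`r_min = 10⁻⁶ s⁻¹`; `r_max = 10⁵ s⁻¹` for isometric
work, configurable `10⁶–10⁸ s⁻¹` for shortening) before any solver sees
it; detailed-balance diagnostics use the unclamped values.

### Free-energy profile conventions

Levels are chained from MDP = 0 through the ΔG parameters; the gap
between the primed (Pi on the secondary site) and unprimed rows carries
the mass-action term `ln([Pi]/K_C)`.  The printed forward/backward forms
of the Pi-shift step are detailed-balanced only if the pre-power-stroke
state's parabola sits at `x_w` and the Pi-release state's at `x1`, while
the attachment pair places the pre-power-stroke minimum at `x1`; the
profile therefore assigns `x_w` to AMDP_PP and `x1` to AMDP_PiR/AMDP′_L,
and the attachment pair is evaluated exactly as written without a
detailed-balance guarantee (the consistency tests cover the attachment,
power-stroke and Pi-shift pairs the landscape can support
simultaneously).

### Scheme variants

`A_beforePS` (release before the stroke via the transient AMDP_T state),
`B_afterPS` (release after the stroke; AMDP_L/AMDP_H replace
AMD_L/AMD_H), `C_beforePS_PiR`/`D_afterPS` (with the pre-power-stroke
AMDP_PP and, in C, the Pi-release AMDP_PiR state; detached and weak
states lumped into MDP), and `E_twostep` — the two-step-release scheme
whose primed row (AMDP′_L, AMDP′_H, AM/AMDP′, MTP′) is mechanically
identical to the unprimed row: the power-stroke transitions of the two
rows reference the same rate functions, Pi is released from every primed
state at the same `k_p+`, and Pi loss from MTP′ is rapid and
irreversible.

## Steady state, transients, observables

Steady shortening solves `da_j/dx = (Σ in − Σ out)/v` from `x = 14 nm`
downward (attached states empty, MT/MDP at their chemical equilibrium at
the start), with an adaptive implicit stepper (LSODA, rtol 10⁻⁸,
atol 10⁻¹²) and a fixed 721-point output grid over `[−22, 14]` nm
(0.05 nm spacing, resolving the steep exponentials near `x3`).  Mean
force, stiffness, attached fraction and ATPase are trapezoid strain
averages over the 36 nm spacing; the ATPase integrand pairs the
detachment rate function with the occupancy of the high-force states
(AMD_H + AMDP′_H), as the model defines it.  `⟨Na⟩` counts
stereospecifically bound states only, so the quantity is comparable
across variants (the weak state is lumped with detached states in
C/D/E).  Unloaded velocity is found by bisection of `⟨F⟩(v)` to
|⟨F⟩| < 10⁻⁴ pN.  Only shortening (v > 0) is supported.

The zero-load power-stroke protocol starts all probability in the first
strongly bound pre-stroke state, disables reverse attachment and every
transition out of detached states, sets [MgATP] = 10 nM, and evaluates
each remaining rate at the origin state's zero-force strain.  The mean
displacement ΔL(t) sums each attached state's zero-force position
relative to the entry state over the not-yet-recycled ensemble (the
MT-like end states are excluded from the normalisation; the
displacement weights sit on the post-stroke states, which keeps ΔL
nondecreasing and bounded by the total stroke distance).

Isometric contraction is not computed from the strain-resolved equations
(singular at v = 0); a fixed-strain compartment model built from the
two-step scheme's rate functions at `x11` (default `x1`) handles it,
with the end-of-stroke pathway lumped into a single detachment rate
`k_det` back to MT.  Its steady state is the null space of the rate
matrix; with `k_det = 0` the scheme is fully reversible and the null
space is the equilibrium distribution the long-time ODE solution
approaches (verified to 10⁻⁸).  Pi jumps switch the pseudo-first-order
rebinding rates from the pre-jump steady state; force is
`k_s·(P(AMD_H) + P(AMDP′_H))`.  The transient is integrated with the
RK45 4(5) embedded pair (rtol 10⁻⁸, atol 10⁻¹²); the pre-jump
equilibration uses the LSODA stiff stepper in chunks with an explicit
convergence check.  The two-secondary-site variant inserts the outer
site (dissociation constant `K_C″`) into the high-force exchange edge;
thermodynamic consistency of the exchange cycle fixes the
inner-to-outer transfer equilibrium at `K_C/K_C″`.

Tension transients are fitted with
`baseline + A(1 − exp(−k(t − Δt)))` for `t > Δt`; Δt is a free
parameter bounded to [0, 5 ms] (the experimentally relevant sub-ms
regime) with multi-start over Δt to avoid the kink's local minima.

Sensitivities are the dimensional ratios `S_ij = Δy_j/Δp_i` for ±10%
parameter perturbations, reported per direction; perturbations that
violate parameter invariants are flagged per cell.

## Reference parameter set

The printed constants are fixed: `k_s = 2.8 pN/nm`, `kBT = 4 pN·nm`,
`k_LH− = 2000 s⁻¹`, window `(−2.8, 18.2)` nm, averaging `(−22, 14)` nm,
site spacing 36 nm, caps as above, `k_p+ = 80 s⁻¹` (mid of the
experimental 40–120 s⁻¹ range) for the slow-release schemes B and E.
The remaining values are this package's own calibrated choices, selected
once so that the two-step scheme shows the model family's characteristic
behaviour and then frozen:

* `x1 = 7.7`, `x2 = 0.7`, `x3 = −0.3`, `x_w = 8.7` nm — a 7 nm main
  stroke plus a 1 nm sub-stroke entering the release state.
* `ΔG_LH = 22`, `ΔG_on = −3`, `ΔG_PiR = −1.4` (kBT) — the net depth of
  the post-stroke well at `x1` is then ≈ 0.5 kBT below the detached
  level, inside the ±5.5 kBT mass-action swing that 0.1–25 mM Pi
  produces, which is what makes the fixed-strain isometric force fall
  monotonically (≈1.9-fold) over that range while Vmax is exactly
  [Pi]-invariant (both state rows are mechanically identical).
* `k_on′ = 2·10⁴ s⁻¹`, `k_Pr′ = 6·10⁴ s⁻¹` — fast attachment-gate
  kinetics; these set the sub-millisecond Pi-transient lag and push the
  one-site k_Pi saturation far beyond 10·K_C.
* `K_C = 3 mM` (secondary site), `K_C″ = 0.3 mM` (outer/surface site),
  transfer equilibrium `K_C′ = 10`.
* `k_5′ = 5 s⁻¹`, `k_2(0) = 1000 s⁻¹`, `k_6 = 10⁴ s⁻¹`, `K_1 = 2·10³
  M⁻¹`, `x_crit = 2 nm`; `F_AM` slopes 1.0 (compression) / 2.8
  (extension) pN/nm.
* Per-variant overrides (mirroring the use of separate parameter tables
  per scheme): A/B use the weak *active-site* Pi dissociation constant
  `K_C = 40 mM`, a small reverse-attachment prefactor
  (`k_on′ = 0.003 s⁻¹` with `ΔG_AMDP-AMDL = 12.4`, so `k_on(x1) ≈ 730
  s⁻¹`) and the 10⁸ s⁻¹ shortening cap; A and C release Pi rapidly
  (`k_p+ = 3000 s⁻¹`).  The small reverse-attachment prefactor is what
  makes variant B's velocity collapse under slow after-stroke release
  (escape through reverse attachment inside the window stripe is then
  weak), and the weak active-site constant keeps variant A's Vmax
  [Pi]-flat (<5% over 0.1–25 mM).

All of these are overridable from TOML/JSON parameter files; unknown
keys are rejected.

## Synthetic-data generators

The generators emulate the statistical structure of the two experiment
families and are fully deterministic under a fixed seed (integer-seeded
`numpy` Generator streams, salted per product so different products from
one spec are independent).

* **Dwell events** — per-spot event counts are Poisson with mean
  `events_per_spot × occupancy([Pi])`, where the occupancy is the
  two-site Hill competition `1 − f1·H(Kd1) − f2·H(Kd2)` (presets
  `Kd1 = 0.3`, `Kd2 = 16 mM`, equal fractions, Hill coefficients 1);
  durations are drawn from a three-phase exponential mixture (presets
  0.05, 0.35, 3.5 s⁻¹ with fractions 0.45/0.35/0.20).  Increasing [Pi]
  scales the amplitudes, not the rates.  Dwells longer than the 15 min
  observation window are dropped (the assay cannot see them); start
  times are uniform subject to the event ending inside the window.
* **Hotspot counts** — expected `N(0)·occupancy` with Poisson noise
  (`N(0) = 51`).  For noisy-recovery checks the counts are normalised by
  the control *expectation*; normalising by a single noisy control draw
  adds a common multiplicative error that biases the small dissociation
  constant downward.
* **Angles** — per-condition Gaussian mixtures (presets: one component
  51.0° ± 13.42° for ADP; two components 68.6° ± 13.8° / 99.2° ± 6.7°
  for ADP-metavanadate and 53.6° ± 8.3° / 87.7° ± 16.6° for ADP-PAB),
  clipped to [0°, 180°].

What the generators do **not** emulate: photophysics (blinking,
bleaching), spot-detection errors, per-spot intensity heterogeneity (a
gamma-mixing option exists conceptually but is off), dwell-time
censoring correlations, or AFM image segmentation errors.  Passing
recovery tests therefore demonstrates estimator correctness under the
assumed data-generating process, not robustness to those artefacts.

## Fitting pipelines

* **Cumulative dwell-time distributions** are survival curves
  `C(t) = #{dwell ≥ t}` (the form a sum of decaying exponentials fits
  directly; an ascending-CDF option exists).  Mixtures of 1–3
  exponentials are fitted by bounded least squares with Poisson (1/√C)
  weights and multi-start log-spaced rate initialisation; 95% CIs come
  from the Jacobian covariance approximation, and a fit is flagged
  *ambiguous* when the covariance is not computable or a rate's CI
  exceeds the rate itself.
* **Model order** is chosen by AICc with a fall-back to the simpler
  model for ambiguous fits and ties.  Because the survival-curve
  residuals are strongly serially correlated, a Gaussian AICc over the
  support points systematically over-selects higher orders; the AICc is
  therefore computed from the exponential-mixture log-likelihood of the
  raw durations at the fitted parameters (sample size = number of
  dwells).  The Gaussian curve-fit AICc remains the fallback when only
  a cumulative curve is available, and a censor-aware maximum-likelihood
  fit (`fit_mle`) is provided as a cross-check.
* **Hotspot counts vs [Pi]** are fitted with
  `1 − f1·[Pi]ⁿ/(Kd1ⁿ+[Pi]ⁿ) − f2·[Pi]ⁿ/(Kd2ⁿ+[Pi]ⁿ)` (Hill
  coefficients default 1, fractions bounded to [0,1] with a soft
  `f1+f2 ≤ 1` penalty), multi-start over log-spaced constant pairs,
  optional per-point weights and an outlier-exclusion mask.  Count
  errors are √N (Poisson).
* **Angle distributions** are fitted as 1- or 2-Gaussian curves on 5°
  histograms by unweighted least squares (r² against the binned counts,
  the standard curve-fitting definition), with a sample-space
  maximum-likelihood mode tested for agreement.  Angles are plain reals
  on [0, 180]; the observed modes are far from wrap-around, so no
  circular statistics are used.  Peak separations are
  `μ_high − μ_low ± √(σ_high² + σ_low²)`.

## Problem sizes and numerical choices

The test suite and acceptance script run the dwell-time analyses at
N = 745 events (20 seeds), the Hill fits on 10–12 concentration points
spanning 0.05–43 mM, angle fits at the per-condition event counts
(848/642/339), steady-state solves on the 721-point grid, and transient
fits on 1001–4001-point traces over 0.2 s.  Velocity bisection uses the
bracket (20–60000 nm/s) and |⟨F⟩| < 10⁻⁴ pN.  Degenerate inputs
(flat transient traces, empty datasets, singular fits) return flagged
results or warnings rather than raising wherever the pipeline can
meaningfully continue.

## Known limitations

* The strain-resolved solver supports shortening only; lengthening
  protocols and length-step (T1/T2) or temperature-jump transients are
  out of scope, as are filament compliance and stochastic
  (finite-ensemble) effects.
* The isometric compartment scheme is a single-strain approximation;
  its occupancy force (`k_s × occupancy`) is a relative measure, not
  the strain-averaged ensemble force.
* The ATPase observable follows the model's printed definition (the
  detachment rate paired with high-force-state occupancy) and is best
  read as a relative, not absolute, turnover measure.
* Parameter values beyond the printed constants are a calibrated
  reference set, not fitted estimates; all are config-overridable.
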