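# Methods

## The model

`cicrsim` integrates a stochastic reaction–diffusion description of
calcium-induced calcium release (CICR) in a ventricular cardiac myocyte,
resolving the cytosol and the sarcoplasmic reticulum (SR) as two spatially
coextensive compartments on the same 2-D (or 1-D) grid.

**Cytosol.** Free Ca²⁺ `C(x, y, t)` obeys

    ∂C/∂t = D_C ∇²C + J_dye + J_buffer − J_pump − kC + J_CRU + k_f C_S

with Fickian diffusion, exchange with a mobile fluorescent indicator
(fluo-3) and an immobile endogenous buffer, SERCA re-uptake
`J_pump = V_pump C^n_pump / (K_pump^n_pump + C^n_pump)`, a linear efflux to
the extracellular space (`k`), a passive SR leak into the cytosol
(`k_f C_S`), and release through Ca²⁺ release units (CRUs). Bound dye
`[CaF]` diffuses and obeys its own transport equation (binding kinetics
`k_f⁺, k_f⁻`, total `[F]_T`); bound buffer `[CaB]` is immobile and obeys the
mass-action ODE `d[CaB]/dt = k_B⁺ C([B]_T − [CaB]) − k_B⁻ [CaB]`, with
`J_buffer = −d[CaB]/dt` and the analogous definition for `J_dye`.

**SR, basic variant.** SR free Ca²⁺ `C_S` diffuses (D_CS), receives what the
pump removes from the cytosol, and loses the leak `k_f C_S` and the release
`J_CRU`. The basic variant carries no SR dye or buffer pools, so the SR
equation's dye/buffer exchange terms vanish identically. (An alternative
reading that re-uses the *cytosolic* dye/buffer fluxes in the SR balance is
available as `sr_dye_buffer="cytosolic"`; it drains the SR roughly 100 µM
deeper over a 300 ms wave and is not the default because the far-field SR
minima it produces are inconsistent with a leak-dominated SR, which the
default reproduces.)

**SR, improved variant.** The SR additionally carries a mobile low-affinity
dye (fluo-5N, `D_F`, `K_F⁺/K_F⁻`, total `[F]_T_SR`) and an immobile buffer
(calsequestrin, `K_CSQ⁺/K_CSQ⁻`, total `[B]_T_SR`), and is drained through
an RyR flux proportional to the local concentration difference,

    J_RyR = I_RyR / (2 F_c Δx Δy) · (C − C_S)   at open release sites,

which is negative during release (the SR sits far above the cytosol) and
self-limits as the compartments equilibrate. The cytosolic deposition keeps
the σ-based `J_CRU` form below; a mass-conserving alternative in which the
cytosol gains exactly `−J_RyR` is available as `cytosol_release="ryr"`.

**Release units.** CRUs sit on a regular lattice (2 µm longitudinally,
0.8 µm transversely, grid-aligned, boundaries included). Each unit is an
atomic stochastic source: closed units fire as a Bernoulli trial per time
step driven by local Ca²⁺ through the saturating rate
`P(C) = P_max C^n_prob / (K_prob + C^n_prob)` (the sensitivity constant
enters un-exponentiated, exactly as the source model prints it; a
`kprob_hill` switch restores the `K^n` form). A fired unit stays open for
`T_open` and then closes permanently (absorbing — one wave per run). Two
firing rules are provided because the source texts state both:

* `firing_rule="rate"` (default): fire when `u < P(C)·Δt`. This is the
  units-consistent reading; per-step firing probability scales with the
  step size.
* `firing_rule="literal"`: fire when `u < P(C)/P_max`. This ignores Δt (the
  effective rate is grid-dependent) but is the comparison the source text
  spells out, and it is the regime in which essentially every unit fires
  during a run.

With the standard `P_max = 0.3 s⁻¹`, the rate rule fires only a handful of
units per run; the published basic-model wave values correspond to that
regime. The published improved-model levels correspond to widespread
firing, so the improved-model scenario presets use the literal rule. Both
rules are exposed on every entry point.

**Open-channel source.** The molar flux of one open channel is
`σ₃ = I_CRU/(2F_c)`, converted internally to 103.63 µM·µm³·ms⁻¹ for
`I_CRU = 20 pA`. Representing a 3-D point source on a 1-D line or 2-D sheet
requires a dimensional adjustment: σ₁ = 0.19 σ₃ and σ₂ = 0.51 σ₃ (adopted
as fixed constants). On the grid each Dirac delta is realised as a point
deposition of σ divided by the cell measure (Δx in 1-D, ΔxΔy in 2-D) into
its containing node — no kernel spreading.

**Source floor.** In 2-D the printed sink magnitude σ₂/(ΔxΔy) demands
~4955 µM from an SR cell that holds 640 µM over one 10-ms opening, which no
positive concentration field can supply. The SR-side withdrawal is
therefore floored at half the locally available content per step; the floor
is inactive in 1-D, where demand stays below content, and the cytosolic
deposition is never reduced (the release current is set by `I_CRU`).

## Parameters

Defaults are the standard diseased-myocyte set: diffusivities
`D_C = 200`, `D_D = 20`, `D_CS = 12`, `D_F = 1.6` µm²/s; resting levels
0.1 µM (cytosol) and 640 µM (SR; 954 µM in the improved variant); SERCA
`V_pump = 0.208 µM/s`, `K_pump = 0.184 µM`, `n_pump = 3.9`; leaks
`k = 10 s⁻¹`, `k_f = 1 s⁻¹` (8 and 0.25 in the improved variant); gating
`P_max = 0.3 s⁻¹`, `K_prob = 15 µM`, `n_prob = 1.6`; fluo-3
`k_f⁺ = 80 (µM s)⁻¹`, `k_f⁻ = 90 s⁻¹`, 50 µM total; endogenous buffer
`k_B⁺ = k_B⁻ = 100`, 123 µM total; fluo-5N `K_F⁺ = 48.8 (µM s)⁻¹`,
`K_F⁻ = 19520 s⁻¹`, 20 µM total; calsequestrin `K_CSQ⁺ = 100 (µM s)⁻¹`,
`K_CSQ⁻ = 60000 s⁻¹`, 0.014 µM total; `I_CRU = 20 pA`, `I_RyR = 0.07 pA`.
`T_open` is not fixed by the source material; the default is 10 ms, the
standard value in this model lineage, and it is configurable. The Hill
exponents are treated as dimensionless.

Everything is stored in the units above and converted once, at
`ModelParams.internal()`, to a uniform µM/µm/ms system (all per-second
rates divided by 1000). Nothing else in the package touches units, and only
`cru_source_strength` touches Faraday's constant.

Neither resting state is an exact fixed point of the pump/leak terms: the
SR bleeds into the cytosol on the `1/k_f` timescale and the cytosol settles
toward `k_f C_S / k`. No rebalancing is applied — the model runs as
formulated and the drift is part of the pre-initiation baseline. This
drift, not wave propagation, dominates the far-field cytosolic levels of
the basic-model runs under the default firing rule.

## Numerics

* Grid: 100 × 20 µm, Δx = 0.4 µm, Δy = 0.8/3 µm, Δt = 0.003125 ms
  (all configurable; extents, channel spacings and mesh must be
  commensurate). x is longitudinal — the only assignment under which the
  channel spacings and the 9.6 µm transverse probe offset are integer
  multiples of the mesh.
* 1-D PDEs: Crank–Nicolson; the linear decay (k or k_f) is time-centred
  (half explicit, half implicit on the diagonal); all nonlinear reaction
  terms are evaluated at time n and applied with weight Δt.
* 2-D PDEs: Peaceman–Rachford ADI — an x-implicit/y-explicit half sweep
  then the transpose — with the decay on each sweep's implicit diagonal and
  the lagged reaction bundle split half per sweep. On y-uniform data with
  zero decay the step reduces exactly to Crank–Nicolson per x-slice.
* Immobile buffers: forward Euler. The fastest explicit coefficient at the
  default step is `K_CSQ⁻Δt ≈ 0.19`, comfortably stable;
  `validate_stability` warns when any explicit coefficient exceeds 0.5 or
  when `P_max·Δt` exceeds 1.
* Boundaries: zero flux via mirror ghost nodes (second order). With
  trapezoid cell weights (boundary nodes own half cells) both schemes
  conserve the discrete integral exactly when decay and sources vanish;
  the test suite checks 1e-10 over 1000 steps and second-order spatial
  convergence on a Gaussian benchmark.
* Update order per step: (1) gate update from the current cytosolic field,
  (2) assemble all reaction fluxes at time n, (3) implicit sweeps for the
  mobile species, (4) Euler for the immobile buffers, (5) bounds
  enforcement. Round-off excursions below 10⁻⁹ µM outside [0, total] are
  clipped; anything larger aborts the run as a stability failure.
* Each implicit sweep is one tridiagonal solve (Thomas algorithm, O(n)),
  delegated to LAPACK's `gtsv`.
* RNG: one PCG64 stream per run; one uniform per channel per step in fixed
  row-major channel order, so trajectories are bit-reproducible for a given
  seed independently of vectorisation.

## Probes and observables

Sensors record nearest-node values each sampling stride (default every 10
steps). The nodal value *on* a point-deposited Dirac source is
mesh-dependent (it grows without bound as the cell measure shrinks), so by
default a probe whose node falls on a release-unit column — including the
two forced-initiation columns at the domain centre — is shifted half a
channel spacing away and records the concentration between release sites
(`sensor_mode="between_sites"`; `"literal"` disables the shift). The
default layout is the published seven-probe arrangement: the far boundary,
symmetric pairs 25 and 38 µm either side of the centre, 1 µm short of the
centre, and the initiation site itself, with a 9.6 µm transverse offset in
2-D.

Derived quantities: per-sensor cytosolic peaks and SR troughs; normalised
fluorescence `F/F₀ = [CaF](t)/[CaF](0)` (bound dye is the only fluorescent
species); SR blink amplitude `|min ΔF/F₀|`; SR depletion (rest minus
trough); wave speed from a least-squares fit of distance-from-source
against half-peak arrival times (absent, not zero, for flat traces);
termination time as the last instant any sensor exceeds rest plus 10 % of
its own peak excursion. Paired runs are compared per sensor and in
aggregate (suppression %, depletion change and ratio, trough discrepancy,
termination ratio); both the sensor-mean and worst-case suppression are
reported because the published figure does not say which it is.

## Study conditions

The scenario presets reconstruct the published configurations: the basic
coupled model in 1-D and 2-D over 300 ms (long enough for the forced
release to traverse the half domain and for every sensor to pass its SR
minimum; the SR leak time constant puts the published far-field minima at
≈0.3 s), and the improved model over 550 ms. The acceptance script runs
the 2-D comparison on a half-resolution mesh (Δx = 0.5 µm, Δy = 0.4 µm,
Δt = 0.0125 ms — the nearest coarsening that keeps mesh, channel lattice
and probe offset commensurate) and averages every reported quantity over
five seeds.

## Fixtures

The fixture generator builds miniature synthetic scenarios — a 10 µm
domain at production resolution, a near-single-channel lattice, Gaussian
initial profiles with closed-form references, and detailed-balance
equilibrium states. These exercise every code path in seconds but do not
emulate real line-scan data: no photon noise, no optical blurring, no
motion, and a wave in a 10 µm box never develops the published far-field
structure. Passing tests demonstrate numerical and statistical
correctness of the implementation, not fidelity of the model to
experimental recordings.

## Known limitations

* With the published fluo-3 kinetics (K_d ≈ 1.1 µM) and 0.1 µM resting
  Ca²⁺, any excursion above a few µM saturates the dye, so simulated
  cytosolic F/F₀ peaks reach ≈ 11–12. Experimentally reported spark F/F₀
  values of ≈ 1.5–2 are not reproducible from these constants together
  with peak Ca²⁺ in the tens of µM; the package reports what the equations
  give.
* The two firing-rule readings cannot be reconciled into a single
  configuration that reproduces every published number; see the gating
  section above for which preset uses which.
* Closure is absorbing; repeated waves, L-type pulse trains, 3-D domains
  and anomalous (fractional) diffusion are out of scope.
* The basic 2-D variant is only integrable at all because of the SR source
  floor; bulk SR depletion in 2-D is therefore bounded by the physically
  available content, and the simulated 1-D/2-D SR discrepancy (≈10–13 µM)
  is well below the published ~40 µM, which would require overdrawing the
  SR below zero.
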