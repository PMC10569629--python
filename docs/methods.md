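# Methods

`tfsupport` models how harvesting the semitendinosus (ST) and gracilis (GR)
tendons for an ACL graft changes each knee muscle's contribution to
frontal-plane support of the medial and lateral tibiofemoral compartments
during 45° sidestep cutting. It pairs an EMG-driven Hill-type
muscle-tendon pipeline (standard model → morphology-adjusted model →
compartment decomposition → statistics) with a synthetic-cohort generator so
that every stage is testable without laboratory data.

## Muscle-tendon model

Each of the 34 muscle-tendon units (MTUs) is a contractile element in series
with a compliant tendon.

**Activation dynamics.** A normalised EMG linear envelope `e(t)` passes
through a discrete second-order recursive filter

    u(t) = α e(t − d) − β₁ u(t − Δt) − β₂ u(t − 2Δt),
    β₁ = C1 + C2,  β₂ = C1·C2,  α = 1 + β₁ + β₂,

which has unit DC gain by construction; `d` is the electromechanical delay
(default 15 ms) rounded to samples. Stability requires |C1|, |C2| < 1. The
activation nonlinearity is `a = (e^{Au} − 1)/(e^A − 1)` with shape factor
`A ∈ [−3, 0)`; it maps 0→0 and 1→1 exactly for every admissible `A`.

**Normalised curves** (pluggable `HillCurves`): active force-length
`f_a = exp(−(l̃−1)²/γ)` with `γ = 0.45`; passive
`f_p = (e^{4(l̃−1)/0.6} − 1)/(e⁴ − 1)` for `l̃ > 1`, else 0; force-velocity a
Hill hyperbola on the shortening side (`f_v(−1) = 0`, `f_v(0) = 1`,
curvature 0.25) with a saturating eccentric branch (plateau 1.4,
half-saturation 0.3); `v_max = 10` optimal lengths/s. Tendon: quadratic toe
`f_t = 1480.3 ε²` for `0 < ε < 0.0127`, then linear
`f_t = 37.526 ε − 0.2375`, zero at or below slack; `f_t ≈ 1` at ε ≈ 3.3%.
A `tendon_stiffness_scale` compresses the strain axis (all slopes multiply),
which gives a numerically clean near-rigid-tendon limit.

**Compliant-tendon equilibrium.** At every frame the normalised fibre length
`l̃` solves

    (a·f_a(l̃)·f_v(ṽ) + f_p(l̃))·cos φ(l̃) = f_t(ε(l̃)),

with constant-thickness pennation `φ = asin(sin φ₀ / l̃)`, tendon length
`l_t = L_MTU − l_m cos φ`, and an implicit backward-difference fibre velocity
`ṽ = (l̃ − l̃_prev)/(v_max Δt)` (first frame isometric). The strength
coefficient and `F_max` multiply both sides and cancel, so the fibre state is
independent of them and `F_MTU = s·F_max·f_t(ε)` is exactly linear in the
strength coefficient `s` — the property the calibration exploits. The root is
found by a bracket-safeguarded Newton iteration on
`l̃ ∈ (sin φ₀ + 10⁻⁶, 2]` with analytic derivatives; steps leaving the
bracket are clamped just inside the violated edge (the stiff force-velocity
branch makes plain Newton overshoot), and an element is converged when its
residual is below 10⁻¹² or its bracket has collapsed below 10⁻¹¹ — several
orders below the 10⁻⁸ agreement the tests demand against an independent
bisection oracle. No root in the bracket raises an error carrying the frame
index. A per-frame equilibrium with finite-difference velocity (rather than a
stiff ODE) is adequate at 100 Hz kinematics and is directly checkable against
the oracle.

## Geometry surrogates

Muscle paths are summarised per MTU by polynomial moment arms: the arm about
each spanned DOF (hip adduction HAA, hip flexion HFE, knee flexion KFE, ankle
dorsiflexion AFE; adduction/flexion/dorsiflexion positive) is a polynomial in
that DOF's angle, and the MTU length is the neutral-pose reference length
minus the arm integrals, so `r = −∂L/∂q` holds analytically. The shipped
34-MTU table (16 EMG channels; deep muscles driven by a synergist's channel)
is a set of synthetic defaults informed by published lower-limb anatomy — it
is not fitted to any subject, and same-channel muscles were deliberately
given distinct arm curvatures so their strength coefficients remain
identifiable. Frontal-plane knee loading per MTU uses a medio-lateral
line-of-action offset `z_F(q_KFE)` (lateral positive) and an axial-force
fraction `c_ax(q_KFE) ∈ [0,1]`:

    F_ax = c_ax·F_MTU,   M_k = −F_ax·z_F   (varus positive).

Moments about the condylar contact points at `∓d` from the knee centre
(default `d_med = d_lat = 22.5 mm`, scaled with the shank):

    M_med = M_k − F_ax·d_med,   M_lat = M_k + F_ax·d_lat,

applied identically to muscle and external loads (the external axial
intersegmental force can be excluded by flag). Compression therefore loads
both condyles — valgus about the medial point, varus about the lateral one —
and a medial muscle whose force line lies *inside* the condylar spacing
(|z_F| < d_med) supports both compartments, which is why the medial
hamstrings' offsets are 12–20 mm.

**Anatomical scaling.** Linear scaling multiplies reference lengths, arm
coefficients, `l_m^o` and `l_t^s` by each MTU's span-fraction-weighted
segment factor (frontal offsets and condylar spacing follow the shank).
`optimize_fiber_tendon_lengths` then refines `(l_m^o, l_t^s)` per MTU so the
normalised fibre length and tendon strain at a reference activation
(`a = 0.5`, isometric) match the generic model over a ≥20-pose grid spanning
the physiological ranges, with the MTU rest length constrained within 1% of
its linearly scaled value; non-convergent MTUs fall back to linear scaling
(logged). Under uniform scaling the refinement reproduces proportional
lengths exactly.

## Signals

All filters are 2nd-order Butterworth applied forward and backward
(zero-phase; the double pass squares the magnitude response), with
odd-reflection padding of three filter lengths so outputs are bit-exact
reproducible. EMG: band-pass 30–500 Hz, full-wave rectification, 6 Hz
low-pass, then division by per-channel MVC maxima with above-1 clipping
(counted and logged). Mechanics channels use a 10 Hz low-pass. Stance-phase
curves are linearly resampled onto a 101-point 0–100% grid (the gait-analysis
convention), which is idempotent on resampled data. Time series are exchanged
in the tab-separated `.sto/.mot` dialect (`key=value` header, `endheader`,
`time` first column).

## Calibration

The closed-loop calibration minimises

    Σ_trials Σ_DOF Σ_t (M_pred − M_exp)² / (N_t·Var(M_exp,DOF))
      + λ Σ_MTU Σ_t [(max(0, l̃−1.5))² + (max(0, 0.5−l̃))²],   λ = 10,

over one walk + one run + one sidestep trial, four DOF (HAA, HFE, KFE, AFE).
Variance normalisation balances DOF of different magnitude; the quadratic
window keeps fibres in the physiological range 0.5–1.5 `l_m^o`. Because
predicted moments are linear in the strength coefficients (equilibrium
invariance above), the search splits into:

* an **inner bounded linear least-squares solve** for all adjustable strength
  coefficients (bounds [0.5, 2.5]), and
* an **outer seeded global-then-local search** over the shared
  activation-dynamics constants `(C1, C2, A)` (bounds C ∈ [−0.95, −0.01],
  A ∈ [−3, −10⁻³]): uniform multi-start, Powell refinement, and an optional
  high-precision simplex polish used by parameter-recovery experiments —
  the strength solve amplifies small activation-constant errors, so recovery
  to a few percent needs the constants to ~10⁻⁴.

`(C1, C2)` are exchangeable in the recursion, so they are recovered up to
permutation. Optionally, per-MTU `(l_m^o, l_t^s)` are refined within ±5% by
coordinate descent (`AdjustableSpec.adjust_fiber_tendon`); this stage is off
in cohort runs because it multiplies run time roughly tenfold for a small
tracking gain at the cohort's ±3% length perturbations. MTUs in the `fixed`
set keep every parameter bit-identical (verified by hashing). Calibration
never returns a model whose objective exceeds the incoming model's, and is
bit-reproducible given (seed, inputs). Default effort per calibration in
cohort runs: 4 starts, 60 Powell evaluations; recovery experiments use 5
starts, 120 + 250 evaluations.

## Morbidity adjustment

MRI ratios of the surgical to contralateral donor muscle map onto the Hill
parameters as: strength × CSA ratio (force ∝ cross-section), optimal fibre
length × volume/CSA ratio (volume = area × length), and tendon slack length
chosen to preserve the MTU rest length `l_m^o cos φ₀ + l_t^s` exactly — the
path and the normalised tendon curve (hence its normalised stiffness) are
unchanged. Each mapping is a pluggable strategy; a multiplicative slack-length
variant can be swapped in. A donor without tendon regeneration transmits no
force: its strength coefficient is set to zero (force transmission through
scar tissue into the semimembranosus fascia is deliberately not modelled).
In one-tendon subjects the regenerated donor is adjusted and the other
zeroed. The adjusted donors are then fixed and the remaining 32 MTUs
recalibrated against the same trials, warm-starting at the standard model's
activation constants with no global restarts, so the adjusted-vs-standard
difference reflects the donor adjustment rather than optimizer basin hopping.

## Outcomes and statistics

Per-muscle compartment moment curves from each sidestep trial are
time-normalised to the 101-point grid and averaged within subject, then
summarised as **contributions to muscular support**: the supporting direction
of a compartment is the sign of its stance-averaged net muscle moment (valgus
medially, varus laterally in cutting), and each muscle receives the
percentage of the total supporting-direction moment it produces at each
point; opposing muscles get negative percentages, so supporting muscles sum
to exactly 100% at every unmasked point (points with no supporting moment are
masked and logged). Stance-average contribution is the mean of the pointwise
percentages (a time-integrated-moment-ratio alternative is a flag), and the
peak moment is the signed extremum of largest magnitude. The
muscle-generated knee-flexion moment reported for the regeneration contrast
is the stance-averaged flexor-direction sum (positive per-muscle KFE
moments), in N·m/kg.

Standard vs adjusted comparisons use a two-level repeated-measures design —
equivalent to a paired t-test (F = t²) — plus uncorrected point-by-point
paired t-tests along the stance grid (a Bonferroni flag exists); the tendon
regeneration contrast (none vs both; one-tendon subjects described but
excluded) is a pooled-variance two-sample t-test. Degenerate cases (zero
difference variance) are flagged rather than reported as spurious
significance. Averaging order: per-trial curves → subject mean → group
statistics.

## Synthetic cohort

The generator emulates the study conditions: 18 subjects (mass 82 ± 16 kg),
four 45° sidestep trials plus one walk and one run trial each, stance
0.25–0.35 s (walk 0.34–0.38 s, run 0.22–0.26 s) at 100 Hz, 16-channel EMG at
2000 Hz, and the 7 both / 5 one (4 GR, 1 ST) / 6 none tendon-regeneration
split (proportionally rescaled for other cohort sizes). Ground truth per
subject: segment scales N(1, 0.03²) clipped to [0.9, 1.1], strength
coefficients U[0.8, 1.5], `l_m^o`/`l_t^s` jitter ±3%, subject-level
C1/C2 ~ U[−0.5, −0.05] and A ~ U[−2.5, −0.5], per-channel MVC maxima.
Donor morphology: contralateral ST ≈ 220 cm³ / 11 cm², GR ≈ 100 cm³ /
5.5 cm² (±15%), with volume deficits 35% ± 8% and CSA deficits 30% ± 8%
truncated to (0, 60%). The truth semimembranosus strength carries a
regeneration-dependent multiplier (1.0 both / 1.1 one / 1.25 none),
reflecting the SM hypertrophy documented in surgical legs — without it the
between-group SM contrast would be pure sampling noise, because nothing else
in the truth distinguishes the groups.

Trials are model-consistent by construction: smooth per-task angle templates
(sidestep knee flexion ≈ 20°→55°→30°), per-channel Gaussian excitation
bursts with task-specific emphasis (walking plantarflexor-dominated, running
quadriceps-dominated, cutting frontal-plane-dominated — which also keeps
same-channel muscles statistically separable across the calibration tasks),
forces and net joint moments from the ground-truth forward model,
experimental moments = truth + Gaussian noise (sd = 2% of each DOF's range;
zero in the noise-free preset), external knee frontal moment = −(net muscle
frontal knee moment) + a small residual, and an axial intersegmental
compression bell (≈1.1/2.2/2.0 body weights for walk/run/cut). Raw EMG is
excitation-modulated 30–500 Hz noise with unit mean rectified value,
synthesised over a ±0.15 s padded window so envelope extraction has real
data at the stance edges. Everything is deterministic under (config, seed).

**What the generator does not emulate** — and hence what passing tests do not
show about real data: inverse-dynamics model inconsistency (experimental
moments are forward-model-consistent up to declared noise; a bias option
exists for stress tests), marker/GRF-level artefacts, non-stationary or
crosstalk-contaminated EMG, subject-specific bone geometry and muscle-path
deviations, altered donor paths after regeneration (the insertion is assumed
unchanged, as in the modelling study), and history-dependent muscle
mechanics.

## Problem sizes in the shipped experiments

Cohort runs use 18 subjects × (2 calibrations + 8 open-loop predictions);
recovery experiments use 6 noise-free subjects at the higher optimizer
budget; oracle checks use 1000 random frames; statistical-validity checks
use 1000 null replicates at n = 18. These sizes keep the full test suite and
the acceptance script comfortably reproducible on a single CPU while leaving
each check's power intact.

## Known limitations

* Contribution percentages are sensitive to the supporting-direction
  convention at points where the net moment is near zero; masked points are
  excluded from stance averages.
* Strength coefficients of same-channel MTUs with nearly parallel moment
  arms are only weakly identifiable; the default table mitigates but cannot
  eliminate this (a structural property of EMG-driven calibration, not of
  the implementation).
* The contact-point decomposition yields compartment *moments*, not contact
  forces; condylar lift-off and load magnitudes are out of scope.
* Left limbs are handled by mirroring at ingestion (right-limb convention
  internally).
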