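# Methods

## Model

The polymerase–DNA complex is reduced to a single overdamped Brownian
particle with two degrees of freedom: the position `x` of the active site
along the template and the separation `r` of the enzyme from the DNA.
The composite potential is separable,

    U(x, r) = V(x) · g(r),      g(r) = 2 e^{−r/r_d} − e^{−2r/r_d},

so the radial section at any axial position is a Morse well whose depth is
|V(x)|.  All energies are expressed in units of k_BT, lengths in nm,
forces in pN; internally the solvers work in SI through the diffusion
coefficient D = k_BT/Γ with Γ = 6πηR (Stokes sphere).

`V(x)` is a piecewise-linear sawtooth over the discrete template sites:
well minima at the site positions `x_k = k·p` (p = 0.34 nm, one base-pair
rise), linear flanks meeting at a common barrier-top level.  The zero of
energy is the dissociated state, the barrier tops sit at −E₀ (E₀ a
uniform long-range electrostatic offset) and the well minima at
−(E_site + E₀).  Consequently the *axial* hopping barrier out of a well
is E_site while the *radial* escape depth at a well is E_r = E_site + E₀;
at the axial barrier a residual radial well of depth E₀ remains.  These
are the only features of the published potential sketches that enter any
result: at the relevant depths (≥ 15 k_BT) every observable is dominated
by Arrhenius factors in the well depths, not by the flank shapes.

Well depths per register follow from contact counting with the enzyme's
two DNA-binding sites (E1/E1' the single-strand affinities of the fingers
site for N₁/N₁−1 bases, E2/E2'/E2'' the duplex affinities of the
thumb + little-finger site for N₂/N₂−1/N₂−2 backbone segments):

| scenario      | E_n          | E_{n+1}       | enzymes                      |
|---------------|--------------|---------------|------------------------------|
| `dpo4_like`   | E1' + E2     | E1 + E2'      | Dpo4 (offset L = 0)          |
| `dbh_like`    | E1' + E2     | E1 + E2       | Dbh, Pol ι, Pol η (L = 1 bp) |
| `replicative` | E1' + E2     | E1 + E2       | ΔE = E1' − E1 ≈ −5 k_BT      |
| `lesion_at_n` | E1 + E2'     | E1 + E2''     | mismatch/lesion at site n    |

Rectification: the enzyme hops thermally between sites n and n+1; dNTP
binds only at n+1 and blocks the backward hop; the activated ternary
complex is locked.  The forward jump to site n+2 before incorporation is
excluded (reflecting boundary), as is forward motion of the primer
terminus past the active site.

## Observables

**Mean first-passage times.**  All deterministic results derive from the
double Boltzmann-weighted integral for 1-D overdamped diffusion with a
reflecting start and absorbing end,

    T = (1/D) ∫_a^b e^{+V(y)} [ ∫_a^y e^{−V(z)} dz ] dy ,

evaluated by adaptive composite-Simpson quadrature (base grid 4097
points, grid-doubling until successive estimates agree to 1 × 10⁻⁶
relative; dominant exponentials factored out; Boltzmann factors capped at
50 k_BT with a warning).  Two closed forms serve as cross-checks, each
validated against the quadrature in the test suite: an exact
piecewise-exponential formula for the sawtooth segment (agrees to
rounding), and a factorized Kramers-style product of one-dimensional
integrals for the Morse escape (agrees to <1% for depths ≥ 10 k_BT; it
degrades to a factor ~2 at zero depth, where the quadrature remains
exact).

**Processivity.**  Dissociation is possible only in the two vulnerable
windows of the cycle: the hopping window (duration T_p1) and the
bound-but-unactivated window (T_p2).  With P_d(E_r) = 1/T_d(E_r), the
per-cycle probabilities are P_d1 = C·P_d(E_m + E₀)·T_p1 (m the deeper
well, C ∈ [1, 2]) and P_d2 = P_d(E_{n+1} + E₀)·T_p2, and
N_p = 1/(P_d1 + P_d2).  For Dpo4-like enzymes (E_n > E_{n+1},
T_p1 < T_p2 at saturating dNTP) the P_d1 term is negligible and
N_p = T_d/T_p2.

**Force response.**  A backward load F (positive toward −x) tilts the
landscape by +βFx, shifting the well depths by ±F·p/2.  The dwell ratio
is taken in its exponential form ρ(F) = exp[(ΔE + Fp)/k_BT]; the binding
rate scales with the accessible-time fraction, R(F) = (1+ρ(0))/(1+ρ(F)),
and the synthesis rate is Michaelis–Menten with the Michaelis constant
rescaled by 1/R(F), preserving k_c at saturation.  Note the exponential
dwell ratio is itself a deep-well approximation: the exact ratio of basin
Boltzmann weights of the sawtooth carries an (E_{n+1}/E_n)-type
prefactor (≈20% at the physiological depths).  The kinetics layer uses
the exponential form throughout; the stochastic layers measure the exact
landscape quantities, and tests that compare the two either use the exact
Boltzmann oracle or run at ΔE = 0 where the forms coincide.

## Default parameters

| parameter | default | meaning / provenance |
|---|---|---|
| T | 300 K | not stated in the source analysis; chosen to reproduce Γ = 9.4e-11 kg/s and k_BT ≈ 4.14e-21 J; configurable |
| η | 1.0e-3 Pa·s | water / cytoplasm viscosity |
| R | 5 nm | Stokes radius of the enzyme |
| p | 0.34 nm | base-pair rise, one translocation step |
| r_d | 0.5 nm | Morse range, half the ~1 nm Debye length |
| L_escape | 5 nm | separation at which dissociation is scored (> 2 r_d) |
| T_p2 | 0.065 s | post-binding vulnerable window (from the 15.3 s⁻¹ activation rate) |
| T_p1 | T_p2/2 | no measured value; honors T_p1 < T_p2 at saturating dNTP; configurable |
| C | 1.5 | midpoint of the stated 1–2 range for the P_d1 prefactor |
| E₀ | 3.9 k_BT (or rule E₀ = E_r/5) | conservative electrostatic offset |

Presets (`dpo4`, `dbh`, `pol_iota`, `replicative`) pin the published
anchors: Dpo4 ΔE = 3 k_BT, E_r = 20.8 k_BT, k_c = 9 s⁻¹, K_m = 230 µM;
Dbh ΔE = 0, E_r = 18.5 k_BT, k_c = 2.3 × 10⁻² s⁻¹, K_m = 0.4 mM;
replicative ΔE = −5 k_BT.  Only affinity *differences* are constrained,
so the Y-family presets pin E1' = E1 = 0 (the fingers site has very low
or no single-strand affinity) and the split of the lesion-case E2''
values is chosen to land the lesion-site depths at 15.8 (Dpo4-like) and
13.5 k_BT (Dbh-like).  The replicative preset's k_c/K_m pair is
illustrative, not a measured pair for a specific enzyme.

## Stochastic layers

**Langevin integrator.**  Eqs. of motion are inertia-free, so the
faithful discretization is first-order Euler–Maruyama:
Δq = −(∂U/∂q)·D·Δt + √(2DΔt)·N(0,1), with mirror reflection at walls
(including r = 0) and first-touch absorption.  The timestep must keep the
deterministic displacement below 5% of the characteristic length at the
steepest slope; violations raise an error carrying a suggested Δt.  One
seeded generator per trajectory (master seed + index) makes results
independent of batching.  Validation runs use reduced barriers
(≤ ~8 k_BT, where 10³–10⁶ steps suffice per passage); the physiological
17–22 k_BT regime is covered by the quadrature layer only, since a single
passage there would need >10⁹ steps.  This is a scaled-down validation:
it certifies the integrator and the MFPT machinery in a regime where both
can be computed, not the deep-barrier regime directly.

With the composed U(x, r) and small E₀ a low-barrier landscape opens an
axial-corridor escape channel (same activation energy as direct radial
escape, larger prefactor), so the 1-D radial MFPT is not a valid oracle
for arbitrary 2-D landscapes; the 2-D integrator is therefore validated
on a nearly flat axial channel where the factorization is exact to ~1%.
The model's own results always use the factorized (1-D radial) escape, as
the separation of the axial and radial problems is part of the model.

**Cycle Monte Carlo.**  The incorporation cycle is simulated
event-driven with exponential waiting times: hop rates 1/T_moving from
the MFPT layer, binding pseudo-first-order rate (k_c/K_m)(1+ρ₀)·S at the
post-translocation site (chosen so the Michaelis–Menten synthesis rate
emerges), activation rate 1/T_p2, dissociation rates P_d per site, and a
residual catalytic time max(1/k_c − T_p2, 0) in the locked activated
state.  Because binding can be ~10⁶-fold slower than hopping, the hop
window (a two-state chain) is sampled exactly — geometric round counts
and Gamma-distributed residence sums — rather than hop by hop; this is a
distribution-exact sampler of the same process.  Exponential waiting
times are a modeling choice layered on the mean-time description; it
makes the per-cycle dissociation probability k_d/(k_d + 1/T_p2) rather
than k_d·T_p2, a relative difference of order P_d2 that vanishes for
processive parameter sets.

## Numerical and design choices

- Symmetric sawtooth with the barrier at the mid-point and a common
  barrier-top level: the published potential sketches are schematic; at
  the operating depths only well depths matter (Arrhenius dominance), and
  this choice reproduces the printed moving times (forward 1.8–11.2 ms
  over E_n = 20–22 k_BT vs the stated "2–10 ms"; backward 0.097 ms vs
  "≈0.1 ms").
- The exact quadrature is treated as ground truth everywhere.  The four
  published processivity anchors (N_p ≈ 100, 10, 0.8, 0.08 at
  E_r = 20.8, 18.5, 15.8, 13.5 k_BT) are jointly consistent with a
  factorized approximation that sits ~25% below the exact double
  integral; the package reports the exact values (121, 13.3, 1.01,
  0.114), which reproduce every anchor *ratio* to a few percent and the
  absolute values to 20–45%.
- Boundary conditions: reflecting at the starting well (structural
  restriction), absorbing at the target (dissociation or arrival at first
  touch).
- Degenerate inputs: zero well depths reduce every MFPT to the exact
  free-diffusion limits (L²/2D), used as test anchors; non-finite
  potentials raise with the offending coordinate; energies above
  50 k_BT are capped with a warning.
- Figure-sweep grids: E_r ∈ [12, 24] k_BT step 0.1; F ∈ [−20, 30] pN
  step 0.5; [dNTP] on a 61-point log grid from 1 µM to 10 mM.  Sweeps are
  deterministic and regenerate bit-identically.

## Limitations

- No sequence dependence, no fidelity/misincorporation model, no
  independent spatial profiles for the two binding-site potentials beyond
  their summed well depths, and no coupling to a helicase beyond a
  constant external force.
- No full 2-D first-passage or splitting-probability treatment: axial
  hopping and radial escape are deliberately factorized, as in the model
  itself.
- The forward jump to the (n+2)th site before nucleotide binding is
  excluded by construction.
- Stochastic validation covers reduced barriers only (see above); deep
  barriers are validated through closed forms and printed anchors, not
  direct simulation.
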