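# Methods

## Physical model

A 1-D strand of cardiac myocytes of length L = 6.4 mm is modeled at two
scales.

**Microscale.** Cells are cylinders (radius r = 11 µm, cross-section
A_cell = π r² ≈ 380 µm², length ε = 0.1 mm) coupled end-to-end through
intercalated discs of relative thickness δ = 10⁻⁴.  Current follows Ohm's
law in the cytoplasm (σ_c = 0.667 mS/mm) but is gated at the discs: the
junction conductance is β·g_jo·g_j(Vj), where g_jo = 2.534 µS is the nominal
disc conductance, β ∈ [0, 1] the gap-junctional coupling fraction (1 =
healthy, ≪1 = pathological uncoupling), and g_j the normalized
voltage-dependent conductance of the resident connexin channel.  The
equivalent nominal disc conductivity is δσ_g = g_jo·δ·ε/A_cell =
6.67·10⁻⁵ S/m, and σ_g = δσ_g/δ ≈ 0.667 mS/mm.

**Conductance laws** (module `gapjunction`).  Two limiting regimes bracket
the junctions' slow gating dynamics:

* *instantaneous*: per polarity branch s, g ∝ G^s·(2·cosh(Vj/VH^s) − 1),
  normalized by its Vj = 0 value (G⁻+G⁺)/2 so g(0) ≈ 1 — a nearly flat,
  almost Ohmic curve;
* *steady-state*: a (modified) Boltzmann bell,
  g = (1 − g_min^s)/(p + exp(A^s(Vj − Vj0^s))) + g_min^s with A = z/kT,
  kT = 25.7 meV.  The negative-polarity parameters govern Vj ≤ d and the
  positive-polarity ones Vj > d (d = 0 for the homotypic channels, 25 mV
  for Cx43-Cx45).  As printed in the source table the superscripts on this
  law are swapped — that assignment would make the curve flat for all
  negative Vj, contradicting the published bell shapes — so the polarity
  assignment above is used; it also makes the two branches continuous at
  Vj = d for all three parameter sets (≈1.291 vs ≈1.294 at d = 25 mV).
* *clamped*: g ≡ 1, the Ohmic reference.

Parameter sets cover Cx43-Cx43, Cx45-Cx45 (near-symmetric) and the
heterotypic Cx43-Cx45 channel, whose strong asymmetry (steep closure for
Vj < 0, persistent opening for Vj > 0) is what produces direction-dependent
conduction.

**Homogenized tissue scale** (modules `homogenize`, `continuum`).
Upscaling the periodic laminate gives the non-Ohmic effective conductivity
σ̂(y), solved implicitly at each macroscopic gradient y = ∂v/∂x from

    σ̂ = σ_c B / (σ_c/σ_g + (1 − δ) B),  B = β g_j(S ε [N](y)),
    [N](y) = (1 − δ)(1 − σ̂/σ_c) y,

where ε[N] is the transjunctional jump and S = 2 a jump-scaling factor
mimicking the dual-voltage-clamp convention under which the g_j(Vj) data
were fitted.  With g_j ≡ 1 this reduces *exactly* to the linear
(harmonic-mean) conductivity σ̂_L = [(1 − δ)/σ_c + 1/(β σ_g)]⁻¹; we keep
the (1 − δ) factor so that identity is exact rather than O(δ).  The tissue
models are the monodomain cable equation

    ∂x(σ̂(∂x v) ∂x v) = A_m (C_m ∂t v + I_ion(v, w)),

with A_m = 2·RCG/r = 363.6 mm⁻¹ (RCG = 2), C_m = 1 µF/cm², and Luo–Rudy I
kinetics for I_ion; `LHM` uses the constant σ̂_L and `NOHM` the tabulated
σ̂(y).

**Cellular reference models** (module `cellmodel`).  The strand is a chain
of resistively coupled nodes, n_div = 10 per cell (Δx = 10 µm, 641 nodes);
intracellular links have conductivity σ_c, intercellular links
Δx·β·g_jo·g_j(Vj)/A_cell (so the link conductance is β g_jo g_j; reading
the compact per-link expression literally would misplace a factor
Δx/(δε) = 10³).  Vj is sampled one full cell away on each side of the
junction, mimicking the dual-clamp measurement.  `CM clamped` fixes
g_j ≡ 1; `CM voltage-gated` re-evaluates g_j every step.

## Numerics

* **Time integration**: forward Euler everywhere, matching the explicit
  scheme of the underlying study.  Cellular models: dt = 0.9× the diffusive
  stability bound Δx²A_mC_m/(2σ_c) ≈ 2.5·10⁻⁴ ms at Δx = 10 µm.  Continuum:
  dt = 0.005 ms at h = 0.1 mm (bound h²A_mC_m/(6σ_c) ≈ 9·10⁻³ ms for the
  consistent-mass scheme).  Halving dt changes CV by < 0.5%.
* **Space**: continuum models use Galerkin linear elements with a
  *consistent* mass matrix (one tridiagonal Thomas solve per step; the
  ionic term is nodally interpolated and therefore stays pointwise).
  Consistent mass was chosen over lumping because it reproduces both the
  published full-coupling CV band (64–65 cm/s at h = 0.1 mm; lumping gives
  ~62) and the published mesh trend (CV increasing with h; lumping gives
  the opposite).  σ̂ is evaluated per element from the current-step
  gradient, keeping the update explicit.
* **σ̂ solve**: damped fixed-point iteration seeded at σ̂_L (damping 0.5
  once the iterates oscillate), tolerance 10⁻¹⁰σ_c, ≤200 iterations, with
  a residual-scan + bisection fallback; tabulation on y ∈ [−2000, 2000]
  mV/mm at 1 mV/mm with linear interpolation proceeds by continuation
  outward from y = 0, which selects the branch continuous from rest when
  the steep steady-state laws admit multiple fixed points.  Queries beyond
  the table fall back to a direct solve (the kernels clamp, as gradients
  stay well inside the range).
* **Luo–Rudy I**: standard 1991 parameter set, [K]o = 5.4 mM.  The solvers
  interpolate the voltage-dependent rates and the purely voltage-dependent
  current terms from a 0.01 mV lookup table (tested against the closed
  forms at 10⁻⁴ relative); the resting state is obtained by relaxing the
  tabulated dynamics for 10 s, so it is a numerical fixed point of the
  solver itself.  Gates are clipped to [0, 1].
* **Pacing**: a boundary current flux of 30 µA/mm² for 5 ms at the paced
  end (zero-flux at the other; retrograde runs swap ends), cycle length
  800 ms.  The amplitude sits inside the published 10–35 µA/mm² range; the
  pulse duration is not published and 5 ms was fixed because short (2 ms)
  pulses fail to ignite the slowly-conducting low-coupling steady-state
  regimes that the protocol is explicitly meant to probe — a seeded
  full-amplitude wave propagates there, so the failure is an electrode
  artifact, not tissue physics.  CV is measured from 0 mV upward crossings
  (linearly interpolated in time) at the 20%/80% strand sites; a run is
  *blocked* if the end distal to the electrode never activates within one
  pacing cycle.
* **Restitution**: cycle lengths 800, 600, 500, 450, 400 ms, then 10 ms
  decrements, 5 beats per cycle length with membrane state carried over;
  CV is measured on the last beat of each train and the protocol stops at
  the first cycle length whose last beat fails distal activation.
* **Problem sizes**: all experiments run on the 6.4 mm strand (641
  cellular / 65 continuum nodes).  Episodes are truncated once the distal
  end activates or the strand has decayed below −60 mV, which leaves
  results identical and keeps the low-coupling crawling-wave runs (~1 cm/s,
  ~600 ms of model time) to a few minutes of wall time.

## Validation oracles

* A resistor-chain steady-state solver over the explicit microstructure
  (nonlinear junction I–V inverted on the branch continued from the origin)
  reproduces the clamped effective conductivity to machine precision and
  the non-Ohmic σ̂(y) to ~10⁻³ relative; its potential profile deviates
  from the homogenized (linear) one by O(ε), halving as ε halves.
* An exhaustive residual scan + bisection reproduces the damped fixed-point
  σ̂ roots.
* With g_j ≡ 1 the NOHM and LHM trajectories are bit-identical, as are the
  clamped and voltage-gated cellular models when g_j is forced to 1.

## Design choices on open points

* The junction conductance printed as "2.534 µm" is read as 2.534 µS, the
  only unit consistent with the printed δσ_g.
* Strand node count: 641 (= 64·10 + 1); the published "642 degrees of
  freedom" presumably counts one extra boundary unknown, and no result here
  is sensitive to it.
* Ties at branch boundaries (Vj = 0, Vj = d) take the negative-polarity
  branch.
* The restitution schedule above 400 ms is not published; the coarse steps
  used (800/600/500/450/400) only serve to accommodate the membrane before
  the 10 ms ramp matters.

## Known limitations

* Steady-state gating is applied instantaneously (the regimes are limits;
  true junctional gating takes seconds, so real tissue sits in between).
* The NOHM applies the jump scaling S = 2 at all coupling levels, whereas
  the cellular dual-clamp-style Vj degenerates toward the bare junction
  jump during slow crawling conduction; near conduction block the NOHM is
  therefore somewhat more closure-prone than the cellular voltage-gated
  model (its heterotypic normal-direction block threshold on a coarse β
  grid lands one grid step higher).
* 1-D only; no bidomain/extracellular field, no ephaptic coupling, no
  time-dependent junction gating, single ionic model.
* The conduction-block classification depends on the observation window
  (one pacing cycle here): crawling waves near 1 cm/s cross the
  classification boundary smoothly.
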