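# nohm — non-Ohmic homogenized conduction in cardiac strands

Gap junctions couple cardiac myocytes electrically, and their conductance
depends non-linearly on the transjunctional voltage `Vj` — strongly so after
gating relaxation (the *steady-state* regime), mildly right after a voltage
step (the *instantaneous* regime).  Standard tissue-scale cable models
ignore this and assume Ohmic coupling, which mispredicts conduction whenever
junctional coupling is low (a hallmark of diseased myocardium).  This
package implements, in 1-D, a multiscale treatment of that problem for
computational electrophysiologists:

* **gapjunction** — published dual-voltage-clamp conductance laws for
  Cx43-Cx43, Cx45-Cx45 and the asymmetric heterotypic Cx43-Cx45 channel:
  instantaneous, `g ∝ G^s (2 cosh(Vj/VH^s) − 1)`, and steady-state
  (Boltzmann), `g = (1 − g_min^s)/(p + e^{A^s (Vj − Vj0^s)}) + g_min^s`,
  with polarity-dependent parameters and `A = z/kT` (`kT` = 25.7 meV).
* **homogenize** — upscaling of a periodic cell/junction laminate
  (cell length ε = 100 µm, disc fraction δ = 10⁻⁴, cytoplasmic conductivity
  σ_c = 0.667 S/m, junction conductance g_jo = 2.534 µS, coupling fraction
  β ∈ [0, 1]).  The non-Ohmic effective conductivity σ̂(y) solves

      σ̂ = σ_c·B / (σ_c/σ_g + (1−δ)·B),   B = β·g_j(S·ε·[N](y)),
      [N](y) = (1−δ)(1 − σ̂/σ_c)·y,

  implicitly at each macroscopic potential gradient `y = ∂v/∂x`; with
  `g_j ≡ 1` it reduces exactly to the linear harmonic mean.  A resistor-chain
  steady-state oracle over the explicit microstructure validates the limit.
* **ionic_lr1** — the Luo–Rudy phase-I (1991) ventricular membrane model.
* **cellmodel** — discrete cell-chain circuit models (10 subcellular nodes
  per 100 µm cell, 641 nodes over the 6.4 mm strand), with junction
  resistors that are voltage-clamped (`CM clamped`) or gated by the
  dual-clamp-style `Vj` (`CM voltage-gated`).
* **continuum** — 65-node monodomain cable solvers: `LHM` (constant linear
  σ̂) and `NOHM` (gradient-dependent σ̂(y)), Galerkin linear elements with a
  consistent mass matrix, forward Euler in time.
* **protocols** — activation/CV estimation, β sweeps, block thresholds,
  CV restitution under progressive pacing, mesh studies.
* **cli** — a `nohm` command wrapping the protocols.

## Worked example

```sh
$ nohm simulate --model nohm --channel Cx43-Cx43 --regime inst --beta 1.0
nohm Cx43-Cx43 inst beta=1 normal: CV = 65.19 cm/s (t1 = 3.66 ms, t2 = 9.49 ms)
```

The wave crosses the 20% site (x = 1.3 mm) at 3.66 ms and the 80% site
(x = 5.1 mm) at 9.49 ms, i.e. 3.8 mm in 5.83 ms ≈ 65 cm/s — healthy
ventricular strand velocity at full coupling.  The asymmetric heterotypic
channel conducts direction-dependently once gating matters:

```sh
$ nohm simulate --model nohm --channel Cx43-Cx45 --regime ss --beta 0.5
nohm Cx43-Cx45 ss beta=0.5 normal: CV = 10.10 cm/s (t1 = 15.65 ms, t2 = 53.27 ms)
$ nohm simulate --model nohm --channel Cx43-Cx45 --regime ss --beta 0.5 --direction retrograde
nohm Cx43-Cx45 ss beta=0.5 retrograde: CV = 57.28 cm/s (t1 = 3.58 ms, t2 = 10.21 ms)
```

Retrograde conduction is ~6× faster than normal here because the
steady-state Cx43-Cx45 conductance curve closes steeply for negative `Vj`
(the polarity a left-to-right wavefront imposes) but stays open for
positive `Vj`.  Other entry points: `nohm sweep-beta`, `nohm restitution`,
`nohm mesh-study`, `nohm sigma-table` (CSV of σ̂(y)), `nohm curves` (CSV of
the conductance laws).

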