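# Methods

## Units and constants

Internally everything is computed in Å, amu, and kcal/mol; the derived time
unit is √(amu·Å²/(kcal/mol)) = 48.89 fs, and all user-facing times are in
femtoseconds.  k_B = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹.  The production time
step is 4.89 fs (0.1 time units); diagnostics that probe energy
conservation use 0.489 fs.

## The bead chain and its stand-in force field

A protein is reduced to its Cα trace: beads of mass 110 amu connected by
virtual bonds of rest length b₀ = 3.8 Å.  Backbone geometry is expressed
in virtual-bond angles θᵢ (vertex at bead i) and signed virtual-bond
dihedrals γᵢ (axis through beads i, i+1), with γ computed as
atan2(|b₂|·b₁·(b₂×b₃), (b₁×b₂)·(b₂×b₃)) and wrapped to (−180°, 180°].
A dihedral whose defining triple is collinear is flagged degenerate (NaN)
and skipped by restraint evaluation and accumulation rather than assigned
an arbitrary value.

The force field is an explicitly declared stand-in — it exercises the
restraint machinery on realistic chain dynamics and claims nothing about
protein energetics:

| term | form | default | rationale |
| --- | --- | --- | --- |
| bond | ½k_b(r−b₀)² | k_b = 25 kcal mol⁻¹ Å⁻² | see below |
| angle | ½k_θ(θ−θ₀)² | θ₀ = 105°, k_θ = 0.01 kcal mol⁻¹ deg⁻² | sd ≈ 7.7° at 300 K, a plausible Cα-trace angle spread |
| torsion | c₁(1+cos γ)+c₃(1+cos 3γ)+c₁ₛ sin γ | 0.2 / 0.3 / 0.3 kcal/mol | soft, multi-minimum; the sin term makes the backbone chiral |
| excluded volume | ε((σ/r)¹²−2(σ/r)⁶+1) for r<σ, pairs \|i−j\|≥3 | ε = 0.5, σ = 4.5 Å | purely repulsive, C¹ at the cutoff |

The bond constant is deliberately soft.  Two accuracy requirements bound it
from above: stability at the production step (ω·Δt ≈ 0.07 at k_b = 25) and,
more stringently, the velocity-Verlet shadow-energy oscillation at the
diagnostic step, which must sit well below the 10⁻⁴ kcal/mol scale at which
within-block energy conservation of the time-averaged algorithm is
asserted.  At k_b = 25 the integrator noise floor on the 25-bead chain at
300 K is 2–5×10⁻⁵ kcal/mol per 100-step window.

The torsion chirality matters: distance restraints cannot distinguish a
fold from its mirror image (every pair distance is reflection-invariant),
so an achiral backbone would reach the enantiomer of a restraint-defining
reference half the time.  Real coarse-grained protein potentials are chiral
for the same reason.

**Random-chain build-up.**  Chains grow from the N-terminus: γ is drawn
uniformly on [−180°, 180°), θ from the Boltzmann weight of the angle term
at 300 K (a truncated normal; no sin θ Jacobian — this *defines* the build
distribution, and the generator's distributional test checks against
exactly it).  A candidate bead closer than 4.0 Å to any bead at sequence
separation ≥ 2 is retried; after 100 failures the build-up backtracks one
residue.  Same seed ⇒ bitwise-identical chain.

## Restraint potentials

Distance penalty (per restraint, bounds d_l ≤ d_u, defaults A = 5 kcal/mol,
σ = 1 Å, κ = 0.01 kcal mol⁻¹ Å⁻¹):

```
V(d) = −A·exp(−(d−d_l)²/2σ²)                 d < d_l
     = −A                                     d_l ≤ d ≤ d_u
     = −A·exp(−(d−d_u)²/2σ²) + κ(d−d_u)      d > d_u
```

V is continuous; the only gradient discontinuity is the κ-sized kink where
the flat bottom meets the linear tail at d_u, accepted and bounded by
κ = 0.01.  The σ = 1 Å default widens the attractor region appropriate for
time-averaged runs (0.5 Å is the configurable legacy value for
instantaneous restraints).  Angle and dihedral penalties use the same
flat-bottom/Gaussian-wall shape without a linear tail (their domains are
bounded); defaults A_θ = 1, A_γ = 5 kcal/mol, wall widths 10° (the angular
wall width is not dictated by anything physical; 10° gives walls of
comparable reduced steepness to the distance term).  The dihedral penalty
measures the circular distance to its bound interval, taken to the nearer
bound, making V 360°-periodic; at the antipodal point the two walls meet
with a gradient-sign change of magnitude ≲ A_γ·e^(−(150/σ_γ)²/2) ≈ 0.

Equivalent-site groups (the bead-level analogue of methyl/ring proton
groups) measure as the equal-weight r⁻⁶ combination over all cross pairs
within a conformation.  Intra-residue restraints are rejected at
construction; ambiguous-NOE alternatives beyond plain groups are rejected
at parse time with a clear error.

## Time averaging

Let y_j be a restrained quantity with exponent m (3 for distances, −1 for
angles).  The memory window is *truncated* at length τ: the average of
y⁻ᵐ uses weight e^(−s/τ) for ages s ∈ [0, τ] and nothing older, so the
full-window normalization is exactly τ(1−e⁻¹).

**Block bookkeeping.**  Steps accumulate into a current block; every n_ave
steps the block's simple mean of y⁻ᵐ is committed with the analytic weight
τ(1−e^(−Δ/τ))·e^(−a/τ) of its time span (Δ = n_ave·Δt, a the block's age),
every older block decays by e^(−Δ/τ), and blocks older than τ are evicted
(τ is treated as an integer number of blocks; the ring buffer holds
round(τ/Δ) of them).  The running sums are maintained recursively and
re-derived from the ring buffer every round(τ/Δ) commits to cancel
floating-point drift.  Between commits the effective average is

```
ȳ = [ (S + Δ·y_now⁻ᵐ) / (N + Δ) ]^(−1/m)
```

with S, N the frozen committed sums — the energy depends only on current
coordinates, which is what makes the scheme conserve energy within blocks.
Before the first commit ȳ = y_now exactly.  Dihedrals commit block means of
sin γ and cos γ and recover ȳ = atan2(s̄, c̄); degenerate-angle steps skip
accumulation and their block weight is renormalized by the valid count,
not imputed.

An independent oracle (`oracle_direct_average`) recomputes the same
definition by direct summation over the full stored history — no
recursion, no ring buffer — and the two routes agree to better than 10⁻⁹
relative error for n_ave ∈ {1, 10, 100}; the oracle takes n_ave as an
argument because the committed information is by construction the sequence
of block means, and with n_ave = 1 it reduces to plain quadrature of the
memory integral.

**Gradients and force scaling.**  The penalty gradient is chained through
the momentary term only: for distances ∂ȳ/∂y = (ȳ/y)⁴·Δ/(N+Δ), for angles
Δ/(N+Δ), for dihedrals through the averaged sine/cosine.  With a full
window this attenuates forces by Δ/[τ(1−e⁻¹)+Δ]; the forces are multiplied
by f, ramped linearly from 1 to f_max = max(1, (1−e⁻¹)τ/Δ) over
N_τ = ⌊τ/Δt⌋ steps (user-settable).  The ramp tracks the window filling,
so the effective restraint stiffness never exceeds its instantaneous
value.  Two deliberate conventions:

- f is *frozen within each block* and advances only at commits (a
  piecewise-constant realization of the linear ramp).  A per-step f would
  change the energy landscape inside a block and destroy exactly the
  conservation property the block update exists to provide.
- After the window fills, f_max·Δ/[τ(1−e⁻¹)+Δ] = 1/(1+Δ/[τ(1−e⁻¹)]): the
  cancellation is exact up to the momentary term's own weight in the
  denominator, 1.6×10⁻³ at τ = 4.89 ps, Δt = 0.489 fs, n_ave = 10.

The penalty *energy* is never scaled in production: replica exchange and
any reweighting must compare unscaled extended energies, or inter-replica
energy differences grow with f_max and exchange stalls.  A diagnostic flag
also scales the energy so that NVE runs can demonstrate within-block
conservation of the full scaled Hamiltonian.

**Energy non-conservation across commits, and heating.**  Each commit
shifts the (scaled) restraint energy discontinuously; microcanonical
time-averaged runs therefore do not conserve energy globally, and because
the scaled forces are quasi-static within the memory lag they do net work
on the chain — kinetic temperature rises in NVE and equilibrates above the
bath in weakly coupled canonical runs.  On this small, soft toy chain the
effect is much stronger than on a real coarse-grained protein: weak
stochastic friction (friction_scale 0.05) cannot balance it at τ = 4.89 ps,
while Berendsen coupling holds the bath temperature.  The experiments are
set up accordingly (below).  The effect shrinks as τ and n_ave grow, which
is why the production-scale settings are τ = 48.9 ps with n_ave = 500 (or
τ = 489 ps with n_ave = 1000).

**Checkpointing.**  The complete memory state serializes to JSON; a resumed
run (coordinates, velocities, RNG state, memory state) is bitwise identical
to an uninterrupted one, which the test suite asserts through the CLI.

## Dynamics

Velocity Verlet for NVE; BAOAB splitting for Langevin dynamics with
friction γ = friction_scale·γ_base, γ_base = 0.5 per natural time unit
(≈ 10 ps⁻¹), chosen so that friction_scale = 0.05 — the stand-in for
scaled-down water friction — gives a velocity decorrelation time of about
2 ps.  At friction_scale = 0 the Langevin step reduces exactly to velocity
Verlet.  Berendsen control rescales velocities by
λ = √(1+(Δt/τ_B)(T_bath/T_kin−1)) after each step, default τ_B = 489 fs.

Kinetic temperature uses N_dof = 3N (no center-of-mass correction;
Langevin dynamics does not conserve momentum), configurable to 3N−3 for
NVE diagnostics.  Trajectories abort with a diagnostic at non-finite
forces or coordinates beyond 10⁴ Å — a clear failure beats silent NaN
propagation.

Temperature replica exchange accepts a swap with
p = min{1, exp[(β_a−β_b)(E_a−E_b)]} on the unscaled extended energies;
accepted swaps exchange bath temperatures (not coordinates) and rescale
velocities by √(T_new/T_old), the standard temperature-REMD convention.
Each replica owns an independent seeded stream; pairing alternates
even/odd over neighbors in temperature order.

## Ensemble analysis

r⁻⁶ ensemble average d̄ = (Σ w_l d_l⁻⁶)^(−1/6) with weights normalized to
1; violation statistic ρᵤ⁺ = √((1/N_d)Σ max(d̄ᵢ−dᵢᵘ,0)²) plus the count of
violated restraints and of excesses ≥ 2 Å.  RMSD is the Kabsch
proper-rotation optimum (SVD with determinant correction — no
reflections, so a mirror-image fold scores high RMSD by design).  GDT_TS
is computed from a *single* all-bead superposition (mean percentage of
beads within 1/2/4/8 Å), a reproducible lower-bound variant of the
multi-superposition search used by assessment servers.  Ward clustering
runs on the pairwise-RMSD matrix (scipy's Lance–Williams update, no
coordinate averaging); families are ranked by cumulative weight and each
family's representative is its member with the lowest single-conformation
ρᵤ⁺ against the restraint set (the simplest consistent per-structure
score; averaging is deliberately not applied there), ties broken by lowest
index, so clustering is deterministic given the ensemble order.

## The standard experiments (tavmd.experiments)

Problem sizes are desk-scale by design; each experiment runs in minutes on
one core.

- **Memory-window fill time**: ⌊τ/Δt⌋ = 10,000 steps at τ = 4.89 ps,
  Δt = 0.489 fs.
- **NVE stability, instantaneous restraints**: a 25-bead chain restrained
  to itself (cutoff 8 Å, pad 0.5 Å, A = 5), 10⁵ velocity-Verlet steps at
  Δt = 0.489 fs; peak-to-peak total-energy variation after the first 1000
  steps is ≈ 1.4×10⁻⁴ kcal/mol.
- **Canonical temperature control**: the same system, Berendsen at 300 K,
  Δt = 4.89 fs, 4 × 500,000 steps; the second-half mean kinetic
  temperature is 300.0 K.
- **Within-block conservation**: NVE time-averaged run (τ = 4.89 ps,
  n_ave = 100, scaled-energy diagnostic), measured over the first 15
  blocks while the chain is still at its starting temperature: within-block
  peak-to-peak < 10⁻⁴ kcal/mol while commits move the energy by
  10²–10³ times more.  Later in such runs the heating described above
  raises the integrator noise with the temperature.
- **Two-reference recovery**: restraints r⁻⁶-averaged (weights ½, ½,
  cutoff 10 Å, pad 0.5 Å, A = 5) over two 15-bead chains 7.5 Å apart;
  4 trajectories per mode, 150,000 steps at Δt = 4.89 fs, Berendsen 300 K
  with tight coupling (τ_B = 48.9 fs), time averaging at the production
  settings τ = 48.9 ps, n_ave = 500.  Time-averaged trajectories visit
  both parents to ≤ 2.5 Å; instantaneous ones never reach parent A.

## What the synthetic data does and does not emulate

References are random chains, not folded proteins: there is no funneled
landscape, no secondary structure, and restraint densities (one per close
pair) are higher and cleaner than experimental NOE sets — no noise, no
ambiguity, no calibration error in the bounds.  Passing these experiments
shows the *algorithm* behaves as designed (conservation structure, scaling
cancellation, ensemble recovery where single-structure restraining fails);
it does not demonstrate accuracy on real NMR data or with a real
coarse-grained force field.

## Known limitations

- The toy force field is not a protein model; temperature-dependent terms,
  side chains, and correlation potentials are out of scope.
- Angular restraint bounds are taken as given (no ϕ/ψ → θ/γ conversion),
  and restraint tables are the package's own format (no NMR-STAR/PDB v2
  adapters).
- Fixed time step only; replica-averaged restraints and post-hoc
  reweighting (WHAM-style) are not implemented — ensemble weights are
  inputs.
- GDT_TS is the single-superposition lower bound.
- The NVE heating of scaled time-averaged runs limits how long a
  microcanonical diagnostic stays at its nominal temperature on this toy
  system; canonical production runs should use Berendsen or strong
  Langevin coupling.
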