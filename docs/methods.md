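# Methods

## Model

A linear homopolymer of N identical monomers in continuous 3-D space.
Four energy terms (all energies in units of the Lennard-Jones scale
`S_LJ = 1`, lengths in units of the reference bond length `r0 = 1`):

| term | form | parameters | default |
|------|------|------------|---------|
| bond | `v_FENE(r) = −log{1 − [(r−r0)/R]²}` | max elongation `R` | `R = 3/7` |
| non-bonded | `v_LJ(r) = 4[(σ/r)¹² − (σ/r)⁶] − v_c` for `r < rc`, else 0 | `σ`, cutoff `rc` | `σ = 2^(−1/6)`, `rc = 2.5 σ` |
| bending | `1 − cos(θ − θ0)` | reference `θ0`, scale `S_θ` | `θ0 = 1.4` rad, `S_θ = 200` |
| torsion | `1 − cos(τ − τ0)` | reference `τ0`, strength `S_τ` | `τ0 = 0.873` rad, `S_τ ≥ 0` free |

with `S_FENE = 98/5`.  `v_c` is always derived from `rc` so the
truncated LJ potential is exactly zero and continuous at the cutoff.
Bond lengths outside `(r0 − R, r0 + R)` are strictly forbidden: moves
that would cross the limit are rejected outright.

Conventions that the printed form of the model leaves open, and how
this package resolves them:

* **Sign of the FENE term.** The restraint is implemented as
  `−log{…}`, which is zero at `r = r0` and diverges to +∞ at the
  stretching limits.  The opposite sign would *reward* stretched bonds
  and contradict the hard stretching limit, so it is not offered.
* **Bending-angle convention.** `θ` is the angle between consecutive
  bond vectors (`θ = 0` for a straight chain).  With `θ0 = 1.4` and
  `τ0 = 0.873` the ideal helix then advances 1.610 rad per monomer
  about its axis — 3.90 ≈ 4 monomers per turn.  The alternative
  interior-angle reading gives 3.29 monomers per turn and is rejected
  on that basis.
* **Dihedral sign.** Standard atan2 construction on the two plane
  normals with the right-hand rule about the central bond; the planar
  cis arrangement is 0, trans is π.  `τ0 > 0` therefore selects one
  handedness, and mirror images of helices score zero helical content.
* **LJ cutoff.** `rc` is a free choice; `rc = 2.5 σ` is the
  conventional default.  Quantitative results (contact energies, exact
  crossover locations) shift slightly with `rc`.
* **Degenerate dihedrals.** Three exactly collinear points leave a
  dihedral undefined; the torsion term for that dihedral is evaluated
  as 0.  This occurs with probability zero during sampling and only
  matters for constructed inputs such as straight rods.

## Sampling

Single-temperature sampling is Metropolis Monte Carlo with two update
types: a **displacement** (one uniformly chosen monomer moved to a
uniform point in a cube of side `rd`), proposed `3N` times as often as
the **torsion pivot** (one uniformly chosen bond; all monomers on one
uniformly chosen side rotated rigidly about the bond axis by an angle
uniform in `[−π, π]`).  The pivot changes exactly one dihedral and the
inter-side contacts, leaving all bonds and bending angles intact, and
is what makes torsion-dominated folding tractable.  `kB = 1`
throughout.

`rd` is calibrated per temperature before measurement by a
multiplicative controller (`rd ← rd·√(acc/0.5)`, 50-sweep windows,
cap 100 iterations, target band 0.45–0.55) and then frozen.  A
"sweep" is N attempted updates.

Incremental energy evaluation recomputes only the affected terms
(O(N) per displacement, O(N²/4) cross-pairs per pivot) and is verified
against full recomputation to 1e−9 relative tolerance; the cached
total energy is resynchronised from scratch at every sampling event,
so accumulation drift never enters recorded observables.

**Replica exchange.** M = 32 replicas at a geometric temperature
ladder on [0.03, 2.5].  Every 400 attempted updates per replica a
conformation swap is attempted with probability
`min(1, exp[(β_a − β_b)(E_a − E_b)])`, alternating between even and
odd neighbour pairs so both neighbours of each replica are attempted
fairly.  Temperatures, displacement ranges and RNG streams stay
attached to their ladder slot; conformations travel.  All randomness
derives from one seed via spawned, per-replica streams, and runs are
bit-reproducible; the compiled inner loop consumes the RNG stream in
exactly the same order as the pure-Python reference implementation, a
property asserted by test.

Run lengths are free parameters of any Monte Carlo study.  The
package's nominal defaults are 10⁴ equilibration and 10⁵ measurement
sweeps; the desk-scale study conditions used by the test suite and
worked examples are listed below.

## Observables and classification

* `Cv(T) = (⟨E²⟩ − ⟨E⟩²)/T²`, with errors from a delete-one-bin
  jackknife over 20 contiguous bins (contiguity makes the error
  estimate robust to autocorrelation on the bin scale).
* `q1` / `q2`: the non-bonded LJ energy split at a bond separation of
  six — `q1` sums pairs with `2 ≤ j−i ≤ 6`, `q2` pairs with
  `j−i > 6`; `q1 + q2` reconciles with the LJ term of the total energy
  on every sampled frame.  A single helix has `q2 ≈ 0` because one
  helical turn spans only ~4 monomers; bundles have `q2 < 0`.
  `q2frac = q2/(q1+q2)` is undefined for contact-free frames
  (|q1+q2| < 1e−12) — those emit a NaN sentinel and are excluded from
  histograms.
* **Helix detection**: a dihedral is helical when its circular
  distance to `τ0` is ≤ 0.35 rad; maximal runs of ≥ 3 consecutive
  helical dihedrals are segments.  0.35 rad is roughly three thermal
  standard deviations at the freezing temperatures of interest
  (`√(T/S_τ)` with `T ≈ 0.1`, `S_τ ≈ 10`), wide enough to tolerate
  thermal jitter and narrow enough to exclude the compressed-spiral
  states discussed below.
* **Classifier** (deterministic cascade, all thresholds
  config-exposed): single helix = one segment covering ≥ 80 % of
  dihedrals with `|q2| < 0.1·|q1+q2|`; two-/three-helix bundle = that
  many segments with `q2` substantially negative; otherwise a frame
  with contact energy above −0.9 per monomer is a random coil, a
  non-helical frame below it is `compact`, and the remainder is
  `mixed`.  Two choices deserve comment.  First, the coil test is
  applied *before* the helical-fraction test: at large `S_τ` even
  high-temperature frames carry fluctuating short helical stretches,
  and an uncollapsed frame is a coil regardless of that transient
  helicity.  Second, the coil/compact boundary (−0.9 per monomer) sits
  inside the measured collapse region of the 30-mer at `S_τ = 0`
  (mean contact energy per monomer ≈ −0.5 at T = 2.5, ≈ −1.5 in the
  liquid phase); it is a frame-level approximation to an ensemble
  concept, and the liquid/amorphous-solid refinement of `compact` is
  made at the ensemble level by position relative to the freezing
  peak.
* **Transitions**: peaks of `Cv(T)` (and of |d⟨q1⟩/dT|, |d⟨q2⟩/dT|)
  exceeding the jackknife error, plus "shoulders" — bounded concave
  islands of the curve, detected as sign changes of the second finite
  difference that contain no peak, persist under 2× coarser
  temperature sampling, and pass a curvature-significance floor.
* **Putative ground states**: during a run the lowest-energy sampled
  frame of *each* observed structure type is kept; afterwards every
  candidate is quenched (L-BFGS local minimisation) and the overall
  quenched minimum is the putative ground state.  Raw sampled minima
  are biased toward whichever basin the coldest replica occupies;
  quenching compares competing structure types by their T → 0
  energies — the standard anneal-and-quench treatment.
* **Ground-state crossover**: ground-state labels on an `S_τ` grid;
  the crossover is the midpoint between the last grid point with the
  "from" label and the first subsequent point with the "to" label,
  with half that interval as the uncertainty.

## Fixture generators

`make_ideal_helix` places monomers by sequential internal-coordinate
construction (all bonds `r0`, bends `θ0`, dihedrals `τ0`) — it is the
zero-temperature single-helix reference.  `make_bundle` packs ideal
antiparallel helices side by side, joined by circular-arc turns whose
sub-bond lengths are solved to sit safely inside the FENE limits; a
small deterministic search over axis spacing, arc height and azimuthal
twist returns the lowest-energy clash-free packing.  `make_random_coil`
emulates the model's high-temperature ensemble: bonds `r0`, bends
pinned at `θ0` (the bending scale `S_θ = 200` dominates every relevant
temperature), dihedrals uniform, with excluded-volume rejection at
1.7 σ so the fixture stays contact-poor.  These generators produce
idealised, fully ordered representatives; sampled equilibrium frames
are noisier, which is why classifier thresholds are windows rather
than equalities.  What passing fixture tests shows is that the
classifier's taxonomy is sound, not that any particular region of the
phase diagram is converged.

## Desk-scale study conditions

Full phase diagrams at the nominal run lengths are cluster-scale.  The
test suite and examples use the following reduced conditions, chosen
once for convergence of the specific quantity they probe:

* **Helix pitch** (geometry anchor): N = 20, `S_τ = 50`, brief anneal
  at T = 0.05 plus L-BFGS minimisation; reports 3.9 ≈ 4 monomers per
  turn.  Deterministic up to minimiser tolerances.
* **Ground-state crossover, N = 30**: grid `S_τ ∈ {8,10,…,18}`,
  32 replicas, 2·10³ equilibration + 6·10⁴ measurement sweeps,
  sampling every 20 sweeps, candidate quenching on.  At these lengths
  the low-`S_τ` points are the hard part: the model has a deep
  metastable family of compressed-spiral ("solenoid") states —
  dihedrals uniformly ≈ 0.45 rather than `τ0`, maximal short-range
  contacts — within 1–2 energy units of the two-helix ground states,
  and escaping them requires replica diffusion through the melt.
  Candidate quenching makes the comparison between structure types a
  T → 0 energy comparison rather than a race between traps.  At these
  conditions the two-helix → single-helix switch lands at
  `S_τ = 14 ± 2`.
* **Heat-capacity signatures, N = 30**: 32 replicas; `S_τ = 0` with
  10⁴ + 3·10⁴ sweeps (glassy low-T states need the longer
  equilibration) shows a separate freezing peak near T ≈ 0.45 and a
  collapse shoulder near T ≈ 0.8; `S_τ = 25` with 5·10³ + 2·10⁴
  sweeps probes the strongly torsion-restrained regime (see
  limitations).

## Known limitations

* Canonical estimates are computed only at the simulated ladder
  temperatures; no multi-histogram reweighting between them.
* At torsion strengths well above the single-helix crossover
  (`S_τ ≳ 20`) the torsional wells (depth ~ 2 S_τ) never melt within
  the ladder window [0.03, 2.5]: the mean energy is linear in T with
  slope (3N − 6)/2 (pure equipartition), and the structural change
  from straight single helix to bent helical filament near T ≈ 0.55
  is energy-degenerate — coexisting phases mix freely within one rung
  with unimodal energy distributions.  In this implementation that
  transition therefore shows in the structural order parameters
  (d⟨q1⟩/dT) but carries no heat-capacity peak; the location (and
  existence) of a calorimetric helix-coil signal at large `S_τ` is
  expected to be sensitive to the choice of the Lennard-Jones cutoff
  `rc`, which is a free parameter here.
* The liquid/amorphous-solid distinction is made at ensemble level
  from the freezing signature; individual compact frames are not
  further resolved, and glassy low-`S_τ` states make the low-T labels
  at small torsion strength the least reliable part of the diagram.
* Helix-axis alignment within bundles (parallel vs. wrap-around
  two-helix geometries) is not scored; bundles are counted by segment
  number only.
* Finite-size transitions only: peaks and shoulders are rounded
  signatures of structural crossovers in chains of 30–50 monomers, not
  thermodynamic phase transitions, and no finite-size extrapolation is
  attempted.
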