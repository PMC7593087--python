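# Methods

## Overview

chromoscape implements a pipeline from 1D epigenetic marking data to 3D
chromosome structural ensembles and a set of ensemble analyses aimed at
structural heterogeneity:

1. **Feature extraction** — histone-mark signal tracks are summed into
   50-kb bins and discretized into 20 signal states per mark.
2. **Chromatin-type calling** — a windowed probabilistic model assigns each
   locus one of five chromatin types (sub-compartments) A1, A2, B1, B2, B3
   (plus NA for masked loci).
3. **Polymer sampling** — the type sequence parameterises a coarse-grained
   chromosome model (one monomer = 50 kb) whose Boltzmann ensemble is
   sampled by annealed Langevin dynamics.
4. **Ensemble analysis** — in-silico ligation maps, Q-based conformational
   clustering, radius-of-gyration free-energy profiles, occupancy free
   energies, and radial A/B positioning.

All randomness flows through numpy `Generator` objects seeded explicitly;
per-replicate streams are derived as `default_rng([seed, replicate])`, so
every stage is bit-reproducible on one platform.

## Signal discretization

Per mark, the pooled per-locus binned signal is mapped to states 1–20: the
top `k = ceil(0.05 n)` loci by signal (ties included) receive state 20, and
the remaining signal range `[min, q)` (with `q` the k-th largest value) is
split into 19 equal-width intervals mapped to states 1–19 by value.
Binning splits interval signal proportionally at bin boundaries, so total
signal is conserved. An all-constant mark degenerates to all-state-20 with
a warning. The intended pooling scope is all loci of all chromosomes of one
cell type in a single call; the function pools whatever loci it is given.

## Type calling

The caller scores each locus `l` per type by

    log prior(type) + sum over marks m and offsets o in [-2, +2] of
        log P(state at l+o, mark m | type, offset o)

and returns the argmax, i.e. the type most consistent with the discretized
signals in a five-locus window. The window truncates at chromosome ends
(no padding). Ties break deterministically to the lowest type in the fixed
order A1 < A2 < B1 < B2 < B3. The shipped model factorizes naive-Bayes
style across (mark, offset) and is fitted from labelled loci with
pseudocount smoothing; it is a surrogate exposing the same windowed-argmax
interface as a trained network, and any model that provides per-(type,
mark, offset, state) conditionals can be plugged into the same container.
NA loci are excluded from both fitting and calling and are set by a
user-supplied mask.

## Polymer model

Energies are in units of ε, lengths in σ (one monomer diameter), kB = 1.
One σ corresponds to 0.165 µm, the calibration that also sets the Q
resolution length and makes the 330-nm trace contact cutoff 2.0 σ.

U = U_HP + U_type-type + U_loops + U_ideal (+ confinement), with
`f(r) = (1 + tanh[µ(r_c − r)])/2`, µ = 3.22, r_c = 1.78 σ:

- **U_type-type** = Σ α_kl f(r_ij) over pairs of typed loci with genomic
  separation ≥ 3 within a 3.0 σ distance cutoff (f ≈ 4·10⁻⁴ there). NA
  loci are inert in this term only.
- **U_loops** = χ Σ f(r_ij) over loop-anchor pairs, χ = −1.612990, no
  distance cutoff (the force is negligible beyond ~3 σ anyway).
- **U_ideal** = Σ_{d=3..500} γ(d) Σ_i f(r_{i,i+d}) with
  γ(d) = γ₁/ln d + γ₂/d + γ₃/d², γ = (−0.030, −0.351, −3.727); |γ|
  decays monotonically from −0.558 at d = 3 to −0.0055 at d = 500.
- **α table**: per-pair values are configuration. The shipped default file
  (`data/alpha_synthetic.json`) is a constructed, clearly-labelled synthetic
  stand-in that honours the known ordering — B–B contacts most favourable
  (B3–B3 = −0.44), A–A and A–B comparable and weaker (≈ −0.26 to −0.28) —
  because the trained per-pair values are not reproduced here. Tests use an
  explicit two-scale toy table.

### Homopolymer and confinement (configuration choices)

The backbone terms are deliberately simple and exposed as configuration:

- bonds: harmonic, k = 300 ε/σ², rest length 1 σ;
- angles: k_a (1 − cos φ) between successive bond vectors, k_a = 2 ε;
- excluded volume: a capped harmonic soft core
  U = E_cap (1 − r/σ)² for r < 1 σ, E_cap = 20 ε, i.e. a finite-energy
  core that strongly resists interpenetration at the sampling temperature
  while still permitting rare strand crossings at the annealing
  temperature. The cap matters: a much softer core lets attractive terms
  collapse distinct domains into a single interpenetrating glob and
  suppresses the two-state dumbbell behaviour entirely.
- confinement: half-harmonic spherical wall (k = 80 ε/σ²) at radius
  R = 0.5 σ (n/φ)^(1/3) with volume fraction φ = 0.1, applied when a whole
  chromosome territory is simulated. Segment-scale studies (below) run
  without a wall.

### Sampling

BAOAB Langevin splitting, mass 1, friction 1/τ. Replicates start from a
random unit-bond chain folded inside the confinement region, velocities
Maxwell–Boltzmann at T_start. Temperature ramps linearly 3.0 → 1.0 ε/kB
per step over the annealing phase (default 5·10⁶ steps at dt = 0.002 τ),
then production at 1.0 ε/kB (default 20·10⁶ steps at dt = 0.001 τ, 40
replicates, a saved frame every 125000 steps). Frames are saved from
production only. Gaussian noise is pre-generated in chunks by the seeded
Generator, so the numba force kernel is fully deterministic. A non-finite
coordinate aborts the replicate with a diagnostic. The sampled mean kinetic
energy per particle is recorded and sits within a few percent of (3/2) kB T.

## Contact maps

- Simulated ensembles: `p_ij = ⟨f(r_ij)⟩` over frames; diagonal retained
  as f(0).
- Traced (or simulated) ensembles under a hard cutoff: entry = fraction of
  structures with both loci resolved and r_ij ≤ 330 nm (2 σ); the
  denominator counts only co-resolved structures, and never-co-resolved
  pairs are NaN and pairwise-deleted downstream.
- Pearson-by-distance: Pearson's R across pairs (i, i+d) per separation d;
  undefined below three jointly defined pairs or at zero variance.
- A/B annotation: observed/expected normalization by per-diagonal means
  (main diagonal excluded), Pearson correlation matrix across locus
  profiles, leading eigenvector, mean-centred; the sign is anchored to a
  caller-supplied A-reference when available, else the first non-zero
  entry is made positive. This is the standard eigenvector convention of
  ligation-map analysis; the choice is a convention, not a fitted quantity.

## Structural heterogeneity

**Q order parameter.** For structures a, b of the same segment,
Q = (1/N) Σ_{i<j} exp(−(r_ij^a − r_ij^b)² / (2δ²)) with δ = 0.165 µm
(1.0 σ): pairs separated similarly in both structures count as similar
even when not in contact. A pair contributes only when all four loci are
resolved; N is the per-comparison count of contributing pairs, and a pair
of structures with no usable pair is an error rather than a default value.
Q is invariant under rigid transformations and equals 1 for identical
internal geometry.

**Clustering.** 1 − Q feeds average-linkage (UPGMA) agglomerative
clustering; the linkage criterion is a package choice (none is prescribed
by the analysis this reproduces), and the cut (k clusters or a height) is
user-specified — k = 2 for the closed/open split on simulation-style
ensembles, k = 3 when a dense-artifact class is expected in traced data.
Sub-clusters come from re-cutting within a cluster.

**Usability filter.** Traced structures are kept when strictly more than
90% of loci are resolved ("over 90%"), a locus counting as resolved only
with all three coordinates finite.

**Order parameters and free energies.** Rg uses resolved loci only.
PMF(Rg) = −kBT ln P(Rg) from a fixed-width histogram (default 25 nm),
anchored so the minimum is 0; empty bins are undefined. The apparent
free-energy gap between conformational states is ln(N_major/N_minor) kBT
from cluster occupancies under an effective-equilibrium reading.

## Radial positioning

Per frame, each locus' radial distance from the all-locus centroid (not
the confinement centre — robust to drift; the difference is small for
centred territories) is normalised by the confinement radius R. Group
densities (A = {A1, A2}, B = {B1, B2, B3}, all) are histogrammed, divided
by spherical-shell volumes and normalised to integrate to 1 — a density,
not a count profile. Segment centre-of-mass distributions use the same
normalisation. These analyses apply to simulated ensembles only: a traced
~2 Mb segment does not define its chromosome's territory centre.

## The scaled two-domain study

`chromoscape.studies.run_two_domain_study` is a fixed desk-scale design
reproducing the two-state closed/open dumbbell phenomenology of a
gene-rich ~2 Mb segment: 39 monomers (1.95 Mb at 50 kb), all A1 (the
segment is A-compartment chromatin), head domain loci 0–15 and tail domain
loci 23–38 each anchored by one CTCF loop, 7-locus linker, no wall (the
segment is embedded in a chromosome, not confined at its own volume
fraction), sampled with the annealed protocol at 60k annealing / 150k
production steps per replicate, a frame every 3000 steps, 14 replicates
(700 frames). Conformations are clustered by 1 − Q at k = 2 and the
larger-mean-Rg cluster is labelled open. Under this design the open state
is a rare minority (of order 1–2% of frames), the apparent free-energy gap
ln(N_closed/N_open) is about 4 kBT, open-cluster mean Rg exceeds the
closed-cluster mean, and the cluster-averaged cutoff maps show two compact
domains whose mutual contact collapses upon opening. The problem size is a
design choice for a single-CPU study; the full-scale protocol (whole
chromosome, 40 × 20M steps) is available through the schedule defaults.

## Synthetic data: what it emulates and what it does not

The generators provide every input with known ground truth: blocky type
sequences (geometric block lengths; each block's type drawn with the
previous type excluded so realised block lengths match the nominal mean),
per-mark signal tracks with type-dependent Gaussian emission clipped at
zero (locations sit ≥ 2 spreads above zero so the clip is immaterial),
validated loop lists, and traced ensembles of closed/open dumbbells built
from confined random-walk blobs with center separations ≤ 2 and ≥ 4 blob
radii respectively, linker interpolation with isotropic jitter, and
independent per-locus dropout.

Limitations to keep in mind when interpreting green tests: emission is
unimodal Gaussian per (type, mark) — real ChIP-Seq signal is heavier-tailed
and spatially autocorrelated; dropout is spatially independent — real
tracing failures cluster along the trace; synthetic dumbbell conformers
have idealised blob geometry rather than polymer statistics (the simulator
provides those); and localization error beyond isotropic jitter is not
modelled. Passing recovery tests therefore demonstrates correctness of the
estimators and the pipeline plumbing, not performance on real microscopy
or ChIP-Seq data.

## Numerical notes

- Discretization thresholds are recorded; values exactly at an interior
  boundary take the higher state, and ties at the top threshold all enter
  state 20.
- The Q matrix is computed from per-structure condensed distance matrices
  in row chunks; with missing data, per-pair counts are tracked exactly.
- Map symmetry is enforced to machine precision after frame averaging.
- The eigenvector annotation zero-fills NaN correlations (loci with no
  defined O/E overlap) before diagonalisation.
- `occupancy_free_energy` requires both counts ≥ 1 and suggests reporting
  a bound when a state was never observed.
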