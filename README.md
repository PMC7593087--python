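# chromoscape

Chromosome structural ensembles from epigenetic marks, and the analysis of
their heterogeneity.

Interphase chromosomes do not fold into a single native structure: both
DNA-tracing microscopy and polymer theory show a fluid ensemble of
conformations, within which short (~2 Mb) gene-rich segments make two-state
transitions between **closed dumbbells** (head and tail loop domains in
contact) and rare **open dumbbells** (domains dissociated). chromoscape is
a Python library for scientists who want to predict such ensembles from 1D
epigenetic data and quantify their heterogeneity:

- **ChIP-Seq featurization** — bin histone-mark signal to 50-kb loci and
  discretize each mark into 20 signal states (top 5% of loci = state 20,
  the rest split linearly).
- **Chromatin-type calling** — assign each locus a sub-compartment type
  (A1, A2, B1, B2, B3) by the windowed argmax
  `type(l) = argmax P(type | states at l-2 .. l+2, all marks)`,
  with a pluggable probability model (a fitted naive-Bayes surrogate ships
  with the package).
- **Polymer sampling** — the minimal chromatin energy function
  `U = U_HP + Σ α_kl f(r_ij) + χ Σ_loops f(r_ij) + Σ_d γ(d) Σ_i f(r_i,i+d)`
  with crosslinking probability `f(r) = (1 + tanh[µ(r_c − r)])/2`
  (µ = 3.22, r_c = 1.78 σ, χ = −1.612990,
  γ(d) = −0.030/ln d − 0.351/d − 3.727/d²), sampled by annealed Langevin
  dynamics (3.0 → 1.0 ε/kB) in spherical confinement at volume fraction 0.1.
- **Ensemble analysis** — in-silico ligation maps `p_ij = ⟨f(r_ij)⟩`,
  330-nm cutoff maps for traced data, Pearson-by-distance and A/B
  eigenvector annotation; the Q order parameter
  `Q = (1/N) Σ_{i<j} exp(−(r_ij^a − r_ij^b)²/2δ²)` (δ = 0.165 µm) with
  1 − Q hierarchical clustering into conformational states; radius of
  gyration, `PMF(Rg) = −kBT ln P(Rg)`, occupancy free energies
  `ln(N_closed/N_open)`; and radial A/B positioning within the territory.
- **Synthetic data** — generators for every input (type sequences, mark
  tracks, loop lists, traced dumbbell ensembles with dropout) with known
  ground truth, so the full pipeline is testable offline.

## Worked example

The closed/open dumbbell analysis at desk scale
(`examples/02_dumbbell_two_state.py`): sample a 39-monomer two-domain
chain with the annealed protocol, cluster by 1 − Q at k = 2:

```python
from chromoscape.studies import run_two_domain_study

result = run_two_domain_study(seed=1, n_replicates=6)
print(result.n_closed, result.n_open, result.free_energy_kbt)
```

The example script prints

```
frames: 300
closed: 298, open: 2 (0.7% open)
apparent free-energy gap: 5.00 kBT
mean Rg closed: 1.73 sigma, open: 2.16 sigma
closed-cluster contacts: {'head': 0.56, 'tail': 0.58, 'between': 0.24}
open-cluster contacts:   {'head': 0.62, 'tail': 0.66, 'between': 0.01}
```

i.e. the open dumbbell is a sub-percent minority state a few kBT above
the closed state, open conformations are visibly more extended, and the
head–tail contact block collapses when the dumbbell opens — the same
two-state picture seen in traced microscopy ensembles, where 912 closed
vs 17 open structures give ln(912/17) ≈ 3.98 ≈ 4 kBT.

Other short examples in `examples/`: type calling from synthetic tracks
(`01`), usability filtering + clustering + PMF of a traced-style ensemble
(`03`), and compartment phase separation with radial A/B ordering (`04`).

A thin CLI wraps the same library for shell pipelines:

```bash
chromoscape synth --seed 1 --out work/inputs
chromoscape discretize --tracks-dir work/inputs --out work/states.tsv
chromoscape predict --states work/states.tsv --fit-labels work/inputs/types.tsv --out work/types.tsv
chromoscape simulate --types work/types.tsv --steps-scale 0.01 --replicates 2 --out work/sim
chromoscape map --traj work/sim --out work/map.tsv
```

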