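# vsfunnel

Staged virtual-screening funnels with graph-attention rescoring, for
computational chemists building hybrid (energy-based + data-driven) hit
discovery pipelines.

A typical campaign docks a multi-million-compound library at increasing
precision (HTVS → SP → XP), keeps compounds below per-stage score
thresholds, rescores the survivors with MM/GBSA, an external surface-based
scorer and a learned activity model, assembles a per-compound consensus
table, and validates the top picks by binding-pose stability analysis and a
dose-response assay.  `vsfunnel` implements everything downstream of the
score producers:

* **Descriptors** (`vsfunnel.chem_io`) — standardization (salt stripping,
  implicit hydrogens) and a pinned descriptor set: average-mass MW,
  heavy atoms, H-bond donors/acceptors, rotatable bonds, and Ertl TPSA
  *including sulfur/phosphorus terms*, the convention required to
  reproduce published tables for thiazole-containing inhibitors.
* **Graph featurization** (`vsfunnel.mol_graph`) — heavy-atom graphs with
  atom/bond features, plus external scores and descriptors z-scored on the
  training split and broadcast into every node.
* **GAT rescorer** (`vsfunnel.gnn_rescorer`) — a multi-head graph-attention
  network with an MLP head regressing pIC50, trained on an 8:1:1 split with
  early stopping, in pure NumPy with hand-verified gradients; deterministic
  on CPU for a fixed seed.
* **Funnel** (`vsfunnel.funnel`) — inclusive-threshold stage filters with
  optional retention caps, best-pose collapse, consensus joins and a
  transparent weighted-z candidate ranking.
* **Pose stability** (`vsfunnel.pose_stability`) — Kabsch superposition on
  binding-site atoms, ligand RMSD series, **PoseScore** (mean RMSD from the
  starting pose, Å) and **PersScore** (fraction of initial protein–ligand
  H-bonds persisting in the final 2 ns, in [0, 1]).
* **Dose-response** (`vsfunnel.assay_analysis`) — the four-parameter
  logistic model
  `Y = Bottom + (Top − Bottom)/(1 + 10^((LogIC50 − X)·hillslope))`
  with self-starting least-squares fitting and IC50 extraction.
* **Synthetic data** (`vsfunnel.synthetic_data`) — seeded generators for
  every fixture: fragment-grammar molecule libraries with planted
  descriptor-linear activity, copula-coupled score tables, replicate
  trajectories with scheduled H-bond occupancy, noisy 4PL curves.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Compute the descriptor row of a published JNK3 inhibitor hit
(N-(4-(2-ethyl-4-(m-tolyl)thiazol-5-yl)pyridin-2-yl)benzamide):

```python
from vsfunnel.chem_io import MoleculeRecord, compute_descriptors

hit = MoleculeRecord(
    id="hit",
    structure="CCc1nc(-c2cccc(C)c2)c(-c2ccnc(NC(=O)c3ccccc3)c2)s1",
)
d = compute_descriptors(hit)
print(round(d.mw, 1), d.heavy_atoms, d.hbd, d.hba, d.rot_bonds, round(d.tpsa, 1))
```

```
399.5 29 1 4 5 83.1
```

— molecular weight 399.5 g/mol over 29 heavy atoms, one N–H donor, four
acceptors (pyridine N, thiazole N, carbonyl O, thiazole S), five rotatable
bonds, and 83.1 Å² of topological polar surface area (the thiazole sulfur
contributes; without the S-inclusive convention the value would drop to
54.9 Å² and miss the published table).

The same pipeline from the shell, end to end on synthetic data:

```bash
vsfunnel simulate library --n 200 --seed 7 --out demo/
vsfunnel train --activity demo/activity.csv --scores demo/scores.csv \
         --out demo/model --seed 7 --epochs 60
vsfunnel rescore --model demo/model --in demo/library.sdf \
         --scores demo/scores.csv --out demo/pred.csv
vsfunnel simulate dose-response --ic50-nm 130 --noise-sd 2 --seed 7 --out demo/dr.csv
vsfunnel fit-ic50 --in demo/dr.csv --out demo/fit.json
```

The last command prints the fitted potency, e.g.

```
IC50 = 133.6 nM (sse 0.377)
```

meaning the 4PL fit recovered the simulated 130 nM inhibitor to within a
few percent under 2-unit response noise.

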