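# Methods

This note documents the models and procedures implemented in `vsfunnel`,
the conventions they pin down, and the design choices made where the
underlying workflow left them open.

## Scope and data flow

The package implements the computational spine of a hybrid
structure-based/data-driven virtual screen for kinase inhibitors:

1. molecule standardization and physicochemical descriptors (`chem_io`);
2. molecular-graph featurization with externally supplied docking/surface
   scores injected as node features (`mol_graph`);
3. a graph-attention (GAT) regressor predicting pIC50 (`nn`,
   `gnn_rescorer`);
4. a staged score-threshold funnel with consensus assembly and ranking
   (`funnel`);
5. binding-pose stability scoring from replicate trajectories
   (`pose_stability`);
6. four-parameter logistic (4PL) dose-response fitting (`assay_analysis`).

The energy producers themselves — docking programs, MM/GBSA solvers,
surface-based scoring networks, metadynamics/MD engines, wet-lab assays —
are out of scope.  Their outputs enter as score tables and trajectory
files; everything downstream of those numbers is implemented here and
testable on synthetic inputs from `synthetic_data`.

## Descriptor conventions

Published descriptor tables for this class of compounds are only
reproducible under specific conventions, which we pin and expose as flags:

* **TPSA** uses Ertl fragment contributions **including sulfur and
  phosphorus terms** (`tpsa_sp=True`).  The common toolkit default omits
  S/P; an aromatic sulfur (thiazole, thiophene) then misses ~28.2 A^2.
  The reference hit compound
  (N-(4-(2-ethyl-4-(m-tolyl)thiazol-5-yl)pyridin-2-yl)benzamide) computes
  to 83.1 A^2 only with the S-inclusive variant.
* **H-bond acceptors** count carbonyl/ether/hydroxyl oxygens, non-pyrrolic
  aromatic nitrogens, basic amines, and aromatic or divalent sulfur, and
  exclude amide nitrogens.  This SMARTS-defined convention gives the hit's
  published count of 4 (pyridine N, thiazole N, carbonyl O, thiazole S);
  sulfur counting can be disabled (`hba_sulfur=False`).
* **Molecular weight** uses average (not monoisotopic) atomic masses,
  reported to one decimal; **rotatable bonds** are non-ring single bonds
  between non-terminal heavy atoms with amide C–N excluded; **donors**
  count N–H/O–H groups once each.
* The published XLogP3-AA column is not reproduced (proprietary
  algorithm); the `logp` field is a Crippen estimate, informational only,
  and never used in filtering or acceptance decisions.
* Salt stripping keeps the organic fragment with the most heavy atoms
  (ties: larger MW, then input order); structures without carbon are
  rejected as non-drug-like.  Tautomer/stereoisomer enumeration is not
  implemented — no downstream stage consumes isomer sets.
* Descriptors are held at full precision internally and rounded only when
  a report table is written.

## Graph featurization and score injection

Molecules become heavy-atom graphs: one node per non-hydrogen atom, one
undirected edge per bond.  Base node features (24 dims) are element
one-hot (C/N/O/S/F/Cl/Br/I/P/other), degree one-hot (0–5), formal charge,
aromaticity, ring membership, implicit-H count and hybridization one-hot
(SP/SP2/SP3/other); edge features are bond-order one-hot plus conjugation
and ring flags.  The base set is not dictated by the workflow being
reproduced; it matches common molecular GAT baselines and is the place to
extend if richer chemistry is needed.

Global per-molecule scalars — the external docking/surface score and the
RDKit descriptors TPSA, MW and rotatable-bond count — are z-scored against
the **training split only** (population standard deviation; a constant
column gets sd 1 so its transform is identically zero) and broadcast into
every node vector.  This "score-augmented node feature" construction is
the package's reading of normalizing an external score together with
molecular properties and incorporating them into the nodes; the
alternative reading (dividing the score by a property) is available as
`normalize_score_by_property` but is not used by the default pipeline.

## GAT regressor

The regression network stacks `n_gat_layers` multi-head attention layers

    e_ij = LeakyReLU(a_src · W h_j + a_dst · W h_i)
    alpha_ij = softmax over in-neighbours j of i (self-loops included)
    h'_i = ELU(concat_heads(sum_j alpha_ij W h_j) + b)

followed by a permutation-invariant readout over nodes (mean by default;
sum and max available) and an MLP head emitting one value per molecule.
Defaults: 3 GAT layers, 4 heads, hidden width 64, MLP 64→32→1 — layer
counts and widths were not specified by the source workflow and are fully
config-exposed.

The implementation is pure NumPy with hand-written reverse-mode gradients
(verified against central finite differences in the test suite) and an
Adam optimizer; it is CPU-only and deterministic for a fixed seed: data
order, parameter initialization and batch shuffling all draw from one
seeded generator, so two runs with the same seed produce identical fit
reports.

Training minimizes MSE under an 8:1:1 train/validation/test split —
validation and test each receive floor(n/10) molecules, the remainder
trains (1072 molecules split 858/107/107).  The split is a seeded uniform
shuffle; a scaffold-based split would be stricter for generalization
claims and is noted as an alternative, not implemented.  Early stopping
monitors validation MSE (default patience 30) and restores the best
parameters; `early_stop_patience=None` disables both, keeping the final
epoch (used by the overfitting sanity test).  Hyperparameter search is a
seeded random search over a discrete config grid maximizing validation
R²; trials are logged and reproducible per seed.

## Funnel semantics

A funnel stage keeps rows with `score <= threshold` — comparisons are
**inclusive**, and the "smaller than" phrasing sometimes used for the
first stage is treated identically for uniformity.  An optional
`max_retained` keeps the most negative rows after thresholding, ties
broken by id, so survivors are invariant to input row order.  Rows with a
missing score are dropped and counted separately.  When a ligand carries
multiple docked poses, `collapse_best_pose` keeps the best (most
negative) score per ligand before filtering, matching the convention of
reporting one score per compound even when up to 5/20 poses per ligand
were docked.

The reference staged protocol screens with increasing docking precision
(HTVS, then SP at ≤ −8.689 kcal/mol, then XP at ≤ −8.101 kcal/mol, with
the first cut at −6.532 kcal/mol); whether its published stage counts were
threshold-emergent or caps is ambiguous, so both mechanisms exist and
compose.  Consensus assembly inner-joins per-method score tables by
molecule id (outer join with missing-flags optional) in a fixed column
order.  `rank_candidates` is a transparent surrogate for what was, in the
original workflow, expert manual triage: each weighted column is z-scored
over the table, sign-aligned so larger is better (energies negated,
predicted pIC50 kept), weighted and summed; ties break by id.  It is
reproducible and documented, not a claim about how experts decide.

## Pose stability

`PoseScore` is the mean ligand heavy-atom RMSD from the starting pose over
all frames of all replicates (Å, lower = more stable).  Each frame is
rigidly superposed on the reference using binding-site protein atoms — by
default Cα atoms within 8 Å of the ligand in the reference pose, falling
back to all protein atoms when fewer than three qualify (synthetic
topologies have no Cα labels) — and the ligand RMSD is then measured
without re-fitting the ligand, so drift inside the pocket is not aligned
away.  Superposition is a Kabsch SVD fit with the determinant correction
guaranteeing a proper rotation.

`PersScore` is the fraction of the reference pose's protein–ligand
hydrogen bonds still present during the final window (default 2 ns) of
the replicates, pooled over (bond, frame) pairs; a per-replicate average
is available (`pooled=False`).  The underlying vendor definition is not
public; this pooled-fraction definition is declared, not inferred.
Hydrogen bonds use geometric criteria — donor–acceptor distance ≤ 3.5 Å
and donor–H–acceptor angle ≥ 120°, both boundaries inclusive — chosen as
field-standard defaults and configurable; the source workflow states no
criteria.  Pose selection ranks candidates by ascending PoseScore, ties
by descending PersScore, then label.

Trajectories enter as in-memory arrays or multi-model PDB files with a
JSON sidecar carrying atom roles (PDB cannot express donor/acceptor roles
reliably).  The metadynamics machinery that produced real trajectories —
solvation, heating, biasing — is not simulated.

## 4PL dose-response

The inhibition curve is

    Y = Bottom + (Top − Bottom) / (1 + 10^((LogIC50 − X) · hillslope))

with X = log10(concentration); concentrations are handled internally in
log10 nM.  Fitting is unweighted least squares (no weighting scheme is
given by the reference protocol) with self-starting initials (bottom =
min y, top = max y, LogIC50 = x nearest the half-range response,
hillslope = 1); replicates are averaged per dose before fitting
(switchable).  Whether the reference analysis constrained Bottom/Top to
0/100 is unstated; both are free by default, with `fix_bottom`/`fix_top`
flags.  The exponent is clipped at ±300 so evaluation is total.  The
standard six-dose ten-fold dilution series (0.1–10,000 nM) is the default
design.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of spec + seed (byte-identical reruns):

* **Libraries** are assembled from a fragment grammar (6 outer ring cores
  × 10 decorations × 7 linkers × 6 inner cores × 10 decorations), so
  every SMILES parses and survives standardization unchanged;
  deduplication is by canonical SMILES.  Planted activity is pIC50 =
  β·z(descriptors) + intercept + N(0, σ²) with defaults β = (0.8, 0.5,
  −0.6) over z-scored (TPSA, MW, rotatable bonds), intercept 5.8 (the
  published hit pIC50s cluster around 5.3–6.8) and σ = 0.2.  This plants
  a recoverable descriptor-linear signal; it does **not** emulate real
  structure–activity landscapes (activity cliffs, scaffold effects,
  assay heterogeneity), so passing recovery tests demonstrates correct
  machinery, not real-data predictive performance.
* **Score tables** draw from declared marginals coupled by a Gaussian
  copula; a target Spearman ρ maps to the latent Pearson correlation via
  ρ_p = 2 sin(πρ_s/6).
* **Trajectories** mirror the reference protocol's shape — ten replicates
  of 10 ns (100 frames at 0.1 ns) by default — with two motion models:
  "stable" (per-atom Gaussian jitter, σ = 0.3 Å) and "drifting"
  (whole-ligand random walk, step 0.2 Å/frame).  Scheduled H-bond
  occupancies are deterministic frame masks realized geometrically
  (acceptor at the reference position when "on", displaced 4 Å when
  "off"), so persistence targets are met exactly rather than in
  expectation.  No force-field realism is claimed.
* **Dose-response** curves add Gaussian noise in response units to exact
  4PL evaluations at the standard dilution series.

## Problem sizes used in the checks

The planted-signal recovery check trains on a 1000-molecule synthetic
library (a size comparable to the 1072-compound activity dataset the
original rescorer used) for up to 100 epochs with patience 15; funnel
oracle equivalence uses 10,000 rows with thresholds placed at the 5000th
and 2000th order statistics; pose-stability sweeps use 2–10 replicates of
40–100 frames over 20 seeds; 4PL recovery uses the six printed doses,
noiseless and with 2-unit (2% of range) noise over 100 seeds.

## Numerical choices and degenerate inputs

* Population (ddof = 0) standard deviations throughout scaling, pinned
  for reproducibility; constant columns scale to zero, never NaN.
* R² requires ≥ 2 points and positive label variance; it is reported as
  NaN for undersized validation splits and such trials rank last in
  hyperparameter search.
* Kabsch fitting rejects masks with < 3 atoms or collinear geometry.
* H-bond boundary comparisons are inclusive with a 1e-9–1e-12 guard
  against floating-point edge effects.
* Funnel tie-breaks (equal scores at a retention cap, equal composite
  ranks) resolve by molecule id, making every ordering deterministic.
* Model persistence is a JSON architecture record plus an npz weight
  archive; loading validates the format version and the weight-key set
  against the declared architecture and fails loudly on truncation.

## Known limitations

* The GAT regressor is NumPy-based and CPU-bound; it is sized for
  thousands of molecules, not the multi-million-compound libraries the
  staged funnel is designed to cut down first.
* Published R² values for the original rescorer (0.9617/0.7866/0.7228)
  depend on a ChEMBL extraction that ships with no accession list and on
  commercial scoring software; they are context, not a target this
  package can or does reproduce.
* Descriptor conventions were reverse-engineered from one published
  compound row; other descriptor software may disagree on exotic
  functional groups.
* PersScore's pooled-fraction definition is one defensible reading of
  "hydrogen-bond persistence"; numbers from vendor implementations are
  not expected to match exactly.
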