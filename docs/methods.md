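# Methods

## Problem setting

The package implements a surrogate model for docking-based binding-affinity
scoring in a deliberately small, fully offline setting: four FDA-approved
Alzheimer's drugs scored against the kinase DYRK2, for which no
experimental affinities exist. Reference labels are docking scores (the
designated reference tool's row of the embedded score table, in kcal/mol,
more negative = stronger). With n = 4 ligands, every fit statistic is a
measure of agreement with the reference scoring function, not of
generalization; the package reports an explicit warning whenever R² is
computed from fewer than 8 items for this reason.

## Representations

**Ligands.** SMILES are parsed with RDKit into heavy-atom graphs.
Hydrogens are added internally only where chemistry requires them —
Gasteiger charge assignment and 3D embedding — and folded back: each
hydrogen's Gasteiger charge is added to its heavy neighbour, so heavy-atom
charges sum to the molecular net charge (enforced to 1e-3 e in tests).
Multi-fragment SMILES are rejected outright rather than reduced to the
largest fragment, so malformed inputs fail loudly. The default atom
feature vector (19-dim) is element one-hot (C,N,O,S,F,Cl,Br,I,P,other) +
degree one-hot (0–5) + formal charge + aromatic flag + Gasteiger charge;
bond features (5-dim) are order one-hot + ring flag. Stereochemistry,
tautomers and protonation states are out of scope.

**Conformers.** Each ligand receives a single 3D conformer: 10 ETKDG
embeddings with seeds derived from the caller's seed, each relaxed with
MMFF94 (UFF fallback), keeping the lowest-energy result. Same seed, same
coordinates, bit for bit. A single conformer is a deliberate
simplification — the physics features inherit its pose noise, which for
flexible molecules can move intra-molecular energies by a few kcal/mol.

**Protein.** The target is a linear residue graph: one node per residue,
edges between sequence neighbours (|E| = |V| − 1). Residue features
(22-dim) are one-hot over the 20 canonical amino acids (X maps to an
all-zero block) + Kyte–Doolittle hydropathy + side-chain charge class. An
optional contact graph adds edges for residue pairs (|i−j| ≥ 2) whose
C-alpha atoms lie within a threshold (default 8 Å, matching the
non-bonded cutoff) of user-supplied coordinates; it exists for ablation
studies and is not part of the main architecture. The packaged DYRK2
construct sequence (417 residues) is kept verbatim, including its
His-tag/TEV linker; `load_paper_fixtures(trim_his_tag=True)` removes the
tag up to the TEV cleavage point for users who prefer the mature
construct.

## Physics terms

Intra-ligand non-bonded energies are the two features fused into the
model:

- Coulomb: k_e q_i q_j / (ε_r r_ij) per pair, k_e = 332.0636
  kcal·mol⁻¹·Å·e⁻², ε_r = 4 (a common implicit-solvent screening value for
  protein-interior electrostatics).
- Lennard-Jones 12-6: 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶] with
  Lorentz–Berthelot mixing. The packaged parameter table is element-keyed
  with GAFF-like representative values; full force-field file ingestion is
  out of scope.

Pairs separated by one or two bonds (1-2, 1-3) are excluded by default
(`bonded12_13`); 1-4 pairs interact unscaled. Every pair term is
multiplied by the classical C¹ switching polynomial
(r_off² − r²)²(r_off² + 2r² − 3r_on²)/(r_off² − r_on²)³ between r_on = 6 Å
and r_off = 8 Å, so the truncated energy and its gradient are continuous.
A clash guard rejects any evaluated pair below 0.5 Å as broken geometry.
Analytic position gradients are provided for both terms and validated
against central finite differences (1e-4 Å step, 1e-4 relative tolerance).

Because the protein branch is sequence-only, there is no protein–ligand
pose in the default pipeline; E_phys is therefore the **intra-ligand**
non-bonded sum, computable from SMILES alone. When a complex structure
with per-atom charges and types is supplied, ligand–protein cross terms
are added on top. This ambiguity (intra vs cross) is inherent to a
sequence-only design and is surfaced explicitly in the API
(`total_physical_energy(ligand, protein_context=...)`).

Both energies are min–max normalized to [0,1] with bounds fitted on the
training set only and frozen with the checkpoint; values outside the
fitted range are clipped at apply time, and the model refuses physics
features outside [0,1]. The fused feature vector is (normalized E_Coul,
normalized E_LJ); their sum E_phys is omitted as redundant.

## Model

Drug branch: two graph-convolution layers (symmetric normalisation
D^-1/2(A+I)D^-1/2, ReLU), 128 units each, mean-pooled. Protein branch: one
such layer, 64 units, mean-pooled. Head: concatenation (128 + 64 + 2) →
512 → 256 → 1 with ReLU and dropout 0.2 on the hidden head layers
(inactive at inference). Mean pooling plus symmetric normalisation makes
predictions invariant to node ordering (tested to 1e-5 kcal/mol).

The widths are wider than a typical first guess (e.g. 64-unit branches
with a 128→64 head) for a specific reason: with batch-size-1 MSE updates
and dropout, the relative gradient noise per step scales like 1/√width,
and within the fixed optimization budget (learning rate 5e-4, at most 300
epochs) narrow heads cannot reach the target fit quality on a four-point
regression. Width buys noise averaging, not expressiveness, here.

The forward/backward passes are written directly in NumPy (parameters in
a flat name → array dict, hand-derived gradients); the gradient
implementation is itself finite-difference-checked in the test suite. A
physics-ablated twin (`physics_feature_count=0`) supports quantifying the
fusion pathway's contribution.

A separate, loop-based message-passing engine implements the general
formulation the convolution layers specialise — concatenation messages
(s_j, e_ij), mean (a = 1/|Ne|) or sum (a = 1) aggregation, synchronous
updates, and a convergence criterion max_i ‖s_i^k − s_i^{k−1}‖₂ < ε with
an iteration cap (defaults ε = 1e-4, k_max = 10). Isolated nodes receive a
zero aggregate, since the mean form is undefined at |Ne| = 0. The engine
is the oracle against which brute-force equivalence is tested; the
production model uses fixed-depth layers rather than convergence
iteration.

## Training protocol

Adam with learning rate 5e-4 and L2 weight decay 1e-5 folded into the
gradient (coupled form), MSE loss, one ligand–protein pair per step,
shuffled each epoch, at most 300 epochs, early stopping with patience 30,
and five random seeds whose predictions are averaged per ligand. All
randomness — weight init, shuffling, dropout masks — derives from the
single training seed; two runs with the same seed are identical bit for
bit.

Two training details matter and are the package's own choices:

- **Monitored quantity.** The patience rule watches the inference-mode
  (dropout-off) loss, evaluated at each epoch's end on the validation
  split when one is provided, else on the training set (with four
  fixtures a validation split is impossible). The raw running training
  loss is dominated by dropout noise and trips the patience rule long
  before the fit stops improving.
- **Output-bias warm start.** The head's final bias is initialized to the
  mean training label. Labels live around −10 kcal/mol while a zero-init
  network outputs near 0; without the warm start, most of the epoch
  budget is spent travelling to the label scale, and the patience rule
  can halt on a mid-journey plateau. With it, optimization starts at the
  right scale and converges smoothly.

Percentage error is 100·|y − ŷ|/|y| (undefined at y = 0, reported as
NaN). RMSE is defined as √MSE and R² as 1 − SS_res/SS_tot; R² of a
constant observation vector is NaN with a warning.

## Synthetic data and what passing tests show

The generator samples molecules from a packaged pool of 84 drug-like
single-fragment SMILES, computes their intra-ligand energies through the
same code path the model uses, and labels them by
label = α·E_Coul + β·E_LJ + γ + δ·n_atoms + N(0, noise_sd²).
Defaults α = 0.15, β = 0.12, γ = −10, δ = 0 were chosen once from the
pool's measured energy scales (E_Coul sd ≈ 2.8, E_LJ sd ≈ 7.8 kcal/mol)
so labels fall in a realistic docking-score range, roughly −11.4 to −4.1
kcal/mol with ≈1.2 kcal/mol spread. A noiseless dataset's coefficients
are recovered exactly (to 1e-6) by linear regression on
(E_Coul, E_LJ, n_atoms, 1), validating the generator before it is used to
test the network.

The headline recovery experiment trains on 60 ligands and evaluates on 20
held-out ones. With 0.2 kcal/mol label noise the fused model's held-out
MAE must be below 0.3 kcal/mol and strictly below the physics-ablated
twin's (measured ≈0.21 vs ≈0.98); without noise it must fall below 0.2.
Passing shows the fusion pathway carries the physics signal end to end.
It does **not** show that the model predicts real binding: synthetic
labels are by construction a function of the very features the model is
given, real docking scores are not, and the pool shares no distributional
guarantee with any screening library.

## Problem sizes and numerical choices

The bundled experiments are sized to run on a laptop CPU: 4 fixture
ligands × 5 seeds for the reproduction run, 80 synthetic ligands (60/20
split) for recovery. The 417-residue protein's normalized adjacency and
the pairwise-energy sums are cached per graph. Energies are evaluated in
float64 throughout; the vectorized pair sums match a naive double loop to
1e-10 kcal/mol and are invariant under rigid motions to 1e-8.

Degenerate inputs are handled explicitly: empty neighbourhoods aggregate
to zero vectors; a single-residue protein has zero edges and still embeds;
min–max fitting refuses constant feature columns; conformer embedding
failures name the ligand and suggest a different seed.

## Known limitations

- The protein branch never sees 3D structure in the default pipeline;
  long-range contacts, pocket topology and protonation effects are
  invisible to it.
- Physics features are intra-ligand in the default pipeline (no pose), so
  they inform the model about ligand strain and charge distribution, not
  about the interface.
- The LJ table is element-keyed; hybridization-specific parameters are
  collapsed to representative values.
- With four ligands, the reproduction experiment measures agreement with
  a docking tool under a fixed protocol — nothing more.
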