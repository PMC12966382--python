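# physdual

A physics-informed, dual-branch graph convolutional network (GCN) that acts
as a fast surrogate for docking-based binding-affinity scoring. The package
targets the low-data regime of drug repurposing against understudied
protein targets — concretely, scoring four FDA-approved Alzheimer's drugs
(brexpiprazole, donepezil, galantamine, rivastigmine) against the kinase
DYRK2 — where no experimental affinities exist and classical docking scores
serve as computational reference labels.

## The model

Each ligand SMILES becomes a heavy-atom molecular graph (atoms as nodes
with element / degree / charge features, bonds as edges); the protein
sequence becomes a linear residue graph with consecutive-residue edges. Two
GCN layers encode the ligand, one encodes the protein chain, both with the
symmetric normalisation `D^-1/2 (A+I) D^-1/2` and mean-pooled readouts.

The learned embeddings are fused with two analytical non-bonded energies
computed from Gasteiger partial charges and a seeded 3D conformer:

- Coulomb: `E_Coul = Σ_ij k_e q_i q_j / (ε_r r_ij)` with
  `k_e = 332.0636 kcal·mol⁻¹·Å·e⁻²` and `ε_r = 4` (implicit-solvent
  screening);
- Lennard-Jones 12-6: `E_LJ = Σ_ij 4 ε_ij [(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶]`
  with Lorentz–Berthelot combining rules,

both truncated at 8 Å through a C¹ switching function active from 6 Å, and
min–max normalized to [0,1] with bounds fitted on the training set. A dense
head maps the concatenated vector to one scalar: the predicted binding
energy in kcal/mol (more negative = stronger).

Training follows a fixed protocol: Adam (lr 5·10⁻⁴, weight decay 10⁻⁵),
dropout 0.2, one ligand–protein pair per step, MSE loss, ≤ 300 epochs with
early stopping (patience 30), repeated over five random seeds whose
predictions are averaged per ligand.

A generic message-passing engine (concatenation messages, mean/sum
aggregation, convergence-controlled iteration) ships alongside as a
brute-force-verifiable reference, and a synthetic-data generator produces
labelled ligand sets whose labels follow a known linear function of the
physics features, enabling parameter-recovery tests entirely offline.

## Worked example

```python
import physdual as pdl

fx = pdl.load_paper_fixtures()
protein = pdl.prepare_protein(fx.protein)          # 417-residue chain graph
graphs = [pdl.prepare_ligand(d, seed=0) for d in fx.drugs]
pairs = pdl.prepare_pairs(graphs, protein, fx.reference_labels)

trained = pdl.train(pairs, seed=0)                 # reference protocol
for p in pdl.predict(trained, pairs):
    print(f"{p.ligand_id:14s} {p.predicted_energy:7.2f} kcal/mol")
```

prints (reference labels −9.9, −10.6, −7.4, −7.0):

```
brexpiprazole   -10.05 kcal/mol
donepezil       -10.63 kcal/mol
galantamine      -7.37 kcal/mol
rivastigmine     -6.95 kcal/mol
```

i.e. a single-seed fit within about 1–2% of each docking-derived label;
averaging over the five protocol seeds tightens this further and is what
the evaluation reports. The same pipeline is scriptable from the shell:

```
physdual synth --n 60 --noise-sd 0.2 --seed 1 --out data/
physdual train --ligands data/ligands.csv --labels data/labels.csv --out run/
physdual predict --checkpoint run/model_seed0.npz --ligands data/ligands.csv --out preds.csv
physdual evaluate --predictions preds.csv --labels data/labels.csv
```

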