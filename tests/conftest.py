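"""Shared fixtures.

Heavy artifacts (prepared fixture graphs, the multi-seed training run, the
synthetic-recovery experiment) are session-scoped so the whole suite pays
for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import physdual as pdl
from physdual.model import ModelConfig


@pytest.fixture(scope="session")
def fixture_set():
    return pdl.load_paper_fixtures()


@pytest.fixture(scope="session")
def dyrk2_graph(fixture_set):
    return pdl.prepare_protein(fixture_set.protein)


@pytest.fixture(scope="session")
def fixture_ligand_graphs(fixture_set):
    """The four study drugs, fully prepared with conformer seed 0."""
    return [pdl.prepare_ligand(rec, seed=0) for rec in fixture_set.drugs]


@pytest.fixture(scope="session")
def fixture_training(fixture_set, dyrk2_graph):
    """Reference training protocol on the four fixture ligands, 5 seeds.

    Returns the seed-averaged predictions and the per-item metrics report
    against the reference-tool labels.
    """
    labels = fixture_set.reference_labels
    per_seed = []
    for seed in pdl.TrainConfig().seeds:
        graphs = [pdl.prepare_ligand(rec, seed=seed) for rec in fixture_set.drugs]
        pairs = pdl.prepare_pairs(graphs, dyrk2_graph, labels)
        trained = pdl.train(pairs, seed=seed)
        per_seed.append(pdl.predict(trained, pairs))
    averaged = pdl.seed_average(per_seed)
    ids = [p.ligand_id for p in averaged]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        report = pdl.compute_metrics(
            [labels[i] for i in ids],
            [p.predicted_energy for p in averaged],
            ids=ids,
        )
    return {"averaged": averaged, "report": report, "labels": labels}


def _held_out_mae(dataset, train_pairs, test_pairs, config, seed=5):
    trained = pdl.train(train_pairs, config, seed=seed)
    preds = pdl.predict(trained, test_pairs)
    y = [dataset.labels[p.ligand_id] for p in preds]
    y_pred = [p.predicted_energy for p in preds]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pdl.compute_metrics(y, y_pred).mae


@pytest.fixture(scope="session")
def synthetic_experiment(dyrk2_graph):
    """Parameter-recovery experiment: 60 training / 20 held-out ligands.

    Labels are the linear physics rule with 0.2 kcal/mol noise (and a
    noiseless twin); the physics-fused model is compared against the
    physics-ablated one on the held-out split.
    """
    out = {}
    for label, noise in (("noisy", 0.2), ("noiseless", 0.0)):
        spec = pdl.SyntheticSpec(n_ligands=80, noise_sd=noise, seed=11)
        dataset = pdl.generate_synthetic_dataset(spec)
        pairs = pdl.prepare_pairs(dataset.graphs, dyrk2_graph, dataset.labels)
        train_pairs, test_pairs = pairs[:60], pairs[60:]
        out[label] = {
            "dataset": dataset,
            "fused_mae": _held_out_mae(dataset, train_pairs, test_pairs, ModelConfig()),
        }
    noisy = out["noisy"]
    spec = noisy["dataset"].spec
    pairs = pdl.prepare_pairs(noisy["dataset"].graphs, dyrk2_graph, noisy["dataset"].labels)
    noisy["ablated_mae"] = _held_out_mae(
        noisy["dataset"], pairs[:60], pairs[60:], ModelConfig(physics_feature_count=0)
    )
    return out


def permute_ligand_graph(graph, perm):
    """Relabel atoms of a ligand graph by ``perm`` (new index of old atom i)."""
    import copy

    g = copy.deepcopy(graph)
    inv = np.empty(len(perm), dtype=int)
    for old, new in enumerate(perm):
        inv[new] = old
    atoms = [None] * graph.n_atoms
    for a in g.atoms:
        a.index = int(perm[a.index])
        atoms[a.index] = a
    g.atoms = atoms
    for b in g.bonds:
        b.i, b.j = int(perm[b.i]), int(perm[b.j])
    if g.coords is not None:
        g.coords = g.coords[inv]
    if hasattr(g, "_gcn_a_norm"):
        del g._gcn_a_norm
    return g
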