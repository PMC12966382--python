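"""Training protocol, metrics, seed averaging, comparison tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

import physdual as pdl
from physdual.errors import InputError
from physdual.ligand import LigandRecord
from physdual.model import ModelConfig
from physdual.protein import ProteinRecord
from physdual.training import (
    GAP_MARKER,
    TrainConfig,
    comparison_table,
    compute_metrics,
    format_comparison,
    load_bundle,
    save_bundle,
    seed_average,
)

FAST_MODEL = ModelConfig(
    drug_hidden_dims=(8, 8), protein_hidden_dims=(8,), fusion_dims=(8,)
)


@pytest.fixture(scope="module")
def tiny_pairs():
    protein = pdl.prepare_protein(ProteinRecord("p", "MKVLHACDEF"))
    # molecules large enough to have non-excluded (1-4+) intra pairs
    records = [
        LigandRecord("bol", "CCCCO"),
        LigandRecord("tol", "Cc1ccccc1"),
        LigandRecord("dme", "COCCOC"),
    ]
    graphs = [pdl.prepare_ligand(r, seed=0) for r in records]
    labels = {"bol": -6.0, "tol": -7.5, "dme": -8.2}
    return pdl.prepare_pairs(graphs, protein, labels)


class TestTrain:
    def test_same_seed_identical_run(self, tiny_pairs):
        cfg = TrainConfig(max_epochs=8, early_stopping_patience=3)
        a = pdl.train(tiny_pairs, FAST_MODEL, cfg, seed=3)
        b = pdl.train(tiny_pairs, FAST_MODEL, cfg, seed=3)
        assert a.loss_curve.epoch_losses == b.loss_curve.epoch_losses
        for k in a.model.params:
            assert np.array_equal(a.model.params[k], b.model.params[k])

    def test_constant_labels_are_learned(self, tiny_pairs):
        pairs = [
            pdl.TrainingPair(p.ligand, p.protein, p.raw_physics, -5.0)
            for p in tiny_pairs
        ]
        trained = pdl.train(
            pairs, FAST_MODEL, TrainConfig(learning_rate=1e-2, max_epochs=200), seed=0
        )
        curve = trained.loss_curve.epoch_losses
        assert curve[-1] < 0.01 * curve[0]  # near zero for a learnable constant
        preds = pdl.predict(trained, pairs)
        assert all(abs(p.predicted_energy + 5.0) < 0.5 for p in preds)

    def test_stopping_epoch_obeys_patience_rule_exactly(self, tiny_pairs):
        # a vanishing learning rate freezes the monitored loss from epoch 1,
        # so the plateau starts immediately and the run must stop at
        # 1 + patience
        cfg = TrainConfig(learning_rate=1e-30, max_epochs=50, early_stopping_patience=7)
        trained = pdl.train(tiny_pairs, FAST_MODEL, cfg, seed=0)
        assert trained.loss_curve.stopping_epoch == 1 + 7
        assert len(trained.loss_curve.epoch_losses) == 1 + 7

    def test_missing_label_rejected(self, tiny_pairs):
        broken = [
            pdl.TrainingPair(p.ligand, p.protein, p.raw_physics, None)
            for p in tiny_pairs
        ]
        with pytest.raises(InputError, match="label"):
            pdl.train(broken, FAST_MODEL)

    def test_loss_curve_length_bounded(self, tiny_pairs):
        cfg = TrainConfig(max_epochs=5, early_stopping_patience=4)
        trained = pdl.train(tiny_pairs, FAST_MODEL, cfg, seed=1)
        assert len(trained.loss_curve) <= 5


class TestPredict:
    def test_order_independent_and_composable(self, tiny_pairs):
        cfg = TrainConfig(max_epochs=8, early_stopping_patience=3)
        trained = pdl.train(tiny_pairs, FAST_MODEL, cfg, seed=0)
        fwd = pdl.predict(trained, tiny_pairs)
        rev = pdl.predict(trained, tiny_pairs[::-1])
        assert {p.ligand_id: p.predicted_energy for p in fwd} == {
            p.ligand_id: p.predicted_energy for p in rev
        }
        # composition: predict == fuse_and_predict per pair
        p0 = tiny_pairs[0]
        direct = trained.model.fuse_and_predict(
            trained.model.encode_drug(p0.ligand),
            trained.model.encode_protein(p0.protein),
            trained.normalize(p0.raw_physics),
            ligand_id=p0.ligand_id,
        )
        assert direct.predicted_energy == pytest.approx(
            fwd[0].predicted_energy, abs=1e-12
        )

    def test_empty_input_empty_output(self, tiny_pairs):
        cfg = TrainConfig(max_epochs=8, early_stopping_patience=3)
        trained = pdl.train(tiny_pairs, FAST_MODEL, cfg, seed=0)
        assert pdl.predict(trained, []) == []

    def test_scheme_mismatch_rejected(self, tiny_pairs):
        cfg = TrainConfig(max_epochs=8, early_stopping_patience=3)
        trained = pdl.train(tiny_pairs, FAST_MODEL, cfg, seed=0)
        trained.ligand_feature_scheme = "exotic"
        with pytest.raises(InputError, match="scheme"):
            pdl.predict(trained, tiny_pairs)

    def test_checkpoint_roundtrip_preserves_predictions(self, tiny_pairs, tmp_path):
        cfg = TrainConfig(max_epochs=8, early_stopping_patience=3)
        trained = pdl.train(tiny_pairs, FAST_MODEL, cfg, seed=2)
        save_bundle(trained, tmp_path / "model.npz")
        loaded = load_bundle(tmp_path / "model.npz")
        a = pdl.predict(trained, tiny_pairs)
        b = pdl.predict(loaded, tiny_pairs)
        for x, y in zip(a, b):
            assert x.predicted_energy == y.predicted_energy


class TestSeedAverage:
    def _mk(self, values):
        return [
            pdl.AffinityPrediction(lid, v) for lid, v in zip(["a", "b"], values)
        ]

    def test_mean_of_constants(self):
        avg = seed_average([self._mk([-10, -7]), self._mk([-10, -7])])
        assert [p.predicted_energy for p in avg] == [-10, -7]

    def test_arithmetic(self):
        avg = seed_average([self._mk([-10, -7]), self._mk([-11, -8])])
        assert [p.predicted_energy for p in avg] == [-10.5, -7.5]

    def test_single_seed_identity(self):
        avg = seed_average([self._mk([-9.4, -6.1])])
        assert [p.predicted_energy for p in avg] == [-9.4, -6.1]

    def test_inconsistent_ligand_sets_rejected(self):
        with pytest.raises(InputError, match="different ligand sets"):
            seed_average(
                [self._mk([-10, -7]), [pdl.AffinityPrediction("zzz", -1.0)]]
            )


class TestComputeMetrics:
    def test_perfect_prediction(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rep = compute_metrics([-9.9, -10.6, -7.4], [-9.9, -10.6, -7.4])
        assert (rep.mae, rep.mse, rep.rmse) == (0.0, 0.0, 0.0)
        assert rep.r2 == 1.0

    def test_hand_computed_example(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rep = compute_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert rep.mae == pytest.approx(2 / 3)
        assert rep.mse == pytest.approx(2 / 3)
        assert rep.r2 == pytest.approx(0.0)

    def test_metric_identities_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            y = rng.normal(size=n) * 5
            yh = y + rng.normal(size=n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rep = compute_metrics(y, yh)
            assert rep.rmse**2 == pytest.approx(rep.mse, abs=1e-10)
            assert rep.mae <= rep.rmse + 1e-12
            assert rep.r2 <= 1.0

    def test_constant_observations_warn_and_nan(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            rep = compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(rep.r2)

    def test_small_sample_warns(self):
        with pytest.warns(RuntimeWarning, match="generalization"):
            compute_metrics([1.0, 2.0], [1.1, 2.2])

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            compute_metrics([1.0], [1.0, 2.0])

    def test_percentage_error_definition(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rep = compute_metrics([-10.0, -8.0], [-9.5, -8.4])
        assert rep.per_item[0][4] == pytest.approx(5.0)
        assert rep.per_item[1][4] == pytest.approx(5.0)


class TestComparisonTable:
    def test_reference_against_itself_zero_error(self, fixture_set):
        table, metrics = comparison_table(
            fixture_set.reference_scores, reference="Vina"
        )
        assert metrics["Vina"].mae == 0.0
        assert metrics["Vina"].rmse == 0.0

    def test_reference_row_roundtrips(self, fixture_set):
        table, _ = comparison_table(fixture_set.reference_scores, reference="Vina")
        assert list(table["Vina"][["brexpiprazole", "donepezil",
                                   "galantamine", "rivastigmine"]]) == [
            -9.9, -10.6, -7.4, -7.0
        ]
        text = format_comparison(table)
        assert "-10.60" in text

    def test_disjoint_ligands_marked_not_dropped(self):
        table, _ = comparison_table(
            {"m1": {"a": -1.0}, "m2": {"b": -2.0}}, reference="m1"
        )
        assert np.isnan(table.loc["b", "m1"])
        assert np.isnan(table.loc["a", "m2"])
        assert GAP_MARKER in format_comparison(table)

    def test_unknown_reference(self):
        with pytest.raises(InputError):
            comparison_table({"m": {"a": 1.0}}, reference="zz")
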