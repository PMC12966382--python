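"""Training protocol and evaluation metrics.

Training follows the reference protocol: Adam (learning rate 5e-4, weight
decay 1e-5), dropout 0.2 in the dense head, one ligand-protein pair per
step, mean-squared-error loss, at most 300 epochs with early stopping at a
patience of 30 epochs, and multi-seed repetition (default 5 seeds) whose
predictions are averaged per ligand. All randomness (weight init, epoch
shuffling, dropout masks) flows from the single integer seed passed to
:func:`train`, so a rerun with the same seed is bit-for-bit identical.

Metrics are the standard regression set: MAE, MSE, RMSE = sqrt(MSE), and
R^2 = 1 - SS_res/SS_tot, plus a per-item percentage error
100 |y - yhat| / |y|.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError
from .ligand import LigandGraph
from .model import AffinityPrediction, ModelConfig, PhysDualGCN
from .physics import (
    EnergyBreakdown,
    MinMaxScaler,
    NonbondedConfig,
    fit_minmax,
    total_physical_energy,
)
from .protein import ProteinGraph

__all__ = [
    "TrainConfig",
    "TrainingPair",
    "TrainedModel",
    "LossCurve",
    "MetricsReport",
    "prepare_pairs",
    "train",
    "predict",
    "seed_average",
    "compute_metrics",
    "comparison_table",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 1e-5
    batch_size: int = 1
    max_epochs: int = 300
    early_stopping_patience: int = 30
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    loss: str = "mse"

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise InputError("learning_rate, batch_size, max_epochs must be positive")
        if self.weight_decay < 0:
            raise InputError("weight_decay must be >= 0")
        if not 0 < self.early_stopping_patience < self.max_epochs:
            raise InputError("patience must satisfy 0 < patience < max_epochs")
        if self.loss != "mse":
            raise InputError(f"unsupported loss {self.loss!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainingPair:
    """One supervised example: featurized graphs + raw physics + label."""

    ligand: LigandGraph
    protein: ProteinGraph
    raw_physics: np.ndarray  # unscaled (E_Coul, E_LJ) in kcal/mol
    label: float | None = None  # kcal/mol
    energy: EnergyBreakdown | None = None

    @property
    def ligand_id(self) -> str:
        return self.ligand.record.id


@dataclass
class LossCurve:
    epoch_losses: list[float]
    stopping_epoch: int

    def __len__(self):
        return len(self.epoch_losses)


@dataclass
class TrainedModel:
    """A model plus everything needed to reproduce its predictions."""

    model: PhysDualGCN
    scalers: list[MinMaxScaler]
    loss_curve: LossCurve
    train_config: TrainConfig
    seed: int
    ligand_feature_scheme: str | None = None
    protein_feature_scheme: str | None = None

    def normalize(self, raw_physics: np.ndarray) -> np.ndarray:
        if not self.scalers:  # physics-ablated model: features unused
            return np.zeros(0)
        if len(self.scalers) != len(raw_physics):
            raise InputError(
                f"checkpoint carries {len(self.scalers)} physics scalers but "
                f"{len(raw_physics)} raw features were supplied"
            )
        return np.array([s.apply(v) for s, v in zip(self.scalers, raw_physics)])


def prepare_pairs(
    ligands: list[LigandGraph],
    protein: ProteinGraph,
    labels: dict[str, float] | None = None,
    config: NonbondedConfig = NonbondedConfig(),
    table=None,
) -> list[TrainingPair]:
    """Assemble training pairs: compute intra-ligand physics, attach labels."""
    pairs = []
    for lig in ligands:
        breakdown = total_physical_energy(lig, None, config, table)
        label = None
        if labels is not None:
            if lig.record.id not in labels:
                raise InputError(f"no label for ligand {lig.record.id!r}")
            label = float(labels[lig.record.id])
        pairs.append(
            TrainingPair(
                ligand=lig,
                protein=protein,
                raw_physics=np.array([breakdown.e_coul, breakdown.e_lj]),
                label=label,
                energy=breakdown,
            )
        )
    return pairs


class _Adam:
    """Adam with L2 weight decay folded into the gradient (coupled form)."""

    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k] + self.wd * p
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] = p - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _fit_scalers(pairs: list[TrainingPair], n_features: int) -> list[MinMaxScaler]:
    return [
        fit_minmax([p.raw_physics[k] for p in pairs]) for k in range(n_features)
    ]


def train(
    pairs: list[TrainingPair],
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    seed: int = 0,
    validation: list[TrainingPair] | None = None,
) -> TrainedModel:
    """Fit the model on labelled pairs; fully deterministic given ``seed``.

    Early stopping monitors the validation loss when a validation set is
    supplied, otherwise the epoch-mean training loss (with only a handful of
    ligands a validation split is impossible). Min-max scalers for the
    physics features are fitted on the training pairs only and frozen.
    """
    if not pairs:
        raise InputError("training needs at least one pair")
    for p in pairs:
        if p.label is None or not np.isfinite(p.label):
            raise InputError(f"ligand {p.ligand_id!r} has no finite label")

    n_phys = model_config.physics_feature_count
    scalers = _fit_scalers(pairs, n_phys) if n_phys else []
    phys = {
        p.ligand_id: np.array([s.apply(v) for s, v in zip(scalers, p.raw_physics)])
        for p in pairs + (validation or [])
    }

    model = PhysDualGCN(model_config, seed=seed)
    # output-bias warm start at the mean label: the head then learns
    # deviations around the label scale instead of travelling from zero,
    # which keeps the early optimization smooth under batch-size-1 updates
    model.params[f"head_b{model._n_head - 1}"][:] = float(
        np.mean([p.label for p in pairs])
    )
    rng = np.random.default_rng(seed + 1)
    opt = _Adam(model.params, train_config.learning_rate, train_config.weight_decay)

    def monitored_loss():
        # Inference-mode (dropout-off) loss on the monitored split; the raw
        # running training loss is dominated by dropout noise and would
        # trigger the patience rule long before the fit stops improving.
        split = validation if validation is not None else pairs
        errs = [
            (model.forward(p.ligand, p.protein, phys[p.ligand_id])[0] - p.label) ** 2
            for p in split
        ]
        return float(np.mean(errs))

    epoch_losses: list[float] = []
    best = np.inf
    since_improve = 0
    stopping_epoch = train_config.max_epochs
    order = np.arange(len(pairs))
    for epoch in range(1, train_config.max_epochs + 1):
        rng.shuffle(order)
        losses = []
        for idx in order:
            p = pairs[idx]
            y, cache = model.forward(
                p.ligand, p.protein, phys[p.ligand_id], training=True, rng=rng
            )
            err = y - p.label
            loss = err**2
            if not np.isfinite(loss):
                raise ComputationError(
                    f"non-finite loss at epoch {epoch}, ligand {p.ligand_id!r}"
                )
            grads = model.backward(cache, 2.0 * err)
            opt.step(model.params, grads)
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
        current = monitored_loss()
        if current < best:
            best = current
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= train_config.early_stopping_patience:
                stopping_epoch = epoch
                break
    else:
        stopping_epoch = train_config.max_epochs
    return TrainedModel(
        model=model,
        scalers=scalers,
        loss_curve=LossCurve(epoch_losses, stopping_epoch),
        train_config=train_config,
        seed=seed,
        ligand_feature_scheme=pairs[0].ligand.feature_scheme,
        protein_feature_scheme=pairs[0].protein.feature_scheme,
    )


def predict(trained: TrainedModel, pairs: list[TrainingPair]) -> list[AffinityPrediction]:
    """Deterministic, order-independent inference over pairs."""
    out = []
    for p in pairs:
        if (
            trained.ligand_feature_scheme is not None
            and p.ligand.feature_scheme != trained.ligand_feature_scheme
        ):
            raise InputError(
                f"ligand {p.ligand_id!r} was featurized with scheme "
                f"{p.ligand.feature_scheme!r}, checkpoint expects "
                f"{trained.ligand_feature_scheme!r}"
            )
        normalized = trained.normalize(p.raw_physics)
        y, _ = trained.model.forward(p.ligand, p.protein, normalized)
        out.append(AffinityPrediction(ligand_id=p.ligand_id, predicted_energy=y))
    return out


def seed_average(
    per_seed_predictions: list[list[AffinityPrediction]],
) -> list[AffinityPrediction]:
    """Arithmetic mean of predictions per ligand across seeds."""
    if not per_seed_predictions:
        raise InputError("no predictions to average")
    ref_ids = [p.ligand_id for p in per_seed_predictions[0]]
    for preds in per_seed_predictions[1:]:
        if [p.ligand_id for p in preds] != ref_ids:
            raise InputError(
                "seed runs predicted different ligand sets; cannot average"
            )
    out = []
    for k, lid in enumerate(ref_ids):
        vals = [preds[k].predicted_energy for preds in per_seed_predictions]
        out.append(AffinityPrediction(ligand_id=lid, predicted_energy=float(np.mean(vals))))
    return out


@dataclass
class MetricsReport:
    per_item: list[tuple[str, float, float, float, float]]  # id, y, yhat, |err|, %err
    mae: float
    mse: float
    rmse: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "mse": self.mse,
            "rmse": self.rmse,
            "r2": self.r2,
            "per_item": [
                {
                    "id": i,
                    "y": y,
                    "y_pred": yh,
                    "abs_error": ae,
                    "pct_error": pe,
                }
                for i, y, yh, ae, pe in self.per_item
            ],
        }

    def __str__(self):
        lines = [f"n={self.n}  MAE={self.mae:.3f}  MSE={self.mse:.3f}  "
                 f"RMSE={self.rmse:.3f}  R2={self.r2:.3f}"]
        for i, y, yh, ae, pe in self.per_item:
            lines.append(
                f"  {i}: y={y:.2f}  y_pred={yh:.2f}  |err|={ae:.2f}  %err={pe:.2f}"
            )
        return "\n".join(lines)


def compute_metrics(y, y_pred, ids: list[str] | None = None) -> MetricsReport:
    """MAE / MSE / RMSE / R^2 and per-item absolute and percentage errors.

    R^2 is reported as NaN (with a warning) when the observed values are
    all identical; a small-sample warning is emitted for n < 8 because R^2
    carries no generalization meaning at such sizes.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1 or y.size == 0:
        raise InputError(
            f"need equal-length non-empty 1-D vectors, got {y.shape} vs {y_pred.shape}"
        )
    if ids is None:
        ids = [str(k) for k in range(y.size)]
    if len(ids) != y.size:
        raise InputError("ids length does not match the value vectors")
    abs_err = np.abs(y - y_pred)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(y != 0, 100.0 * abs_err / np.abs(y), np.nan)
    mae = float(abs_err.mean())
    mse = float((abs_err**2).mean())
    rmse = float(np.sqrt(mse))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn(
            "R^2 is undefined when all observed values are identical; reporting NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        r2 = float("nan")
    else:
        r2 = float(1.0 - (abs_err**2).sum() / ss_tot)
    if y.size < 8:
        warnings.warn(
            f"R^2 computed from only n={y.size} items is a fit diagnostic, "
            "not evidence of generalization",
            RuntimeWarning,
            stacklevel=2,
        )
    per_item = [
        (ids[k], float(y[k]), float(y_pred[k]), float(abs_err[k]), float(pct[k]))
        for k in range(y.size)
    ]
    return MetricsReport(per_item=per_item, mae=mae, mse=mse, rmse=rmse, r2=r2, n=y.size)


GAP_MARKER = "-"


def comparison_table(
    method_scores: dict[str, dict[str, float]],
    reference: str,
):
    """Cross-method score matrix plus per-method metrics vs a reference.

    ``method_scores`` maps method name -> {ligand_id: score}. Ligands missing
    from a method appear as an explicit gap marker, never silently dropped;
    metrics for a method use only the ligands it shares with the reference.
    Returns ``(table: pandas.DataFrame, metrics: dict[str, MetricsReport])``.
    """
    if reference not in method_scores:
        raise InputError(f"reference method {reference!r} not in the score table")
    ligands = sorted({lid for scores in method_scores.values() for lid in scores})
    table = pd.DataFrame(
        {
            method: [scores.get(lid, np.nan) for lid in ligands]
            for method, scores in method_scores.items()
        },
        index=ligands,
    )
    ref = method_scores[reference]
    metrics = {}
    for method, scores in method_scores.items():
        shared = [lid for lid in ligands if lid in scores and lid in ref]
        if shared:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                metrics[method] = compute_metrics(
                    [ref[lid] for lid in shared],
                    [scores[lid] for lid in shared],
                    ids=shared,
                )
    return table, metrics


def format_comparison(table: pd.DataFrame) -> str:
    return table.to_string(na_rep=GAP_MARKER, float_format=lambda v: f"{v:.2f}")


# -- checkpointing -----------------------------------------------------------


def save_bundle(trained: TrainedModel, path) -> None:
    """Serialize weights + config + scalers + schemes into one .npz bundle."""
    meta = {
        "model_config": trained.model.config.to_dict(),
        "train_config": trained.train_config.to_dict(),
        "seed": trained.seed,
        "scalers": [(s.lower, s.upper) for s in trained.scalers],
        "ligand_feature_scheme": trained.ligand_feature_scheme,
        "protein_feature_scheme": trained.protein_feature_scheme,
        "loss_curve": trained.loss_curve.epoch_losses,
        "stopping_epoch": trained.loss_curve.stopping_epoch,
    }
    np.savez(
        path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **trained.model.state_dict(),
    )


def load_bundle(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = PhysDualGCN(ModelConfig.from_dict(meta["model_config"]), seed=meta["seed"])
    model.load_state_dict(state)
    tc = meta["train_config"]
    tc["seeds"] = tuple(tc["seeds"])
    return TrainedModel(
        model=model,
        scalers=[MinMaxScaler(lo, hi) for lo, hi in meta["scalers"]],
        loss_curve=LossCurve(meta["loss_curve"], meta["stopping_epoch"]),
        train_config=TrainConfig(**tc),
        seed=meta["seed"],
        ligand_feature_scheme=meta["ligand_feature_scheme"],
        protein_feature_scheme=meta["protein_feature_scheme"],
    )
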