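"""The many-to-one recurrent surrogate of tumor volume change.

The model reads an 18-step, two-channel stimulus sequence (radiation effect,
antibody code) and predicts the vector of up to five inter-measurement volume
changes dVC'_i from the final step's hidden state.  The loss is a masked sum
of squares,

    Loss = sum_i (dVC_i - dVC'_i)^2        over measured intervals only,

averaged over the batch.  Targets are scaled by ``target_scale`` (default
100 mm^3) during optimization and unscaled on prediction, so the public
surface always speaks mm^3.

Training defaults follow the study protocol: 100 hidden units, Adam with
lr = 1e-3, beta1 = 0.9, beta2 = 0.999, eps = 1e-8, batch size 100 and 5000
epochs; validation holds out two whole treatment groups (= 100 samples of a
26-group, 50-sample study) rather than a random 20% of samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .preprocess import Dataset

__all__ = [
    "ModelConfig",
    "SurrogateModel",
    "TrainResult",
    "CrossValFold",
    "masked_loss",
    "train",
    "predict",
    "crossvalidate",
]


@dataclass(frozen=True)
class ModelConfig:
    hidden_units: int = 100
    n_steps: int = 18
    n_input_channels: int = 2
    n_outputs: int = 5
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 100
    epochs: int = 5000
    seed: int = 0
    target_scale: float = 100.0
    grad_clip: float = 5.0
    n_validation_groups: int = 2

    def __post_init__(self) -> None:
        if min(self.hidden_units, self.n_steps, self.n_outputs, self.batch_size) < 1:
            raise ValueError("sizes must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.target_scale <= 0:
            raise ValueError("target_scale must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d) -> "ModelConfig":
        return cls(**d)


@dataclass
class SurrogateModel:
    """Trained LSTM surrogate: weights + configuration + seed provenance."""

    config: ModelConfig
    params: nn.Params

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return predict(self, inputs)

    def predict_batch(self, inputs: np.ndarray) -> np.ndarray:
        x = np.asarray(inputs, dtype=float)
        self._check_shape(x)
        y, _ = nn.lstm_forward(self.params, x)
        return y * self.config.target_scale

    def hidden_states(self, inputs: np.ndarray, cell: bool = False) -> np.ndarray:
        """Per-step hidden (or cell) state for one sequence, shape (T, H)."""
        x = np.asarray(inputs, dtype=float)
        if x.ndim == 2:
            x = x[None]
        self._check_shape(x)
        _, cache = nn.lstm_forward(self.params, x)
        return cache["c" if cell else "h"][0]

    def _check_shape(self, x: np.ndarray) -> None:
        c = self.config
        if x.ndim != 3 or x.shape[1] != c.n_steps or x.shape[2] != c.n_input_channels:
            raise ValueError(
                f"expected inputs (n, {c.n_steps}, {c.n_input_channels}), got {x.shape}"
            )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(
            json.dumps(self.config.to_dict(), indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        path = Path(path)
        config = ModelConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
        with np.load(path.with_suffix(".npz")) as z:
            params = {k: z[k].copy() for k in z.files}
        return cls(config=config, params=params)


@dataclass
class TrainResult:
    model: SurrogateModel
    train_curve: np.ndarray
    val_curve: np.ndarray
    validation_groups: tuple[str, ...] = ()

    @property
    def config(self) -> ModelConfig:
        return self.model.config


@dataclass
class CrossValFold:
    holdout_groups: tuple[str, ...]
    result: TrainResult
    holdout_loss: float


def masked_loss(
    predicted: np.ndarray, target: np.ndarray, mask: np.ndarray
) -> float:
    """Sum of squared errors over mask-true entries; batches average samples.

    For 1-D inputs this is a plain masked sum of squares.  For 2-D inputs
    (batch, n_outputs) each sample contributes its masked sum and the batch
    value is the mean over samples; a sample whose mask is all False
    contributes zero.
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if p.shape != t.shape or p.shape != m.shape:
        raise ValueError(f"shape mismatch: {p.shape}, {t.shape}, {m.shape}")
    sq = np.where(m, (p - t) ** 2, 0.0)
    if p.ndim == 1:
        return float(sq.sum())
    if p.ndim == 2:
        return float(sq.sum(axis=1).mean())
    raise ValueError("predicted must be 1-D or 2-D")


def _loss_and_grad(params, x, targets, mask):
    y, cache = nn.lstm_forward(params, x)
    diff = np.where(mask, y - targets, 0.0)
    loss = float((diff**2).sum(axis=1).mean())
    dy = 2.0 * diff / x.shape[0]
    grads = nn.lstm_backward(params, cache, dy)
    return loss, grads


def _eval_loss(params, x, targets, mask) -> float:
    y, _ = nn.lstm_forward(params, x)
    return masked_loss(y, targets, mask)


def _split_validation(
    dataset: Dataset,
    config: ModelConfig,
    rng: np.random.Generator,
    validation_groups: Sequence[str] | None,
):
    gids = dataset.group_ids.astype(str)
    if validation_groups is None:
        groups = list(dataset.unique_groups)
        k = config.n_validation_groups
        if k == 0 or len(groups) <= k:
            validation_groups = ()
        else:
            idx = rng.choice(len(groups), size=k, replace=False)
            validation_groups = tuple(groups[i] for i in sorted(idx))
    validation_groups = tuple(str(g) for g in validation_groups)
    val_mask = np.isin(gids, validation_groups)
    return dataset.subset(~val_mask), dataset.subset(val_mask), validation_groups


def train(
    dataset: Dataset,
    config: ModelConfig | None = None,
    validation_groups: Sequence[str] | None = None,
) -> TrainResult:
    """Fit the surrogate with Adam on the masked squared-error loss.

    Validation holds out whole treatment groups (``validation_groups`` if
    given, else ``config.n_validation_groups`` groups chosen by the seeded
    RNG).  Deterministic: the seed fixes initialization, the validation
    split and the per-epoch shuffling.

    Raises
    ------
    FloatingPointError
        If the training loss goes non-finite (diverged optimization).
    """
    config = config or ModelConfig()
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)

    train_ds, val_ds, val_groups = _split_validation(
        dataset, config, rng, validation_groups
    )
    if len(train_ds) == 0:
        raise ValueError("validation split left no training samples")

    scale = config.target_scale
    xtr = train_ds.inputs.astype(float)
    ttr = train_ds.targets / scale
    mtr = train_ds.mask.astype(bool)
    has_val = len(val_ds) > 0
    if has_val:
        xva = val_ds.inputs.astype(float)
        tva = val_ds.targets / scale
        mva = val_ds.mask.astype(bool)

    params = nn.init_params(
        config.n_input_channels, config.hidden_units, config.n_outputs, rng
    )
    opt = nn.Adam(
        params, config.learning_rate, config.beta1, config.beta2, config.epsilon
    )

    n = len(train_ds)
    bs = min(config.batch_size, n)
    train_curve = np.empty(config.epochs)
    val_curve = np.full(config.epochs, np.nan)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            sel = order[start : start + bs]
            loss, grads = _loss_and_grad(params, xtr[sel], ttr[sel], mtr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss became non-finite at epoch {epoch}"
                )
            nn.clip_grad_norm(grads, config.grad_clip)
            opt.step(params, grads)
            losses.append(loss)
        train_curve[epoch] = float(np.mean(losses))
        if has_val:
            val_curve[epoch] = _eval_loss(params, xva, tva, mva)

    model = SurrogateModel(config=config, params=params)
    return TrainResult(
        model=model,
        train_curve=train_curve,
        val_curve=val_curve,
        validation_groups=val_groups,
    )


def predict(model: SurrogateModel, inputs: np.ndarray) -> np.ndarray:
    """Predicted volume changes dVC' (mm^3) for one encoded schedule."""
    x = np.asarray(inputs, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a single (n_steps, channels) matrix, got {x.shape}")
    return model.predict_batch(x[None])[0]


def crossvalidate(
    dataset: Dataset,
    config: ModelConfig | None = None,
    n_repeats: int = 5,
    n_holdout_groups: int = 2,
    seed: int | None = None,
) -> list[CrossValFold]:
    """Leave-``n_holdout_groups``-out validation repeated ``n_repeats`` times.

    Each repeat draws a fresh random pair of groups, trains on the remainder
    and reports the masked loss (mm^3 scale) on the held-out samples.  With
    ``n_holdout_groups = 0`` a single fold trains on everything and reports
    NaN holdout loss.
    """
    config = config or ModelConfig()
    groups = list(dataset.unique_groups)
    if n_holdout_groups >= len(groups):
        raise ValueError(
            f"cannot hold out {n_holdout_groups} of {len(groups)} groups"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)

    folds: list[CrossValFold] = []
    n_folds = n_repeats if n_holdout_groups > 0 else 1
    for fold in range(n_folds):
        if n_holdout_groups > 0:
            idx = rng.choice(len(groups), size=n_holdout_groups, replace=False)
            holdout = tuple(groups[i] for i in sorted(idx))
        else:
            holdout = ()
        fold_config = dataclasses.replace(
            config, seed=int(rng.integers(0, 2**31 - 1))
        )
        result = train(dataset, fold_config, validation_groups=holdout)
        if holdout:
            sel = np.isin(dataset.group_ids.astype(str), holdout)
            held = dataset.subset(sel)
            pred = result.model.predict_batch(held.inputs)
            loss = masked_loss(pred, held.targets, held.mask)
        else:
            loss = float("nan")
        folds.append(CrossValFold(holdout, result, loss))
    return folds
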