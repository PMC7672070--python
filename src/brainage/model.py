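"""Age regression from 3D volumes with a small residual CNN.

The regressor mirrors the architecture family used for brain-age prediction
from T1-weighted MRI: a convolutional stem, residual stages with stride-2
downsampling, batch normalisation and ReLU activations, global average
pooling and a linear head, trained by minimising the mean squared error with
Adam.  The network is implemented on top of :mod:`brainage.nn` and accepts
any input grid whose dimensions are compatible with its total downsampling
factor, from desk-scale 32x32x32 cohorts up to full 182x218x182 scans.

Raw CNN predictions regress toward the cohort mean age, so the module also
provides the standard linear bias correction: ordinary least squares of the
raw prediction on chronological age, fitted on the training split only, then
inverted, yhat = (yhat_raw - alpha) / beta.  The brain-age difference (delta)
is the corrected prediction minus chronological age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .cohort import VolumeSample, stack_volumes

__all__ = [
    "ModelConfig",
    "SplitPlan",
    "BiasCorrection",
    "PredictionRecord",
    "AgeModel",
    "make_split",
    "build_model",
    "train",
    "predict",
    "fit_bias_correction",
    "apply_bias_correction",
    "evaluate",
    "records_to_frame",
]

# Fractions of the total cohort assigned to (train, validation, healthy-test,
# general-test); defaults follow the 3,067 / 3,962 / 2,057 / 12,296 split of a
# 21,382-subject cohort.
DEFAULT_FRACTIONS = (0.1434, 0.1853, 0.0962, 0.5751)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters for the age regressor."""

    input_shape: tuple[int, int, int] = (32, 32, 32)
    channels: tuple[int, ...] = (4, 8, 16)   # one entry per residual stage
    blocks_per_stage: int = 1
    stem_stride: int = 2
    use_batch_norm: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 16
    n_epochs: int = 12
    normalize_input: bool = True             # per-volume z-scoring
    center_target: bool = True               # regress age minus training mean
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")
        if not self.channels:
            raise ValueError("at least one stage is required")

    @property
    def total_downsampling(self) -> int:
        return self.stem_stride * 2 ** (len(self.channels) - 1)


@dataclass
class SplitPlan:
    """Disjoint cohort split; only healthy subjects may enter the first three sets."""

    train: list[str]
    validation: list[str]
    healthy_test: list[str]
    general_test: list[str]
    healthy: dict[str, bool]

    def __post_init__(self):
        sets = [set(self.train), set(self.validation),
                set(self.healthy_test), set(self.general_test)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("split sets must be pairwise disjoint")
        for name in ("train", "validation", "healthy_test"):
            for sid in getattr(self, name):
                if not self.healthy.get(sid, False):
                    raise ValueError(f"unhealthy subject {sid} in healthy-only set {name}")


@dataclass(frozen=True)
class BiasCorrection:
    """Linear age-bias model ``raw_pred ~ alpha + beta * age`` fitted on training data.

    ``mode`` selects how the correction is applied:

    * ``"invert"`` (default): ``corrected = (raw - alpha) / beta``;
    * ``"residual"``: subtract the fitted residual trend,
      ``corrected = raw - (alpha + beta * age) + age``.
    """

    alpha: float
    beta: float
    mode: str = "invert"

    def __post_init__(self):
        if self.beta == 0:
            raise ValueError("bias-correction slope beta must be nonzero")
        if self.mode not in ("invert", "residual"):
            raise ValueError("mode must be 'invert' or 'residual'")


@dataclass(frozen=True)
class PredictionRecord:
    subject_id: str
    age: float
    raw_pred: float
    corrected_pred: float
    delta: float                    # corrected_pred - age, always

    def __post_init__(self):
        if not np.isclose(self.delta, self.corrected_pred - self.age, atol=1e-9):
            raise ValueError("delta must equal corrected_pred - age")


def make_split(
    subjects: Sequence[str],
    healthy_flags: Sequence[bool],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitPlan:
    """Randomly assign subjects to train/validation/healthy-test/general-test.

    Unhealthy subjects all land in the general-test set; the three
    healthy-only sets are filled to ``round(n_total * fraction)`` from the
    shuffled healthy pool and the remaining healthy subjects join the general
    set.
    """
    subjects = list(subjects)
    healthy_flags = list(healthy_flags)
    if len(subjects) != len(healthy_flags):
        raise ValueError("subjects and healthy_flags must align")
    if len(fractions) != 4:
        raise ValueError("need four fractions (train, val, healthy-test, general-test)")
    if not np.isclose(sum(fractions), 1.0, atol=1e-6):
        raise ValueError("fractions must sum to 1")

    n = len(subjects)
    healthy = {s: bool(h) for s, h in zip(subjects, healthy_flags)}
    pool = [s for s in subjects if healthy[s]]
    unhealthy = [s for s in subjects if not healthy[s]]

    sizes = [int(round(n * f)) for f in fractions[:3]]
    if sum(sizes) > len(pool):
        raise ValueError(
            f"healthy pool ({len(pool)}) smaller than requested healthy-set "
            f"sizes ({sizes})")

    rng = np.random.default_rng(seed)
    pool = [pool[i] for i in rng.permutation(len(pool))]
    train_ids = pool[:sizes[0]]
    val_ids = pool[sizes[0]:sizes[0] + sizes[1]]
    htest_ids = pool[sizes[0] + sizes[1]:sum(sizes)]
    general = pool[sum(sizes):] + unhealthy
    return SplitPlan(train=train_ids, validation=val_ids, healthy_test=htest_ids,
                     general_test=general, healthy=healthy)


class AgeModel:
    """3D residual CNN mapping a batch of volumes to one age each."""

    def __init__(self, cfg: ModelConfig):
        for dim in cfg.input_shape:
            if dim < cfg.total_downsampling:
                raise ValueError(
                    f"input_shape {cfg.input_shape} has a dimension smaller than "
                    f"the network's total downsampling factor {cfg.total_downsampling}")
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)

        def bn(c):
            return nn.BatchNorm3d(c, dtype=dtype) if cfg.use_batch_norm else nn._Identity()

        layers: list[nn.Layer] = [
            nn.Conv3d(1, cfg.channels[0], 3, cfg.stem_stride, rng, dtype),
            bn(cfg.channels[0]),
            nn.ReLU(),
        ]
        c_prev = cfg.channels[0]
        for stage, c in enumerate(cfg.channels):
            for block in range(cfg.blocks_per_stage):
                stride = 2 if (stage > 0 and block == 0) else 1
                layers.append(nn.ResidualBlock3d(c_prev, c, stride, rng,
                                                 cfg.use_batch_norm, dtype))
                c_prev = c
        layers.append(nn.GlobalAvgPool3d())
        layers.append(nn.Linear(c_prev, 1, rng, dtype))
        self.net = nn._Sequential(layers)
        self.output_offset = 0.0     # set by train() when targets are centered
        self._dtype = dtype

    # -- plumbing -----------------------------------------------------------
    def params(self):
        return list(self.net.params())

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _buffers(self) -> list[nn.BatchNorm3d]:
        out = []

        def walk(layer):
            if isinstance(layer, nn.BatchNorm3d):
                out.append(layer)
            for attr in ("layers",):
                for sub in getattr(layer, attr, []):
                    walk(sub)
            for attr in ("main", "skip"):
                sub = getattr(layer, attr, None)
                if sub is not None:
                    walk(sub)

        walk(self.net)
        return out

    def get_state(self) -> dict:
        return {
            "params": [p.value.copy() for p in self.params()],
            "running": [(b.running_mean.copy(), b.running_var.copy())
                        for b in self._buffers()],
            "output_offset": self.output_offset,
        }

    def set_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.value[...] = v
        for b, (mean, var) in zip(self._buffers(), state["running"]):
            b.running_mean[...] = mean
            b.running_var[...] = var
        self.output_offset = state["output_offset"]

    # -- inference ----------------------------------------------------------
    def _prepare(self, volumes: np.ndarray) -> np.ndarray:
        x = np.asarray(volumes, dtype=self._dtype)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != tuple(self.cfg.input_shape):
            raise ValueError(f"expected volumes of shape (N,)+{self.cfg.input_shape}, "
                             f"got {x.shape}")
        x = x[:, None]               # add channel axis
        if self.cfg.normalize_input:
            mean = x.mean(axis=(2, 3, 4), keepdims=True)
            std = x.std(axis=(2, 3, 4), keepdims=True)
            x = (x - mean) / (std + 1e-8)
        return x

    def forward_batch(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.net.forward(x, train)[:, 0]

    def predict(self, volumes: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x = self._prepare(volumes)
        preds = [self.forward_batch(x[i:i + batch_size], train=False)
                 for i in range(0, len(x), batch_size)]
        return np.concatenate(preds).astype(np.float64) + self.output_offset


def build_model(cfg: ModelConfig) -> AgeModel:
    """Construct a seeded, untrained age regressor from a config."""
    return AgeModel(cfg)


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept either (volumes, ages) arrays or a list of VolumeSample."""
    if isinstance(dataset, tuple):
        X, y = dataset
        return np.asarray(X), np.asarray(y, dtype=np.float64)
    if len(dataset) and isinstance(dataset[0], VolumeSample):
        _, X, y = stack_volumes(dataset)
        return X, y
    raise TypeError("dataset must be (volumes, ages) or a list of VolumeSample")


def train(model: AgeModel, train_set, val_set=None, cfg: ModelConfig | None = None):
    """Train by MSE/Adam; retain the parameters with the best validation MAE.

    Returns ``(model, history)`` where history maps ``"train_loss"`` and
    ``"val_mae"`` to per-epoch lists.  With ``n_epochs == 0`` the model is
    returned untouched.  Raises ``RuntimeError`` if the loss goes non-finite.
    """
    cfg = cfg or model.cfg
    history: dict[str, list[float]] = {"train_loss": [], "val_mae": []}
    if cfg.n_epochs == 0:
        return model, history

    Xtr, ytr = _as_arrays(train_set)
    if len(Xtr) == 0:
        raise ValueError("training set is empty")
    Xval, yval = (None, None)
    if val_set is not None:
        Xval, yval = _as_arrays(val_set)

    if cfg.center_target:
        model.output_offset = float(ytr.mean())
    y_fit = ytr - model.output_offset

    xtr = model._prepare(Xtr)
    optimizer = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    n = len(xtr)
    best_state, best_mae = None, np.inf

    for epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = xtr[idx], y_fit[idx]
            optimizer.zero_grad()
            pred = model.forward_batch(xb, train=True)
            resid = pred - yb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"starting {start}: loss={loss}")
            grad = (2.0 * resid / len(idx)).astype(pred.dtype)[:, None]
            model.net.backward(grad)
            optimizer.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))

        if Xval is not None and len(Xval):
            val_mae = float(np.mean(np.abs(model.predict(Xval) - yval)))
        else:
            val_mae = history["train_loss"][-1] ** 0.5
        history["val_mae"].append(val_mae)
        if val_mae < best_mae:
            best_mae = val_mae
            best_state = model.get_state()

    if best_state is not None:
        model.set_state(best_state)
    return model, history


def predict(model: AgeModel, volumes) -> np.ndarray:
    """Raw (uncorrected) age predictions, one per volume, order preserved."""
    if not isinstance(volumes, np.ndarray):
        if len(volumes) and isinstance(volumes[0], VolumeSample):
            volumes = np.stack([v.voxels for v in volumes])
        else:
            volumes = np.asarray(volumes)
    preds = model.predict(volumes)
    if not np.all(np.isfinite(preds)):
        raise RuntimeError("model produced non-finite predictions")
    return preds


def fit_bias_correction(raw_preds_train: np.ndarray, ages_train: np.ndarray,
                        mode: str = "invert") -> BiasCorrection:
    """OLS of raw prediction on chronological age: ``raw ~ alpha + beta*age``.

    Must be fitted on the training split only; applying the result to other
    splits is how leakage is avoided.
    """
    raw = np.asarray(raw_preds_train, dtype=float)
    ages = np.asarray(ages_train, dtype=float)
    if len(raw) != len(ages):
        raise ValueError("raw predictions and ages must align")
    if len(ages) < 3:
        raise ValueError("need at least 3 training subjects")
    if np.ptp(ages) == 0:
        raise ValueError("constant training ages: slope undefined")
    beta, alpha = np.polyfit(ages, raw, 1)
    return BiasCorrection(alpha=float(alpha), beta=float(beta), mode=mode)


def apply_bias_correction(
    bc: BiasCorrection,
    raw_preds: np.ndarray,
    ages: np.ndarray,
    subject_ids: Sequence[str] | None = None,
) -> list[PredictionRecord]:
    """Correct raw predictions and compute per-subject brain-age differences."""
    raw = np.asarray(raw_preds, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(raw) != len(ages):
        raise ValueError("raw predictions and ages must align")
    if subject_ids is None:
        subject_ids = [f"sub-{i:05d}" for i in range(len(raw))]
    if bc.mode == "invert":
        corrected = (raw - bc.alpha) / bc.beta
    else:
        corrected = raw - (bc.alpha + bc.beta * ages) + ages
    return [
        PredictionRecord(subject_id=str(sid), age=float(a), raw_pred=float(r),
                         corrected_pred=float(c), delta=float(c - a))
        for sid, a, r, c in zip(subject_ids, ages, raw, corrected)
    ]


def evaluate(records: Sequence[PredictionRecord]) -> tuple[float, float]:
    """Mean absolute error (years) and Pearson r of corrected prediction vs age.

    With constant predictions the correlation is undefined and reported as
    NaN (never coerced to 0).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ages = np.array([r.age for r in records])
    preds = np.array([r.corrected_pred for r in records])
    if np.ptp(ages) == 0:
        raise ValueError("constant ages: correlation undefined")
    mae = float(np.mean(np.abs(preds - ages)))
    if np.ptp(preds) == 0:
        return mae, float("nan")
    r = float(np.corrcoef(preds, ages)[0, 1])
    return mae, r


def records_to_frame(records: Sequence[PredictionRecord]):
    """Prediction records as a DataFrame (subject_id, age, raw_pred, corrected_pred, delta)."""
    import pandas as pd

    return pd.DataFrame([{
        "subject_id": r.subject_id, "age": r.age, "raw_pred": r.raw_pred,
        "corrected_pred": r.corrected_pred, "delta": r.delta,
    } for r in records])
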