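"""Training loop, optimiser and cross-validation for the gravity models.

Training processes one sample (source port) per gradient step: sample
lengths vary with the number of candidate regions, so no batching is
attempted. The objective is the cross-entropy between observed flows and the
log-softmax of the model scores. Adam with an L2 weight penalty drives the
updates; the learning rate is cut by a factor of 0.1 after 10 epochs without
validation-CPC improvement, training stops after 20 stagnant epochs, and the
parameters of the best validation-CPC epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, log_softmax
from .evaluate import allocate_flows, corr, mean_cpc, nrmse
from .features import ODSample
from .models import build_model, _ModelBase

MAX_EPOCHS_DEFAULT = 200


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-5
    lr_reduce_factor: float = 0.1
    lr_patience: int = 10
    early_stop_patience: int = 20
    max_epochs: int = MAX_EPOCHS_DEFAULT
    seed: int = 0
    cv_folds: int = 5
    val_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.lr_patience <= 0 or self.early_stop_patience <= 0:
            raise ValueError("patience values must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


class Adam:
    """Adam with a classic L2 penalty added to the gradients."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sample_loss(model: _ModelBase, sample: ODSample, mode: str = "train",
                rng: np.random.Generator | None = None) -> Tensor:
    """Cross-entropy loss tensor of one sample: -sum_j y_j log softmax(f)_j."""
    scores = model.forward(sample.X, mode=mode, rng=rng)
    return -(Tensor(sample.y) * log_softmax(scores)).sum()


def predict_sample(model: _ModelBase, sample: ODSample) -> np.ndarray:
    """Deterministic flow prediction for one sample (eval mode)."""
    scores = model.forward(sample.X, mode="eval").data
    return allocate_flows(scores, sample.O_i)


def prediction_pairs(model: _ModelBase, samples: Sequence[ODSample]):
    return [(predict_sample(model, s), s.y) for s in samples]


@dataclass
class TrainReport:
    """Per-epoch history and the best validation CPC reached."""

    history: list[dict] = field(default_factory=list)
    best_val_cpc: float = float("-inf")
    best_epoch: int = -1
    stopped_epoch: int = -1


@dataclass
class EvaluationReport:
    """Cross-validation summary mirroring the flow-model comparison layout."""

    model: str
    fold_cpc: list[float]
    cpc_mean: float
    cpc_max: float
    cpc_min: float
    nrmse: float
    corr: float
    n_params: int
    train_reports: list[TrainReport] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "cpc_mean": self.cpc_mean,
            "cpc_max": self.cpc_max,
            "cpc_min": self.cpc_min,
            "nrmse": self.nrmse,
            "corr": self.corr,
            "parameters": self.n_params,
            "fold_cpc": self.fold_cpc,
        }


def _split(samples: Sequence[ODSample], val_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(len(samples))
    n_val = max(1, int(round(val_fraction * len(samples))))
    val = [samples[i] for i in idx[:n_val]]
    train = [samples[i] for i in idx[n_val:]]
    return train, val


def train(
    model: _ModelBase,
    samples: Sequence[ODSample],
    cfg: TrainConfig = TrainConfig(),
    val_samples: Sequence[ODSample] | None = None,
) -> tuple[_ModelBase, TrainReport]:
    """Fit a model with per-sample gradient steps and CPC-based model selection.

    When ``val_samples`` is None, a seeded ``val_fraction`` split of
    ``samples`` provides the validation set. The returned model carries the
    parameters of the epoch with the best validation mean CPC.
    """
    if len(samples) < 2 and val_samples is None:
        raise ValueError("need at least 2 samples to split train/validation")
    rng = np.random.default_rng(cfg.seed)
    if val_samples is None:
        train_set, val_set = _split(samples, cfg.val_fraction, rng)
    else:
        train_set, val_set = list(samples), list(val_samples)

    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    report = TrainReport()
    best_state = model.state_dict()
    stagnant = 0
    since_lr_cut = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        total_loss = 0.0
        for i in order:
            s = train_set[i]
            model.zero_grad()
            loss = sample_loss(model, s, mode="train", rng=rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, sample {s.source!r}"
                )
            loss.backward()
            opt.step()
            total_loss += float(loss.data)
        val_cpc = mean_cpc(prediction_pairs(model, val_set))
        report.history.append({"epoch": epoch, "loss": total_loss, "val_cpc": val_cpc,
                               "lr": opt.lr})
        if val_cpc > report.best_val_cpc:
            report.best_val_cpc = val_cpc
            report.best_epoch = epoch
            best_state = model.state_dict()
            stagnant = 0
            since_lr_cut = 0
        else:
            stagnant += 1
            since_lr_cut += 1
        if since_lr_cut >= cfg.lr_patience:
            opt.lr *= cfg.lr_reduce_factor
            since_lr_cut = 0
        if stagnant >= cfg.early_stop_patience:
            break
    report.stopped_epoch = epoch
    model.load_state_dict(best_state)
    return model, report


def fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    """Seeded fold label per sample index; folds are near-equal-size."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % folds
    rng.shuffle(labels)
    return labels


def cross_validate(
    spec,
    samples: Sequence[ODSample],
    cfg: TrainConfig = TrainConfig(),
    aggregate: str = "pooled",
) -> EvaluationReport:
    """K-fold cross-validation of a model spec over the source-port samples.

    Each fold trains a freshly initialised model on the other folds and
    evaluates CPC/NRMSE/correlation on the held-out fold; NRMSE and
    correlation are averaged over folds.
    """
    if len(samples) < cfg.cv_folds:
        raise ValueError("fewer samples than folds")
    labels = fold_assignment(len(samples), cfg.cv_folds, cfg.seed)
    fold_cpc, fold_nrmse, fold_corr, reports = [], [], [], []
    for fold in range(cfg.cv_folds):
        train_set = [s for s, l in zip(samples, labels) if l != fold]
        val_set = [s for s, l in zip(samples, labels) if l == fold]
        # same init seed per fold: fold scores then differ only through the data
        model = build_model(spec, seed=cfg.seed)
        model, rep = train(model, train_set, cfg, val_samples=val_set)
        pairs = prediction_pairs(model, val_set)
        fold_cpc.append(mean_cpc(pairs))
        fold_nrmse.append(nrmse(pairs, aggregate))
        fold_corr.append(corr(pairs, aggregate))
        reports.append(rep)
    return EvaluationReport(
        model=type(spec).__name__,
        fold_cpc=fold_cpc,
        cpc_mean=float(np.mean(fold_cpc)),
        cpc_max=float(np.max(fold_cpc)),
        cpc_min=float(np.min(fold_cpc)),
        nrmse=float(np.nanmean(fold_nrmse)),
        corr=float(np.nanmean(fold_corr)),
        n_params=build_model(spec, 0).n_params(),
        train_reports=reports,
    )
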