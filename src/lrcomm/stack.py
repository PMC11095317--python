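"""Stacking ensemble for ligand-receptor pair classification.

Three base learners — a polynomial-kernel soft-margin SVM, a 1-D CNN and a
multi-head-attention classifier — are trained on a 70% "basic" split of the
training pairs.  Their class-probability outputs on the remaining 30%
"meta" split form six meta-features per sample, ordered
[SVM(y=0), SVM(y=1), CNN(y=0), CNN(y=1), MHA(y=0), MHA(y=1)], on which a
three-layer softmax perceptron (the meta-classifier) is trained with Adam
under a cosine-annealing learning-rate schedule and cross-entropy loss.

A pair is called interacting when P(y=1) is strictly larger than P(y=0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.svm import SVC
from sklearn.model_selection import train_test_split

from . import _nn
from ._nn import cosine_lr, cross_entropy, scaled_dot_attention  # noqa: F401

__all__ = [
    "SvmConfig",
    "CnnConfig",
    "MhaConfig",
    "MetaConfig",
    "LearnerConfig",
    "TrainedLearner",
    "StackedModel",
    "train_svm",
    "train_cnn",
    "train_mha",
    "make_meta_features",
    "fit_stacking",
    "predict_proba",
    "classify",
    "cosine_lr",
    "cross_entropy",
    "scaled_dot_attention",
]


@dataclass
class SvmConfig:
    C: float = 2.5
    gamma: float = 0.1
    kernel: str = "poly"
    tol: float = 1e-3
    cache_size: float = 100.0


@dataclass
class CnnConfig:
    epochs: int = 30
    lr: float = 1e-3
    weight_decay: float = 1e-5
    batch: int = 64
    filters: tuple[int, int, int] = (32, 64, 128)
    kernel: int = 3
    fc_hidden: int = 128


@dataclass
class MhaConfig:
    input_dim: int = 400
    heads: int = 8
    hidden: int = 256
    dropout: float = 0.2
    epochs: int = 30
    lr: float = 1e-3
    weight_decay: float = 1e-5
    batch: int = 64


@dataclass
class MetaConfig:
    hidden: tuple[int, int] = (12, 8)
    lr: float = 0.01
    eta_min: float = 1e-6
    epochs: int = 100


@dataclass
class LearnerConfig:
    svm: SvmConfig = field(default_factory=SvmConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    mha: MhaConfig = field(default_factory=MhaConfig)
    meta: MetaConfig = field(default_factory=MetaConfig)

    def to_dict(self) -> dict:
        return asdict(self)


class TrainedLearner:
    """A trained base learner exposing two-class probability scores."""

    def __init__(self, kind: str, scorer, n_features: int) -> None:
        self.kind = kind
        self._scorer = scorer
        self.n_features = n_features

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"{self.kind}: feature width {X.shape[1]} != trained width "
                f"{self.n_features}"
            )
        out = self._scorer(X)
        assert out.shape == (X.shape[0], 2)
        return out


def _check_two_classes(y: np.ndarray, where: str) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError(f"{where}: need both classes 0 and 1 present")
    return y


def train_svm(
    X: np.ndarray, y: np.ndarray, cfg: SvmConfig | None = None, seed: int = 0
) -> TrainedLearner:
    """Polynomial-kernel soft-margin SVM with Platt-calibrated probabilities."""
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y, "train_svm")
    clf = SVC(
        C=cfg.C,
        gamma=cfg.gamma,
        kernel=cfg.kernel,
        tol=cfg.tol,
        cache_size=cfg.cache_size,
        probability=True,
        random_state=seed,
    )
    clf.fit(X, y)
    # predict_proba column order follows clf.classes_, here [0, 1]
    return TrainedLearner("svm", clf.predict_proba, X.shape[1])


def cnn_min_length(n_pools: int = 3) -> int:
    """Smallest feature length that survives all 2x poolings (8 for 3 pools)."""
    return 2**n_pools


def train_cnn(
    X: np.ndarray, y: np.ndarray, cfg: CnnConfig | None = None, seed: int = 0
) -> TrainedLearner:
    """Three conv/batch-norm/ReLU/max-pool stages then two dense layers.

    Convolutions are length-preserving (kernel 3, stride 1, padding 1); each
    2x max-pool halves the length, so inputs must be at least 8 long.
    """
    cfg = cfg or CnnConfig()
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y, "train_cnn")
    L = X.shape[1]
    if L < cnn_min_length():
        raise ValueError(
            f"train_cnn: feature length {L} below minimum {cnn_min_length()}"
        )
    rng = np.random.default_rng(seed)
    f1, f2, f3 = cfg.filters
    flat = f3 * (L // 2 // 2 // 2)
    net = _nn.Network(
        [
            _Reshape3d(),
            _nn.Conv1dSame(1, f1, rng, kernel=cfg.kernel),
            _nn.BatchNorm(f1),
            _nn.ReLU(),
            _nn.MaxPool1d(),
            _nn.Conv1dSame(f1, f2, rng, kernel=cfg.kernel),
            _nn.BatchNorm(f2),
            _nn.ReLU(),
            _nn.MaxPool1d(),
            _nn.Conv1dSame(f2, f3, rng, kernel=cfg.kernel),
            _nn.BatchNorm(f3),
            _nn.ReLU(),
            _nn.MaxPool1d(),
            _nn.Flatten(),
            _nn.Dense(flat, cfg.fc_hidden, rng),
            _nn.ReLU(),
            _nn.Dense(cfg.fc_hidden, 2, rng),
        ]
    )
    net.fit(
        X,
        y,
        rng=rng,
        epochs=cfg.epochs,
        batch=cfg.batch,
        lr=cfg.lr,
        weight_decay=cfg.weight_decay,
    )
    return TrainedLearner("cnn", net.predict_proba, L)


def train_mha(
    X: np.ndarray, y: np.ndarray, cfg: MhaConfig | None = None, seed: int = 0
) -> TrainedLearner:
    """Batch-norm, 8-head attention over the sample vector, then an MLP head.

    Each sample acts as a single token of width input_dim; per-head width is
    input_dim / heads (50 at the 400-dim default).
    """
    cfg = cfg or MhaConfig()
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y, "train_mha")
    d = X.shape[1]
    if d % cfg.heads:
        raise ValueError(
            f"train_mha: input_dim {d} not divisible by heads {cfg.heads}"
        )
    rng = np.random.default_rng(seed)
    net = _nn.Network(
        [
            _nn.BatchNorm(d),
            _nn.SingleTokenMHA(d, cfg.heads, rng),
            _nn.Dense(d, cfg.hidden, rng),
            _nn.ReLU(),
            _nn.Dropout(cfg.dropout, rng),
            _nn.Dense(cfg.hidden, 2, rng),
        ]
    )
    net.fit(
        X,
        y,
        rng=rng,
        epochs=cfg.epochs,
        batch=cfg.batch,
        lr=cfg.lr,
        weight_decay=cfg.weight_decay,
    )
    return TrainedLearner("mha", net.predict_proba, d)


class _Reshape3d(_nn.Layer):
    """(N, L) -> (N, 1, L) single-channel view for the conv stack."""

    def forward(self, x, train):
        return x[:, None, :]

    def backward(self, dout):
        return dout[:, 0, :]


def make_meta_features(
    base: tuple[TrainedLearner, TrainedLearner, TrainedLearner], X: np.ndarray
) -> np.ndarray:
    """Six meta-features per sample, column order SVM | CNN | MHA, (y=0, y=1)."""
    if len(base) != 3:
        raise ValueError("exactly three base learners required")
    return np.hstack([learner.score(X) for learner in base])


@dataclass
class StackedModel:
    base: tuple[TrainedLearner, TrainedLearner, TrainedLearner]
    meta: _nn.Network
    split_seed: int
    config: LearnerConfig
    basic_index: np.ndarray
    meta_index: np.ndarray


def _build_meta_net(cfg: MetaConfig, rng: np.random.Generator) -> _nn.Network:
    h1, h2 = cfg.hidden
    return _nn.Network(
        [
            _nn.Dense(6, h1, rng),
            _nn.ReLU(),
            _nn.Dense(h1, h2, rng),
            _nn.ReLU(),
            _nn.Dense(h2, 2, rng),
        ]
    )


def fit_stacking(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LearnerConfig | None = None,
    seed: int = 0,
) -> StackedModel:
    """Train the full ensemble with a seeded stratified 70/30 split.

    Base learners see the 70% basic split; the meta perceptron is fit on the
    base learners' probability outputs over the 30% meta split, with Adam
    (lr 0.01) annealed cosine-wise to eta_min and cross-entropy loss.
    """
    cfg = cfg or LearnerConfig()
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y, "fit_stacking")
    idx = np.arange(X.shape[0])
    basic_idx, meta_idx = train_test_split(
        idx, test_size=0.3, stratify=y, random_state=seed
    )
    for part, name in ((basic_idx, "basic"), (meta_idx, "meta")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(
                f"{name} split lost a class; re-seed or enlarge the data"
            )
    Xb, yb = X[basic_idx], y[basic_idx]
    base = (
        train_svm(Xb, yb, cfg.svm, seed=seed),
        train_cnn(Xb, yb, cfg.cnn, seed=seed + 1),
        train_mha(Xb, yb, cfg.mha, seed=seed + 2),
    )
    E = make_meta_features(base, X[meta_idx])
    rng = np.random.default_rng(seed + 3)
    meta_net = _build_meta_net(cfg.meta, rng)
    meta_net.fit(
        E,
        y[meta_idx],
        rng=rng,
        epochs=cfg.meta.epochs,
        batch=max(32, E.shape[0]),
        lr=cfg.meta.lr,
        cosine_eta_min=cfg.meta.eta_min,
    )
    return StackedModel(
        base=base,
        meta=meta_net,
        split_seed=seed,
        config=cfg,
        basic_index=basic_idx,
        meta_index=meta_idx,
    )


def predict_proba(model: StackedModel, X: np.ndarray) -> np.ndarray:
    """Meta-classifier P(y=1) per pair."""
    E = make_meta_features(model.base, X)
    return model.meta.predict_proba(E)[:, 1]


def classify(model: StackedModel, X: np.ndarray) -> np.ndarray:
    """Interacting iff P(y=1) strictly exceeds P(y=0); ties are class 0."""
    return (predict_proba(model, X) > 0.5).astype(int)


def save_manifest(path: Path, cfg: LearnerConfig, seed: int, extra: dict | None = None) -> None:
    payload = {"config": cfg.to_dict(), "seed": seed}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
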