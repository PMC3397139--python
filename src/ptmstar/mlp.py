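"""Single-hidden-layer perceptrons trained by online back-propagation.

The classifier family is deliberately classical: sigmoid units throughout,
squared-error loss, per-sample (online) gradient descent with momentum, and
a fixed number of epochs.  Over-fitting is handled not by early stopping but
by checkpointing: a deep copy of the network is saved every few epochs, and
after training the checkpoint that maximises a chosen objective — AUC (A),
recall (R) or precision (P) at threshold 0.5 — on an evaluation split is
selected.  A checkpoint from an early epoch can legitimately win.

``train_family`` repeats this for hidden-layer sizes 2, 4, ..., 20 and all
three objectives, yielding the 30 networks (10 per objective) that the
consensus layer combines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import metrics

HIDDEN_SIZES = tuple(range(2, 21, 2))  # 2..20 step 2 -> 10 networks/objective
OBJECTIVES = ("A", "R", "P")  # AUC, recall, precision


@dataclass
class MLPModel:
    """One feed-forward network: input -> hidden (sigmoid) -> 1 (sigmoid)."""

    w1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    threshold: float = 0.5
    objective_tag: str | None = None  # "A" | "R" | "P" once selected
    feature_set_id: str | None = None
    epoch: int = 0  # training epoch this checkpoint was taken at

    @property
    def input_dim(self) -> int:
        return self.w1.shape[1]

    @property
    def hidden_k(self) -> int:
        return self.w1.shape[0]

    def copy(self) -> "MLPModel":
        return MLPModel(
            w1=self.w1.copy(), b1=self.b1.copy(), w2=self.w2.copy(),
            b2=self.b2, threshold=self.threshold,
            objective_tag=self.objective_tag,
            feature_set_id=self.feature_set_id, epoch=self.epoch,
        )

    def to_json(self) -> str:
        return json.dumps({
            "format": "ptmstar-mlp/1",
            "input_dim": self.input_dim,
            "hidden_k": self.hidden_k,
            "w1": self.w1.ravel().tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "threshold": self.threshold,
            "objective_tag": self.objective_tag,
            "feature_set_id": self.feature_set_id,
            "epoch": self.epoch,
        })

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        obj = json.loads(text)
        if obj.get("format") != "ptmstar-mlp/1":
            raise ValueError(f"unknown model format {obj.get('format')!r}")
        k, d = obj["hidden_k"], obj["input_dim"]
        return cls(
            w1=np.array(obj["w1"], dtype=float).reshape(k, d),
            b1=np.array(obj["b1"], dtype=float),
            w2=np.array(obj["w2"], dtype=float),
            b2=float(obj["b2"]),
            threshold=float(obj["threshold"]),
            objective_tag=obj.get("objective_tag"),
            feature_set_id=obj.get("feature_set_id"),
            epoch=int(obj.get("epoch", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class TrainConfig:
    """Back-propagation hyperparameters.

    The number of iterations is a free choice; the defaults are classical
    online-BP settings and every field is configurable.
    """

    epochs: int = 1000
    learning_rate: float = 0.1
    momentum: float = 0.9
    checkpoint_every: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.epochs >= self.checkpoint_every >= 1):
            raise ValueError(
                f"need epochs >= checkpoint_every >= 1, got "
                f"{self.epochs} / {self.checkpoint_every}"
            )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def init_mlp(
    input_dim: int, hidden_k: int, seed: int = 0,
    feature_set_id: str | None = None,
) -> MLPModel:
    """Fresh network with weights drawn uniformly from [-0.5, 0.5]."""
    if input_dim < 1 or hidden_k < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    return MLPModel(
        w1=rng.uniform(-0.5, 0.5, size=(hidden_k, input_dim)),
        b1=rng.uniform(-0.5, 0.5, size=hidden_k),
        w2=rng.uniform(-0.5, 0.5, size=hidden_k),
        b2=float(rng.uniform(-0.5, 0.5)),
        feature_set_id=feature_set_id,
    )


def forward(model: MLPModel, x: np.ndarray) -> float | np.ndarray:
    """Network output(s) in (0,1): sigmoid(w2 . sigmoid(w1 x + b1) + b2).

    Accepts a single feature vector or an (n, input_dim) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if (x.shape[-1] if x.size else model.input_dim) != model.input_dim:
        raise ValueError(
            f"input dim {x.shape[-1]} != model input dim {model.input_dim}"
        )
    h = _sigmoid(x @ model.w1.T + model.b1)
    out = _sigmoid(h @ model.w2 + model.b2)
    return float(out) if single else out


def train_bp(
    model: MLPModel, x: np.ndarray, y: np.ndarray, config: TrainConfig
) -> list[MLPModel]:
    """Online back-propagation; returns deep-copied checkpoints.

    Per-sample squared-error gradient descent with momentum; sample order is
    reshuffled every epoch from ``config.seed``.  A checkpoint is appended
    every ``checkpoint_every`` epochs and at the final epoch.  Training data
    must contain both classes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("empty training data")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    w1, b1 = model.w1.copy(), model.b1.copy()
    w2, b2 = model.w2.copy(), model.b2
    v_w1 = np.zeros_like(w1)
    v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2)
    v_b2 = 0.0
    lr, mom = config.learning_rate, config.momentum

    rng = np.random.default_rng(config.seed)
    checkpoints: list[MLPModel] = []
    n = x.shape[0]
    for epoch in range(1, config.epochs + 1):
        for i in rng.permutation(n):
            xi = x[i]
            h = _sigmoid(w1 @ xi + b1)
            o = _sigmoid(w2 @ h + b2)
            delta_o = (y[i] - o) * o * (1.0 - o)
            delta_h = w2 * delta_o * h * (1.0 - h)
            v_w2 = mom * v_w2 + lr * delta_o * h
            v_b2 = mom * v_b2 + lr * delta_o
            v_w1 = mom * v_w1 + lr * np.outer(delta_h, xi)
            v_b1 = mom * v_b1 + lr * delta_h
            w2 = w2 + v_w2
            b2 = b2 + v_b2
            w1 = w1 + v_w1
            b1 = b1 + v_b1
        if epoch % config.checkpoint_every == 0 or epoch == config.epochs:
            checkpoints.append(MLPModel(
                w1=w1.copy(), b1=b1.copy(), w2=w2.copy(), b2=float(b2),
                threshold=model.threshold, feature_set_id=model.feature_set_id,
                epoch=epoch,
            ))
    return checkpoints


def select_checkpoint(
    checkpoints: list[MLPModel],
    eval_x: np.ndarray,
    eval_y: np.ndarray,
    objective: str,
) -> MLPModel:
    """The checkpoint maximising the objective on the evaluation split.

    Objectives: "A" = AUC, "R" = recall at the model threshold, "P" =
    precision at the model threshold.  Ties are broken by higher AUC, then
    by the later checkpoint.  The returned model carries the objective tag.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}")
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    best: tuple[float, float, int] | None = None
    best_model: MLPModel | None = None
    for i, ckpt in enumerate(checkpoints):
        scores = forward(ckpt, eval_x)
        a = metrics.auc(scores, eval_y)
        if objective == "A":
            m = a
        else:
            pred = (np.asarray(scores) >= ckpt.threshold).astype(int)
            m = (metrics.recall(pred, eval_y) if objective == "R"
                 else metrics.precision(pred, eval_y))
        key = (m, a, i)
        if best is None or key >= best:
            best, best_model = key, ckpt
    assert best_model is not None
    selected = best_model.copy()
    selected.objective_tag = objective
    return selected


def train_family(
    train_x: np.ndarray,
    train_y: np.ndarray,
    eval_x: np.ndarray,
    eval_y: np.ndarray,
    config: TrainConfig,
    feature_set_id: str | None = None,
) -> dict[tuple[str, int], MLPModel]:
    """Train one network per hidden size (2..20 step 2) and select the A, R
    and P checkpoints from each run: 30 models, keyed by (objective, k).

    Each hidden size gets its own seed (config.seed offset by k) so the ten
    runs are independent but jointly deterministic.
    """
    family: dict[tuple[str, int], MLPModel] = {}
    for k in HIDDEN_SIZES:
        run_cfg = replace(config, seed=config.seed + k)
        model = init_mlp(
            train_x.shape[1], k, seed=run_cfg.seed,
            feature_set_id=feature_set_id,
        )
        checkpoints = train_bp(model, train_x, train_y, run_cfg)
        for objective in OBJECTIVES:
            family[(objective, k)] = select_checkpoint(
                checkpoints, eval_x, eval_y, objective
            )
    return family
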