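"""The per-window deep classifier and its training loop.

Architecture (per window of shape E x W): a 1x1 convolution lifts the E
embedding channels to F filters; a residual branch conv1D(F -> Fb, kernel 3)
-> ReLU -> conv1D(Fb -> F, kernel 3) is added back onto the skip path and
passed through ReLU; a masked max-pool over the window yields an F-vector;
a final dense layer produces K class logits, softmaxed into probabilities.
Padded window columns are excluded from the pool by masking, so zero-padding
never influences the score.

Training minimises softmax cross-entropy with Adam on randomly sampled
labelled windows, with dev-loss early stopping (the checkpoint from the best
dev epoch is restored).  Given (seed, config, data) the whole run is
deterministic in single-threaded mode.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import nn
from .embedder import EmbeddedSequence
from .windowing import Window, WindowSpec, sample_training_windows, slide_windows
from .window_scoring import PositionScoreTrack


@dataclass
class BaseModelConfig:
    """Hyperparameters of one ensemble member.

    Defaults F=1100 / Fb=550 and the lr grid follow the full-scale protocol;
    scaled-down runs override them (see docs/methods.md).
    """

    W: int = 32
    lr: float = 1e-4
    F: int = 1100
    Fb: int = 550
    E: int = 1280
    K: int = 2
    seed: int = 0
    patience: int = 5
    max_epochs: int = 50
    batch_size: int = 256
    kernel: int = 3
    step: int = 4  # inference stride
    windows_per_seq: int = 1  # N: training windows per sequence per epoch

    def __post_init__(self) -> None:
        if not (self.F >= self.Fb >= 1):
            raise ValueError("require F >= Fb >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.W, self.step, self.windows_per_seq)


class WindowClassifier:
    """ResNet-block window classifier with explicit NumPy forward/backward."""

    def __init__(self, config: BaseModelConfig) -> None:
        self.config = config
        c = config
        rng = np.random.default_rng(c.seed)
        k = c.kernel
        self.params: dict[str, np.ndarray] = {
            "w_in": nn.he_init(rng, (c.F, c.E, 1), c.E),
            "b_in": np.zeros(c.F),
            "w_r1": nn.he_init(rng, (c.Fb, c.F, k), c.F * k),
            "b_r1": np.zeros(c.Fb),
            "w_r2": nn.he_init(rng, (c.F, c.Fb, k), c.Fb * k),
            "b_r2": np.zeros(c.F),
            "w_fc": nn.he_init(rng, (c.F, c.K), c.F),
            "b_fc": np.zeros(c.K),
        }

    def forward(
        self, x: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, dict]:
        """x: (B, E, W), mask: (B, W) -> logits (B, K) plus backward cache."""
        p = self.params
        x = x * mask[:, None, :]  # padded columns contribute nothing anywhere
        h0, cols0 = nn.conv1d_forward(x, p["w_in"], p["b_in"])
        r1, cols1 = nn.conv1d_forward(h0, p["w_r1"], p["b_r1"])
        a1 = nn.relu(r1)
        r2, cols2 = nn.conv1d_forward(a1, p["w_r2"], p["b_r2"])
        pre = h0 + r2  # residual addition
        h1 = nn.relu(pre)
        pooled, idx = nn.masked_max_pool(h1, mask)
        logits = pooled @ p["w_fc"] + p["b_fc"]
        cache = dict(
            x=x, cols0=cols0, cols1=cols1, cols2=cols2,
            h0=h0, r1=r1, a1=a1, pre=pre, h1=h1, pooled=pooled, idx=idx,
        )
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        g: dict[str, np.ndarray] = {}
        g["w_fc"] = cache["pooled"].T @ dlogits
        g["b_fc"] = dlogits.sum(axis=0)
        dpooled = dlogits @ p["w_fc"].T
        dh1 = nn.masked_max_pool_backward(dpooled, cache["idx"], cache["h1"].shape)
        dpre = nn.relu_backward(dh1, cache["pre"])
        W = cache["x"].shape[2]
        da1, g["w_r2"], g["b_r2"] = nn.conv1d_backward(
            dpre, cache["cols2"], p["w_r2"], W
        )
        dr1 = nn.relu_backward(da1, cache["r1"])
        dh0_branch, g["w_r1"], g["b_r1"] = nn.conv1d_backward(
            dr1, cache["cols1"], p["w_r1"], W
        )
        dh0 = dpre + dh0_branch  # skip path + branch
        _, g["w_in"], g["b_in"] = nn.conv1d_backward(
            dh0, cache["cols0"], p["w_in"], W
        )
        return g

    def predict_proba(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x, mask)
        return nn.softmax(logits)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def build_model(config: BaseModelConfig) -> WindowClassifier:
    return WindowClassifier(config)


def score_window(model: WindowClassifier, window: Window) -> np.ndarray:
    """Probability vector over the K classes for a single window."""
    E, W = window.slice.shape
    if (E, W) != (model.config.E, model.config.W):
        raise ValueError(
            f"window shape {(E, W)} does not match model "
            f"{(model.config.E, model.config.W)}"
        )
    return model.predict_proba(window.slice[None], window.mask[None])[0]


def _batched(windows: Sequence[Window]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([w.slice for w in windows])
    m = np.stack([w.mask for w in windows])
    return x, m


def score_windows(
    model: WindowClassifier, windows: Sequence[Window], batch_size: int = 512
) -> np.ndarray:
    out = []
    for i in range(0, len(windows), batch_size):
        x, m = _batched(windows[i : i + batch_size])
        out.append(model.predict_proba(x, m))
    return np.concatenate(out) if out else np.zeros((0, model.config.K))


def score_sequence(
    model: WindowClassifier, emb: EmbeddedSequence, spec: WindowSpec | None = None
) -> PositionScoreTrack:
    """Slide over the sequence and score every window position."""
    spec = spec or WindowSpec(model.config.W, model.config.step, 1)
    windows = slide_windows(emb, spec)
    scores = score_windows(model, windows)
    positions = [w.nc for w in windows]
    return PositionScoreTrack(
        sequence_id=emb.id,
        model_id=f"seed{model.config.seed}_W{model.config.W}",
        positions=np.asarray(positions),
        scores=scores,
        seq_length=emb.length,
    )


@dataclass
class TrainedBaseModel:
    """A trained member: parameters restored to the best dev epoch."""

    config: BaseModelConfig
    model: WindowClassifier
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0

    def save(self, path: str | Path) -> None:
        meta = json.dumps(
            {"config": asdict(self.config), "history": self.history,
             "best_epoch": self.best_epoch}
        )
        np.savez(
            path,
            __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
            **self.model.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedBaseModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = BaseModelConfig(**meta["config"])
            model = WindowClassifier(config)
            for k in model.params:
                model.params[k] = data[k]
        return cls(config, model, meta["history"], meta["best_epoch"])


DevEvaluator = Callable[[WindowClassifier], tuple[float, float]]


def make_window_dev_evaluator(
    dev: Sequence[EmbeddedSequence],
    config: BaseModelConfig,
    family_index: dict[str, int],
) -> DevEvaluator:
    """Dev metric on a fixed, reproducible set of labelled dev windows.

    Windows are drawn once with a seed derived from the model seed, so every
    epoch is scored on the same set; returns (cross-entropy, error rate).
    """
    rng = np.random.default_rng([config.seed, 0xDE])
    spec = WindowSpec(config.W, config.step, config.windows_per_seq)
    windows: list[Window] = []
    for emb in dev:
        windows.extend(sample_training_windows(emb, spec, rng, family_index))
    y = np.array([w.label for w in windows])

    def evaluate(model: WindowClassifier) -> tuple[float, float]:
        probs = score_windows(model, windows)
        loss = float(-np.log(probs[np.arange(len(y)), y] + 1e-300).mean())
        err = float((probs.argmax(axis=1) != y).mean())
        return loss, err

    return evaluate


def train(
    model: WindowClassifier,
    train_seqs: Sequence[EmbeddedSequence],
    dev_seqs: Sequence[EmbeddedSequence],
    family_index: dict[str, int],
    dev_evaluator: DevEvaluator | None = None,
) -> TrainedBaseModel:
    """Adam / cross-entropy training with patience-based early stopping.

    Each epoch draws ``windows_per_seq`` fresh windows per training sequence
    (epoch-seeded, hence reproducible), then evaluates the dev metric; training
    stops after ``patience`` epochs without dev improvement or at
    ``max_epochs``, and the best epoch's parameters are restored.
    """
    if not train_seqs:
        raise ValueError("empty training stream")
    c = model.config
    if dev_evaluator is None:
        if not dev_seqs:
            raise ValueError("dev set required for early stopping")
        dev_evaluator = make_window_dev_evaluator(dev_seqs, c, family_index)

    spec = WindowSpec(c.W, c.step, c.windows_per_seq)
    opt = nn.Adam(model.params, lr=c.lr)
    stopper = nn.EarlyStopping(c.patience)
    history: list[dict] = []

    for epoch in range(1, c.max_epochs + 1):
        rng = np.random.default_rng([c.seed, epoch])
        windows: list[Window] = []
        for emb in train_seqs:
            windows.extend(sample_training_windows(emb, spec, rng, family_index))
        order = rng.permutation(len(windows))
        losses = []
        for i in range(0, len(order), c.batch_size):
            batch = [windows[j] for j in order[i : i + c.batch_size]]
            x, m = _batched(batch)
            y = np.array([w.label for w in batch])
            logits, cache = model.forward(x, m)
            loss, dlogits = nn.cross_entropy(logits, y)
            grads = model.backward(dlogits, cache)
            opt.step(grads)
            losses.append(loss)
        dev_loss, dev_err = dev_evaluator(model)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "dev_loss": dev_loss, "dev_error": dev_err}
        )
        if stopper.update(epoch, dev_loss, model.params):
            break

    if stopper.best_snapshot is not None:
        model.params.update(
            {k: v.copy() for k, v in stopper.best_snapshot.items()}
        )
    return TrainedBaseModel(c, model, history, stopper.best_epoch)
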