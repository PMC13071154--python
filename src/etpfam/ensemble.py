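"""Ensemble voting strategies over per-model aggregated scores.

Given I base models each emitting a K-class score vector s_ik per sequence,
the final family prediction kappa* can be formed by:

* simple voting       — kappa* = argmax_k sum_i delta(kappa_i, k)
* score voting        — kappa* = argmax_k sum_i s_ik
* LWM (per model)     — kappa* = argmax_k sum_i w_i s_ik
* LWF perceptron      — kappa* = argmax_k sum_i w_ik s_ik + b_k
* LWF MLP             — kappa* = argmax_k f_k(s_k), one small MLP per family
* stacking perceptron — kappa* = argmax_k sum_l sum_i w_ilk s_il + b_k
* stacking MLP        — a single MLP over the I*K concatenation

The learned strategies fit their weights by full-batch gradient descent
(adaptive-moment updates) on softmax cross-entropy over the development
partition, with an internal held-out slice of dev for early stopping.  The
per-family strategies are where ensembles rescue families no single model
gets right: the combiner learns which member to trust for each family.

Tie-breaking is everywhere to the lowest class index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import NotFittedError
from .nn import Adam, EarlyStopping, relu, softmax
from .window_scoring import AggregatedScore

STRATEGIES = (
    "simple", "score", "lwm",
    "lwf_perceptron", "lwf_mlp",
    "stack_perceptron", "stack_mlp",
)
LEARNED = STRATEGIES[2:]

#: above this many stacking-perceptron weights (I*K*K) a warning is issued
STACK_SIZE_WARN = 50_000_000


@dataclass
class ScoreBlock:
    """Dense tensor of aggregated scores: (sequence, model, class)."""

    sequence_ids: list[str]
    model_ids: list[str]
    tensor: np.ndarray  # (S, I, K)
    method: str = "swc"

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        S, I, K = self.tensor.shape
        if S != len(self.sequence_ids) or I != len(self.model_ids):
            raise ValueError("tensor shape inconsistent with id lists")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("non-finite scores in block")

    @property
    def n_models(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_classes(self) -> int:
        return self.tensor.shape[2]

    def subset_models(self, model_ids: Sequence[str]) -> "ScoreBlock":
        idx = [self.model_ids.index(m) for m in model_ids]
        return ScoreBlock(
            list(self.sequence_ids), list(model_ids),
            self.tensor[:, idx, :], self.method,
        )


def block_from_aggregated(
    aggregated: Sequence[AggregatedScore],
    model_ids: Sequence[str] | None = None,
    sequence_ids: Sequence[str] | None = None,
) -> ScoreBlock:
    """Assemble a complete (S, I, K) block from per-(model, sequence) scores."""
    by_key = {(a.sequence_id, a.model_id): a for a in aggregated}
    model_ids = list(model_ids or dict.fromkeys(a.model_id for a in aggregated))
    sequence_ids = list(
        sequence_ids or dict.fromkeys(a.sequence_id for a in aggregated)
    )
    methods = {a.method for a in aggregated}
    if len(methods) != 1:
        raise ValueError(f"mixed aggregation methods in block: {sorted(methods)}")
    K = len(next(iter(by_key.values())).s)
    tensor = np.zeros((len(sequence_ids), len(model_ids), K))
    for si, sid in enumerate(sequence_ids):
        for mi, mid in enumerate(model_ids):
            try:
                tensor[si, mi] = by_key[(sid, mid)].s
            except KeyError:
                raise ValueError(f"missing score for ({sid}, {mid})") from None
    return ScoreBlock(sequence_ids, model_ids, tensor, methods.pop())


# ---------------------------------------------------------------- voting ---

def _argmax_rows(z: np.ndarray) -> np.ndarray:
    """Row-wise argmax; numpy resolves ties to the lowest index."""
    return z.argmax(axis=1)


def simple_vote(block: ScoreBlock) -> np.ndarray:
    """Each model casts one vote (its argmax); most-voted class wins."""
    S, I, K = block.tensor.shape
    votes = block.tensor.argmax(axis=2)  # (S, I)
    counts = np.zeros((S, K))
    for i in range(I):
        counts[np.arange(S), votes[:, i]] += 1.0
    return _argmax_rows(counts)


def score_vote(block: ScoreBlock) -> np.ndarray:
    """Sum of the models' score vectors; maximal class wins."""
    return _argmax_rows(block.tensor.sum(axis=1))


def lwm_scores(block: ScoreBlock, w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (block.n_models,):
        raise ValueError(f"need {block.n_models} model weights, got {w.shape}")
    return np.einsum("sik,i->sk", block.tensor, w)


def lwm_predict(block: ScoreBlock, w: np.ndarray) -> np.ndarray:
    return _argmax_rows(lwm_scores(block, w))


def lwf_perceptron_scores(
    block: ScoreBlock, w: np.ndarray, b: np.ndarray
) -> np.ndarray:
    return np.einsum("sik,ik->sk", block.tensor, w) + b[None, :]


def lwf_mlp_scores(block: ScoreBlock, p: Mapping[str, np.ndarray]) -> np.ndarray:
    # one MLP per family k: hidden = relu(W1_k @ s_k + b1_k); out = w2_k.h + b2_k
    X = block.tensor  # (S, I, K)
    h = relu(np.einsum("khi,sik->skh", p["W1"], X) + p["b1"][None])
    return np.einsum("skh,kh->sk", h, p["w2"]) + p["b2"][None]


def stack_perceptron_scores(
    block: ScoreBlock, w: np.ndarray, b: np.ndarray
) -> np.ndarray:
    S = block.tensor.shape[0]
    flat = block.tensor.reshape(S, -1)  # (S, I*K), model-major
    return flat @ w + b[None, :]


def stack_mlp_scores(block: ScoreBlock, p: Mapping[str, np.ndarray]) -> np.ndarray:
    S = block.tensor.shape[0]
    flat = block.tensor.reshape(S, -1)
    h = relu(flat @ p["W1"] + p["b1"][None])
    return h @ p["W2"] + p["b2"][None]


@dataclass
class FitMeta:
    """Optimizer settings for learned combiners."""

    lr: float = 0.05
    max_iters: int = 400
    patience: int = 5
    holdout_frac: float = 0.1
    seed: int = 0


@dataclass
class EnsembleCombiner:
    """A tagged strategy + parameter set with a fit-on-dev contract.

    ``simple`` and ``score`` carry no parameters; the learned strategies must
    be fitted (on the development partition) before predicting.
    """

    strategy: str
    params: dict[str, np.ndarray] = field(default_factory=dict)
    fit_meta: FitMeta | None = None
    fitted: bool = False
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy '{self.strategy}'")
        if self.strategy in ("simple", "score"):
            self.fitted = True

    def class_scores(self, block: ScoreBlock) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError(
                f"combiner '{self.strategy}' must be fitted before predicting"
            )
        p = self.params
        if self.strategy == "simple":
            raise ValueError("simple voting has no class scores; use predict()")
        if self.strategy == "score":
            return block.tensor.sum(axis=1)
        if self.strategy == "lwm":
            return lwm_scores(block, p["w"])
        if self.strategy == "lwf_perceptron":
            return lwf_perceptron_scores(block, p["w"], p["b"])
        if self.strategy == "lwf_mlp":
            return lwf_mlp_scores(block, p)
        if self.strategy == "stack_perceptron":
            return stack_perceptron_scores(block, p["w"], p["b"])
        return stack_mlp_scores(block, p)

    def predict(self, block: ScoreBlock) -> np.ndarray:
        if self.strategy == "simple":
            return simple_vote(block)
        return _argmax_rows(self.class_scores(block))

    def save(self, path: str | Path) -> None:
        meta = {"strategy": self.strategy, "fitted": self.fitted,
                "history": self.history}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleCombiner":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        out = cls(meta["strategy"], params)
        out.fitted = meta["fitted"]
        out.history = meta["history"]
        return out


# ---------------------------------------------------------------- fitting ---

def _init_params(
    strategy: str, I: int, K: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    if strategy == "lwm":
        return {"w": np.ones(I)}
    if strategy == "lwf_perceptron":
        # w=1, b=0 starts exactly at score voting; families never seen in dev
        # keep this initialization (graceful fallback)
        return {"w": np.ones((I, K)), "b": np.zeros(K)}
    if strategy == "lwf_mlp":
        H = 2 * I
        return {
            "W1": rng.standard_normal((K, H, I)) * np.sqrt(2.0 / I),
            "b1": np.zeros((K, H)),
            "w2": rng.standard_normal((K, H)) * np.sqrt(1.0 / H),
            "b2": np.zeros(K),
        }
    if strategy == "stack_perceptron":
        n_weights = I * K * K
        if n_weights > STACK_SIZE_WARN:
            warnings.warn(
                f"stacking perceptron allocates {n_weights} weights "
                f"(I*K*K with I={I}, K={K}); expect heavy memory use and "
                "overfitting at large K", RuntimeWarning,
            )
        # own-class block pattern: starts exactly at score voting
        w = np.zeros((I, K, K))
        w[:, np.arange(K), np.arange(K)] = 1.0
        return {"w": w.reshape(I * K, K), "b": np.zeros(K)}
    if strategy == "stack_mlp":
        H = 256
        return {
            "W1": rng.standard_normal((I * K, H)) * np.sqrt(2.0 / (I * K)),
            "b1": np.zeros(H),
            "W2": rng.standard_normal((H, K)) * np.sqrt(1.0 / H),
            "b2": np.zeros(K),
        }
    raise ValueError(strategy)


def _class_scores_and_grads(
    strategy: str, params: dict, block: ScoreBlock, dZ: np.ndarray
) -> dict[str, np.ndarray]:
    """Backprop dLoss/dZ (S, K) into the strategy's parameters."""
    X = block.tensor
    if strategy == "lwm":
        return {"w": np.einsum("sik,sk->i", X, dZ)}
    if strategy == "lwf_perceptron":
        return {"w": np.einsum("sik,sk->ik", X, dZ), "b": dZ.sum(axis=0)}
    if strategy == "lwf_mlp":
        pre = np.einsum("khi,sik->skh", params["W1"], X) + params["b1"][None]
        h = relu(pre)
        dh = dZ[:, :, None] * params["w2"][None]  # (S, K, H)
        dpre = dh * (pre > 0)
        return {
            "w2": np.einsum("skh,sk->kh", h, dZ),
            "b2": dZ.sum(axis=0),
            "W1": np.einsum("skh,sik->khi", dpre, X),
            "b1": dpre.sum(axis=0),
        }
    S = X.shape[0]
    flat = X.reshape(S, -1)
    if strategy == "stack_perceptron":
        return {"w": flat.T @ dZ, "b": dZ.sum(axis=0)}
    if strategy == "stack_mlp":
        pre = flat @ params["W1"] + params["b1"][None]
        h = relu(pre)
        dh = dZ @ params["W2"].T
        dpre = dh * (pre > 0)
        return {
            "W2": h.T @ dZ, "b2": dZ.sum(axis=0),
            "W1": flat.T @ dpre, "b1": dpre.sum(axis=0),
        }
    raise ValueError(strategy)


def _ce(Z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    P = softmax(Z)
    n = len(y)
    loss = float(-np.log(P[np.arange(n), y] + 1e-300).mean())
    G = P.copy()
    G[np.arange(n), y] -= 1.0
    return loss, G / n


def fit_combiner(
    strategy: str,
    dev_block: ScoreBlock,
    dev_labels: np.ndarray,
    fit_meta: FitMeta | None = None,
) -> EnsembleCombiner:
    """Fit a learned combiner on the development partition.

    Full-batch adaptive-moment gradient descent on the softmax cross-entropy
    of the strategy's class scores; an internal held-out fraction of dev
    drives early stopping (best checkpoint restored).  Families absent from
    the dev fit never have their per-family parameters updated, so for them
    the LWF strategies stay at their score-voting initialization.
    """
    if strategy not in LEARNED:
        raise ValueError(f"strategy '{strategy}' has nothing to fit")
    meta = fit_meta or FitMeta()
    y = np.asarray(dev_labels)
    S, I, K = dev_block.tensor.shape
    if len(y) != S:
        raise ValueError("labels/block length mismatch")
    rng = np.random.default_rng(meta.seed)
    params = _init_params(strategy, I, K, rng)

    perm = rng.permutation(S)
    n_hold = max(1, int(round(meta.holdout_frac * S))) if S > 1 else 0
    hold_idx, fit_idx = perm[:n_hold], perm[n_hold:]
    if len(fit_idx) == 0:
        fit_idx = perm
    fit_block = ScoreBlock(
        [dev_block.sequence_ids[i] for i in fit_idx], list(dev_block.model_ids),
        dev_block.tensor[fit_idx], dev_block.method,
    )
    y_fit = y[fit_idx]
    hold_block = (
        ScoreBlock(
            [dev_block.sequence_ids[i] for i in hold_idx],
            list(dev_block.model_ids),
            dev_block.tensor[hold_idx], dev_block.method,
        )
        if n_hold else fit_block
    )
    y_hold = y[hold_idx] if n_hold else y_fit

    # per-family parameters only learn for families present in the fit slice
    present = np.zeros(K, dtype=bool)
    present[np.unique(y_fit)] = True
    per_family_axis = {
        "lwf_perceptron": {"w": 1, "b": 0},
        "lwf_mlp": {"W1": 0, "b1": 0, "w2": 0, "b2": 0},
    }.get(strategy)

    combiner = EnsembleCombiner(strategy, params, meta)
    combiner.fitted = True  # scoring needed during fitting
    opt = Adam(params, lr=meta.lr)
    stopper = EarlyStopping(meta.patience)
    history = []
    for it in range(1, meta.max_iters + 1):
        Z = combiner.class_scores(fit_block)
        loss, dZ = _ce(Z, y_fit)
        grads = _class_scores_and_grads(strategy, params, fit_block, dZ)
        if per_family_axis is not None:
            for name, axis in per_family_axis.items():
                g = np.moveaxis(grads[name], axis, 0)
                g[~present] = 0.0
        opt.step(grads)
        hold_loss, _ = _ce(combiner.class_scores(hold_block), y_hold)
        history.append({"iter": it, "fit_loss": loss, "holdout_loss": hold_loss})
        if stopper.update(it, hold_loss, params):
            break
    if stopper.best_snapshot is not None:
        params.update({k: v.copy() for k, v in stopper.best_snapshot.items()})
    combiner.history = history
    return combiner


def make_combiner(strategy: str, **params: np.ndarray) -> EnsembleCombiner:
    """Build a combiner with explicitly supplied parameters (no fitting)."""
    c = EnsembleCombiner(strategy, {k: np.asarray(v, float) for k, v in params.items()})
    if params:
        c.fitted = True
    return c


# ------------------------------------------------------- member selection ---

def ensemble_error(
    strategy: str,
    block: ScoreBlock,
    labels: np.ndarray,
    fit_block: ScoreBlock | None = None,
    fit_labels: np.ndarray | None = None,
    fit_meta: FitMeta | None = None,
) -> float:
    """Prediction error of one strategy, fitting it first if learned."""
    if strategy in LEARNED:
        comb = fit_combiner(strategy, fit_block if fit_block is not None else block,
                            fit_labels if fit_labels is not None else labels,
                            fit_meta)
    else:
        comb = EnsembleCombiner(strategy)
    pred = comb.predict(block)
    return float((pred != np.asarray(labels)).mean())


def select_members(
    model_dev_errors: Mapping[str, float],
    dev_block: ScoreBlock,
    dev_labels: np.ndarray,
    max_members: int = 10,
    error_threshold: float = 0.20,
    rng: np.random.Generator | None = None,
    strategies: Sequence[str] = ("simple", "score", "lwm", "lwf_perceptron"),
    fit_meta: FitMeta | None = None,
) -> tuple[list[str], "pd.DataFrame"]:
    """Randomly draw ensemble members among models with CwS dev error below
    the threshold, and trace each strategy's dev error at sizes 1..max.

    ``model_dev_errors`` maps model_id -> CwS dev error.  Returns the ordered
    member list and the incremental dev-error curve (long-form DataFrame with
    columns size, strategy, dev_error).
    """
    import pandas as pd

    rng = rng or np.random.default_rng(0)
    eligible = [m for m in dev_block.model_ids
                if model_dev_errors[m] < error_threshold]
    if not eligible:
        raise ValueError(
            f"no model has dev error below {error_threshold:.0%}"
        )
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    members = order[:max_members]
    rows = []
    for size in range(1, len(members) + 1):
        sub = dev_block.subset_models(members[:size])
        for strat in strategies:
            err = ensemble_error(strat, sub, dev_labels, fit_meta=fit_meta)
            rows.append({"size": size, "strategy": strat, "dev_error": err})
    return members, pd.DataFrame(rows)
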