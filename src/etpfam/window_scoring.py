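"""Collapse per-position class scores into one score vector per sequence.

Three aggregation rules turn a track of per-window probability vectors
s_ik(n) into a single per-class score s_ik for a (model, sequence) pair:

* CwS (central window score): the score row at the window position nearest
  the sequence midpoint.
* SwA (sliding window area): the mean of the score rows over all evaluated
  positions — the (normalised) area under s_ik(n).
* SwC (sliding window coverage): the fraction of evaluated positions where
  class k wins the argmax.

The per-model family prediction is then simply argmax_k s_ik, ties broken by
the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Method = Literal["cws", "swa", "swc"]


@dataclass
class PositionScoreTrack:
    """Per-window class scores of one model along one sequence."""

    sequence_id: str
    model_id: str
    positions: np.ndarray  # (P,) strictly increasing window centres
    scores: np.ndarray  # (P, K); each row a probability vector
    seq_length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.positions) != self.scores.shape[0]:
            raise ValueError("positions/scores length mismatch")
        if len(self.positions) < 1:
            raise ValueError("track must have at least one position")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("score rows must sum to 1")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]


@dataclass
class AggregatedScore:
    """One per-class score vector per (model, sequence) after aggregation."""

    sequence_id: str
    model_id: str
    method: Method
    s: np.ndarray  # (K,)

    @property
    def kappa(self) -> int:
        """Predicted class: lowest index attaining the maximum score."""
        return predict(self.s)


def predict(s: np.ndarray) -> int:
    """argmax with deterministic ties-to-lowest-index."""
    return int(np.argmax(s))


def central_window_score(track: PositionScoreTrack) -> AggregatedScore:
    """Score row at the position nearest the sequence midpoint.

    Equidistant positions resolve to the earlier one.  When the sequence
    length is unknown the midpoint of the evaluated range is used.
    """
    if track.seq_length is not None:
        mid = (track.seq_length - 1) / 2.0
    else:
        mid = (track.positions[0] + track.positions[-1]) / 2.0
    dist = np.abs(track.positions.astype(float) - mid)
    i = int(np.argmin(dist))  # argmin ties -> earlier position
    return AggregatedScore(track.sequence_id, track.model_id, "cws",
                           track.scores[i].copy())


def sliding_window_area(track: PositionScoreTrack) -> AggregatedScore:
    """Mean of the score rows over all evaluated positions."""
    s = track.scores.mean(axis=0)
    return AggregatedScore(track.sequence_id, track.model_id, "swa", s)


def sliding_window_coverage(track: PositionScoreTrack) -> AggregatedScore:
    """Fraction of evaluated positions won by each class."""
    winners = track.scores.argmax(axis=1)
    counts = np.bincount(winners, minlength=track.n_classes).astype(float)
    s = counts / track.n_positions
    return AggregatedScore(track.sequence_id, track.model_id, "swc", s)


_METHODS = {
    "cws": central_window_score,
    "swa": sliding_window_area,
    "swc": sliding_window_coverage,
}


def aggregate(track: PositionScoreTrack, method: Method) -> AggregatedScore:
    try:
        return _METHODS[method](track)
    except KeyError:
        raise ValueError(f"unknown aggregation method '{method}'") from None


def write_score_table(
    aggregated: Iterable[AggregatedScore], path: str | Path
) -> None:
    """Serialize aggregated scores as a wide TSV (k0..k{K-1} columns)."""
    rows = []
    for a in aggregated:
        row = {"sequence_id": a.sequence_id, "model_id": a.model_id,
               "method": a.method}
        row.update({f"k{j}": a.s[j] for j in range(len(a.s))})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_score_table(path: str | Path) -> list[AggregatedScore]:
    df = pd.read_csv(path, sep="\t")
    kcols = sorted(
        (c for c in df.columns if c.startswith("k") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    return [
        AggregatedScore(
            str(r["sequence_id"]), str(r["model_id"]), r["method"],
            np.array([r[c] for c in kcols], dtype=float),
        )
        for _, r in df.iterrows()
    ]
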