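"""Evaluation: error rates, per-family F1 tables, rescue and binned analyses.

The error rate is defined through recall: e = 1 - r = 1 - TP/(TP+FN), pooled
over all test sequences (micro).  In the single-label, always-predict setting
this equals the misclassified fraction.  Per-family F1 = 2TP/(2TP+FP+FN).

A prediction on a multi-domain sequence counts as correct when it matches ANY
annotated family of the sequence; per-family bookkeeping attributes the TP
(or FN) to the sequence's primary family — the leftmost domain — so that per
family TP + FN equals the number of test sequences carrying that primary
label, and TPs+FNs sum to the number of test sequences overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

Labels = Mapping[str, Sequence[int] | int]


def _label_list(v: Sequence[int] | int) -> list[int]:
    return [int(v)] if np.isscalar(v) else list(v)


@dataclass
class FamilyMetrics:
    """Per-family confusion counts and rates plus pooled summaries."""

    table: pd.DataFrame  # family, TP, FP, FN, recall, error, F1, n_test, n_train
    micro_error: float
    macro_f1: float

    def for_family(self, family: int | str) -> pd.Series:
        return self.table.set_index("family").loc[family]


def _check_ids(predictions: Mapping[str, int], labels: Labels) -> list[str]:
    missing = set(labels) - set(predictions)
    extra = set(predictions) - set(labels)
    if missing or extra:
        raise ValueError(
            f"prediction/label id mismatch (missing={sorted(missing)[:3]}, "
            f"extra={sorted(extra)[:3]})"
        )
    return list(labels)


def error_rate(predictions: Mapping[str, int], labels: Labels) -> float:
    """Micro error 1 - TP/(TP+FN): the fraction of sequences whose prediction
    matches none of their annotated families."""
    ids = _check_ids(predictions, labels)
    if not ids:
        return 0.0
    wrong = sum(
        predictions[i] not in _label_list(labels[i]) for i in ids
    )
    return wrong / len(ids)


def f1_table(
    predictions: Mapping[str, int],
    labels: Labels,
    n_families: int | None = None,
    train_family_sizes: Mapping[int, int] | None = None,
) -> FamilyMetrics:
    """Per-family TP/FP/FN, recall, error and F1, plus micro/macro summaries.

    Families with no test member and never predicted are excluded from the
    macro mean; a family with test members but zero TP+FP+FN contributes
    F1 = 0 by convention.
    """
    ids = _check_ids(predictions, labels)
    fams = set()
    for i in ids:
        fams.add(_label_list(labels[i])[0])
        fams.add(int(predictions[i]))
    K = n_families if n_families is not None else (max(fams) + 1 if fams else 0)
    TP = np.zeros(K, dtype=int)
    FP = np.zeros(K, dtype=int)
    FN = np.zeros(K, dtype=int)
    n_test = np.zeros(K, dtype=int)
    for i in ids:
        labs = _label_list(labels[i])
        primary = labs[0]
        pred = int(predictions[i])
        n_test[primary] += 1
        if pred in labs:
            TP[primary] += 1
        else:
            FN[primary] += 1
            FP[pred] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(n_test > 0, TP / np.maximum(TP + FN, 1), np.nan)
        denom = 2 * TP + FP + FN
        f1 = np.where(denom > 0, 2 * TP / np.maximum(denom, 1), 0.0)
    table = pd.DataFrame(
        {
            "family": np.arange(K),
            "TP": TP, "FP": FP, "FN": FN,
            "recall": recall,
            "error": 1.0 - recall,
            "F1": f1,
            "n_test": n_test,
            "n_train": [
                (train_family_sizes or {}).get(k, 0) for k in range(K)
            ],
        }
    )
    total = n_test.sum()
    micro = float(FN.sum() / total) if total else 0.0
    has_test = n_test > 0
    macro = float(f1[has_test].mean()) if has_test.any() else 0.0
    return FamilyMetrics(table, micro, macro)


def rescue_analysis(
    metrics_a: FamilyMetrics, metrics_b: FamilyMetrics
) -> pd.DataFrame:
    """Families completely missed by model a (error 100%) yet perfectly
    predicted by model b (error 0%) — the per-family rescue effect."""
    a = metrics_a.table.set_index("family")
    b = metrics_b.table.set_index("family")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    tested = (a["n_test"] > 0) & (b["n_test"] > 0)
    rescued = tested & (a["error"] == 1.0) & (b["error"] == 0.0)
    out = pd.DataFrame(
        {
            "family": common[rescued],
            "n_test": a.loc[rescued, "n_test"].to_numpy(),
            "error_a": 1.0,
            "error_b": 0.0,
        }
    ).reset_index(drop=True)
    out.attrs["n_failed_a"] = int((tested & (a["error"] == 1.0)).sum())
    out.attrs["n_rescued"] = int(rescued.sum())
    return out


def kmer_jaccard(a: str, b: str, k: int = 3) -> float:
    """Shared k-mer Jaccard identity between two residue strings."""
    if len(a) < k or len(b) < k:
        return float(a == b)
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    inter = len(sa & sb)
    union = len(sa | sb)
    return inter / union if union else 0.0


def family_similarity(
    test_seqs: Mapping[str, str],
    train_seqs: Mapping[str, str],
    similarity_fn: Callable[[str, str], float] = kmer_jaccard,
) -> float:
    """Test-to-train similarity of one family: for each test member take the
    maximum similarity to any train member, then average those maxima."""
    if not test_seqs:
        return float("nan")
    if not train_seqs:
        return 0.0
    maxima = [
        max(similarity_fn(t, r) for r in train_seqs.values())
        for t in test_seqs.values()
    ]
    return float(np.mean(maxima))


def binned_performance(
    metrics: FamilyMetrics,
    key: str = "train_family_size",
    n_bins: int = 5,
    family_key_values: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Mean F1 over families ordered and binned by a family-level key.

    ``key`` is either 'train_family_size' (taken from the metrics table) or
    'test_to_train_similarity' (supplied via ``family_key_values``, e.g. from
    :func:`family_similarity`).  Families without test members are excluded.
    """
    t = metrics.table[metrics.table["n_test"] > 0].copy()
    if key == "train_family_size":
        t["key"] = t["n_train"].astype(float)
    elif key == "test_to_train_similarity":
        if family_key_values is None:
            raise ValueError("similarity binning needs family_key_values")
        t["key"] = [family_key_values.get(f, np.nan) for f in t["family"]]
        t = t.dropna(subset=["key"])
    else:
        raise ValueError(f"unknown binning key '{key}'")
    t = t.sort_values(["key", "family"]).reset_index(drop=True)
    n_bins = min(n_bins, len(t)) or 1
    t["bin"] = (np.arange(len(t)) * n_bins) // max(len(t), 1)
    out = (
        t.groupby("bin")
        .agg(mean_key=("key", "mean"), mean_F1=("F1", "mean"),
             n_families=("family", "count"))
        .reset_index()
    )
    return out
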