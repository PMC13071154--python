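"""Synthetic desk-scale benchmarks with the statistical structure the
method assumes.

Two generator tiers:

* :func:`generate_benchmark` builds a full pipeline input — sequences,
  domain annotations, a train/dev/test split and per-residue embedding
  tracks.  Each family has a fixed random motif vector; a sequence's track is
  Gaussian background noise plus the family motif added over the annotated
  domain span.  Family sizes follow a power law (heavy class imbalance), a
  configurable fraction of sequences carries two domains from distinct
  families, and sequence lengths are bounded.  This emulates the shape of a
  Pfam-style clustered benchmark, not protein biology.

* :func:`generate_score_block` skips the sequence level entirely and emits
  per-(model, sequence) score vectors with a prescribed per-model-per-family
  reliability matrix p_ik and confusion targets, so the ensemble layer is
  testable in milliseconds with known ground truth.

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    DatasetSplit,
    DomainAnnotation,
    ProteinSequence,
    SPLIT_COLUMNS,
    write_fasta,
    write_split_table,
)
from .embedder import EmbeddedSequence, EmbeddingStore
from .ensemble import ScoreBlock

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class BenchmarkSpec:
    """Defines the synthetic study conditions.

    Defaults are the desk-scale conditions used throughout the test suite:
    12 families, 16-dim embeddings, 300 sequences, unit-norm motifs over a
    Gaussian background of sd 0.5, power-law family sizes, 10% multi-domain
    sequences and a 60/20/20 partition split.
    """

    n_families: int = 12
    embed_dim: int = 16
    n_sequences: int = 300
    motif_strength: float = 1.0
    background_noise_sd: float = 0.5
    sequence_length_range: tuple[int, int] = (40, 120)
    family_size_alpha: float = 1.0  # power-law exponent over family ranks
    min_family_size: int = 3
    multi_domain_fraction: float = 0.1
    partition_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    max_len: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.partition_fractions) - 1.0) > 1e-9:
            raise ValueError("partition fractions must sum to 1")
        lo, hi = self.sequence_length_range
        if lo < 8 or hi < lo:
            raise ValueError("invalid sequence length range")
        if self.multi_domain_fraction > 0 and lo < 4 * _MIN_DOM:
            raise ValueError(
                f"two domains cannot fit the minimum length {lo}; "
                f"need at least {4 * _MIN_DOM}"
            )
        if not (0 <= self.multi_domain_fraction <= 1):
            raise ValueError("multi_domain_fraction must be in [0, 1]")


_MIN_DOM = 10  # minimum domain length in residues


@dataclass
class SyntheticBenchmark:
    """The generated artifact bundle, writable to disk."""

    spec: BenchmarkSpec
    sequences: list[ProteinSequence]
    split: DatasetSplit
    embeddings: list[EmbeddedSequence]
    motifs: np.ndarray = field(repr=False, default=None)  # (K, E)

    def partition(self, name: str) -> list[EmbeddedSequence]:
        ids = set(self.split.ids_in(name))
        return [e for e in self.embeddings if e.id in ids]

    def sequence_labels(self, name: str) -> dict[str, list[int]]:
        """id -> class indices (primary first) for one partition."""
        return {i: self.split.labels_for(i) for i in self.split.ids_in(name)}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "sequences.fasta",
            "split": out / "split.tsv",
            "store": out / "embeddings.h5",
        }
        write_fasta(self.sequences, paths["fasta"])
        write_split_table(self.split, paths["split"])
        EmbeddingStore.create(paths["store"], self.embeddings).close()
        return paths


def _family_sizes(spec: BenchmarkSpec, rng: np.random.Generator) -> np.ndarray:
    K = spec.n_families
    w = (np.arange(1, K + 1, dtype=float)) ** (-spec.family_size_alpha)
    w /= w.sum()
    floor = spec.min_family_size * K
    if floor > spec.n_sequences:
        raise ValueError("n_sequences too small for min_family_size")
    sizes = np.full(K, spec.min_family_size)
    extra = rng.multinomial(spec.n_sequences - floor, w)
    return sizes + extra


def _partition_counts(n: int, fr: tuple[float, float, float]) -> tuple[int, int, int]:
    n_dev = max(1, int(round(fr[1] * n))) if n >= 3 else 0
    n_test = max(1, int(round(fr[2] * n))) if n >= 3 else 0
    n_train = n - n_dev - n_test
    if n_train < 1:  # tiny families stay in train
        return n, 0, 0
    return n_train, n_dev, n_test


def generate_benchmark(spec: BenchmarkSpec) -> SyntheticBenchmark:
    """Generate sequences, split and embedding tracks, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    K, E = spec.n_families, spec.embed_dim
    motifs = rng.standard_normal((K, E))
    motifs /= np.linalg.norm(motifs, axis=1, keepdims=True)
    motifs *= spec.motif_strength
    fam_names = [f"FAM{k:04d}" for k in range(K)]
    sizes = _family_sizes(spec, rng)

    # per-family member lists, then stratified partition assignment
    seqs: list[ProteinSequence] = []
    embs: list[EmbeddedSequence] = []
    rows: list[tuple] = []
    lo, hi = spec.sequence_length_range
    counter = 0
    for k in range(K):
        n_train, n_dev, n_test = _partition_counts(
            int(sizes[k]), spec.partition_fractions
        )
        parts = (["train"] * n_train + ["dev"] * n_dev + ["test"] * n_test)
        parts = [parts[i] for i in rng.permutation(len(parts))]
        for part in parts:
            sid = f"SYN{counter:05d}"
            counter += 1
            L = int(rng.integers(lo, hi + 1))
            residues = "".join(
                _AA[j] for j in rng.integers(0, len(_AA), size=L)
            )
            multi = (
                spec.multi_domain_fraction > 0
                and rng.random() < spec.multi_domain_fraction
            )
            domains = _draw_domains(rng, L, k, K, multi)
            track = rng.normal(0.0, spec.background_noise_sd, size=(E, L))
            annots = []
            for fam_k, ds, de in domains:
                track[:, ds:de] += motifs[fam_k][:, None]
                annots.append(
                    DomainAnnotation(fam_names[fam_k], ds + 1, de)
                )
                rows.append((sid, part, fam_names[fam_k], ds + 1, de))
            seqs.append(ProteinSequence(sid, residues))
            embs.append(EmbeddedSequence(sid, track, annots))

    records = pd.DataFrame(rows, columns=SPLIT_COLUMNS)
    family_index = {f: k for k, f in enumerate(fam_names)}
    split = DatasetSplit(records, family_index)
    return SyntheticBenchmark(spec, seqs, split, embs, motifs)


def _draw_domains(
    rng: np.random.Generator, L: int, k: int, K: int, multi: bool
) -> list[tuple[int, int, int]]:
    """Return [(family, start0, end0_exclusive)] spans, disjoint."""
    if multi and K > 1:
        half = L // 2
        d1 = int(rng.integers(_MIN_DOM, max(half - 2, _MIN_DOM) + 1))
        d2 = int(rng.integers(_MIN_DOM, max(L - half - 2, _MIN_DOM) + 1))
        s1 = int(rng.integers(0, half - d1 + 1))
        s2 = half + int(rng.integers(0, L - half - d2 + 1))
        k2 = int((k + 1 + rng.integers(0, K - 1)) % K)
        if k2 == k:
            k2 = (k + 1) % K
        return [(k, s1, s1 + d1), (k2, s2, s2 + d2)]
    dlen = int(rng.integers(max(_MIN_DOM, int(0.4 * L)), int(0.8 * L) + 1))
    dlen = min(dlen, L)
    start = int(rng.integers(0, L - dlen + 1))
    return [(k, start, start + dlen)]


@dataclass
class SyntheticScoreSpec:
    """Direct driver for ensemble tests: prescribed model reliabilities.

    ``reliability[i, k]`` is the probability that model i's argmax equals the
    true family k; otherwise the argmax lands on ``confusion[i, k]``.  Scores
    are softened into probability vectors with uniform noise bounded by
    ``temperature`` (< 1 keeps the designated winner on top).
    """

    n_models: int
    reliability: np.ndarray  # (I, K)
    confusion: np.ndarray | None = None  # (I, K) int targets
    temperature: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.reliability = np.asarray(self.reliability, dtype=float)
        if self.reliability.ndim != 2 or self.reliability.shape[0] != self.n_models:
            raise ValueError("reliability must be (n_models, K)")
        if np.any((self.reliability < 0) | (self.reliability > 1)):
            raise ValueError("reliabilities must lie in [0, 1]")
        if not (0 < self.temperature < 1):
            raise ValueError("temperature must be in (0, 1)")
        K = self.reliability.shape[1]
        if self.confusion is None:
            self.confusion = (np.arange(K)[None, :] + 1) % K * np.ones(
                (self.n_models, 1), dtype=int
            )
        self.confusion = np.asarray(self.confusion, dtype=int)


def generate_score_block(
    spec: SyntheticScoreSpec, labels: np.ndarray
) -> ScoreBlock:
    """Draw an (S, I, K) score block consistent with the reliability matrix."""
    rng = np.random.default_rng(spec.seed)
    y = np.asarray(labels, dtype=int)
    I, K = spec.reliability.shape
    S = len(y)
    tensor = rng.random((S, I, K)) * spec.temperature
    correct = rng.random((S, I)) < spec.reliability[:, y].T  # (S, I)
    winners = np.where(correct, y[:, None], spec.confusion[:, y].T)
    tensor[np.arange(S)[:, None], np.arange(I)[None, :], winners] += 1.0
    tensor /= tensor.sum(axis=2, keepdims=True)
    return ScoreBlock(
        [f"s{j}" for j in range(S)],
        [f"m{i}" for i in range(I)],
        tensor,
    )


def expert_quarters_spec(
    n_models: int = 4,
    n_families: int = 20,
    p_expert: float = 0.95,
    p_off: float = 0.1,
    temperature: float = 0.5,
    seed: int = 0,
) -> SyntheticScoreSpec:
    """Reliability pattern where each model is the sole expert on a disjoint
    slice of the families — the regime where per-family weighting rescues
    families no single model can carry."""
    rel = np.full((n_models, n_families), p_off)
    per = n_families // n_models
    for i in range(n_models):
        hi = (i + 1) * per if i < n_models - 1 else n_families
        rel[i, i * per : hi] = p_expert
    return SyntheticScoreSpec(n_models, rel, temperature=temperature, seed=seed)
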