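"""Per-residue embedding tracks: synthetic embedder, adapters, HDF5 store.

Every classifier in this package consumes an ``EmbeddedSequence``: an E x L
real matrix with one column per residue.  In production these columns come
from a protein language model (ESM2, E=1280; ProtT5, E=1024) through the
adapter interface; the test suite and the synthetic benchmark use the built-in
deterministic embedder, which hashes each centred 5-mer to a pseudo-random
unit-variance vector.  That gives windows family-discriminative local signal
— identical 5-mers always map to identical columns — with no model weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np

from .data_model import DomainAnnotation, ProteinSequence
from .errors import ConfigurationError, LookupKeyError


@dataclass
class EmbeddedSequence:
    """An E x L per-residue embedding track with optional domain labels."""

    id: str
    matrix: np.ndarray  # shape (E, L)
    labels: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("embedding track must be 2-D (E x L)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"non-finite entries in track '{self.id}'")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class EmbedderSpec:
    """Identifies an embedder and its output dimension.

    ``deterministic_seed`` only affects the synthetic embedder; external
    language-model adapters ignore it.
    """

    name: str = "synthetic"
    dim: int = 16
    deterministic_seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigurationError("embedding dim must be >= 1")


#: Known external adapters and their fixed embedding dimensions.
ADAPTER_DIMS = {"esm2": 1280, "prott5": 1024}

_KMER = 5  # centred k-mer width of the synthetic embedder


def _kmer_vector(kmer: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.blake2b(
        f"{seed}:{kmer}".encode(), digest_size=8
    ).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return rng.standard_normal(dim)


def synthetic_embed(
    sequence: ProteinSequence, dim: int, seed: int = 0
) -> np.ndarray:
    """Deterministic 5-mer-hash embedding: column n depends only on the
    residue letters at n-2..n+2 (edge-padded with '-') and the seed."""
    half = _KMER // 2
    padded = "-" * half + sequence.residues + "-" * half
    cache: dict[str, np.ndarray] = {}
    cols = []
    for n in range(sequence.length):
        kmer = padded[n : n + _KMER]
        if kmer not in cache:
            cache[kmer] = _kmer_vector(kmer, dim, seed)
        cols.append(cache[kmer])
    return np.stack(cols, axis=1)


def _load_plm_adapter(name: str) -> Callable[[ProteinSequence, int], np.ndarray]:
    raise ConfigurationError(
        f"embedder '{name}' requires an external protein language model "
        "runtime; install its adapter package and register it via "
        "register_adapter()"
    )


_ADAPTERS: dict[str, Callable[[ProteinSequence, int], np.ndarray]] = {}


def register_adapter(
    name: str, fn: Callable[[ProteinSequence, int], np.ndarray]
) -> None:
    """Register an external embedder; ``fn(seq, dim) -> (dim, L) array``."""
    _ADAPTERS[name] = fn


def embed(
    sequence: ProteinSequence,
    spec: EmbedderSpec,
    labels: Sequence[DomainAnnotation] | None = None,
) -> EmbeddedSequence:
    """Embed one sequence according to ``spec``."""
    if sequence.length < 1:
        raise ValueError("cannot embed an empty sequence")
    if spec.name == "synthetic":
        matrix = synthetic_embed(sequence, spec.dim, spec.deterministic_seed)
    elif spec.name in _ADAPTERS:
        matrix = _ADAPTERS[spec.name](sequence, spec.dim)
    elif spec.name in ADAPTER_DIMS:
        if spec.dim != ADAPTER_DIMS[spec.name]:
            raise ConfigurationError(
                f"embedder '{spec.name}' has fixed dim {ADAPTER_DIMS[spec.name]}"
            )
        matrix = _load_plm_adapter(spec.name)(sequence, spec.dim)
    else:
        raise ConfigurationError(f"unknown embedder '{spec.name}'")
    if matrix.shape != (spec.dim, sequence.length):
        raise ValueError(
            f"embedder returned shape {matrix.shape}, "
            f"expected {(spec.dim, sequence.length)}"
        )
    return EmbeddedSequence(sequence.id, matrix, list(labels or []))


class EmbeddingStore:
    """Random-access HDF5 container: one dataset per sequence id.

    Matrices are retrievable by id without loading the whole store, which is
    what the window sampler needs during training.
    """

    def __init__(self, path: str | Path, mode: str = "r") -> None:
        self._h5 = h5py.File(str(path), mode)

    @classmethod
    def create(
        cls,
        path: str | Path,
        embedded: Sequence[EmbeddedSequence],
        embedder_name: str = "synthetic",
    ) -> "EmbeddingStore":
        ids = [e.id for e in embedded]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in embedding store input")
        dims = {e.dim for e in embedded}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dims: {sorted(dims)}")
        store = cls(path, "w")
        store._h5.attrs["embedder"] = embedder_name
        store._h5.attrs["dim"] = next(iter(dims)) if dims else 0
        for e in embedded:
            store._h5.create_dataset(e.id, data=e.matrix)
        store._h5.flush()
        return store

    @property
    def dim(self) -> int:
        return int(self._h5.attrs.get("dim", 0))

    @property
    def embedder_name(self) -> str:
        return str(self._h5.attrs.get("embedder", ""))

    def ids(self) -> list[str]:
        return list(self._h5.keys())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._h5

    def get(self, seq_id: str) -> np.ndarray:
        if seq_id not in self._h5:
            raise LookupKeyError(f"id '{seq_id}' not in embedding store")
        return np.asarray(self._h5[seq_id])

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "EmbeddingStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
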