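"""Window extraction from embedding tracks.

Training uses randomly sampled labelled windows; inference slides a window
with a discrete step along the whole protein.  Windows shorter than W (short
sequences, or the final flush-right window) are zero-padded on the right with
a mask so downstream pooling can ignore the padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedder import EmbeddedSequence


@dataclass(frozen=True)
class WindowSpec:
    """W = window length (residues), step = inference stride,
    N = windows sampled per sequence per training epoch."""

    W: int = 32
    step: int = 4
    N: int = 1

    def __post_init__(self) -> None:
        if self.W < 1 or self.step < 1 or self.N < 1:
            raise ValueError("W, step and N must all be >= 1")


@dataclass
class Window:
    """An E x W slice of a track with 0-based [nb, ne) coordinates.

    ``mask`` flags real (non-padded) columns; ``label`` is a class index for
    training windows and None at inference.  The centre is nb + floor(W/2).
    """

    sequence_id: str
    nb: int
    ne: int
    slice: np.ndarray  # (E, W)
    mask: np.ndarray  # (W,) of {0., 1.}
    label: int | None = None

    @property
    def nc(self) -> int:
        return self.nb + (self.ne - self.nb) // 2


def pad_window(slice_: np.ndarray, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad a narrow slice with zero columns to width W; return mask."""
    E, width = slice_.shape
    if width > W:
        raise ValueError(f"slice width {width} exceeds window length {W}")
    mask = np.zeros(W)
    mask[:width] = 1.0
    if width == W:
        return slice_, mask
    out = np.zeros((E, W))
    out[:, :width] = slice_
    return out, mask


def _make_window(
    emb: EmbeddedSequence, nb: int, W: int, label: int | None = None
) -> Window:
    L = emb.length
    raw = emb.matrix[:, nb : min(nb + W, L)]
    sl, mask = pad_window(raw, W)
    return Window(emb.id, nb, nb + W, sl, mask, label)


def slide_windows(emb: EmbeddedSequence, spec: WindowSpec) -> list[Window]:
    """Deterministic inference slide: starts 0, step, 2*step, ... while the
    window fits, plus a final flush-right window so the C-terminus is always
    covered.  A sequence shorter than W yields one padded window."""
    L, W = emb.length, spec.W
    if L < W:
        return [_make_window(emb, 0, W)]
    starts = list(range(0, L - W + 1, spec.step))
    if starts[-1] + W < L:
        starts.append(L - W)
    return [_make_window(emb, nb, W) for nb in starts]


def _domain_overlaps(emb: EmbeddedSequence, nb: int, W: int, L: int) -> list[int]:
    """Overlap in residues between window [nb, nb+W) and each annotated domain."""
    we = min(nb + W, L)
    out = []
    for d in emb.labels:
        ds, de = d.as_zero_based()
        out.append(max(0, min(we, de) - max(nb, ds)))
    return out


def valid_training_starts(
    emb: EmbeddedSequence, W: int
) -> tuple[list[int], list[int]]:
    """Enumerate window starts eligible for training and their labels.

    A start is eligible when the window overlaps some annotated domain by at
    least min(ceil(W/2), domain length) residues.  The label is the family of
    the maximal-overlap domain, ties broken by the leftmost domain.
    """
    if not emb.labels:
        raise ValueError(f"sequence '{emb.id}' has no domain annotation")
    L = emb.length
    starts = list(range(0, max(L - W, 0) + 1))
    fams = [d.family for d in emb.labels]
    dom_lens = [d.end - d.start + 1 for d in emb.labels]
    need = [min((W + 1) // 2, dl) for dl in dom_lens]
    ok_starts, labels = [], []
    for nb in starts:
        ov = _domain_overlaps(emb, nb, W, L)
        if not any(o >= n for o, n in zip(ov, need)):
            continue
        best = max(range(len(ov)), key=lambda j: (ov[j], -emb.labels[j].start))
        ok_starts.append(nb)
        labels.append(fams[best])
    return ok_starts, labels


def sample_training_windows(
    emb: EmbeddedSequence,
    spec: WindowSpec,
    rng: np.random.Generator,
    family_index: dict[str, int],
) -> list[Window]:
    """Draw N labelled windows uniformly from the eligible starts.

    Reproducible given the rng state.  Raises if the sequence carries no
    annotation (training requires labels).
    """
    starts, fams = valid_training_starts(emb, spec.W)
    if not starts:
        # every eligible placement failed (degenerate geometry); fall back to
        # the whole-sequence padded window labelled by the largest overlap
        starts, fams = [0], [emb.labels[0].family]
    picks = rng.integers(0, len(starts), size=spec.N)
    return [
        _make_window(emb, starts[p], spec.W, family_index[fams[p]]) for p in picks
    ]
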