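"""Low/high-motion split of a timeseries and motion-blocks permutation.

Each participant's frames are labelled LOW or HIGH by sorting on the FD
series: the lowest-motion half of the frames is LOW, the rest HIGH.  Runs of
consecutive same-label frames form "motion blocks"; the permutation null
reassigns whole blocks (never individual frames) to the two halves, which
preserves the weak temporal autocorrelation of BOLD data inside the null
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fc import EdgeVector, ParcelTimeseries, edges

LOW, HIGH = 0, 1


@dataclass
class SplitAssignment:
    """Per-frame LOW/HIGH labels plus the derived motion blocks.

    ``blocks`` is an ordered list of half-open frame ranges ``(start, end)``,
    each a maximal run of identically-labelled frames that does not cross a
    run boundary.
    """

    label: np.ndarray          # per frame, LOW or HIGH
    blocks: list[tuple[int, int]]
    permuted: bool = False

    @property
    def n_frames(self) -> int:
        return self.label.shape[0]

    def frames(self, which: int) -> np.ndarray:
        """Frame indices with the given label, in temporal order."""
        return np.flatnonzero(self.label == which)

    def block_labels(self) -> np.ndarray:
        return np.asarray([self.label[s] for s, _ in self.blocks])


@dataclass
class HalfSummary:
    edges_low: EdgeVector
    edges_high: EdgeVector
    fd_low: float
    fd_high: float
    n_low: int
    n_high: int


def _blocks_from_labels(label: np.ndarray, run_starts: list[int]) -> list[tuple[int, int]]:
    n = label.shape[0]
    boundary = np.zeros(n, dtype=bool)
    boundary[np.asarray(run_starts, dtype=int)] = True
    blocks: list[tuple[int, int]] = []
    start = 0
    for t in range(1, n):
        if label[t] != label[t - 1] or boundary[t]:
            blocks.append((start, t))
            start = t
    blocks.append((start, n))
    return blocks


def assign_halves(fd: np.ndarray, run_starts: list[int] | None = None) -> SplitAssignment:
    """Label the lowest-FD half of the frames LOW and the rest HIGH.

    Frames are stably sorted by FD (ties broken by temporal order, earlier
    frames going LOW first); with an odd frame count LOW receives the extra
    frame.  Blocks are maximal same-label runs broken at run boundaries.
    """
    fd = np.asarray(fd, dtype=float).ravel()
    n = fd.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames to split")
    if run_starts is None:
        run_starts = [0]
    order = np.argsort(fd, kind="stable")
    n_low = (n + 1) // 2
    label = np.full(n, HIGH, dtype=int)
    label[order[:n_low]] = LOW
    return SplitAssignment(
        label=label, blocks=_blocks_from_labels(label, run_starts), permuted=False
    )


def permute_assignment(assignment: SplitAssignment, seed) -> SplitAssignment:
    """Randomly reassign whole motion blocks to the two halves.

    Blocks are shuffled uniformly and dealt to one half until its frame count
    first reaches half the total; the remainder go to the other half.  A fair
    coin decides which half is labelled LOW.  The multiset of block lengths is
    unchanged by construction.
    """
    blocks = assignment.blocks
    if len(blocks) < 2:
        raise ValueError(
            "cannot permute a single-block assignment; the FD series has no "
            "low/high alternation (more frames or finer FD variation needed)"
        )
    rng = np.random.default_rng(seed)
    n = assignment.n_frames
    order = rng.permutation(len(blocks))
    label_a = LOW if rng.random() < 0.5 else HIGH
    label_b = HIGH if label_a == LOW else LOW
    new_label = np.empty(n, dtype=int)
    a_frames = 0
    b_blocks = 0
    for k, bi in enumerate(order):
        s, e = blocks[bi]
        last_and_b_empty = (k == len(order) - 1) and b_blocks == 0
        if a_frames < n / 2 and not last_and_b_empty:
            new_label[s:e] = label_a
            a_frames += e - s
        else:
            new_label[s:e] = label_b
            b_blocks += 1
    # block boundaries are inherited: the permutation relabels blocks but a
    # maximal-run recomputation could merge adjacent same-label blocks, which
    # would change the block-length multiset; keep the original partition.
    return SplitAssignment(label=new_label, blocks=list(blocks), permuted=True)


def summarize_half(ts: ParcelTimeseries, assignment: SplitAssignment) -> HalfSummary:
    """Edges and mean FD for each half of a split timeseries.

    Frames of each half are gathered preserving temporal order before the
    correlation (which is order-free but deterministic gathering keeps the
    computation auditable).
    """
    if assignment.n_frames != ts.n_frames:
        raise ValueError("assignment does not match timeseries frame count")
    idx_low = assignment.frames(LOW)
    idx_high = assignment.frames(HIGH)
    for name, idx in (("low", idx_low), ("high", idx_high)):
        if idx.size < 3:
            raise ValueError(f"{name}-motion half has {idx.size} frames; need >= 3")
    return HalfSummary(
        edges_low=edges(ts.data[:, idx_low]),
        edges_high=edges(ts.data[:, idx_high]),
        fd_low=float(ts.fd[idx_low].mean()),
        fd_high=float(ts.fd[idx_high].mean()),
        n_low=int(idx_low.size),
        n_high=int(idx_high.size),
    )
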