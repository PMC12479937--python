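"""Core functional-connectivity containers and edge computation.

A participant's parcellated BOLD data is held as a nodes x frames matrix with
an aligned framewise-displacement (FD) series in mm and the frame indices at
which separate fMRI runs begin.  Edges are the pairwise Pearson correlations
between node timeseries, Fisher-z (atanh) transformed so they can enter linear
models; the edge vector uses a fixed row-major upper-triangle ordering
(i < j, i ascending then j) so that files written by one tool can be read by
another without ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: correlations are clipped to +/- (1 - R_CLIP_EPS) before atanh so that
#: degenerate (perfectly correlated) node pairs stay finite.
R_CLIP_EPS = 1e-7

DEFAULT_TR = 0.8  # seconds per frame


@dataclass
class ParcelTimeseries:
    """Parcellated BOLD timeseries for one participant.

    Parameters
    ----------
    data : ndarray of shape (n_nodes, n_frames)
        BOLD signal, arbitrary units, one row per parcel/node.
    fd : ndarray of shape (n_frames,)
        Framewise displacement in mm, aligned to the frames of ``data``.
    run_starts : sequence of int
        0-based frame indices where runs begin; strictly increasing and
        starting at 0.  A single concatenated run is ``[0]``.
    tr : float
        Repetition time in seconds (default 0.8).
    """

    data: np.ndarray
    fd: np.ndarray
    run_starts: list[int] = field(default_factory=lambda: [0])
    tr: float = DEFAULT_TR

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float).ravel()
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D nodes x frames matrix")
        if self.fd.shape[0] != self.data.shape[1]:
            raise ValueError(
                f"FD length {self.fd.shape[0]} does not match "
                f"frame count {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)) or not np.all(np.isfinite(self.fd)):
            raise ValueError("non-finite values in timeseries or FD")
        rs = list(self.run_starts)
        if not rs or rs[0] != 0 or any(b <= a for a, b in zip(rs, rs[1:])):
            raise ValueError("run_starts must be strictly increasing and begin at 0")
        if rs[-1] >= max(self.n_frames, 1):
            raise ValueError("run start beyond end of data")
        self.run_starts = rs
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def take_frames(self, idx: np.ndarray) -> "ParcelTimeseries":
        """Return a copy restricted to frame indices ``idx`` (kept order).

        Run boundaries are remapped: a run survives if at least one of its
        frames is kept, and its new start is the position of its first kept
        frame in the output.
        """
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError("cannot take zero frames from a timeseries")
        bounds = np.asarray(self.run_starts + [self.n_frames])
        run_of = np.searchsorted(bounds, idx, side="right") - 1
        new_starts = [0]
        for k in range(1, idx.size):
            if run_of[k] != run_of[k - 1]:
                new_starts.append(k)
        return replace(
            self, data=self.data[:, idx], fd=self.fd[idx], run_starts=new_starts
        )


@dataclass
class EdgeVector:
    """Fisher-z connectivity edges in the fixed upper-triangle ordering."""

    z: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        if self.z.shape[0] != n_edges(self.n_nodes):
            raise ValueError(
                f"expected {n_edges(self.n_nodes)} edges for "
                f"{self.n_nodes} nodes, got {self.z.shape[0]}"
            )

    @property
    def r(self) -> np.ndarray:
        return np.tanh(self.z)

    def to_matrix(self) -> np.ndarray:
        """Symmetric node x node matrix of z values with unit diagonal in r."""
        m = vec_to_matrix(self.z, self.n_nodes)
        np.fill_diagonal(m, np.arctanh(1 - R_CLIP_EPS))
        return m


@dataclass
class CensorMask:
    keep: np.ndarray
    threshold: float

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.keep))


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def edge_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) node indices for each edge under the package ordering."""
    return np.triu_indices(n_nodes, k=1)


def matrix_to_vec(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    i, j = np.triu_indices(m.shape[0], k=1)
    return m[i, j]


def vec_to_matrix(v: np.ndarray, n_nodes: int) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    out = np.zeros((n_nodes, n_nodes))
    i, j = np.triu_indices(n_nodes, k=1)
    out[i, j] = v
    out[j, i] = v
    return out


def censor(ts: ParcelTimeseries, threshold: float) -> tuple[ParcelTimeseries, CensorMask]:
    """Drop frames whose FD meets or exceeds ``threshold`` (mm).

    A frame is kept iff ``fd < threshold`` (strict); ``threshold=np.inf``
    keeps everything.  Raises if no frame survives.
    """
    if not threshold > 0:
        raise ValueError("censoring threshold must be positive (or inf)")
    keep = ts.fd < threshold
    mask = CensorMask(keep=keep, threshold=float(threshold))
    if mask.n_kept == 0:
        raise ValueError(
            f"censoring at FD < {threshold} mm removed every frame"
        )
    if mask.n_kept == ts.n_frames:
        return ts, mask
    return ts.take_frames(np.flatnonzero(keep)), mask


def meets_minimum(ts: ParcelTimeseries, min_minutes: float = 8.0) -> bool:
    """True iff the series carries at least ``min_minutes`` of data."""
    return ts.n_frames * ts.tr >= min_minutes * 60.0


def clamp_frames(ts: ParcelTimeseries, max_frames: int = 600) -> ParcelTimeseries:
    """Keep only the earliest ``max_frames`` frames (temporal prefix)."""
    if max_frames < 1:
        raise ValueError("max_frames must be >= 1")
    if ts.n_frames <= max_frames:
        return ts
    return ts.take_frames(np.arange(max_frames))


def pearson_edges(data: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r over rows of ``data``, upper-triangle vector."""
    data = np.asarray(data, dtype=float)
    n_nodes, n_frames = data.shape
    if n_frames < 3:
        raise ValueError(f"need >= 3 frames to correlate, got {n_frames}")
    if n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    sd = data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance node(s): {bad.tolist()}")
    return matrix_to_vec(np.corrcoef(data))


def edges(ts: ParcelTimeseries | np.ndarray) -> EdgeVector:
    """Fisher-z edge vector of a timeseries.

    r is clipped to +/-(1 - 1e-7) before atanh; ordering is the fixed
    row-major upper triangle.
    """
    data = ts.data if isinstance(ts, ParcelTimeseries) else np.asarray(ts, float)
    r = pearson_edges(data)
    r = np.clip(r, -(1 - R_CLIP_EPS), 1 - R_CLIP_EPS)
    return EdgeVector(z=np.arctanh(r), n_nodes=data.shape[0])


def mean_fd(ts: ParcelTimeseries) -> float:
    """Arithmetic mean of the per-frame FD (mm) over current frames."""
    if ts.fd.size == 0:
        raise ValueError("empty FD series")
    return float(np.mean(ts.fd))
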