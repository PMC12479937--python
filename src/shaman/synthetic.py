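"""Generative simulator of motion-contaminated parcellated BOLD cohorts.

The model works backwards from the assumptions of the massively univariate
connectivity regression.  Two basis correlation matrices — a participant-stable
"BRAIN" pattern and a time-varying "MOTION" pattern — are Cholesky-factorised
and used to draw correlated Gaussian node timeseries.  Framewise displacement
is *defined* as the variance across nodes of the motion series at each frame,
so high-FD frames are exactly the frames where the motion pattern is most
strongly expressed.  Each participant's observed series mixes the two sources
as

    mixed = sqrt(w_brain) * brain + sqrt(w_motion) * motion_unit

with w_brain equal to the participant's (all-positive) trait value and
w_motion equal to the participant's mean FD, after which every node is
rescaled to unit sample variance.

Because edges are correlations, the motion pattern's expression at an edge is
the *share* w_motion / (w_brain + w_motion), so the amount of motion artifact
visible in a participant's connectivity — and the difference between their
high- and low-motion halves — depends on the trait value itself.  The default
cohort therefore carries a genuine trait-specific motion impact (the planted
signal the split-half analysis should detect).  ``null_trait`` replaces the
analysis trait with an independent draw (a randomly assigned pseudo-trait,
like analysing participant ID), which is the ground-truth null for
specificity and type-I calibration.  ``trait_motion_coupling`` optionally
adds a quadratic link from the trait to the per-participant motion variance
(a proportional link would cancel exactly in the correlation normalisation
and plant nothing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fc import ParcelTimeseries

#: worked mixing weights: brain (trait) 1.6329, motion (mean FD) 0.2216.
EXAMPLE_WEIGHTS = (1.6329, 0.2216)

#: default mean motion variance (mm FD scale) when no coupling target given.
DEFAULT_MOTION_LEVEL = 0.2216

_PD_SHRINK = 0.95
_PD_MAX_ITER = 200


@dataclass
class BasisPattern:
    """A positive-definite target correlation matrix with a name."""

    values: np.ndarray
    name: str = "CUSTOM"
    shrinkage_iterations: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("basis must be square")
        if not np.allclose(v, v.T):
            raise ValueError("basis must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("basis must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("basis entries must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.values)

    def offdiag_mask(self) -> np.ndarray:
        """Boolean upper-triangle vector marking the lit (nonzero) edges."""
        from .fc import matrix_to_vec

        return matrix_to_vec(self.values) != 0


@dataclass
class MixingDesign:
    """Per-participant design columns and mixing weights."""

    w_brain: np.ndarray
    w_motion: np.ndarray
    trait: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.w_brain = np.asarray(self.w_brain, dtype=float)
        self.w_motion = np.asarray(self.w_motion, dtype=float)
        self.trait = np.asarray(self.trait, dtype=float)
        n = self.trait.shape[0]
        if self.w_brain.shape[0] != n or self.w_motion.shape[0] != n:
            raise ValueError("design column lengths differ")
        if np.any(self.w_brain < 0) or np.any(self.w_motion < 0):
            raise ValueError("variance weights must be non-negative")
        if np.any(self.trait <= 0):
            raise ValueError("trait values must be positive after shifting")


@dataclass
class CohortConfig:
    n_nodes: int = 64
    n_frames: int = 512
    n_participants: int = 256
    peak: float = 0.3
    trait_motion_coupling: float = 0.0
    motion_level: float = DEFAULT_MOTION_LEVEL
    motion_scale_sigma: float = 0.5
    null_trait: bool = False
    seed: int | None = None
    full_scale: bool = False  # 394 x 1024 x 1024 study-scale dimensions

    def resolved(self) -> "CohortConfig":
        if self.full_scale:
            return CohortConfig(
                n_nodes=394, n_frames=1024, n_participants=1024,
                peak=self.peak, trait_motion_coupling=self.trait_motion_coupling,
                motion_level=self.motion_level,
                motion_scale_sigma=self.motion_scale_sigma,
                null_trait=self.null_trait,
                seed=self.seed, full_scale=True,
            )
        return self


@dataclass
class SyntheticCohort:
    participants: list[ParcelTimeseries]
    design: MixingDesign
    basis_brain: BasisPattern
    basis_motion: BasisPattern
    config: CohortConfig = field(default_factory=CohortConfig)

    @property
    def trait(self) -> np.ndarray:
        return self.design.trait


def build_basis(
    pattern: np.ndarray,
    peak: float = 0.3,
    ridge_step: float = _PD_SHRINK,
    name: str = "CUSTOM",
) -> BasisPattern:
    """Scale a binary/real symmetric pattern into a PD correlation matrix.

    Off-diagonal entries are ``peak * pattern`` (the pattern is symmetrised as
    the elementwise max of itself and its transpose), the diagonal is 1.  If
    the result is not positive definite the off-diagonals are repeatedly
    multiplied by ``ridge_step`` until a Cholesky factorisation succeeds; the
    number of shrink iterations applied is recorded on the result.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.ndim != 2 or pattern.shape[0] != pattern.shape[1]:
        raise ValueError("pattern must be square")
    if not 0 < peak < 1:
        raise ValueError("peak must lie in (0, 1)")
    if not 0 < ridge_step < 1:
        raise ValueError("ridge_step must lie in (0, 1)")
    sym = np.maximum(pattern, pattern.T)
    mat = peak * sym
    np.fill_diagonal(mat, 1.0)
    iters = 0
    while True:
        try:
            np.linalg.cholesky(mat)
            break
        except np.linalg.LinAlgError:
            iters += 1
            if iters > _PD_MAX_ITER:
                raise ValueError(
                    "failed to reach positive definiteness within "
                    f"{_PD_MAX_ITER} shrink iterations"
                )
            off = mat - np.diag(np.diag(mat))
            mat = off * ridge_step
            np.fill_diagonal(mat, 1.0)
    return BasisPattern(values=mat, name=name, shrinkage_iterations=iters)


def text_block_patterns(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint structured off-diagonal masks for BRAIN and MOTION.

    Stylised stand-ins for pattern bitmaps, built from equicorrelated
    communities (which stay positive definite at any peak below 1, so
    neither source is weakened by PD shrinkage): BRAIN lights the edges
    inside the first third of the nodes, MOTION lights two disjoint
    communities covering the remaining two thirds.  The masks are
    edge-disjoint so the two sources occupy distinct parts of the
    connectivity matrix.
    """
    if n_nodes < 6:
        raise ValueError("need at least 6 nodes for the default patterns")
    brain = np.zeros((n_nodes, n_nodes))
    motion = np.zeros((n_nodes, n_nodes))
    third = n_nodes // 3
    mid = third + (n_nodes - third) // 2
    brain[:third, :third] = 1.0
    motion[third:mid, third:mid] = 1.0
    motion[mid:, mid:] = 1.0
    np.fill_diagonal(brain, 0.0)
    np.fill_diagonal(motion, 0.0)
    return brain, motion


def default_bases(n_nodes: int, peak: float = 0.3) -> tuple[BasisPattern, BasisPattern]:
    b, m = text_block_patterns(n_nodes)
    return (
        build_basis(b, peak=peak, name="BRAIN"),
        build_basis(m, peak=peak, name="MOTION"),
    )


def draw_correlated_series(basis: BasisPattern, n_frames: int, seed) -> np.ndarray:
    """Nodes x frames Gaussian series with target correlation ``basis``.

    White standard-normal draws are premultiplied by the Cholesky factor of
    the basis correlation matrix, so each node is unit-variance in expectation
    and the empirical node correlation converges to the basis as the frame
    count grows.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((basis.n_nodes, n_frames))
    return basis.cholesky() @ white


def fd_from_series(motion_series: np.ndarray) -> np.ndarray:
    """FD series defined as the across-node variance at each frame.

    Population convention (divide by n_nodes); non-negative everywhere and
    zero exactly when all nodes agree at a frame.
    """
    motion_series = np.asarray(motion_series, dtype=float)
    if motion_series.ndim != 2 or motion_series.shape[0] < 2:
        raise ValueError("need a nodes x frames matrix with >= 2 nodes")
    return motion_series.var(axis=0, ddof=0)


def mix_series(
    brain: np.ndarray,
    motion: np.ndarray,
    w_brain: float,
    w_motion: float,
    variance_correct: bool = True,
) -> np.ndarray:
    """Mix brain and motion series by their design variance weights.

    ``mixed = sqrt(w_brain)*brain + sqrt(w_motion)*motion``; with independent
    unit-variance inputs the pre-correction variance is w_brain + w_motion.
    When ``variance_correct`` is set, each node of the mixed series is then
    rescaled to unit sample variance so the downstream correlation-matrix
    regressions see comparably scaled participants.
    """
    brain = np.asarray(brain, dtype=float)
    motion = np.asarray(motion, dtype=float)
    if brain.shape != motion.shape:
        raise ValueError("brain and motion series shapes differ")
    if w_brain < 0 or w_motion < 0:
        raise ValueError("mixing weights must be non-negative")
    mixed = np.sqrt(w_brain) * brain + np.sqrt(w_motion) * motion
    if variance_correct:
        sd = mixed.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        mixed = mixed / sd
    return mixed


def _positive_shift(x: np.ndarray, eps: float = 0.01) -> np.ndarray:
    """Shift a vector so that every entry is strictly positive."""
    lo = x.min()
    if lo > 0:
        return x
    return x - lo + eps


def generate_cohort(
    config: CohortConfig | None = None,
    basis_brain: BasisPattern | None = None,
    basis_motion: BasisPattern | None = None,
    zero_motion: bool = False,
    **overrides,
) -> SyntheticCohort:
    """Simulate a cohort with known trait and motion ground truth.

    Per participant: draw a brain series from the BRAIN basis and a motion
    series from the MOTION basis; scale the motion series by a per-participant
    motion scale (independent of, or coupled to, the brain column according to
    ``config.trait_motion_coupling``); define FD as the per-frame cross-node
    variance of the scaled motion series; mix with weights
    ``w_brain`` (the all-positive brain design column) and
    ``w_motion = mean FD``; variance-correct each node to unit variance.

    The coupling link is quadratic (motion variance proportional to the
    squared brain column): because edge correlations normalise out any
    proportional scaling of the two variance weights, a proportional link
    would cancel exactly and plant nothing.

    ``config.null_trait`` makes the returned analysis trait an independent
    draw (a randomly assigned pseudo-trait, like using participant ID),
    statistically unrelated to every series and FD value — the ground-truth
    null for specificity and type-I calibration.  Otherwise the analysis
    trait is the brain design column itself.

    ``zero_motion`` overrides the mixing so motion contributes nothing and the
    FD series is identically zero (null-motion cohort).
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    config = config.resolved()
    if config.n_participants < 2:
        raise ValueError("need at least 2 participants")
    if config.seed is None:
        raise ValueError("a seed is required for a reproducible cohort")
    if not 0 <= config.trait_motion_coupling <= 1:
        raise ValueError("trait_motion_coupling must lie in [0, 1]")
    if basis_brain is None or basis_motion is None:
        bb, bm = default_bases(config.n_nodes, peak=config.peak)
        basis_brain = basis_brain or bb
        basis_motion = basis_motion or bm
    if basis_brain.n_nodes != config.n_nodes or basis_motion.n_nodes != config.n_nodes:
        raise ValueError("basis dimension does not match n_nodes")

    root = np.random.SeedSequence(config.seed)
    ss_trait, ss_scale, ss_series, ss_null = root.spawn(4)
    rng_trait = np.random.default_rng(ss_trait)
    rng_scale = np.random.default_rng(ss_scale)

    n = config.n_participants
    brain_col = _positive_shift(rng_trait.standard_normal(n))
    # per-participant motion variance scale: constant by default (the
    # cohort's FD differences then come only from within-scan fluctuation),
    # optionally lognormal-heterogeneous and/or quadratically coupled to the
    # brain column
    lam = config.trait_motion_coupling
    if config.motion_scale_sigma > 0:
        indep = rng_scale.lognormal(mean=0.0, sigma=config.motion_scale_sigma,
                                    size=n)
        indep = indep / indep.mean()
    else:
        indep = np.ones(n)
    coupled = brain_col**2 / np.mean(brain_col**2)
    scale2 = config.motion_level * ((1 - lam) * indep + lam * coupled)
    if config.null_trait:
        trait = _positive_shift(
            np.random.default_rng(ss_null).standard_normal(n)
        )
    else:
        trait = brain_col

    Lb = basis_brain.cholesky()
    Lm = basis_motion.cholesky()
    child = ss_series.spawn(n)
    participants: list[ParcelTimeseries] = []
    w_brain = np.empty(n)
    w_motion = np.empty(n)
    for i in range(n):
        rng = np.random.default_rng(child[i])
        brain = Lb @ rng.standard_normal((config.n_nodes, config.n_frames))
        motion_unit = Lm @ rng.standard_normal((config.n_nodes, config.n_frames))
        if zero_motion:
            fd = np.zeros(config.n_frames)
            w_b, w_m = float(brain_col[i]), 0.0
        else:
            motion_scaled = np.sqrt(scale2[i]) * motion_unit
            fd = fd_from_series(motion_scaled)
            w_b, w_m = float(brain_col[i]), float(fd.mean())
        mixed = mix_series(brain, motion_unit, w_b, w_m)
        participants.append(ParcelTimeseries(data=mixed, fd=fd, run_starts=[0]))
        w_brain[i], w_motion[i] = w_b, w_m

    design = MixingDesign(
        w_brain=w_brain, w_motion=w_motion, trait=trait, seed=config.seed
    )
    return SyntheticCohort(
        participants=participants,
        design=design,
        basis_brain=basis_brain,
        basis_motion=basis_motion,
        config=config,
    )
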