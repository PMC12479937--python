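"""Motion impact score: split-half residual regression with permutation NPC.

Pipeline (per trait): split every participant's timeseries into low/high
motion halves, regress each half's Fisher-z edges on the half's mean FD
across participants, difference the residuals (high - low), and regress the
trait against the difference at every edge.  Because traits are stable over a
scan, the per-edge trait coefficient is null unless residual motion distorts
the trait-FC effect.  Inference is by motion-blocks permutation: the same
pipeline is repeated with random block splits, and the per-edge t-values are
fused across edges with Stouffer's combining (non-parametric combining, each
edge its own "modality") into one omnibus Z — the motion impact score — with
a family-wise-error-controlled permutation p-value.  Directional variants
count only edges whose motion impact shares (overestimation) or opposes
(underestimation) the sign of the trait-FC effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .fc import ParcelTimeseries, edges, mean_fd, n_edges
from .split import HalfSummary, assign_halves, permute_assignment, summarize_half
from .traitqc import trait_fc

__all__ = [
    "TraitModel",
    "ImpactMap",
    "NullEnsemble",
    "MotionImpactResult",
    "MotionImpactScore",
    "residual_difference",
    "impact_glm",
    "npc_stouffer",
    "stouffer_z",
    "directional_scores",
    "run_shaman",
    "power_analysis",
]


@dataclass
class TraitModel:
    """Trait of interest plus optional covariates, one row per participant."""

    trait: np.ndarray
    covariates: np.ndarray | None = None
    participant_ids: list | None = None

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float).ravel()
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != self.trait.shape[0]:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != self.trait.shape[0]:
                raise ValueError("covariate rows do not match trait length")
        if not np.all(np.isfinite(self.trait)):
            raise ValueError("missing values in trait; apply listwise exclusion first")

    @property
    def n(self) -> int:
        return self.trait.shape[0]


@dataclass
class ImpactMap:
    """Per-edge trait coefficient on the residual difference, with t-values."""

    beta: np.ndarray
    t: np.ndarray
    df: int


@dataclass
class NullEnsemble:
    """P x E matrix of per-edge t-values from block-permuted splits."""

    stats: np.ndarray
    seeds: list | None = None

    @property
    def n_perm(self) -> int:
        return self.stats.shape[0]


@dataclass
class MotionImpactResult:
    omnibus_z: float
    omnibus_p: float
    over_z: float
    over_p: float
    under_z: float
    under_p: float
    edge_z: np.ndarray
    impact: ImpactMap
    trait_fc_t: np.ndarray
    null: NullEnsemble
    null_edge_z: np.ndarray
    alpha: float = 0.05
    gate: float = 2.0
    seed: int | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# vectorised OLS primitives (shared design, many response columns)
# ---------------------------------------------------------------------------

def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of every column of Y on the shared design X."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant regressor?)")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


def _ols_t(Y: np.ndarray, X: np.ndarray, col: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Coefficient and t-value of design column ``col`` for every Y column."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than regressors ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[col, col], 0.0))
    b = beta[col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    return b, t, df


def residual_difference(halves: list[HalfSummary]) -> np.ndarray:
    """Participant x edge matrix of split-half residual differences.

    For each edge, the low-half edges are regressed (across participants) on
    an intercept and the low-half mean FD; likewise the high half on the
    high-half mean FD; the returned matrix is residual_high - residual_low.
    """
    if len(halves) < 3:
        raise ValueError("need at least 3 participants")
    Ylow = np.stack([h.edges_low.z for h in halves])
    Yhigh = np.stack([h.edges_high.z for h in halves])
    fd_low = np.array([h.fd_low for h in halves])
    fd_high = np.array([h.fd_high for h in halves])
    n = len(halves)
    ones = np.ones(n)
    r_low = _residualize(Ylow, np.column_stack([ones, fd_low]))
    r_high = _residualize(Yhigh, np.column_stack([ones, fd_high]))
    return r_high - r_low


def impact_glm(diff: np.ndarray, model: TraitModel) -> ImpactMap:
    """Regress the trait against the residual difference at every edge."""
    diff = np.asarray(diff, dtype=float)
    if diff.shape[0] != model.n:
        raise ValueError("participant count mismatch between diff and model")
    cols = [np.ones(model.n), model.trait]
    if model.covariates is not None:
        cols.extend(model.covariates.T)
    X = np.column_stack(cols)
    beta, t, df = _ols_t(diff, X, col=1)
    return ImpactMap(beta=beta, t=t, df=df)


# ---------------------------------------------------------------------------
# non-parametric combining
# ---------------------------------------------------------------------------

def stouffer_z(z: np.ndarray) -> float:
    """Stouffer's combined Z of a vector of z-values: sum(z) / sqrt(E)."""
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("cannot combine an empty z-vector")
    return float(z.sum() / np.sqrt(z.size))


def _directional_stat(t: np.ndarray, direction) -> np.ndarray:
    """Orient a t array so that larger always means more extreme."""
    if isinstance(direction, str):
        if direction != "two_sided":
            raise ValueError(f"unknown direction {direction!r}")
        return np.abs(t)
    sign = np.asarray(direction, dtype=float)
    return sign * t


def _edge_p_to_z(p: np.ndarray, n_perm: int) -> np.ndarray:
    # p can hit 1 when a value is the ensemble minimum; clip away from both
    # ends at half the permutation resolution so Phi^-1 stays finite.
    lo = 0.5 / (n_perm + 1)
    return stats.norm.isf(np.clip(p, lo, 1 - lo))


def npc_stouffer(
    observed: ImpactMap | np.ndarray,
    null: NullEnsemble | np.ndarray,
    direction="two_sided",
    include: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Stouffer non-parametric combining of per-edge permutation p-values.

    Per edge, the observed statistic gets an add-one empirical p against the
    null ensemble (one-sided in ``direction``, or on |t|), mapped to
    ``z = Phi^-1(1 - p)``.  The combined score is ``Z = sum(z) / sqrt(E)``
    over the included edges.  Each permutation is then ranked against the
    same ensemble by the identical two-pass recipe, and the omnibus p is
    ``(1 + #{Z_perm >= Z_obs}) / (1 + P)``.

    Returns ``(Z, p, edge_z, null_edge_z)`` where ``null_edge_z`` is the
    P x E matrix of per-permutation edge z-values (reused for node-level
    recombination).
    """
    t_obs = observed.t if isinstance(observed, ImpactMap) else np.asarray(observed, float)
    t_null = null.stats if isinstance(null, NullEnsemble) else np.asarray(null, float)
    if t_null.ndim != 2 or t_null.shape[1] != t_obs.shape[0]:
        raise ValueError("null ensemble edge count does not match observed")
    P, E = t_null.shape
    s_obs = _directional_stat(t_obs, direction)
    s_null = _directional_stat(t_null, direction)

    p_obs = (1 + np.sum(s_null >= s_obs[None, :], axis=0)) / (P + 1)
    edge_z = _edge_p_to_z(p_obs, P)
    # rank of each permutation within the ensemble: count of values >= own
    counts = stats.rankdata(-s_null, axis=0, method="max")
    null_edge_z = _edge_p_to_z(counts / (P + 1), P)

    if include is None:
        include = np.ones(E, dtype=bool)
    include = np.asarray(include, dtype=bool)
    k = int(include.sum())
    if k == 0:
        warnings.warn("empty edge set in combining; returning Z=0, p=1")
        return 0.0, 1.0, edge_z, null_edge_z
    Z = stouffer_z(edge_z[include])
    Z_perm = null_edge_z[:, include].sum(axis=1) / np.sqrt(k)
    p = float((1 + np.sum(Z_perm >= Z)) / (P + 1))
    return Z, p, edge_z, null_edge_z


def directional_scores(
    impact: ImpactMap,
    trait_fc_t: np.ndarray,
    null: NullEnsemble,
    gate: float = 2.0,
) -> tuple[float, float, float, float]:
    """Motion over- and underestimation scores.

    Edges whose trait-FC |t| does not exceed ``gate`` are ignored (the sign of
    the trait-FC effect there is uncertain).  Among the rest, edges where the
    motion impact shares the trait-FC sign form the overestimation set and
    are combined one-sided in the trait-FC direction; edges of opposite sign
    form the underestimation set, combined one-sided against the trait-FC
    direction.  The two sets are disjoint by construction.
    """
    trait_fc_t = np.asarray(trait_fc_t, dtype=float)
    if trait_fc_t.shape[0] != impact.t.shape[0]:
        raise ValueError("trait-FC t length does not match edge count")
    certain = np.abs(trait_fc_t) > gate
    sign = np.sign(trait_fc_t)
    over = _selective_directional(impact.t, null.stats, sign, certain, flip=1)
    under = _selective_directional(impact.t, null.stats, sign, certain, flip=-1)
    return over[0], over[1], under[0], under[1]


def _selective_directional(t_obs: np.ndarray, t_null: np.ndarray,
                           sign: np.ndarray, certain: np.ndarray,
                           flip: int) -> tuple[float, float]:
    """One directional score with row-wise sign selection.

    The edge set is *data-dependent* (edges whose impact t agrees with
    ``flip * sign``), so to keep the permutation comparison fair the same
    selection rule is applied to every permutation row: each row combines
    the one-sided edge z-values over its own agreement set.  Combining a
    fixed observed-selected set would build in a selection bias and reject
    far too often under the null.
    """
    P = t_null.shape[0]
    direction = flip * sign
    s_obs = direction * t_obs
    s_null = direction * t_null
    p_obs = (1 + np.sum(s_null >= s_obs[None, :], axis=0)) / (P + 1)
    z_obs = _edge_p_to_z(p_obs, P)
    counts = stats.rankdata(-s_null, axis=0, method="max")
    z_null = _edge_p_to_z(counts / (P + 1), P)

    if not certain.any():
        warnings.warn("all edges gated; directional score Z=0, p=1")
        return 0.0, 1.0
    sel_obs = certain & (np.sign(t_obs) == direction)
    k_obs = int(sel_obs.sum())
    Z_obs = float(z_obs[sel_obs].sum() / np.sqrt(k_obs)) if k_obs else 0.0
    sel_null = certain[None, :] & (np.sign(t_null) == direction[None, :])
    k_null = sel_null.sum(axis=1)
    Z_null = np.where(
        k_null > 0,
        (z_null * sel_null).sum(axis=1) / np.sqrt(np.maximum(k_null, 1)),
        0.0,
    )
    p = float((1 + np.sum(Z_null >= Z_obs)) / (P + 1))
    return Z_obs, p


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _observed_halves(dataset: list[ParcelTimeseries]) -> tuple[list[HalfSummary], list]:
    assignments = [assign_halves(ts.fd, ts.run_starts) for ts in dataset]
    halves = [summarize_half(ts, a) for ts, a in zip(dataset, assignments)]
    return halves, assignments


class MotionImpactScore(BaseEstimator):
    """Trait-specific motion impact estimator (split-half permutation test).

    Parameters
    ----------
    n_perm : int
        Number of motion-blocks permutations forming the null (the smallest
        attainable omnibus p is ``1/(n_perm+1)``).
    alpha : float
        Significance level reported alongside the scores.
    gate : float
        |t| threshold on the trait-FC effect below which an edge's sign is
        treated as unknown and excluded from the directional scores.
    random_state : int or None
        Master seed; per-permutation and per-participant streams are spawned
        from it, so results do not depend on execution order.

    Attributes (after ``fit``)
    --------------------------
    omnibus_z_, omnibus_p_ : float
        Whole-matrix motion impact score and its permutation p-value.
    over_z_, over_p_, under_z_, under_p_ : float
        Motion over-/underestimation scores.
    edge_z_ : ndarray (E,)
        Per-edge z-values entering the omnibus combination.
    impact_ : ImpactMap
        Per-edge trait coefficients and t-values on the residual difference.
    result_ : MotionImpactResult
        The full result object.
    """

    def __init__(self, n_perm: int = 1000, alpha: float = 0.05,
                 gate: float = 2.0, random_state: int | None = None):
        self.n_perm = n_perm
        self.alpha = alpha
        self.gate = gate
        self.random_state = random_state

    def fit(self, X: list[ParcelTimeseries], y, covariates=None, trait_fc_t=None):
        """Fit the motion impact score on a cohort.

        Parameters
        ----------
        X : list of ParcelTimeseries
            One entry per participant (already censored/clamped as desired).
        y : array-like
            Trait values, one per participant.
        covariates : array-like, optional
            Additional participant-level covariates for the impact
            regression.
        trait_fc_t : array-like, optional
            Per-edge trait-FC t-values for the directional gating; computed
            from the full-data edges (trait + mean FD model) when omitted.
        """
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        model = TraitModel(trait=np.asarray(y, float), covariates=covariates)
        if len(X) != model.n:
            raise ValueError("participant count mismatch between data and trait")
        result = run_shaman(
            X, model, n_perm=self.n_perm, alpha=self.alpha, gate=self.gate,
            seed=self.random_state, trait_fc_t=trait_fc_t,
        )
        self.result_ = result
        self.omnibus_z_ = result.omnibus_z
        self.omnibus_p_ = result.omnibus_p
        self.over_z_ = result.over_z
        self.over_p_ = result.over_p
        self.under_z_ = result.under_z
        self.under_p_ = result.under_p
        self.edge_z_ = result.edge_z
        self.impact_ = result.impact
        self.n_features_in_ = result.edge_z.shape[0]
        return self

    def significant_(self) -> bool:
        return self.omnibus_p_ < self.alpha


def run_shaman(
    dataset: list[ParcelTimeseries],
    model: TraitModel,
    n_perm: int = 1000,
    alpha: float = 0.05,
    gate: float = 2.0,
    seed: int | None = None,
    trait_fc_t: np.ndarray | None = None,
) -> MotionImpactResult:
    """Full split-half motion impact analysis for one trait.

    Orchestrates the observed FD-sorted split, the residual-difference trait
    regression, ``n_perm`` motion-blocks permutations for the null, and the
    Stouffer combination into omnibus and directional scores.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_part = len(dataset)
    if n_part != model.n:
        raise ValueError("participant count mismatch")
    n_nodes = dataset[0].n_nodes
    if any(ts.n_nodes != n_nodes for ts in dataset):
        raise ValueError("all participants must share n_nodes")

    halves, assignments = _observed_halves(dataset)
    diff = residual_difference(halves)
    impact = impact_glm(diff, model)

    if trait_fc_t is None:
        full_edges = np.stack([edges(ts).z for ts in dataset])
        fds = np.array([mean_fd(ts) for ts in dataset])
        fc_effect = trait_fc(full_edges, model.trait, covariates=fds.reshape(-1, 1))
        trait_fc_t = fc_effect.t
    trait_fc_t = np.asarray(trait_fc_t, dtype=float)

    root = np.random.SeedSequence(seed)
    perm_seqs = root.spawn(n_perm)
    E = n_edges(n_nodes)
    null_t = np.empty((n_perm, E))
    for j, seq in enumerate(perm_seqs):
        part_seqs = seq.spawn(n_part)
        perm_halves = [
            summarize_half(ts, permute_assignment(a, ps))
            for ts, a, ps in zip(dataset, assignments, part_seqs)
        ]
        null_t[j] = impact_glm(residual_difference(perm_halves), model).t
    null = NullEnsemble(stats=null_t, seeds=[seed])

    omni_z, omni_p, edge_z, null_edge_z = npc_stouffer(impact, null, "two_sided")
    over_z, over_p, under_z, under_p = directional_scores(
        impact, trait_fc_t, null, gate=gate
    )
    return MotionImpactResult(
        omnibus_z=omni_z, omnibus_p=omni_p,
        over_z=over_z, over_p=over_p, under_z=under_z, under_p=under_p,
        edge_z=edge_z, impact=impact, trait_fc_t=trait_fc_t,
        null=null, null_edge_z=null_edge_z,
        alpha=alpha, gate=gate, seed=seed,
    )


def power_analysis(
    generator,
    sizes: list[int],
    reps: int = 20,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
    score: str = "omnibus",
) -> dict[int, float]:
    """Detection rate of the motion impact score at each sample size.

    ``generator(n, seed)`` must return ``(dataset, TraitModel)``.  For each
    size, ``reps`` independent cohorts are generated and analysed; the rate
    is the fraction whose selected score is significant at ``alpha``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(n < 1 for n in sizes):
        raise ValueError("sizes must be positive")
    root = np.random.SeedSequence(seed)
    rates: dict[int, float] = {}
    for n in sizes:
        hits = 0
        for seq in root.spawn(reps):
            s_gen, s_run = seq.spawn(2)
            dataset, model = generator(n, s_gen)
            res = run_shaman(dataset, model, n_perm=n_perm, alpha=alpha,
                             seed=int(s_run.generate_state(1)[0] % (2**31)))
            p = {"omnibus": res.omnibus_p, "over": res.over_p,
                 "under": res.under_p}[score]
            hits += p < alpha
        rates[n] = hits / reps
    return rates
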