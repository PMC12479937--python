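"""Companion edgewise-regression and quality-control analyses.

Covers the conventional mass-univariate trait-FC and motion-FC regressions
(one OLS per edge, shared design across participants), effect-size summaries
(t-to-r conversion and percentiles of |r|), trait-motion correlations,
edge-for-edge matrix similarity, and the log-log Spearman metric for how much
signal variance a denoising step leaves related to motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _perms

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class EffectMatrix:
    """Per-edge OLS results for one predictor of interest."""

    beta: np.ndarray
    t: np.ndarray
    df: int
    predictor: str = "trait"
    covariates: tuple[str, ...] = ()

    @property
    def r_effect(self) -> np.ndarray:
        """Effect size as a (partial) correlation, r = t / sqrt(t^2 + df)."""
        return self.t / np.sqrt(self.t**2 + self.df)

    @property
    def model(self) -> str:
        rhs = " + ".join(["1", self.predictor, *self.covariates])
        return f"FC ~ {rhs}"


@dataclass
class VarianceAssessment:
    rho_before: float
    rho_after: float

    @property
    def var_explained_before(self) -> float:
        return self.rho_before**2

    @property
    def var_explained_after(self) -> float:
        return self.rho_after**2

    @property
    def relative_reduction(self) -> float:
        return 1 - (self.rho_after / self.rho_before) ** 2


class EdgewiseOLS(BaseEstimator):
    """Massively univariate OLS of edges on a shared participant design.

    ``fit(X, Y)`` takes a design matrix ``X`` of shape (n_participants,
    n_regressors) — without intercept, which is always added — and an edge
    table ``Y`` of shape (n_participants, E).  The coefficient and t-value of
    the column selected by ``predictor_col`` are exposed per edge.
    """

    def __init__(self, predictor_col: int = 0, predictor_name: str = "trait",
                 covariate_names: tuple[str, ...] = ()):
        self.predictor_col = predictor_col
        self.predictor_name = predictor_name
        self.covariate_names = covariate_names

    def fit(self, X, Y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1:
            X = X.T
        Y = np.asarray(Y, dtype=float)
        n, k = X.shape
        if Y.shape[0] != n:
            raise ValueError("design and edge-table participant counts differ")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
            raise ValueError("missing values; apply listwise exclusion upstream")
        design = np.column_stack([np.ones(n), X])
        p = design.shape[1]
        if n <= p:
            raise ValueError(f"need > {p} participants for {p} regressors")
        if np.linalg.matrix_rank(design) < p:
            raise ValueError("rank-deficient design (constant predictor?)")
        xtx_inv = np.linalg.inv(design.T @ design)
        beta_all = xtx_inv @ (design.T @ Y)
        resid = Y - design @ beta_all
        df = n - p
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        col = self.predictor_col + 1  # account for intercept
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[col, col], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta_all[col] / se, 0.0)
        self.beta_ = beta_all[col]
        self.t_ = t
        self.df_ = df
        self.n_features_in_ = k
        self.effect_ = EffectMatrix(
            beta=self.beta_, t=self.t_, df=df,
            predictor=self.predictor_name, covariates=self.covariate_names,
        )
        return self


def trait_fc(edge_table: np.ndarray, trait: np.ndarray,
             covariates: np.ndarray | None = None,
             trait_name: str = "trait",
             covariate_names: tuple[str, ...] = ("FD",)) -> EffectMatrix:
    """Edgewise trait-FC effect: OLS of each edge on (1, trait, covariates)."""
    trait = np.asarray(trait, dtype=float).ravel()
    if covariates is None:
        X = trait.reshape(-1, 1)
        names: tuple[str, ...] = ()
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != trait.shape[0]:
            covariates = covariates.T
        X = np.column_stack([trait, covariates])
        names = covariate_names[: covariates.shape[1]]
    est = EdgewiseOLS(predictor_col=0, predictor_name=trait_name,
                      covariate_names=names).fit(X, edge_table)
    return est.effect_


def motion_fc(edge_table: np.ndarray, mean_fd: np.ndarray) -> EffectMatrix:
    """Motion-FC effect matrix: FC ~ 1 + FD, beta in Fisher-z per mm FD."""
    mean_fd = np.asarray(mean_fd, dtype=float).ravel()
    if np.ptp(mean_fd) == 0:
        raise ValueError("mean FD is constant across participants")
    est = EdgewiseOLS(predictor_col=0, predictor_name="FD",
                      covariate_names=()).fit(mean_fd.reshape(-1, 1), edge_table)
    return est.effect_


def effect_percentile(effect: EffectMatrix | np.ndarray, q: float = 98) -> float:
    """q-th percentile of |r_effect| across edges (linear interpolation)."""
    if not 0 < q <= 100:
        raise ValueError("q must lie in (0, 100]")
    r = effect.r_effect if isinstance(effect, EffectMatrix) else np.asarray(effect)
    if r.size == 0:
        raise ValueError("no edges")
    return float(np.percentile(np.abs(r), q))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho at tiny n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    all_perms = np.array(list(_perms(range(n))))
    permuted = ry[all_perms]  # (n!, n)
    rx_c = rx - rx.mean()
    pc = permuted - permuted.mean(axis=1, keepdims=True)
    num = pc @ rx_c
    den = np.sqrt((rx_c**2).sum() * (pc**2).sum(axis=1))
    rhos = np.abs(num / den)
    return float(np.mean(rhos >= obs - 1e-12))


def trait_fd_corr(trait: np.ndarray, mean_fd: np.ndarray) -> dict:
    """Pearson and Spearman correlation of a trait with mean FD.

    Two-sided p-values; the Spearman p is an exact permutation value below
    n = 10 and the usual t-approximation above.
    """
    trait = np.asarray(trait, dtype=float).ravel()
    mean_fd = np.asarray(mean_fd, dtype=float).ravel()
    n = trait.size
    if n < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(trait) == 0 or np.ptp(mean_fd) == 0:
        raise ValueError("constant input")
    pr = stats.pearsonr(trait, mean_fd)
    sr = stats.spearmanr(trait, mean_fd)
    if n < 10:
        sp = _exact_spearman_p(trait, mean_fd)
    else:
        sp = float(sr.pvalue)
    return {
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic), "spearman_p": sp,
    }


def matrix_similarity(a, b) -> tuple[float, float]:
    """Edge-for-edge Pearson r and Spearman rho between two edge vectors."""
    va = a.beta if isinstance(a, EffectMatrix) else np.asarray(a, float).ravel()
    vb = b.beta if isinstance(b, EffectMatrix) else np.asarray(b, float).ravel()
    if va.shape != vb.shape:
        raise ValueError("edge vectors differ in length (ordering mismatch?)")
    r = float(stats.pearsonr(va, vb).statistic)
    rho = float(stats.spearmanr(va, vb).statistic)
    return r, rho


def variance_reduction(var_before: np.ndarray, var_after: np.ndarray,
                       mean_fd: np.ndarray) -> VarianceAssessment:
    """Denoising performance via the log-log Spearman variance-vs-FD model.

    rho is the Spearman correlation of log(mean node variance) with
    log(mean FD) across participants, before and after denoising; the
    relative reduction in the proportion of signal variance related to motion
    is ``1 - (rho_after / rho_before)^2``.
    """
    var_before = np.asarray(var_before, dtype=float).ravel()
    var_after = np.asarray(var_after, dtype=float).ravel()
    mean_fd = np.asarray(mean_fd, dtype=float).ravel()
    for name, v in (("var_before", var_before), ("var_after", var_after),
                    ("mean_fd", mean_fd)):
        if np.any(v <= 0):
            raise ValueError(f"{name} must be strictly positive (log model)")
    rb = float(stats.spearmanr(np.log(var_before), np.log(mean_fd)).statistic)
    ra = float(stats.spearmanr(np.log(var_after), np.log(mean_fd)).statistic)
    if rb == 0 or math.isnan(rb):
        raise ValueError("rho_before is zero; relative reduction undefined")
    return VarianceAssessment(rho_before=rb, rho_after=ra)


def relative_reduction_from_proportions(var_explained_before: float,
                                        var_explained_after: float) -> float:
    """Relative reduction given rho^2 proportions directly (worked example:
    0.73 before, 0.23 after -> 0.68493..., i.e. 69% rounded)."""
    if var_explained_before <= 0:
        raise ValueError("var_explained_before must be positive")
    return 1 - var_explained_after / var_explained_before
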