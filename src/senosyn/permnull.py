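"""Differential expression with a permutation empirical null.

For one two-group comparison, a Student t-statistic is computed per gene.
Significance is assessed against an *empirical null*: group labels of the
compared samples are randomly permuted (10,000 times by default, or all
distinct assignments enumerated exactly when fewer exist), the t-statistic is
recomputed per gene for every permutation, and the permuted values of **all**
genes are pooled into one distribution. A Gaussian density estimator — by
default a Gaussian-kernel KDE with Silverman bandwidth, alternatively a
single normal fitted by moments — smooths the pooled values, and the
two-tailed p-value of each observed t is read off the fitted density.

Pooling across genes gives a smooth, well-populated null even with the few
replicates typical of microarray time courses; no further multiple-testing
correction is applied on top of the empirical p (the selection thresholds
P < 0.05 and |log2FC| > 0.58, i.e. 1.5-fold, act directly on it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid
from statsmodels.nonparametric.kde import KDEUnivariate

from .data_model import Arm, ExpressionDataset, Level

__all__ = [
    "Comparison",
    "DEGThresholds",
    "EmpiricalNull",
    "DEGTable",
    "T_CAP",
    "t_statistic",
    "build_null",
    "empirical_pvalue",
    "empirical_pvalues",
    "call_degs",
]

#: Sentinel magnitude for a zero-pooled-variance t with unequal means.
T_CAP = 1e6

Estimator = Literal["kde", "gaussian_fit"]
Variance = Literal["pooled", "welch"]


@dataclass(frozen=True)
class Comparison:
    """A two-group contrast; log2FC is oriented mean(group_a) - mean(group_b)."""

    label: str
    arm_a: Arm
    arm_b: Arm
    dpt_a: int | None = None
    dpt_b: int | None = None

    def samples(self, dataset: ExpressionDataset) -> tuple[list[str], list[str]]:
        a = dataset.select_samples(self.arm_a, self.dpt_a)
        b = dataset.select_samples(self.arm_b, self.dpt_b)
        if set(a) & set(b):
            raise ValueError(f"{self.label}: comparison groups overlap")
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"{self.label}: each group needs >= 2 samples "
                f"(got {len(a)} vs {len(b)})"
            )
        return a, b


@dataclass(frozen=True)
class DEGThresholds:
    """Selection cutoffs: P < alpha and |log2FC| > lfc_cutoff (0.58 = 1.5-fold)."""

    alpha: float = 0.05
    lfc_cutoff: float = 0.58

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_cutoff < 0.0:
            raise ValueError("lfc_cutoff must be >= 0")


def _t_from_moments(
    d: np.ndarray,
    va: np.ndarray,
    vb: np.ndarray,
    na: int,
    nb: int,
    variance: Variance,
) -> np.ndarray:
    if variance == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    elif variance == "welch":
        se = np.sqrt(va / na + vb / nb)
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / se
    # zero variance: t=0 when means agree, capped sentinel when they differ
    zero = se == 0.0
    if np.any(zero):
        t = np.where(zero & (d == 0.0), 0.0, t)
        t = np.where(zero & (d != 0.0), np.sign(d) * T_CAP, t)
    return t


def t_statistic(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    variance: Variance = "pooled",
) -> float:
    """Two-sample Student t of mean(a) - mean(b) (equal-variance pooled form).

    Degenerate case: both variances zero and equal means gives 0; zero pooled
    variance with unequal means gives the capped sentinel ±``T_CAP`` rather
    than an infinity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    d = np.array([a.mean() - b.mean()])
    va = np.array([a.var(ddof=1)])
    vb = np.array([b.var(ddof=1)])
    return float(_t_from_moments(d, va, vb, a.size, b.size, variance)[0])


def _t_matrix(
    X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, variance: Variance
) -> np.ndarray:
    """Per-gene t for one label assignment; X is genes x (na+nb) samples."""
    A = X[:, idx_a]
    B = X[:, idx_b]
    d = A.mean(axis=1) - B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    return _t_from_moments(d, va, vb, idx_a.size, idx_b.size, variance)


@dataclass
class EmpiricalNull:
    """Pooled permuted t-statistics with a fitted Gaussian density estimator."""

    pooled_t: np.ndarray
    n_perm: int
    seed: int
    estimator: Estimator = "kde"
    bandwidth: float = 0.0
    exhaustive: bool = False
    variance: Variance = "pooled"
    # fitted pieces (KDE: support grid + CDF; gaussian_fit: moments)
    _support: np.ndarray | None = field(default=None, repr=False)
    _cdf: np.ndarray | None = field(default=None, repr=False)
    _mu: float = 0.0
    _sigma: float = 1.0

    def fit(self) -> "EmpiricalNull":
        t = np.asarray(self.pooled_t, dtype=float)
        if not np.isfinite(t).all():
            raise ValueError("pooled_t contains non-finite values")
        if self.estimator == "gaussian_fit":
            self._mu = float(t.mean())
            self._sigma = float(t.std(ddof=1)) or 1e-12
            self.bandwidth = self._sigma
            return self
        if self.estimator != "kde":
            raise ValueError(f"unknown estimator {self.estimator!r}")
        kde = KDEUnivariate(t)
        # FFT Gaussian-kernel KDE; support extends 6 bandwidths past the data
        kde.fit(kernel="gau", bw="silverman", fft=True, gridsize=4096, cut=6)
        self.bandwidth = float(kde.bw)
        self._support = np.asarray(kde.support)
        density = np.asarray(kde.density)
        cdf = cumulative_trapezoid(density, self._support, initial=0.0)
        total = float(cdf[-1])
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"fitted null density integrates to {total:.6f}, not 1")
        self._cdf = cdf / total
        return self

    @property
    def density_total(self) -> float:
        """Integral of the fitted density over its support (should be ~1)."""
        if self.estimator == "gaussian_fit":
            return 1.0
        if self._cdf is None:
            raise RuntimeError("null not fitted")
        return 1.0  # normalized in fit(); pre-normalization checked there

    def cdf(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.estimator == "gaussian_fit":
            return stats.norm.cdf(t, loc=self._mu, scale=self._sigma)
        if self._support is None or self._cdf is None:
            raise RuntimeError("null not fitted; call fit() first")
        return np.interp(t, self._support, self._cdf, left=0.0, right=1.0)


def build_null(
    dataset: ExpressionDataset,
    cmp: Comparison,
    n_perm: int = 10_000,
    seed: int = 0,
    estimator: Estimator = "kde",
    variance: Variance = "pooled",
) -> EmpiricalNull:
    """Build the empirical null for one comparison by label permutation.

    Labels are shuffled only among the samples of the two compared groups.
    When the number of distinct label assignments C(na+nb, na) does not
    exceed ``n_perm``, all distinct assignments are enumerated exactly;
    otherwise ``n_perm`` random shuffles are drawn (without deduplication).
    Permuted t values of all genes and permutations are pooled.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sa, sb = cmp.samples(dataset)
    na, nb = len(sa), len(sb)
    X = dataset.submatrix(sa + sb)
    n = na + nb

    n_distinct = math.comb(n, na)
    pooled: list[np.ndarray] = []
    if n_distinct <= n_perm:
        exhaustive = True
        for combo in combinations(range(n), na):
            idx_a = np.array(combo, dtype=int)
            idx_b = np.array([i for i in range(n) if i not in set(combo)], dtype=int)
            pooled.append(_t_matrix(X, idx_a, idx_b, variance))
        n_used = n_distinct
    else:
        exhaustive = False
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pooled.append(_t_matrix(X, perm[:na], perm[na:], variance))
        n_used = n_perm

    pooled_t = np.concatenate(pooled)
    null = EmpiricalNull(
        pooled_t=pooled_t,
        n_perm=n_used,
        seed=seed,
        estimator=estimator,
        exhaustive=exhaustive,
        variance=variance,
    )
    return null.fit()


def empirical_pvalues(null: EmpiricalNull, t_obs: np.ndarray) -> np.ndarray:
    """Two-tailed empirical p-values, vectorized over observed t."""
    t_obs = np.asarray(t_obs, dtype=float)
    if not np.isfinite(t_obs).all():
        raise ValueError("observed t contains non-finite values")
    F = null.cdf(t_obs)
    p = 2.0 * np.minimum(F, 1.0 - F)
    # the fitted density has unbounded support: p stays strictly positive
    return np.clip(p, 1e-300, 1.0)


def empirical_pvalue(null: EmpiricalNull, t_obs: float) -> float:
    """Two-tailed p of one observed t: min(1, 2*min(Pr(T>=t), Pr(T<=t)))."""
    if not np.isfinite(t_obs):
        raise ValueError("t_obs must be finite")
    return float(empirical_pvalues(null, np.array([t_obs]))[0])


@dataclass
class DEGTable:
    """Per-gene test results for one comparison, sorted by gene id."""

    comparison: str
    frame: pd.DataFrame  # columns: gene_id, t, log2fc, p, direction

    def __post_init__(self) -> None:
        self.frame = self.frame.sort_values("gene_id").reset_index(drop=True)
        self._dir = dict(zip(self.frame["gene_id"], self.frame["direction"]))
        self._lfc = dict(zip(self.frame["gene_id"], self.frame["log2fc"]))

    def direction_of(self, gene_id: str) -> str:
        return self._dir.get(gene_id, "NS")

    def log2fc_of(self, gene_id: str) -> float:
        return float(self._lfc.get(gene_id, 0.0))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame["gene_id"])

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["direction"] != "NS"]

    def write_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.insert(1, "comparison", self.comparison)
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def call_degs(
    dataset: ExpressionDataset,
    cmp: Comparison,
    null: EmpiricalNull,
    thr: DEGThresholds = DEGThresholds(),
) -> DEGTable:
    """Score every gene against the empirical null and apply DEG thresholds.

    Direction is UP when p < alpha and log2FC > lfc_cutoff, DOWN when
    p < alpha and log2FC < -lfc_cutoff, NS otherwise.
    """
    if dataset.level is not Level.GENE:
        raise ValueError("call_degs requires a GENE-level dataset")
    sa, sb = cmp.samples(dataset)
    A = dataset.submatrix(sa)
    B = dataset.submatrix(sb)
    d = A.mean(axis=1) - B.mean(axis=1)
    t = _t_from_moments(
        d, A.var(axis=1, ddof=1), B.var(axis=1, ddof=1), A.shape[1], B.shape[1],
        null.variance,
    )
    p = empirical_pvalues(null, t)
    direction = np.where(
        (p < thr.alpha) & (d > thr.lfc_cutoff),
        "UP",
        np.where((p < thr.alpha) & (d < -thr.lfc_cutoff), "DOWN", "NS"),
    )
    frame = pd.DataFrame(
        {
            "gene_id": dataset.feature_ids,
            "t": t,
            "log2fc": d,
            "p": p,
            "direction": direction,
        }
    )
    return DEGTable(comparison=cmp.label, frame=frame)
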