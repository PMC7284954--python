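"""Hand-rolled comparison statistics for community and assay data.

The statistics themselves (paired t, Bonferroni, Bray-Curtis, one-way
permutational MANOVA, multivariate dispersion) are implemented here rather
than delegated, so each can be verified against an independent oracle in the
test suite.  Only distribution functions come from scipy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "TTestResult",
    "PermanovaResult",
    "DispersionResult",
    "paired_t_test",
    "bonferroni",
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
    "dispersion_check",
]


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    ss_total: float
    ss_within: float
    ss_between: float


@dataclass(frozen=True)
class DispersionResult:
    group_dispersions: dict
    f_stat: float
    p_value: float
    n_permutations: int
    seed: int | None


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on differences x - y.

    Pairs with a missing (NaN) side are dropped with a log message.  With
    zero-variance nonzero differences the statistic diverges; t is reported
    as signed infinity and p as its limit, 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    complete = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~complete).sum())
    if dropped:
        logger.info("paired_t_test: dropped %d incomplete pairs", dropped)
    d = x[complete] - y[complete]
    n = d.size
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, have {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, df, 1.0)
        logger.warning("paired_t_test: zero-variance differences, t is infinite")
        return TTestResult(math.copysign(math.inf, mean), df, 0.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, p)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> tuple[list[float], list[bool]]:
    """Bonferroni-adjusted p-values and significance flags at ``alpha``."""
    p_values = list(p_values)
    m = len(p_values)
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    adjusted = [min(1.0, m * p) for p in p_values]
    flags = [p <= alpha for p in adjusted]
    return adjusted, flags


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity ``sum|u-v| / sum(u+v)`` in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = float(np.sum(u + v))
    if denom == 0.0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(u - v)) / denom)


def bray_curtis_matrix(abundances, binary: bool = False) -> np.ndarray:
    """Pairwise Bray-Curtis distances for a samples-x-taxa matrix.

    ``binary=True`` reduces counts to presence/absence first (literature
    reports are frequently presence-only).
    """
    X = np.asarray(abundances, dtype=float)
    if binary:
        X = (X > 0).astype(float)
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(X[i], X[j])
    return out


# ---------------------------------------------------------------------------
# PerMANOVA


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if (dist < -1e-12).any():
        raise ValueError("distances must be non-negative")
    return dist


def _encode_groups(groups) -> tuple[np.ndarray, int]:
    uniques, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes, len(uniques)


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dist,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way permutational MANOVA on a distance matrix.

    Sums of squares follow the standard partition of squared inter-point
    distances: ``SS_total = sum_{i<j} d_ij^2 / n`` and ``SS_within`` is the
    analogous within-group sum; ``pseudo-F = (SS_between/(g-1)) /
    (SS_within/(n-g))``.  The p-value uses label permutations with the +1
    correction: ``(1 + #{F* >= F}) / (1 + n_permutations)``.
    """
    dist = _validate_distance_matrix(dist)
    codes, n_groups = _encode_groups(groups)
    n = dist.shape[0]
    if codes.size != n:
        raise ValueError("group labels must match the matrix dimension")
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if n < 3:
        raise ValueError("need at least three samples")
    counts = np.bincount(codes, minlength=n_groups)
    if counts.max() == n:
        raise ValueError("one group contains all samples")
    if n - n_groups < 1:
        raise ValueError("residual degrees of freedom are zero (all groups singletons)")

    d2 = dist**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ssw = _ss_within(d2, perm, n_groups)
        ssb = ss_total - ssw
        f_perm = (ssb / (n_groups - 1)) / (ssw / (n - n_groups))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)

    return PermanovaResult(
        pseudo_F=float(f_obs),
        r_squared=float(ss_between / ss_total),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        ss_total=float(ss_total),
        ss_within=float(ss_within),
        ss_between=float(ss_between),
    )


# ---------------------------------------------------------------------------
# dispersion


def _pcoa_coordinates(dist: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Principal-coordinate embedding, keeping positive-eigenvalue axes."""
    n = dist.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ (dist**2) @ centering
    eigval, eigvec = np.linalg.eigh(gower)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > tol * max(eigval.max(), 1.0)
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def _geometric_median(points: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Weiszfeld iteration for the spatial median."""
    median = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - median, axis=1)
        if (d < tol).any():
            return points[d < tol][0]
        w = 1.0 / d
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - median) < tol:
            return new
        median = new
    return median


def _dispersion_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = z.size
    grand = z.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        zg = z[codes == g]
        ss_between += zg.size * (zg.mean() - grand) ** 2
        ss_within += ((zg - zg.mean()) ** 2).sum()
    if ss_within == 0.0:
        return 0.0 if ss_between == 0.0 else math.inf
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def dispersion_check(
    dist,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity-of-dispersion check (betadisper-style).

    Samples are embedded by principal coordinates; each sample's distance to
    its group's spatial median is the dispersion score, compared across
    groups with an ANOVA-type F whose null distribution comes from label
    permutations.
    """
    dist = _validate_distance_matrix(dist)
    raw_groups = np.asarray(groups)
    codes, n_groups = _encode_groups(raw_groups)
    n = dist.shape[0]
    if codes.size != n:
        raise ValueError("group labels must match the matrix dimension")
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if n - n_groups < 1:
        raise ValueError("residual degrees of freedom are zero")

    coords = _pcoa_coordinates(dist)
    if coords.shape[1] == 0:  # all points identical
        z = np.zeros(n)
    else:
        z = np.empty(n)
        for g in range(n_groups):
            idx = np.flatnonzero(codes == g)
            median = _geometric_median(coords[idx])
            z[idx] = np.linalg.norm(coords[idx] - median, axis=1)

    f_obs = _dispersion_f(z, codes, n_groups)
    rng = np.random.default_rng(seed)
    if f_obs == 0.0 and np.allclose(z, 0.0):
        p = 1.0
    else:
        exceed = sum(
            _dispersion_f(z, rng.permutation(codes), n_groups) >= f_obs
            for _ in range(n_permutations)
        )
        p = (1 + exceed) / (1 + n_permutations)

    labels = np.unique(raw_groups)
    group_disp = {labels[g]: float(z[codes == g].mean()) for g in range(n_groups)}
    return DispersionResult(
        group_dispersions=group_disp,
        f_stat=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
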