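"""Community-structure comparison: Bray-Curtis distances, PERMANOVA, MRPP,
nMDS ordination and Kruskal-Wallis tests.

The method-comparison experiments ask how much of the between-sample
variation in community composition is attributable to the laboratory (or the
protocol family).  That is a one-factor PERMANOVA on the Bray-Curtis distance
matrix: the pseudo-F statistic partitions the total sum of squared distances
into between- and within-group components (R² = SS_between / SS_total), with
significance from random permutations of the group labels.  MRPP tests the
same hypothesis through the observed mean within-group distance (delta)
against its permutation distribution, with chance-corrected effect size
A = 1 - delta / E[delta].  When the number of distinct label arrangements is
small (<= 10,000) both tests switch automatically to exhaustive enumeration,
making the p-value exact.

Permutation p-values use the (1 + exceedances) / (1 + n_perm) estimator, so
they are never 0 and are bounded below by 1/(1 + n_perm).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal
from sympy.utilities.iterables import multiset_permutations

from .design import AbundanceTable

EXHAUSTIVE_LIMIT = 10_000


class StatsError(ValueError):
    pass


@dataclass
class PermTestResult:
    method: str  # permanova | mrpp
    statistic: float  # pseudo-F or observed delta
    effect_size: float  # R^2 or A
    p_value: float
    n_perm: int
    exhaustive: bool
    seed: int | None = None
    excluded_groups: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """``1 - 2 sum(min(x,y)) / (sum x + sum y)``; nan for two empty vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise StatsError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        return float("nan")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def distance_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Symmetric Bray-Curtis matrix over a table's samples (zero diagonal)."""
    X = table.data.to_numpy(dtype=float).T
    if (X.sum(axis=1) == 0).any():
        empty = [s for s, tot in zip(table.samples, X.sum(axis=1)) if tot == 0]
        raise StatsError(f"all-zero samples have undefined distances: {empty}")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.samples, columns=table.samples)


def _as_square(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    D = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise StatsError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise StatsError("distance matrix must be symmetric")
    if np.abs(np.diag(D)).max() > 0:
        raise StatsError("distance matrix diagonal must be zero")
    return D


def _group_indices(groups: Sequence) -> tuple[np.ndarray, list]:
    labels = pd.Series(list(groups))
    cats = sorted(labels.unique().tolist())
    codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()
    return codes, cats


def _n_distinct_perms(codes: np.ndarray) -> float:
    n = len(codes)
    out = math.lgamma(n + 1)
    for c in np.bincount(codes):
        out -= math.lgamma(c + 1)
    return math.exp(out)


def _label_permutations(codes: np.ndarray, n_perm: int, seed: int | None):
    """Yield (permuted codes, exhaustive?) — exhaustive when the distinct
    arrangements of the label multiset fit the enumeration budget."""
    if _n_distinct_perms(codes) <= EXHAUSTIVE_LIMIT:
        return [np.array(p) for p in multiset_permutations(codes.tolist())], True
    rng = np.random.default_rng(seed)
    return [rng.permutation(codes) for _ in range(n_perm)], False


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Anderson's pseudo-F and R² from squared distances and group codes."""
    n = len(codes)
    ss_total = D2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0 or df_within <= 0:
        f = float("inf") if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, float(r2)


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermTestResult:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    Significance comes from permuting group labels: Monte-Carlo with
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``, or exact enumeration of
    all distinct labelings when there are at most 10,000 of them (the
    identity arrangement is then part of the enumeration, so
    ``p = #{F >= F_obs} / total``).
    """
    D = _as_square(dist)
    codes, cats = _group_indices(groups)
    if len(codes) != D.shape[0]:
        raise StatsError("groups length does not match the distance matrix")
    if len(cats) < 2:
        raise StatsError("PERMANOVA needs at least 2 groups")
    D2 = D**2
    f_obs, r2 = _pseudo_f(D2, codes, len(cats))
    perms, exhaustive = _label_permutations(codes, n_perm, seed)
    f_perm = np.array([_pseudo_f(D2, p, len(cats))[0] for p in perms])
    if exhaustive:
        p = float(np.mean(f_perm >= f_obs - 1e-12))
    else:
        p = float((1 + np.sum(f_perm >= f_obs - 1e-12)) / (1 + len(perms)))
    return PermTestResult("permanova", f_obs, r2, p, len(perms), exhaustive, seed)


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------

def _delta(D: np.ndarray, codes: np.ndarray, groups_used: np.ndarray) -> float:
    """Group-size-weighted mean within-group distance over usable groups."""
    n_used = sum(np.sum(codes == g) for g in groups_used)
    delta = 0.0
    for g in groups_used:
        idx = np.flatnonzero(codes == g)
        sub = D[np.ix_(idx, idx)]
        within = sub[np.triu_indices(len(idx), k=1)]
        delta += (len(idx) / n_used) * within.mean()
    return float(delta)


def mrpp(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermTestResult:
    """Multi-response permutation procedure on a distance matrix.

    Observed delta is the group-size-weighted mean within-group distance;
    the chance-corrected effect size is ``A = 1 - delta / E[delta_perm]``
    with the expectation taken over the permutation set.  Singleton groups
    have no within-group distance and are excluded from delta (reported).
    """
    D = _as_square(dist)
    codes, cats = _group_indices(groups)
    if len(codes) != D.shape[0]:
        raise StatsError("groups length does not match the distance matrix")
    if len(cats) < 2:
        raise StatsError("MRPP needs at least 2 groups")
    sizes = np.bincount(codes, minlength=len(cats))
    usable = np.flatnonzero(sizes >= 2)
    excluded = tuple(str(cats[g]) for g in np.flatnonzero(sizes < 2))
    if len(usable) == 0:
        raise StatsError("MRPP needs at least one group with >= 2 members")
    delta_obs = _delta(D, codes, usable)
    perms, exhaustive = _label_permutations(codes, n_perm, seed)
    deltas = np.array([_delta(D, p, usable) for p in perms])
    expected = float(deltas.mean())
    a = 1.0 - delta_obs / expected if expected > 0 else 0.0
    if exhaustive:
        p = float(np.mean(deltas <= delta_obs + 1e-12))
    else:
        p = float((1 + np.sum(deltas <= delta_obs + 1e-12)) / (1 + len(perms)))
    return PermTestResult("mrpp", delta_obs, float(a), p, len(perms), exhaustive, seed, excluded)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def nmds(
    dist: pd.DataFrame,
    k: int = 2,
    restarts: int = 4,
    seed: int | None = 0,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, float]:
    """Non-metric multidimensional scaling with deterministic orientation.

    Minimises Kruskal stress-1 by SMACOF with monotone regression (best of
    ``restarts`` seeded starts).  The embedding is centred and rotated onto
    its principal axes with a fixed sign convention, so the same seed gives
    identical coordinates.  Returns (coordinates, stress).
    """
    import inspect

    from sklearn.manifold import MDS

    D = _as_square(dist)
    if D.shape[0] < k + 1:
        raise StatsError(f"nMDS in {k} dimensions needs at least {k + 1} samples")
    kwargs = dict(
        n_components=k,
        n_init=restarts,
        max_iter=max_iter,
        random_state=None if seed is None else int(seed),
        normalized_stress=True,
    )
    # parameters renamed in sklearn >= 1.9 (metric -> metric_mds,
    # dissimilarity -> metric)
    if "metric_mds" in inspect.signature(MDS).parameters:
        kwargs.update(metric_mds=False, metric="precomputed")
    else:
        kwargs.update(metric=False, dissimilarity="precomputed")
    mds = MDS(**kwargs)
    coords = mds.fit_transform(D)
    stress = float(mds.stress_)
    coords = coords - coords.mean(axis=0)
    # principal-axis rotation + sign fix: largest-|loading| coordinate positive
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    idx = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(D.shape[0])
    return (
        pd.DataFrame(coords, index=idx, columns=[f"nmds{j + 1}" for j in range(k)]),
        stress,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with the chi-square p approximation.

    All-identical values give (H=0, p=1) rather than an error.
    """
    codes, cats = _group_indices(groups)
    if len(cats) < 2:
        raise StatsError("Kruskal-Wallis needs at least 2 groups")
    x = np.asarray(values, dtype=float)
    if len(x) != len(codes):
        raise StatsError("values and groups length mismatch")
    samples = [x[codes == g] for g in range(len(cats))]
    if np.ptp(x) == 0:
        return 0.0, 1.0
    h, p = kruskal(*samples)
    return float(h), float(p)
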