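"""Rarefaction, alpha/beta diversity, NMDS ordination and PERMANOVA.

Alpha diversity uses Shannon entropy (natural log) and the bias-corrected
Chao1 richness estimator; beta diversity is Bray-Curtis.  PERMANOVA is the
single-factor permutation test on a distance matrix (pseudo-F from the
partition of squared distances); ordination is non-metric MDS minimizing
Kruskal stress-1 with seeded restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

from .containers import CommunityMatrix
from .errors import (
    DepthError,
    InvalidArgumentError,
    UndefinedDistanceError,
    UndefinedDiversityError,
    UnderdeterminedDesignError,
)


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefy(matrix: CommunityMatrix, depth="min", seed: int = 0) -> CommunityMatrix:
    """Subsample every sample without replacement to a common depth.

    ``depth='min'`` uses the smallest library size.  A single multivariate
    hypergeometric draw per sample; each rarefied row sums exactly to depth.
    """
    counts = matrix.counts.to_numpy(dtype=np.int64)
    row_sums = counts.sum(axis=1)
    if depth == "min":
        depth = int(row_sums.min())
    depth = int(depth)
    if depth < 1:
        raise InvalidArgumentError("rarefaction depth must be >= 1")
    shallow = row_sums < depth
    if shallow.any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(shallow)]
        raise DepthError(f"depth {depth} exceeds library size of samples: {bad}")

    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        if row_sums[i] == depth:
            out[i] = counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    df = pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns)
    return CommunityMatrix(counts=df, is_rarefied=True, rarefaction_depth=depth)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over positive entries (nats)."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise UndefinedDiversityError("all-zero abundance vector")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are singleton/doubleton counts; the corrected form never divides
    by zero when doubletons are absent.
    """
    x = np.asarray(counts, dtype=float)
    if not np.allclose(x, np.round(x)):
        raise InvalidArgumentError("Chao1 requires integer counts")
    x = np.round(x).astype(np.int64)
    x = x[x > 0]
    if x.size == 0:
        raise UndefinedDiversityError("all-zero abundance vector")
    s_obs = x.size
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def observed_richness(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def alpha_diversity(matrix: CommunityMatrix) -> pd.DataFrame:
    """Per-sample Shannon, Chao1 and observed richness."""
    rows = []
    for sid in matrix.sample_ids:
        v = matrix.counts.loc[sid].to_numpy()
        rows.append((sid, shannon(v), chao1(v), observed_richness(v)))
    return pd.DataFrame(rows, columns=["sample_id", "shannon", "chao1", "observed_richness"])


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis_pair(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if x.sum() == 0 or y.sum() == 0:
        raise UndefinedDistanceError("Bray-Curtis undefined for all-zero samples")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis(matrix: CommunityMatrix) -> pd.DataFrame:
    """All-pairs Bray-Curtis distance matrix (square DataFrame in [0, 1])."""
    x = matrix.values()
    if (x.sum(axis=1) == 0).any():
        bad = [matrix.sample_ids[i] for i in np.flatnonzero(x.sum(axis=1) == 0)]
        raise UndefinedDistanceError(f"all-zero samples: {bad}")
    totals = x.sum(axis=1)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = diff / (totals[i] + totals[i + 1 :])
    d = d + d.T
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    k: int


def nmds(dist: pd.DataFrame, k: int = 2, n_restarts: int = 20, seed: int = 0) -> OrdinationResult:
    """Non-metric MDS in ``k`` dimensions; best Kruskal stress-1 over restarts."""
    n = dist.shape[0]
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    if n < k + 1:
        raise InvalidArgumentError(f"need at least {k + 1} samples for k={k}")
    d = dist.to_numpy()
    off = d[np.triu_indices(n, 1)]
    if np.allclose(off, off[0]):
        warnings.warn("degenerate (all-equal) distances; returning origin coordinates")
        coords = pd.DataFrame(
            np.zeros((n, k)), index=dist.index, columns=[f"NMDS{i + 1}" for i in range(k)]
        )
        return OrdinationResult(coordinates=coords, stress=0.0, k=k)
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        max_iter=500,
        random_state=seed,
        normalized_stress=True,
    )
    xy = model.fit_transform(d)
    coords = pd.DataFrame(xy, index=dist.index, columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(coordinates=coords, stress=float(model.stress_), k=k)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    factor: str
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, groups: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Within-group and total sum of squared distances (Gower partition)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_within, ss_total


def permanova(
    dist: pd.DataFrame,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "group",
) -> PermanovaResult:
    """Single-factor PERMANOVA with free label permutation.

    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)); the permutation
    p-value is (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    if n_permutations < 99:
        raise InvalidArgumentError("n_permutations must be >= 99")
    labels = np.asarray(labels)
    if labels.shape[0] != dist.shape[0]:
        raise InvalidArgumentError("labels length must match distance matrix")
    uniq, groups = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise UnderdeterminedDesignError("need at least two groups")
    sizes = np.bincount(groups)
    if (sizes < 2).any():
        bad = [str(uniq[i]) for i in np.flatnonzero(sizes < 2)]
        raise UnderdeterminedDesignError(f"groups with a single sample: {bad}")

    d2 = dist.to_numpy() ** 2
    n, a = d2.shape[0], uniq.size

    def f_stat(g: np.ndarray) -> float:
        ss_w, ss_t = _permanova_ss(d2, g, a)
        ss_a = ss_t - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(groups)
    ss_w, ss_t = _permanova_ss(d2, groups, a)
    r2 = (ss_t - ss_w) / ss_t

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        if f_stat(perm) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        factor=factor,
        pseudo_F=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# group dissimilarity
# ---------------------------------------------------------------------------

def group_dissimilarity(dist: pd.DataFrame, labels) -> pd.Series:
    """Mean within-group pairwise dissimilarity per group.

    Singleton groups are skipped with a warning (no pairs to average).
    """
    labels = pd.Series(np.asarray(labels), index=dist.index)
    out = {}
    for g, idx in labels.groupby(labels).groups.items():
        ids = list(idx)
        if len(ids) < 2:
            warnings.warn(f"group {g!r} has a single sample; skipped")
            continue
        sub = dist.loc[ids, ids].to_numpy()
        out[g] = float(sub[np.triu_indices(len(ids), 1)].mean())
    return pd.Series(out, name="mean_dissimilarity")
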