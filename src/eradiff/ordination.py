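"""PCA, PERMANOVA, and dispersion-homogeneity permutation tests.

PERMANOVA follows Anderson's among/within partition of squared pairwise
distances with a pseudo-F statistic and label-permutation p values.  The
dispersion test embeds the distance matrix by principal-coordinates
analysis, measures each sample's distance to its group centroid (negative
eigenvalue axes contribute negatively to squared distances) and permutes
group labels of those distances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from eradiff.feature_table import DistanceMatrix, InputError


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_variance_ratio: np.ndarray  # per component, fractions
    mean: np.ndarray  # column means removed before decomposition


@dataclass
class PermanovaResult:
    f: float
    r2: float
    p: float
    n_permutations: int
    seed: int | None


@dataclass
class DispersionResult:
    distances_to_centroid: np.ndarray
    group_labels: np.ndarray
    f: float
    p: float
    n_permutations: int
    seed: int | None


def pca(matrix, n_components: int) -> PcaResult:
    """Principal component analysis of a samples x features matrix.

    Columns are centered internally; components come from the SVD of the
    centered matrix.  Sign convention: the largest-magnitude loading of each
    component is positive.  ``n_components`` beyond the matrix rank is
    truncated with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InputError("PCA needs a 2-D matrix with at least 2 rows")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but matrix rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    total_var = float((s**2).sum())
    ratios = (s[:n_components] ** 2 / total_var) if total_var > 0 else np.zeros(n_components)
    loadings = vt[:n_components].T
    scores = u[:, :n_components] * s[:n_components]
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=np.asarray(ratios, dtype=float),
        mean=mean,
    )


def _group_indices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def _permanova_f(d2: np.ndarray, groups: list[np.ndarray], ss_total: float) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances for a fixed grouping."""
    n = d2.shape[0]
    a = len(groups)
    ss_within = 0.0
    for idx in groups:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf, (ss_among / ss_total if ss_total > 0 else 0.0)
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    d: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` with seeded random label
    permutations; ``exact=True`` enumerates every distinct permutation
    instead (the identity counts once, giving ``p = #{F >= F_obs}/n!``).
    """
    labels = np.asarray(labels)
    if d.n != len(labels):
        raise InputError("labels length does not match distance matrix")
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise InputError("PERMANOVA needs at least 2 groups")
    d2 = d.values**2
    n = d.n
    ss_total = d2.sum() / (2.0 * n)
    f_obs, r2 = _permanova_f(d2, groups, ss_total)

    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm_labels = labels[list(perm)]
            f_perm, _ = _permanova_f(d2, _group_indices(perm_labels), ss_total)
            count += f_perm >= f_obs - 1e-12
            total += 1
        return PermanovaResult(
            f=float(f_obs), r2=float(r2), p=count / total, n_permutations=total, seed=seed
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_labels = rng.permutation(labels)
        f_perm, _ = _permanova_f(d2, _group_indices(perm_labels), ss_total)
        count += f_perm >= f_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(f=float(f_obs), r2=float(r2), p=p, n_permutations=n_perm, seed=seed)


def _pcoa_parts(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary parts.

    Returns ``(pos, neg)`` coordinate blocks: axes from positive eigenvalues
    scaled by sqrt(eigenvalue) and axes from negative eigenvalues scaled by
    sqrt(-eigenvalue).  Squared inter-point distances in the embedding are
    ``||dx_pos||^2 - ||dx_neg||^2``.
    """
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=0)
    g = a - row[:, None] - row[None, :] + a.mean()
    evals, evecs = np.linalg.eigh(g)
    tol = max(1.0, np.abs(evals).max(initial=1.0)) * n * np.finfo(float).eps
    pos = evals > tol
    neg = evals < -tol
    pos_coords = evecs[:, pos] * np.sqrt(evals[pos])
    neg_coords = evecs[:, neg] * np.sqrt(-evals[neg])
    return pos_coords, neg_coords


def dispersion_test(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Test homogeneity of multivariate dispersion across groups.

    Each sample's distance to its group centroid is computed in
    principal-coordinate space (negative-eigenvalue axes subtract from the
    squared distance, clamped at zero); the F statistic is the one-way ANOVA
    F on those distances, with p from permuting the distances' group labels.
    Groups of size 1 are excluded with a warning.
    """
    groups = np.asarray(groups)
    if d.n != len(groups):
        raise InputError("group labels length does not match distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    singletons = uniq[counts < 2]
    if len(singletons) > 0:
        warnings.warn(
            f"excluding groups of size 1 from dispersion test: {singletons.tolist()}",
            stacklevel=2,
        )
        keep = ~np.isin(groups, singletons)
        sub = DistanceMatrix(
            values=d.values[np.ix_(keep, keep)],
            ids=[d.ids[i] for i in np.flatnonzero(keep)],
        )
        return dispersion_test(sub, groups[keep], n_perm=n_perm, seed=seed)
    if len(uniq) < 2:
        raise InputError("dispersion test needs at least 2 groups with >= 2 samples")

    pos, neg = _pcoa_parts(d.values)
    z = np.empty(d.n)
    for idx in _group_indices(groups):
        c_pos = pos[idx].mean(axis=0)
        c_neg = neg[idx].mean(axis=0) if neg.shape[1] else np.zeros(0)
        sq = ((pos[idx] - c_pos) ** 2).sum(axis=1)
        if neg.shape[1]:
            sq = sq - ((neg[idx] - c_neg) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.clip(sq, 0.0, None))

    f_obs = _anova_f(z, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm = _anova_f(z, rng.permutation(groups))
        count += f_perm >= f_obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return DispersionResult(
        distances_to_centroid=z,
        group_labels=groups,
        f=float(f_obs),
        p=p,
        n_permutations=n_perm,
        seed=seed,
    )


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    k = 0
    for idx in _group_indices(labels):
        k += 1
        gm = values[idx].mean()
        ss_between += len(idx) * (gm - grand) ** 2
        ss_within += ((values[idx] - gm) ** 2).sum()
    n = len(values)
    if ss_within <= 0:
        return np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def week_bins(collection_days) -> np.ndarray:
    """Map chemotherapy day indices to week bins 1-4.

    Week 1 covers everything through day 7 (including pre-day-0 admission
    days), week 2 is days 8-14, week 3 days 15-21, week 4 day 22 and later.
    """
    days = np.asarray(collection_days, dtype=int)
    bins = np.full(days.shape, 4, dtype=int)
    bins[days <= 21] = 3
    bins[days <= 14] = 2
    bins[days <= 7] = 1
    return bins
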