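"""Community-level statistics: dissimilarities, PERMANOVA, PCoA, diversity.

Bray-Curtis is computed on raw counts (the abundance-weighted
convention used by adonis) and Jaccard on presence/absence as a true
set dissimilarity.  PERMANOVA is the one-factor permutational MANOVA
of McArdle & Anderson: sums of squares come directly from squared
dissimilarities, significance from permuting group labels, with exact
enumeration of all distinct assignments when few enough exist.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy, ttest_ind

from .tables import CountTable


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix."""

    sample_ids: list
    values: np.ndarray
    metric: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be 0")
        self.values = v

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PermanovaResult:
    """One-factor PERMANOVA summary."""

    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    exact: bool = False
    permuted_f: np.ndarray = None

    def __post_init__(self) -> None:
        assert -1e-12 <= self.r2 <= 1 + 1e-12


def bray_curtis(ct: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on raw counts: sum|u-v| / sum(u+v)."""
    mat = squareform(pdist(ct.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(ct.sample_ids, mat, "bray_curtis")


def jaccard(ct: CountTable) -> DistanceMatrix:
    """Jaccard dissimilarity on presence/absence: 1 - |A&B| / |A|B|."""
    mat = squareform(pdist(ct.counts > 0, metric="jaccard"))
    return DistanceMatrix(ct.sample_ids, mat, "jaccard")


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, k: int):
    """(pseudo-F, R2) from squared dissimilarities and integer labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.nonzero(labels == g)[0]
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def _distinct_assignments(group_sizes) -> int:
    n = sum(group_sizes)
    total = math.factorial(n)
    for s in group_sizes:
        total //= math.factorial(s)
    return total


def _enumerate_labels(labels: np.ndarray, k: int):
    """Yield every distinct assignment of the multiset of labels."""
    n = labels.size
    positions = list(range(n))
    counts = [int((labels == g).sum()) for g in range(k)]

    def rec(pos, remaining):
        g = len(remaining) - 1
        if g == 0:
            out = np.empty(n, dtype=np.int64)
            out[list(pos)] = 0
            yield out
            return
        for combo in itertools.combinations(pos, remaining[g]):
            rest = tuple(p for p in pos if p not in set(combo))
            for out in rec(rest, remaining[:g]):
                out[list(combo)] = g
                yield out

    yield from rec(tuple(positions), counts)


def permanova(d: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0,
              keep_permuted: bool = False, exact_limit: int = 10_000) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)) from the
    McArdle-Anderson decomposition of squared dissimilarities.  The
    p-value permutes group labels: exact enumeration over all distinct
    assignments when their number is <= ``exact_limit`` (p = fraction
    of assignments with F >= observed, the identity included),
    otherwise Monte Carlo with p = (1 + #{F_perm >= F}) / (1 + n_perm).
    """
    grouping = pd.Series(grouping) if not isinstance(grouping, pd.Series) else grouping
    labels_raw = grouping.loc[d.sample_ids]
    if labels_raw.isna().any():
        raise ValueError("grouping must cover every sample in the distance matrix")
    levels = list(dict.fromkeys(labels_raw))
    k = len(levels)
    n = len(d.sample_ids)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if k == n:
        raise ValueError("every sample in its own group: no residual df")
    labels = np.array([levels.index(v) for v in labels_raw], dtype=np.int64)
    sizes = [int((labels == g).sum()) for g in range(k)]
    if min(sizes) < 2:
        warnings.warn("a group has fewer than 2 members; PERMANOVA power is minimal")
    d2 = d.values ** 2
    f_obs, r2 = _permanova_stats(d2, labels, k)
    n_assign = _distinct_assignments(sizes)
    if n_assign <= exact_limit:
        fs = np.array([_permanova_stats(d2, lab, k)[0] for lab in _enumerate_labels(labels, k)])
        p = float((fs >= f_obs - 1e-12).sum() / fs.size)
        return PermanovaResult(f_obs, r2, p, int(fs.size), True,
                               fs if keep_permuted else None)
    rng = np.random.default_rng(seed)
    fs = np.empty(n_perm)
    for b in range(n_perm):
        fs[b] = _permanova_stats(d2, rng.permutation(labels), k)[0]
    p = float((1 + (fs >= f_obs - 1e-12).sum()) / (1 + n_perm))
    return PermanovaResult(f_obs, r2, p, n_perm, False, fs if keep_permuted else None)


def pcoa(d: DistanceMatrix):
    """Principal-coordinate analysis (classical MDS).

    Eigendecomposition of the Gower-centered matrix -0.5*J*D^2*J.
    Coordinates use only positive eigenvalues but every eigenvalue is
    reported (negative ones indicate non-Euclidean dissimilarity and
    are not corrected).

    Returns ``(coordinates, eigenvalues)``: a samples x axes DataFrame
    and a descending Series of all n eigenvalues.
    """
    n = d.values.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d.values ** 2) @ J
    eigvals, eigvecs = eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-10 * abs(eigvals).max(), 1e-12)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=d.sample_ids, columns=cols),
        pd.Series(eigvals, index=[f"PCo{i + 1}" for i in range(n)], name="eigenvalue"),
    )


def shannon(ct: CountTable) -> pd.Series:
    """Shannon diversity H = -sum p_i ln p_i per sample (natural log)."""
    if (ct.depths == 0).any():
        raise ValueError("zero-depth sample")
    values = [entropy(row) for row in ct.counts]
    return pd.Series(values, index=ct.sample_ids, name="shannon")


def welch_t(x, y):
    """Welch's unequal-variance two-sample t test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom
    and a two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
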