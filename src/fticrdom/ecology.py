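"""Chemodiversity statistics on the samples x units intensity matrix.

DOM operational units are treated exactly like taxa in community ecology:
intensities are sum-normalized, rounded and rarefied to a fixed depth, and
fed into richness (observed, Chao1), diversity (Shannon), Bray-Curtis
dissimilarity, and the permutation tests (Mantel, PERMANOVA) relating DOM
composition to space and grouping factors.

All stochastic operations take a seed and are bit-reproducible given it.
Permutation p-values use the (count + 1)/(n_perm + 1) correction, so they
are never zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

__all__ = [
    "sum_normalize",
    "to_counts",
    "rarefy",
    "observed_richness",
    "chao1",
    "shannon",
    "bray_curtis",
    "mantel",
    "permanova",
    "accumulation_curve",
    "rank_abundance",
]


def sum_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (row) to unit total intensity."""
    totals = matrix.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cannot sum-normalize all-zero sample rows")
    return matrix.div(totals, axis=0)


def to_counts(matrix: pd.DataFrame, pseudo_depth: int = 43_000) -> pd.DataFrame:
    """Convert intensities to integer pseudo-counts for rarefaction:
    sum-normalize, scale to ``pseudo_depth``, round half to even."""
    return sum_normalize(matrix).mul(pseudo_depth).pipe(np.rint).astype(np.int64)


def rarefy(
    matrix: pd.DataFrame,
    depth: int,
    n_reps: int = 10,
    seed: int | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Subsample each sample's integer counts to exactly ``depth`` without
    replacement, ``n_reps`` times.

    Samples with a total below ``depth`` are dropped with a warning.
    Returns the list of rarefied matrices and their element-wise mean.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = matrix.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("rarefy expects integer counts; use to_counts() first")
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(matrix.index[~keep])
        warnings.warn(f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}")
    sub = counts[keep]
    index = matrix.index[keep]
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        out = np.empty_like(sub)
        for i, row in enumerate(sub):
            out[i] = rng.multivariate_hypergeometric(row, depth)
        reps.append(pd.DataFrame(out, index=index, columns=matrix.columns))
    mean = sum(reps) / n_reps
    return reps, mean


def observed_richness(counts: np.ndarray) -> int:
    counts = np.asarray(counts)
    return int((counts > 0).sum())


def chao1(counts: np.ndarray) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2), with the bias-corrected form
    S_obs + F1(F1-1) / (2(F2+1)) when there are no doubletons."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("chao1 requires non-negative integer counts")
    s_obs = observed_richness(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i (zeros skipped)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample rows, in [0, 1]."""
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    zero_rows = matrix.index[x.sum(axis=1) == 0]
    if len(zero_rows) > 1:
        warnings.warn(
            f"all-zero rows {list(zero_rows)}: their pairwise dissimilarity is undefined (NaN)"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(a, a.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return a


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test of correlation between two distance matrices.

    The statistic is the Pearson (or Spearman) correlation of the lower
    triangles; significance comes from simultaneous row/column permutations
    of the second matrix.  One-sided p: fraction of permutations with
    r >= observed, with the +1 correction.
    """
    if list(d1.index) != list(d2.index):
        if set(d1.index) != set(d2.index):
            raise ValueError("distance matrices must cover the same samples")
        d2 = d2.loc[d1.index, d1.index]
    a = _check_distance(d1)
    b = _check_distance(d2)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)

    def vec(m: np.ndarray) -> np.ndarray:
        v = m[il]
        return rankdata(v) if method == "spearman" else v

    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    x = vec(a)
    r_obs = float(np.corrcoef(x, vec(b))[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = float(np.corrcoef(x, vec(b[np.ix_(perm, perm)]))[0, 1])
        if r >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p


def _permanova_stats(d2: np.ndarray, group_indices: list[np.ndarray], n: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and group index arrays."""
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for idx in group_indices:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    k = len(group_indices)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dist: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """One-way PERMANOVA (Anderson's pseudo-F) on a distance matrix.

    Returns (pseudo_F, R2, p).  R2 = SS_between / SS_total.  The p-value is
    the fraction of label permutations with F >= observed, +1-corrected.
    """
    a = _check_distance(dist)
    labels = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    labels = labels.loc[dist.index]
    uniq = labels.unique()
    if len(uniq) < 2 or any((labels == g).sum() < 2 for g in uniq):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = a.shape[0]
    d2 = a**2
    codes = labels.to_numpy()
    group_idx = [np.flatnonzero(codes == g) for g in uniq]
    f_obs, r2 = _permanova_stats(d2, group_idx, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        permuted = [perm[idx] for idx in group_idx]
        f, _ = _permanova_stats(d2, permuted, n)
        if f >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(f_obs), float(r2), p


def accumulation_curve(
    matrix: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Species-accumulation curve: mean number of distinct units observed in
    the first k samples, averaged over random sample orders."""
    presence = matrix.to_numpy() > 0
    n = presence.shape[0]
    rng = np.random.default_rng(seed)
    acc = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        seen = np.cumsum(presence[order], axis=0) > 0
        acc += seen.sum(axis=1)
    return pd.DataFrame(
        {"n_samples": np.arange(1, n + 1), "mean_richness": acc / n_perm}
    )


def rank_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample rank-abundance table (long format, abundances descending)."""
    rows = []
    for sid, row in matrix.iterrows():
        present = row[row > 0].sort_values(ascending=False)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "rank": np.arange(1, len(present) + 1),
                    "unit_id": present.index,
                    "abundance": present.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", "rank", "unit_id", "abundance"]
    )
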