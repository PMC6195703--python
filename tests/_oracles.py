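"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the formula-space
oracle enumerates the full element grid with vectorized rule masks, the
clustering oracle is an all-pairs union-find, and the KDE/diversity oracles
are direct transcriptions of the defining formulas.
"""

from __future__ import annotations

import math

import numpy as np

from fticrdom.chem_core import ELEMENTS

_E = ELEMENTS.elements


def formula_space(max_mass: float):
    """All (c,h,o,n,p,s) tuples obeying the twelve rules and the element
    bounds with monoisotopic mass <= max_mass, as (counts, masses) sorted
    by mass."""
    cmax = min(100, int(max_mass / 12.0) + 1)
    hmax = min(150, 2 * cmax + 4 + 1 + 2)
    omax = min(50, int(max_mass / _E["O"]) + 1)
    c, h, o, n, p, s = np.meshgrid(
        np.arange(1, cmax + 1),
        np.arange(1, hmax + 1),
        np.arange(0, omax + 1),
        np.arange(0, 5),
        np.arange(0, 2),
        np.arange(0, 2),
        indexing="ij",
        sparse=True,
    )
    mass = (
        c * _E["C"] + h * _E["H"] + o * _E["O"] + n * _E["N"] + p * _E["P"] + s * _E["S"]
    )
    valid = (
        (3 * h >= c)
        & (h <= 2 * c + n + p + 2)
        & ((n + h + p) % 2 == 0)
        & (n <= c)
        & (o + s <= c + 2 * n + 3 * p)
        & (o + s >= p)
        & (mass <= max_mass)
    )
    idx = np.nonzero(valid)
    counts = np.stack(
        [idx[0] + 1, idx[1] + 1, idx[2], idx[3], idx[4], idx[5]], axis=1
    )
    masses = mass[idx]
    order = np.argsort(masses)
    return counts[order], masses[order]


def enumerate_oracle(counts, masses, neutral: float, tolerance_ppm: float):
    """Formula set within tolerance of a neutral mass, from the grid."""
    tol = neutral * tolerance_ppm * 1e-6
    lo = np.searchsorted(masses, neutral - tol)
    hi = np.searchsorted(masses, neutral + tol, side="right")
    return {tuple(int(v) for v in row) for row in counts[lo:hi]}


def cluster_oracle(mz: np.ndarray, tolerance_rel: float) -> set[frozenset[int]]:
    """All-pairs union-find: i~j iff |mz_i - mz_j| < tol * min(mz_i, mz_j)."""
    n = len(mz)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(mz[i] - mz[j]) < tolerance_rel * min(mz[i], mz[j]):
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def kde_oracle(oc, hc, weights, oc_nodes, hc_nodes, h_oc, h_hc):
    """Direct kernel-sum weighted density (nested loops, no vectorization)."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    out = np.zeros((len(oc_nodes), len(hc_nodes)))
    norm = 1.0 / (2.0 * math.pi * h_oc * h_hc)
    for i, x in enumerate(oc_nodes):
        for j, y in enumerate(hc_nodes):
            total = 0.0
            for xk, yk, wk in zip(oc, hc, w):
                total += wk * math.exp(
                    -0.5 * (((x - xk) / h_oc) ** 2 + ((y - yk) / h_hc) ** 2)
                )
            out[i, j] = total * norm
    return out


def shannon_oracle(counts, base=2.0):
    total = sum(counts)
    h = 0.0
    for ci in counts:
        if ci > 0:
            pi = ci / total
            h -= pi * math.log(pi, base)
    return h


def chao1_oracle(counts):
    s_obs = sum(1 for ci in counts if ci > 0)
    f1 = sum(1 for ci in counts if ci == 1)
    f2 = sum(1 for ci in counts if ci == 2)
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1**2 / (2.0 * f2)


def bray_curtis_oracle(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den
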