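"""Stoichiometric compound categories and weighted van Krevelen densities.

Each formula is assigned to exactly one of six DOM compound classes from its
aromaticity index (AI), H/C, O/C ratios and nitrogen content.  The class
boundaries overlap as printed (H/C = 2.0 satisfies both the carbohydrate
rule and the aliphatic window), so assignment is an ordered cascade with the
saturated/carbohydrate rule applied first:

1. H/C >= 2.0 or O/C >= 0.9        -> saturated_carbohydrate_like
2. AI > 0.66                       -> polycyclic_aromatic
3. 0.50 < AI <= 0.66               -> polyphenol
4. AI <= 0.50 and H/C <= 1.5       -> phenolic_highly_unsaturated
5. AI <= 0.50, 1.5 <= H/C < 2.0, N = 0  -> unsaturated_aliphatic
6. AI <= 0.50, 1.5 <= H/C < 2.0, N >= 1 -> peptide_like

The density surface on the van Krevelen plane (H/C against O/C) uses a
weighted sum of axis-aligned bivariate normal kernels; per-group weights are
the median sum-normalized abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_core import MolecularFormula, aromaticity_index

__all__ = [
    "CATEGORIES",
    "classify",
    "VKDensityGrid",
    "vk_density",
    "median_weights",
    "category_abundance",
]

CATEGORIES = (
    "polycyclic_aromatic",
    "polyphenol",
    "phenolic_highly_unsaturated",
    "unsaturated_aliphatic",
    "saturated_carbohydrate_like",
    "peptide_like",
    "unclassified",
)


def classify(formula: MolecularFormula, ai_modified: bool = False) -> str:
    """Assign a formula to its DOM compound category (total, deterministic)."""
    hc = formula.h / formula.c
    oc = formula.o / formula.c
    ai = aromaticity_index(formula, modified=ai_modified)
    if hc >= 2.0 or oc >= 0.9:
        return "saturated_carbohydrate_like"
    if ai > 0.66:
        return "polycyclic_aromatic"
    if ai > 0.50:
        return "polyphenol"
    if hc <= 1.5:
        return "phenolic_highly_unsaturated"
    if formula.n == 0:
        return "unsaturated_aliphatic"
    if formula.n >= 1:
        return "peptide_like"
    return "unclassified"


@dataclass
class VKDensityGrid:
    """A weighted kernel density surface over the van Krevelen plane."""

    oc_nodes: np.ndarray
    hc_nodes: np.ndarray
    density: np.ndarray          # shape (len(oc_nodes), len(hc_nodes))
    bandwidth: tuple[float, float]
    group: str | None = None

    def integral(self) -> float:
        return float(
            np.trapezoid(np.trapezoid(self.density, self.hc_nodes, axis=1), self.oc_nodes)
        )

    def to_frame(self) -> pd.DataFrame:
        oc, hc = np.meshgrid(self.oc_nodes, self.hc_nodes, indexing="ij")
        return pd.DataFrame(
            {"oc": oc.ravel(), "hc": hc.ravel(), "density": self.density.ravel()}
        )


def _weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    mean = np.average(x, weights=w)
    return float(np.sqrt(np.average((x - mean) ** 2, weights=w)))


def vk_density(
    oc: np.ndarray,
    hc: np.ndarray,
    weights: np.ndarray | None = None,
    grid_shape: tuple[int, int] = (200, 200),
    bandwidth: tuple[float, float] | None = None,
    pad_bandwidths: float = 3.0,
    group: str | None = None,
) -> VKDensityGrid:
    """Weighted 2-D kernel density on the van Krevelen plane.

    The estimate is a weight-normalized sum of axis-aligned bivariate normal
    kernels.  Default per-axis bandwidths follow the bivariate normal-
    reference rule h_j = sigma_j * n_eff^(-1/6) computed on the weighted
    sample, with effective sample size n_eff = (sum w)^2 / sum w^2; the grid
    spans the data range padded by ``pad_bandwidths`` bandwidths per side.
    Weights are normalized to sum to 1, so rescaling all weights by a
    constant leaves the density unchanged.
    """
    oc = np.asarray(oc, dtype=float)
    hc = np.asarray(hc, dtype=float)
    if oc.shape != hc.shape or oc.ndim != 1:
        raise ValueError("oc and hc must be equal-length 1-D arrays")
    if weights is None:
        weights = np.ones_like(oc)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be >= 0 and not all zero")
    w = w / w.sum()

    if bandwidth is None:
        if np.ptp(oc) == 0 or np.ptp(hc) == 0:
            raise ValueError(
                "degenerate bandwidth: all points coincide on an axis; "
                "pass an explicit bandwidth=(h_oc, h_hc)"
            )
        n_eff = 1.0 / np.sum(w**2)
        sd_oc = _weighted_sd(oc, w)
        sd_hc = _weighted_sd(hc, w)
        bandwidth = (sd_oc * n_eff ** (-1 / 6), sd_hc * n_eff ** (-1 / 6))
    h_oc, h_hc = bandwidth
    if h_oc <= 0 or h_hc <= 0:
        raise ValueError("bandwidths must be positive")

    oc_nodes = np.linspace(
        oc.min() - pad_bandwidths * h_oc, oc.max() + pad_bandwidths * h_oc, grid_shape[0]
    )
    hc_nodes = np.linspace(
        hc.min() - pad_bandwidths * h_hc, hc.max() + pad_bandwidths * h_hc, grid_shape[1]
    )
    # (n_points, n_nodes) Gaussian kernel matrices per axis
    kx = np.exp(-0.5 * ((oc_nodes[None, :] - oc[:, None]) / h_oc) ** 2) / (
        h_oc * np.sqrt(2 * np.pi)
    )
    ky = np.exp(-0.5 * ((hc_nodes[None, :] - hc[:, None]) / h_hc) ** 2) / (
        h_hc * np.sqrt(2 * np.pi)
    )
    density = (kx * w[:, None]).T @ ky
    return VKDensityGrid(oc_nodes, hc_nodes, density, (float(h_oc), float(h_hc)), group)


def median_weights(
    matrix: pd.DataFrame,
    sample_ids: list[str] | None = None,
    exclude_zeros: bool = False,
) -> pd.Series:
    """Per-unit median of sum-normalized intensities across samples.

    This is the "median molecular abundance" weight for the van Krevelen
    density of a sample group.  Zeros (absences) are included in the median
    by default; ``exclude_zeros=True`` takes the median over presences only.
    """
    sub = matrix.loc[sample_ids] if sample_ids is not None else matrix
    norm = sub.div(sub.sum(axis=1), axis=0)
    if exclude_zeros:
        return norm.where(norm > 0).median(axis=0).fillna(0.0)
    return norm.median(axis=0)


def category_abundance(
    annotations: pd.DataFrame,
    matrix: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    category_col: str = "category",
) -> pd.DataFrame:
    """Per-group relative intensity share of each compound category.

    ``annotations`` must carry ``unit_id`` and a category column; only
    annotated units (non-empty formula) enter the totals.  Each row (group)
    sums to 1; a group with zero annotated intensity yields a NaN row and a
    warning.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    ann = annotations[annotations["formula"] != ""].set_index("unit_id")
    units = [u for u in matrix.columns if u in ann.index]
    cat = ann.loc[units, category_col]
    out = pd.DataFrame(
        0.0, index=sorted(groups.unique()), columns=list(CATEGORIES)
    )
    for group in out.index:
        samples = groups[groups == group].index
        sub = matrix.loc[matrix.index.intersection(samples), units]
        total = float(sub.to_numpy().sum())
        if total == 0:
            warnings.warn(f"group {group!r} has zero annotated intensity")
            out.loc[group] = np.nan
            continue
        per_cat = sub.sum(axis=0).groupby(cat).sum() / total
        for c, v in per_cat.items():
            out.loc[group, c] = v
    return out
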