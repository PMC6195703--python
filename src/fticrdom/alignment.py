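"""Cross-sample peak clustering into operational units.

Peaks from all samples are pooled, globally sorted by m/z, and chained by
single linkage: a new unit starts whenever the gap to the previous peak is
not strictly less than ``tolerance_rel`` times the previous m/z.  This is a
deterministic O(n log n) procedure; a brute-force union-find over all
in-tolerance pairs serves as its correctness oracle in the test suite.  The
tolerance is applied pairwise-adjacent (not to the cluster centroid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import SampleSpectrum

__all__ = [
    "OperationalUnit",
    "cluster_peaks",
    "filter_units",
    "drop_singletons",
    "unit_table",
    "intensity_matrix",
]


@dataclass
class OperationalUnit:
    """A cross-sample cluster of peaks treated as one molecular species
    (the mass-spectrometric analogue of an OTU)."""

    unit_id: int
    representative_mz: float  # intensity-weighted mean of member m/z
    sample_ids: np.ndarray    # one entry per member peak
    mzs: np.ndarray
    intensities: np.ndarray

    @property
    def n_peaks(self) -> int:
        return len(self.mzs)

    @property
    def n_samples(self) -> int:
        return len(set(self.sample_ids.tolist()))

    def intensity_by_sample(self) -> dict[str, float]:
        """Summed intensity per sample (two same-sample peaks in one unit
        are summed; flagged upstream as possible under-resolution)."""
        out: dict[str, float] = {}
        for sid, inten in zip(self.sample_ids.tolist(), self.intensities):
            out[sid] = out.get(sid, 0.0) + float(inten)
        return out


def cluster_peaks(
    spectra: list[SampleSpectrum],
    tolerance_rel: float = 1e-6,
) -> list[OperationalUnit]:
    """Cluster all peaks across samples into operational units.

    Adjacent peaks in the globally sorted m/z stream belong to the same unit
    iff their gap is strictly less than ``tolerance_rel`` x the lower m/z
    ("difference ratios less than 1e-6").  Every peak lands in exactly one
    unit; the result is invariant to input ordering.
    """
    if not spectra:
        return []
    mz = np.concatenate([s.mz for s in spectra])
    if len(mz) == 0:
        return []
    intensity = np.concatenate([s.intensity for s in spectra])
    sample_ids = np.concatenate(
        [np.full(s.n_peaks, s.sample_id, dtype=object) for s in spectra]
    )
    # Deterministic under permutation of input: sort by (mz, sample, intensity).
    order = np.lexsort((intensity, sample_ids.astype(str), mz))
    mz, intensity, sample_ids = mz[order], intensity[order], sample_ids[order]

    gaps = np.diff(mz)
    new_unit = np.concatenate(([True], gaps >= tolerance_rel * mz[:-1]))
    labels = np.cumsum(new_unit) - 1

    units = []
    boundaries = np.flatnonzero(new_unit).tolist() + [len(mz)]
    for uid, (lo, hi) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        m, i, s = mz[lo:hi], intensity[lo:hi], sample_ids[lo:hi]
        rep = float(np.average(m, weights=i))
        units.append(
            OperationalUnit(
                unit_id=uid,
                representative_mz=rep,
                sample_ids=s,
                mzs=m,
                intensities=i,
            )
        )
    assert labels[-1] == len(units) - 1
    return units


def filter_units(
    units: list[OperationalUnit],
    min_peaks: int = 10,
    min_samples: int | None = None,
) -> list[OperationalUnit]:
    """Keep units with at least ``min_peaks`` member peaks (clusters with
    fewer are not annotated) and, optionally, at least ``min_samples``
    distinct samples (the core-molecule occupancy rule)."""
    if min_peaks < 1:
        raise ValueError("min_peaks must be >= 1")
    out = [u for u in units if u.n_peaks >= min_peaks]
    if min_samples is not None:
        out = [u for u in out if u.n_samples >= min_samples]
    return out


def drop_singletons(units: list[OperationalUnit]) -> list[OperationalUnit]:
    """Remove units backed by exactly one member peak."""
    return [u for u in units if u.n_peaks > 1]


def unit_table(units: list[OperationalUnit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "representative_mz": [u.representative_mz for u in units],
            "n_peaks": [u.n_peaks for u in units],
            "n_samples": [u.n_samples for u in units],
        }
    )


def intensity_matrix(
    units: list[OperationalUnit],
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Wide samples x units abundance table (summed member intensities)."""
    if sample_ids is None:
        seen: dict[str, None] = {}
        for u in units:
            for sid in u.sample_ids.tolist():
                seen.setdefault(sid)
        sample_ids = sorted(seen)
    data = np.zeros((len(sample_ids), len(units)))
    row = {sid: k for k, sid in enumerate(sample_ids)}
    for j, u in enumerate(units):
        for sid, inten in u.intensity_by_sample().items():
            if sid in row:
                data[row[sid], j] = inten
    return pd.DataFrame(
        data, index=pd.Index(sample_ids, name="sample_id"),
        columns=[u.unit_id for u in units],
    )
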