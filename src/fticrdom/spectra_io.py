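"""Reading, filtering, and writing per-sample peak lists.

A peak list is delimited text with at least ``mz`` and ``intensity`` columns
(``snr`` optional, defaulting to +inf).  Spectra are held as sorted numpy
arrays inside a :class:`SampleSpectrum`; the signal-to-noise filter, blank
subtraction, and an optional linear ppm recalibration hook operate on that
contract.  An mzML reader (centroided spectra, via pyteomics) feeds the same
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampleSpectrum",
    "PeakListFormatError",
    "read_peaklist",
    "write_peaklist",
    "read_mzml",
    "filter_snr",
    "subtract_blanks",
    "recalibrate",
    "RecalibrationResult",
]


class PeakListFormatError(ValueError):
    """A peak list file is malformed; ``.rows`` lists offending line numbers."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


@dataclass
class SampleSpectrum:
    """One sample's centroided peak list, sorted ascending by m/z."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (len(self.mz) == len(self.intensity) == len(self.snr)):
            raise ValueError("mz, intensity, snr must have equal length")
        if np.any(~np.isfinite(self.mz)) or np.any(self.mz <= 0):
            raise ValueError("m/z values must be finite and positive")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self.snr = self.snr[order]

    @property
    def n_peaks(self) -> int:
        return len(self.mz)

    @property
    def is_blank(self) -> bool:
        return bool(self.metadata.get("blank", False))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mz": self.mz, "intensity": self.intensity, "snr": self.snr}
        )


def read_peaklist(
    path: str | Path,
    sample_id: str | None = None,
    columns: dict[str, str] | None = None,
    sep: str | None = None,
    metadata: dict | None = None,
) -> SampleSpectrum:
    """Read a delimited peak list into a sorted :class:`SampleSpectrum`.

    ``columns`` remaps instrument-export column names onto the canonical
    ``mz``/``intensity``/``snr``.  Malformed rows (non-numeric or
    non-positive m/z or intensity) are collected and reported together with
    their line numbers rather than silently dropped.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    colmap = {"mz": "mz", "intensity": "intensity", "snr": "snr"}
    if columns:
        colmap.update(columns)
    for canonical in ("mz", "intensity"):
        if colmap[canonical] not in df.columns:
            raise PeakListFormatError(
                f"{path}: required column {colmap[canonical]!r} not found "
                f"(columns: {list(df.columns)})"
            )
    mz = pd.to_numeric(df[colmap["mz"]], errors="coerce")
    intensity = pd.to_numeric(df[colmap["intensity"]], errors="coerce")
    if colmap["snr"] in df.columns:
        snr = pd.to_numeric(df[colmap["snr"]], errors="coerce")
    else:
        snr = pd.Series(np.inf, index=df.index)
    bad = mz.isna() | intensity.isna() | (mz <= 0) | (intensity <= 0) | snr.isna()
    if bad.any():
        # +2: header line plus 1-based numbering
        rows = [int(i) + 2 for i in df.index[bad]]
        raise PeakListFormatError(
            f"{path}: {bad.sum()} malformed row(s) at line(s) {rows}", rows=rows
        )
    return SampleSpectrum(
        sample_id=sample_id or path.stem,
        mz=mz.to_numpy(),
        intensity=intensity.to_numpy(),
        snr=snr.to_numpy(),
        metadata=metadata or {},
    )


def write_peaklist(spectrum: SampleSpectrum, path: str | Path, sep: str | None = None) -> None:
    """Write a spectrum in the same dialect :func:`read_peaklist` reads,
    at full float precision (round-trip safe)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    spectrum.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_mzml(path: str | Path, sample_id: str | None = None, metadata: dict | None = None) -> SampleSpectrum:
    """Read centroided peaks from an mzML file (all MS1 spectra pooled).

    mzML carries no per-peak signal-to-noise estimate, so snr is +inf and the
    S/N filter becomes a no-op unless the caller supplies one.
    """
    from pyteomics import mzml as _mzml

    mzs, intens = [], []
    with _mzml.MzML(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            mzs.append(np.asarray(spec["m/z array"], dtype=float))
            intens.append(np.asarray(spec["intensity array"], dtype=float))
    if not mzs:
        raise PeakListFormatError(f"{path}: no MS1 spectra found")
    mz = np.concatenate(mzs)
    intensity = np.concatenate(intens)
    keep = intensity > 0
    return SampleSpectrum(
        sample_id=sample_id or Path(path).stem,
        mz=mz[keep],
        intensity=intensity[keep],
        snr=np.full(keep.sum(), np.inf),
        metadata=metadata or {},
    )


def filter_snr(spectrum: SampleSpectrum, threshold: float = 5.0) -> SampleSpectrum:
    """Keep peaks with signal-to-noise strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = spectrum.snr > threshold
    return replace(
        spectrum,
        mz=spectrum.mz[keep],
        intensity=spectrum.intensity[keep],
        snr=spectrum.snr[keep],
    )


def subtract_blanks(
    samples: list[SampleSpectrum],
    blanks: list[SampleSpectrum],
    tolerance_rel: float = 1e-6,
) -> list[SampleSpectrum]:
    """Remove sample peaks whose m/z matches any blank peak within a
    relative tolerance (default the clustering tolerance, 1e-6)."""
    if not blanks:
        warnings.warn("no blank spectra provided; blank subtraction is a no-op")
        return list(samples)
    blank_mz = np.sort(np.concatenate([b.mz for b in blanks]))
    out = []
    for spec in samples:
        idx = np.searchsorted(blank_mz, spec.mz)
        matched = np.zeros(spec.n_peaks, dtype=bool)
        for shift in (-1, 0):
            j = np.clip(idx + shift, 0, len(blank_mz) - 1)
            matched |= np.abs(spec.mz - blank_mz[j]) < tolerance_rel * blank_mz[j]
        out.append(
            replace(
                spec,
                mz=spec.mz[~matched],
                intensity=spec.intensity[~matched],
                snr=spec.snr[~matched],
            )
        )
    return out


@dataclass
class RecalibrationResult:
    spectrum: SampleSpectrum
    slope: float
    intercept: float
    residual_ppm: np.ndarray


def recalibrate(
    spectrum: SampleSpectrum,
    reference_pairs: list[tuple[float, float]],
) -> RecalibrationResult:
    """Least-squares linear mass recalibration mz' = a*mz + b.

    ``reference_pairs`` are (observed, true) m/z pairs from internal
    calibrants; at least two distinct observed values are required.  This is
    a deliberately simple hook — instrument-specific segmented calibration is
    out of scope — and residual ppm errors at the references are reported so
    the fit quality is visible.
    """
    pairs = np.asarray(reference_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2 or pairs.shape[1] != 2:
        raise ValueError("need >= 2 (observed, true) reference pairs")
    obs, true = pairs[:, 0], pairs[:, 1]
    if np.ptp(obs) == 0:
        raise ValueError("reference observed m/z are colinear (all equal); cannot fit")
    a, b = np.polyfit(obs, true, deg=1)
    fitted = a * obs + b
    residual_ppm = (fitted - true) / true * 1e6
    return RecalibrationResult(
        spectrum=replace(spectrum, mz=a * spectrum.mz + b),
        slope=float(a),
        intercept=float(b),
        residual_ppm=residual_ppm,
    )


def qc_counts(stages: dict[str, list[SampleSpectrum]]) -> pd.DataFrame:
    """Per-sample peak counts across named filter stages (the QC funnel)."""
    rows: dict[str, dict[str, int]] = {}
    for stage, spectra in stages.items():
        for spec in spectra:
            rows.setdefault(spec.sample_id, {})[stage] = spec.n_peaks
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")
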