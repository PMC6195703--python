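"""Ground-truth synthetic DOM datasets.

Emulates negative-mode direct-infusion FT-ICR-MS of dissolved organic
matter: a pool of valid CHONPS formulas is rendered as [M-H]- monoisotopic
peaks with 13C isotopologue satellites at natural abundance (intensity ratio
C x 1.07%, the linear small-abundance model) and 34S satellites where sulfur
is present, degraded by ppm-scale mass jitter, lognormal intensity noise,
spurious noise peaks, and blank contamination.  Every emitted peak's
provenance (formula, isotopologue label, noise, blank) is recorded in a
truth table, so recovery of the annotation pipeline is computable exactly.

What this generator does NOT emulate: instrument resolution and peak shape,
space-charge effects, adducts other than deprotonation, and multiply
charged species.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import OperationalUnit
from .annotation import Annotation, ROUTE_ISOTOPE, mz_of
from .chem_core import (
    DEFAULT_BOUNDS,
    ELEMENTS,
    MolecularFormula,
    monoisotopic_mass,
    validate_formula,
    within_bounds,
)
from .classification import CATEGORIES, classify
from .spectra_io import SampleSpectrum

__all__ = [
    "SyntheticDesign",
    "StudyData",
    "sample_formula_pool",
    "render_spectrum",
    "render_study",
    "recovery_report",
]

#: Natural 34S/32S abundance ratio (4.25% / 95.0%).
S34_RATIO = 0.0447

#: DOM-like default category mix (highly unsaturated compounds dominate).
DEFAULT_CATEGORY_MIX = {
    "phenolic_highly_unsaturated": 0.30,
    "unsaturated_aliphatic": 0.20,
    "saturated_carbohydrate_like": 0.15,
    "peptide_like": 0.15,
    "polyphenol": 0.10,
    "polycyclic_aromatic": 0.10,
}


@dataclass
class SyntheticDesign:
    """Study-level generator settings.

    The defaults define the standard benchmark: 100 formulas over
    150-700 Da, two groups of six samples, 0.5 ppm mass jitter, exact
    isotope intensity ratios, lognormal between-sample intensity noise,
    0.2 noise peaks per Da, five blank-contaminant formulas in two blanks.
    """

    seed: int
    n_formulas: int = 100
    mass_range: tuple[float, float] = (150.0, 700.0)
    category_mix: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    groups: dict[str, int] = field(default_factory=lambda: {"A": 6, "B": 6})
    category_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"A": {"peptide_like": 2.0}, "B": {}}
    )
    mass_jitter_ppm: float = 0.5
    intensity_sd: float = 0.8          # lognormal sigma of between-sample noise
    isotope_ratio_sd: float = 0.0      # 0 = exact natural-abundance ratios
    base_intensity: float = 1e5        # lognormal median of formula base abundance
    base_sigma: float = 0.8
    noise_floor: float = 10.0          # snr = intensity / noise_floor for true peaks
    noise_peaks_per_da: float = 0.2
    n_blank_formulas: int = 5
    n_blanks: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("mass_jitter_ppm", "intensity_sd", "isotope_ratio_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def sample_formula_pool(
    n: int,
    seed: int,
    mass_range: tuple[float, float] = (150.0, 700.0),
    category_mix: dict[str, float] | None = None,
    bounds: dict[str, tuple[int, int]] | None = None,
    max_attempts_per_formula: int = 5000,
) -> pd.DataFrame:
    """Rejection-sample ``n`` distinct valid formulas in a mass window.

    With ``category_mix`` the pool hits the requested per-category counts
    (fractions rounded to integers); without it the natural mix of accepted
    draws is kept.  Deterministic under ``seed``.  Raises when a requested
    category cannot be produced within the attempt budget (e.g. peptides
    with the N bound forced to zero).
    """
    if n < 1:
        raise ValueError("requested pool size must be >= 1")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    rng = np.random.default_rng(seed)
    quotas: Counter[str] | None = None
    if category_mix is not None:
        unknown = set(category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(category_mix.values())
        quotas = Counter()
        for cat, frac in category_mix.items():
            quotas[cat] = round(n * frac / total)
        # fix rounding drift on the largest quota
        drift = n - sum(quotas.values())
        quotas[max(quotas, key=quotas.get)] += drift

    chosen: dict[MolecularFormula, str] = {}
    lo, hi = mass_range
    attempts = 0
    budget = max_attempts_per_formula * n
    while len(chosen) < n:
        attempts += 1
        if attempts > budget:
            missing = {c: k for c, k in (quotas or {}).items() if k > 0}
            raise ValueError(
                f"could not satisfy the requested pool within {budget} draws; "
                f"unmet categories: {missing or 'n/a'} (infeasible mix or bounds?)"
            )
        c = int(rng.integers(max(4, b["c"][0]), min(45, b["c"][1]) + 1))
        nn = int(rng.choice(5, p=[0.45, 0.2, 0.15, 0.12, 0.08]))
        nn = min(nn, b["n"][1])
        p = int(rng.integers(b["p"][0], b["p"][1] + 1)) if rng.random() < 0.1 else 0
        s = int(rng.integers(b["s"][0], b["s"][1] + 1)) if rng.random() < 0.15 else 0
        h_lo = max(b["h"][0], int(np.ceil(c / 3)))
        h_hi = min(b["h"][1], 2 * c + nn + p + 2)
        if h_lo > h_hi:
            continue
        h = int(rng.integers(h_lo, h_hi + 1))
        if (nn + h + p) % 2 != 0:
            h += 1 if h < h_hi else -1
        o_hi = min(b["o"][1], c + 2 * nn + 3 * p)
        o = int(rng.integers(max(b["o"][0], p - s, 0), o_hi + 1))
        f = MolecularFormula(c=c, h=h, o=o, n=nn, p=p, s=s)
        ok, _ = validate_formula(f)
        if not ok or not within_bounds(f, b) or f in chosen:
            continue
        if not lo <= monoisotopic_mass(f) <= hi:
            continue
        cat = classify(f)
        if quotas is not None:
            if quotas.get(cat, 0) <= 0:
                continue
            quotas[cat] -= 1
        chosen[f] = cat

    rows = [
        {
            "formula": str(f),
            "category": cat,
            "mass": monoisotopic_mass(f),
            "c": f.c, "h": f.h, "o": f.o, "n": f.n, "p": f.p, "s": f.s,
        }
        for f, cat in chosen.items()
    ]
    return pd.DataFrame(rows).sort_values("mass", ignore_index=True)


def _emit_peak(rng, mz_theoretical: float, jitter_ppm: float) -> float:
    return mz_theoretical * (1.0 + rng.normal(0.0, jitter_ppm * 1e-6))


def render_spectrum(
    pool: pd.DataFrame,
    abundances: np.ndarray,
    design: SyntheticDesign,
    sample_id: str,
    rng: np.random.Generator,
    c13_abundance: float = ELEMENTS.c13_abundance,
    kind_suffix: str = "",
) -> tuple[SampleSpectrum, pd.DataFrame]:
    """Render one sample: [M-H]- monoisotopic peaks, 13C satellites at
    C x abundance ratio, 34S satellites for S-bearing formulas, plus
    spurious noise peaks.  Returns the spectrum and its truth rows."""
    d13c = ELEMENTS.isotope_shifts["13C"]
    d34s = ELEMENTS.isotope_shifts["34S"]
    mzs: list[float] = []
    intens: list[float] = []
    snrs: list[float] = []
    truth: list[dict] = []

    def add(mz, inten, formula, kind, snr=None):
        if snr is None:
            snr = inten / design.noise_floor
        mzs.append(mz)
        intens.append(inten)
        snrs.append(snr)
        truth.append(
            {"sample_id": sample_id, "mz": mz, "intensity": inten, "snr": snr,
             "formula": formula, "kind": kind}
        )

    for row, abundance in zip(pool.itertuples(index=False), abundances):
        if abundance <= 0:
            continue
        ion = mz_of(row.mass)
        add(_emit_peak(rng, ion, design.mass_jitter_ppm), float(abundance),
            row.formula, "mono" + kind_suffix)
        ratio = row.c * c13_abundance
        if design.isotope_ratio_sd > 0:
            ratio *= float(np.exp(rng.normal(0.0, design.isotope_ratio_sd)))
        add(_emit_peak(rng, ion + d13c, design.mass_jitter_ppm),
            float(abundance) * ratio, row.formula, "13C" + kind_suffix)
        if row.s >= 1:
            add(_emit_peak(rng, ion + d34s, design.mass_jitter_ppm),
                float(abundance) * row.s * S34_RATIO, row.formula, "34S" + kind_suffix)

    lo, hi = design.mass_range
    n_noise = int(rng.poisson(design.noise_peaks_per_da * (hi - lo)))
    for _ in range(n_noise):
        add(
            float(rng.uniform(mz_of(lo), mz_of(hi))),
            float(rng.lognormal(np.log(20 * design.noise_floor), 1.0)),
            "", "noise",
            snr=float(rng.uniform(1.0, 8.0)),
        )
    spectrum = SampleSpectrum(
        sample_id=sample_id,
        mz=np.array(mzs),
        intensity=np.array(intens),
        snr=np.array(snrs),
        metadata={"blank": kind_suffix == "_blank"},
    )
    return spectrum, pd.DataFrame(truth)


@dataclass
class StudyData:
    """A rendered multi-sample study plus its complete ground truth."""

    samples: list[SampleSpectrum]
    blanks: list[SampleSpectrum]
    truth_formulas: pd.DataFrame     # formula, category, mass, element counts
    truth_peaks: pd.DataFrame        # per-peak provenance
    truth_abundances: pd.DataFrame   # samples x formulas (pre-noise abundances)
    sample_groups: dict[str, str]
    design: SyntheticDesign


def render_study(design: SyntheticDesign) -> StudyData:
    """Render a full multi-group study from a :class:`SyntheticDesign`.

    Per-sample abundances are base lognormal (one draw per formula) times
    lognormal sample noise times the group's per-category multiplier.
    Blank-contaminant formulas are rendered into the blanks and spiked into
    every sample.  All truth tables are returned alongside the data.
    """
    rng = np.random.default_rng(design.seed)
    pool = sample_formula_pool(
        design.n_formulas,
        seed=int(rng.integers(2**31)),
        mass_range=design.mass_range,
        category_mix=design.category_mix,
    )
    blank_pool = (
        sample_formula_pool(
            design.n_blank_formulas,
            seed=int(rng.integers(2**31)),
            mass_range=design.mass_range,
            category_mix=None,
        )
        if design.n_blank_formulas > 0
        else pool.iloc[0:0]
    )
    base = design.base_intensity * rng.lognormal(0.0, design.base_sigma, len(pool))
    blank_base = design.base_intensity * rng.lognormal(
        0.0, design.base_sigma, len(blank_pool)
    )

    samples: list[SampleSpectrum] = []
    truth_rows: list[pd.DataFrame] = []
    abundance_rows: dict[str, np.ndarray] = {}
    sample_groups: dict[str, str] = {}
    for group, n_samples in design.groups.items():
        mult = design.category_multipliers.get(group, {})
        cat_mult = pool["category"].map(lambda c: mult.get(c, 1.0)).to_numpy()
        for i in range(n_samples):
            sid = f"{group}{i + 1:02d}"
            sample_groups[sid] = group
            abund = base * cat_mult * rng.lognormal(0.0, design.intensity_sd, len(pool))
            abundance_rows[sid] = abund
            spec, truth = render_spectrum(pool, abund, design, sid, rng)
            if len(blank_pool):
                blank_abund = blank_base * rng.lognormal(
                    0.0, design.intensity_sd, len(blank_pool)
                )
                bspec, btruth = render_spectrum(
                    blank_pool, blank_abund, design, sid, rng, kind_suffix="_blankcontam"
                )
                keep = btruth["kind"] != "noise"  # noise already added with the sample
                spec = SampleSpectrum(
                    sample_id=sid,
                    mz=np.concatenate([spec.mz, bspec.mz[keep.to_numpy()]]),
                    intensity=np.concatenate(
                        [spec.intensity, bspec.intensity[keep.to_numpy()]]
                    ),
                    snr=np.concatenate([spec.snr, bspec.snr[keep.to_numpy()]]),
                )
                truth = pd.concat([truth, btruth[keep]], ignore_index=True)
            samples.append(spec)
            truth_rows.append(truth)

    blanks: list[SampleSpectrum] = []
    for j in range(design.n_blanks):
        bid = f"blank{j + 1:02d}"
        if len(blank_pool):
            blank_abund = blank_base * rng.lognormal(
                0.0, design.intensity_sd, len(blank_pool)
            )
            bspec, btruth = render_spectrum(
                blank_pool, blank_abund, design, bid, rng, kind_suffix="_blank"
            )
            blanks.append(bspec)
            truth_rows.append(btruth)

    truth_peaks = pd.concat(truth_rows, ignore_index=True)
    truth_abundances = pd.DataFrame(
        abundance_rows, index=pool["formula"]
    ).T.rename_axis("sample_id")
    return StudyData(
        samples=samples,
        blanks=blanks,
        truth_formulas=pool,
        truth_peaks=truth_peaks,
        truth_abundances=truth_abundances,
        sample_groups=sample_groups,
        design=design,
    )


def recovery_report(
    study: StudyData,
    units: list[OperationalUnit],
    annotations: dict[int, Annotation],
) -> dict:
    """Score annotation output against generator truth.

    A truth formula is *recoverable* when some post-filter unit's member
    peaks are, by majority, that formula's monoisotopic peaks; it is
    *recovered* when that unit was annotated with exactly that formula.
    Also reports the fraction of isotope-verified assignments that are
    correct and whose C_dev lies inside the acceptance interval.
    """
    provenance = {
        (r.sample_id, r.mz): (r.formula, r.kind)
        for r in study.truth_peaks.itertuples(index=False)
    }
    unit_mode: dict[int, tuple[str, str]] = {}
    for u in units:
        tags = [
            provenance.get((sid, mz))
            for sid, mz in zip(u.sample_ids.tolist(), u.mzs.tolist())
        ]
        tags = [t for t in tags if t is not None]
        if tags:
            unit_mode[u.unit_id] = Counter(tags).most_common(1)[0][0]

    mono_unit_of: dict[str, int] = {}
    for uid, (formula, kind) in unit_mode.items():
        if kind == "mono" and formula:
            # prefer the larger unit if a formula maps to several
            prev = mono_unit_of.get(formula)
            if prev is None:
                mono_unit_of[formula] = uid
    truth_set = set(study.truth_formulas["formula"])
    recoverable = [f for f in truth_set if f in mono_unit_of]
    recovered = []
    iso_total = iso_correct = iso_cdev_ok = 0
    lo, hi = (-3.0, 1.0)
    for f in recoverable:
        ann = annotations.get(mono_unit_of[f])
        if ann is not None and ann.formula is not None and str(ann.formula) == f:
            recovered.append(f)
    for uid, ann in annotations.items():
        if ann.route == ROUTE_ISOTOPE and ann.formula is not None:
            iso_total += 1
            if lo < (ann.c_dev if ann.c_dev is not None else np.inf) < hi:
                iso_cdev_ok += 1
            mode = unit_mode.get(uid)
            if mode is not None and mode[1].startswith("mono") and mode[0] == str(ann.formula):
                iso_correct += 1
    return {
        "n_truth_formulas": len(truth_set),
        "n_recoverable": len(recoverable),
        "n_recovered": len(recovered),
        "recovery_rate": len(recovered) / len(recoverable) if recoverable else np.nan,
        "n_isotope_verified": iso_total,
        "isotope_verified_correct_rate": iso_correct / iso_total if iso_total else np.nan,
        "cdev_within_bounds_rate": iso_cdev_ok / iso_total if iso_total else np.nan,
    }
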