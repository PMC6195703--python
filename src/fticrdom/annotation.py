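"""Molecular formula assignment to operational units.

The assignment route mirrors the carbon-isotope verification workflow:

1.  For each unit, candidate formulas are enumerated inside the element
    bounds C1-100 H1-150 O0-50 N0-4 P0-1 S0-1 under the twelve exclusion
    rules, within a ppm tolerance of the unit's neutral mass.
2.  The carbon number is estimated from the 13C isotopologue satellite:
    c_est = (I_iso / I_mono) / 0.0107.  The candidate whose carbon count
    deviates least from c_est (smallest |C_dev|) is accepted when C_dev lies
    strictly inside (-3, 1).
3.  Isotope-verified formulas become scaffolds; unassigned units whose mass
    differs from a scaffold by one chemical building block (CH2, H2O, CO2,
    ...) inherit the block-shifted formula, breadth-first up to ``max_hops``.
4.  Isotopologue satellites (13C, 15N, 34S, 33S, 18O, 17O, 2H, 13C2, 13C3,
    13C34S) of annotated units are labelled and excluded from the molecule
    inventory.

All ions are deprotonated molecules [M-H]- (the DOM negative-ESI
convention); the electron mass is accounted for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import OperationalUnit
from .chem_core import (
    BUILDING_BLOCKS,
    DEFAULT_BOUNDS,
    ELEMENTS,
    BuildingBlock,
    ElementTable,
    MolecularFormula,
    apply_block,
    monoisotopic_mass,
    validate_formula,
)

__all__ = [
    "AnnotationConfig",
    "FormulaCandidate",
    "Annotation",
    "isotopologue_table",
    "neutral_mass",
    "mz_of",
    "enumerate_formulas",
    "estimate_carbon_number",
    "select_formula",
    "propagate_blocks",
    "label_isotopologues",
    "annotate_dataset",
]

ROUTE_ISOTOPE = "isotope_verified"
ROUTE_BLOCK = "building_block"
ROUTE_UNASSIGNED = "unassigned"


def isotopologue_table(table: ElementTable = ELEMENTS) -> dict[str, float]:
    """Isotopologue label -> mass shift (Da); composite shifts are exact
    sums of their components."""
    s = table.isotope_shifts
    return {
        "13C": s["13C"],
        "15N": s["15N"],
        "34S": s["34S"],
        "33S": s["33S"],
        "18O": s["18O"],
        "17O": s["17O"],
        "2H": s["2H"],
        "13C2": 2 * s["13C"],
        "13C3": 3 * s["13C"],
        "13C34S": s["13C"] + s["34S"],
    }


#: Minimum element counts a parent formula needs to exhibit each satellite.
_ISOTOPOLOGUE_GATES: dict[str, tuple[tuple[str, int], ...]] = {
    "13C": (("c", 1),),
    "15N": (("n", 1),),
    "34S": (("s", 1),),
    "33S": (("s", 1),),
    "18O": (("o", 1),),
    "17O": (("o", 1),),
    "2H": (("h", 1),),
    "13C2": (("c", 2),),
    "13C3": (("c", 3),),
    "13C34S": (("c", 1), ("s", 1)),
}


@dataclass
class AnnotationConfig:
    """Tolerances and thresholds of the annotation pipeline.

    tolerance_ppm     candidate-enumeration mass tolerance (ppm of neutral mass)
    tolerance_rel     relative m/z tolerance for satellite / block matching
    c_dev_bounds      open interval of acceptable C_dev
    c13_abundance     natural 13C/12C abundance ratio
    max_hops          building-block propagation rounds
    ion_mode          only "[M-H]-" is supported
    aggregation       'sum' pools intensities over shared samples for the
                      isotope ratio; 'median' takes the per-sample median ratio
    """

    tolerance_ppm: float = 1.0
    tolerance_rel: float = 1e-6
    c_dev_bounds: tuple[float, float] = (-3.0, 1.0)
    c13_abundance: float = ELEMENTS.c13_abundance
    max_hops: int = 3
    ion_mode: str = "[M-H]-"
    aggregation: str = "sum"
    bounds: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def to_dict(self) -> dict:
        return {
            "tolerance_ppm": self.tolerance_ppm,
            "tolerance_rel": self.tolerance_rel,
            "c_dev_bounds": list(self.c_dev_bounds),
            "c13_abundance": self.c13_abundance,
            "max_hops": self.max_hops,
            "ion_mode": self.ion_mode,
            "aggregation": self.aggregation,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }


@dataclass(frozen=True)
class FormulaCandidate:
    formula: MolecularFormula
    theoretical_mass: float      # neutral monoisotopic mass, Da
    mass_error_ppm: float        # signed, observed vs theoretical
    c_dev: float | None = None


@dataclass
class Annotation:
    """A formula bound to an operational unit, with its verification route."""

    unit_id: int
    formula: MolecularFormula | None
    route: str = ROUTE_UNASSIGNED
    mass_error_ppm: float | None = None
    c_dev: float | None = None
    scaffold_unit_id: int | None = None
    block_path: tuple[str, ...] = ()
    isotopologue_links: list[tuple[str, int]] = field(default_factory=list)


def neutral_mass(mz: float, ion_mode: str = "[M-H]-", table: ElementTable = ELEMENTS) -> float:
    """Neutral monoisotopic mass from an observed ion m/z.

    For a deprotonated molecule, M = mz + m(H) - m(e-): the ion has lost a
    proton but keeps the extra electron's mass.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if ion_mode != "[M-H]-":
        raise ValueError(f"unsupported ion mode {ion_mode!r}")
    return mz + table.elements["H"] - table.electron


def mz_of(neutral: float, ion_mode: str = "[M-H]-", table: ElementTable = ELEMENTS) -> float:
    """Inverse of :func:`neutral_mass` (round-trips to < 1e-9 Da)."""
    if ion_mode != "[M-H]-":
        raise ValueError(f"unsupported ion mode {ion_mode!r}")
    return neutral - table.elements["H"] + table.electron


def enumerate_formulas(
    neutral: float,
    tolerance_ppm: float = 1.0,
    bounds: dict[str, tuple[int, int]] | None = None,
    table: ElementTable = ELEMENTS,
) -> list[FormulaCandidate]:
    """All valid formulas within ``tolerance_ppm`` of a neutral mass.

    Exactly the set of formulas inside the element bounds that pass the
    twelve exclusion rules, sorted by |mass error| then lexicographically.
    Loops run over S, P, N, O with the C count bracketing the residual mass
    and H solved from the remainder, so the cost is far below the full grid.
    """
    if not 0 < neutral <= 2000:
        raise ValueError("neutral mass must lie in (0, 2000] Da")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    e = table.elements
    mC, mH, mO, mN, mP, mS = (e[x] for x in "CHONPS")
    tol = neutral * tolerance_ppm * 1e-6
    out: list[FormulaCandidate] = []
    for s in range(b["s"][0], b["s"][1] + 1):
        for p in range(b["p"][0], b["p"][1] + 1):
            for n in range(b["n"][0], b["n"][1] + 1):
                base = s * mS + p * mP + n * mN
                o_max = min(b["o"][1], int((neutral + tol - base - mC - mH) / mO))
                for o in range(b["o"][0], o_max + 1):
                    rem_o = neutral - base - o * mO
                    c_hi = min(b["c"][1], int((rem_o + tol - mH) / mC))
                    for c in range(b["c"][0], c_hi + 1):
                        rem = rem_o - c * mC
                        h_mid = rem / mH
                        for h in {math.floor(h_mid), math.ceil(h_mid)}:
                            if not b["h"][0] <= h <= b["h"][1]:
                                continue
                            mass = base + o * mO + c * mC + h * mH
                            if abs(mass - neutral) > tol:
                                continue
                            f = MolecularFormula(c=c, h=h, o=o, n=n, p=p, s=s)
                            ok, _ = validate_formula(f)
                            if not ok:
                                continue
                            err_ppm = (neutral - mass) / mass * 1e6
                            out.append(FormulaCandidate(f, mass, err_ppm))
    out.sort(key=lambda cand: (abs(cand.mass_error_ppm), cand.formula))
    return out


def _find_unit_at(
    target_mz: float,
    rep_mz: np.ndarray,
    tolerance_rel: float,
) -> int | None:
    """Index of the unit nearest to ``target_mz`` within relative tolerance,
    or None."""
    i = int(np.searchsorted(rep_mz, target_mz))
    best, best_d = None, np.inf
    for j in (i - 1, i):
        if 0 <= j < len(rep_mz):
            d = abs(rep_mz[j] - target_mz)
            if d < tolerance_rel * target_mz and d < best_d:
                best, best_d = j, d
    return best


def estimate_carbon_number(
    unit: OperationalUnit,
    all_units: list[OperationalUnit],
    tolerance_rel: float = 1e-6,
    c13_abundance: float = ELEMENTS.c13_abundance,
    aggregation: str = "sum",
    table: ElementTable = ELEMENTS,
    _sorted_reps: np.ndarray | None = None,
    _sorted_index: list[int] | None = None,
) -> float | None:
    """Carbon-number estimate from the 13C satellite intensity ratio.

    Looks for a unit at ``representative_mz + delta(13C)``; returns
    ``(I_iso / I_mono) / abundance`` with intensities pooled over the
    samples shared by the two units (``aggregation='sum'``) or the median of
    per-sample ratios (``'median'``).  ``None`` when no satellite unit is
    found or the shared monoisotopic intensity is zero.
    """
    if _sorted_reps is None:
        order = sorted(range(len(all_units)), key=lambda k: all_units[k].representative_mz)
        _sorted_reps = np.array([all_units[k].representative_mz for k in order])
        _sorted_index = order
    target = unit.representative_mz + table.isotope_shifts["13C"]
    j = _find_unit_at(target, _sorted_reps, tolerance_rel)
    if j is None:
        return None
    iso_unit = all_units[_sorted_index[j]]
    mono_by = unit.intensity_by_sample()
    iso_by = iso_unit.intensity_by_sample()
    shared = sorted(set(mono_by) & set(iso_by))
    if not shared:
        return None
    if aggregation == "sum":
        i_mono = sum(mono_by[s] for s in shared)
        i_iso = sum(iso_by[s] for s in shared)
        if i_mono == 0:
            return None
        return (i_iso / i_mono) / c13_abundance
    elif aggregation == "median":
        ratios = [iso_by[s] / mono_by[s] for s in shared if mono_by[s] > 0]
        if not ratios:
            return None
        return float(np.median(ratios)) / c13_abundance
    raise ValueError(f"unknown aggregation {aggregation!r}")


def select_formula(
    candidates: list[FormulaCandidate],
    c_est: float,
    c_dev_bounds: tuple[float, float] = (-3.0, 1.0),
) -> FormulaCandidate | None:
    """Pick the candidate with the smallest |C_dev| among those whose
    C_dev = C - c_est lies strictly inside the open acceptance interval.

    Ties break on smallest |mass error| then lexicographic formula.  Returns
    None (unassigned) when no candidate survives.
    """
    lo, hi = c_dev_bounds
    survivors = []
    for cand in candidates:
        c_dev = cand.formula.c - c_est
        if lo < c_dev < hi:
            survivors.append(replace(cand, c_dev=c_dev))
    if not survivors:
        return None
    return min(
        survivors,
        key=lambda cand: (abs(cand.c_dev), abs(cand.mass_error_ppm), cand.formula),
    )


def propagate_blocks(
    annotations: dict[int, Annotation],
    units: list[OperationalUnit],
    blocks: tuple[BuildingBlock, ...] = BUILDING_BLOCKS,
    tolerance_rel: float = 1e-6,
    tolerance_ppm: float = 1.0,
    max_hops: int = 3,
    ion_mode: str = "[M-H]-",
    bounds: dict[str, tuple[int, int]] | None = None,
) -> dict[int, Annotation]:
    """Extend annotations to neighbouring units one building block away.

    Breadth-first over at most ``max_hops`` rounds; each round only uses
    scaffolds annotated before the round started, so the result does not
    depend on unit processing order.  When several scaffolds propose
    formulas for one unit, the winner has the smallest |mass error|, then
    the most proposing scaffolds (majority vote), then the lexicographically
    smallest formula.  Returns the new annotations (route='building_block').
    """
    by_id = {u.unit_id: u for u in units}
    order = sorted(by_id, key=lambda uid: by_id[uid].representative_mz)
    rep = np.array([by_id[uid].representative_mz for uid in order])
    new_annotations: dict[int, Annotation] = {}
    current = dict(annotations)

    for _ in range(max_hops):
        scaffold_ids = [
            uid for uid, ann in current.items()
            if ann.formula is not None and uid in by_id
        ]
        # candidate proposals per unannotated unit
        proposals: dict[int, list[tuple[float, MolecularFormula, int, str]]] = {}
        for sid in scaffold_ids:
            ann = current[sid]
            base_mz = by_id[sid].representative_mz
            for block in blocks:
                for sign in (1, -1):
                    derived = apply_block(ann.formula, block, sign, bounds=bounds or DEFAULT_BOUNDS)
                    if derived is None:
                        continue
                    target = base_mz + sign * block.mass
                    if target <= 0:
                        continue
                    j = _find_unit_at(target, rep, tolerance_rel)
                    if j is None:
                        continue
                    uid = order[j]
                    if uid in current and current[uid].formula is not None:
                        continue
                    unit_neutral = neutral_mass(by_id[uid].representative_mz, ion_mode)
                    theo = monoisotopic_mass(derived)
                    err_ppm = (unit_neutral - theo) / theo * 1e6
                    if abs(err_ppm) > tolerance_ppm:
                        continue
                    label = f"{'+' if sign > 0 else '-'}{block.name}"
                    proposals.setdefault(uid, []).append((err_ppm, derived, sid, label))
        if not proposals:
            break
        for uid, cands in proposals.items():
            votes: dict[MolecularFormula, int] = {}
            for _, f, _, _ in cands:
                votes[f] = votes.get(f, 0) + 1
            err_ppm, formula, sid, label = min(
                cands, key=lambda t: (abs(t[0]), -votes[t[1]], t[1])
            )
            parent = current[sid]
            ann = Annotation(
                unit_id=uid,
                formula=formula,
                route=ROUTE_BLOCK,
                mass_error_ppm=err_ppm,
                scaffold_unit_id=sid if not parent.block_path else parent.scaffold_unit_id,
                block_path=parent.block_path + (label,),
            )
            current[uid] = ann
            new_annotations[uid] = ann
    return new_annotations


def label_isotopologues(
    units: list[OperationalUnit],
    annotations: dict[int, Annotation],
    table: dict[str, float] | None = None,
    tolerance_rel: float = 1e-6,
) -> set[int]:
    """Attach isotopologue links to annotated units and return the set of
    satellite unit ids (excluded from the molecule inventory).

    A link requires the parent formula to contain the substituted element(s)
    (a 34S satellite needs S >= 1, 13C3 needs C >= 3, ...) and the satellite
    unit must not itself carry a monoisotopic formula annotation.
    """
    shifts = table or isotopologue_table()
    by_id = {u.unit_id: u for u in units}
    order = sorted(by_id, key=lambda uid: by_id[uid].representative_mz)
    rep = np.array([by_id[uid].representative_mz for uid in order])
    linked: set[int] = set()
    for uid, ann in annotations.items():
        if ann.formula is None or uid not in by_id:
            continue
        base = by_id[uid].representative_mz
        for label, shift in shifts.items():
            gates = _ISOTOPOLOGUE_GATES[label]
            if any(getattr(ann.formula, el) < k for el, k in gates):
                continue
            j = _find_unit_at(base + shift, rep, tolerance_rel)
            if j is None:
                continue
            partner = order[j]
            if partner == uid:
                continue
            partner_ann = annotations.get(partner)
            if partner_ann is not None and partner_ann.formula is not None:
                continue
            ann.isotopologue_links.append((label, partner))
            linked.add(partner)
    return linked


def annotate_dataset(
    units: list[OperationalUnit],
    config: AnnotationConfig | None = None,
) -> tuple[dict[int, Annotation], dict]:
    """Run the full annotation pipeline on (already filtered) units.

    enumerate -> isotope-verify -> select -> propagate blocks -> label
    isotopologues.  Returns annotations for every unit plus a QC summary
    mirroring the filtering funnel: units entering annotation, units with an
    isotope-verified formula, with a block-propagated formula, and
    isotopologue satellites excluded from the inventory.
    """
    cfg = config or AnnotationConfig()
    order = sorted(range(len(units)), key=lambda k: units[k].representative_mz)
    sorted_reps = np.array([units[k].representative_mz for k in order])

    annotations: dict[int, Annotation] = {}
    for u in units:
        neutral = neutral_mass(u.representative_mz, cfg.ion_mode)
        try:
            candidates = enumerate_formulas(neutral, cfg.tolerance_ppm, cfg.bounds)
        except ValueError:
            candidates = []
        chosen = None
        c_est = estimate_carbon_number(
            u,
            units,
            tolerance_rel=cfg.tolerance_rel,
            c13_abundance=cfg.c13_abundance,
            aggregation=cfg.aggregation,
            _sorted_reps=sorted_reps,
            _sorted_index=order,
        )
        if c_est is not None and candidates:
            chosen = select_formula(candidates, c_est, cfg.c_dev_bounds)
        if chosen is not None:
            annotations[u.unit_id] = Annotation(
                unit_id=u.unit_id,
                formula=chosen.formula,
                route=ROUTE_ISOTOPE,
                mass_error_ppm=chosen.mass_error_ppm,
                c_dev=chosen.c_dev,
            )
        else:
            annotations[u.unit_id] = Annotation(unit_id=u.unit_id, formula=None)

    propagated = propagate_blocks(
        {k: v for k, v in annotations.items() if v.formula is not None},
        units,
        tolerance_rel=cfg.tolerance_rel,
        tolerance_ppm=cfg.tolerance_ppm,
        max_hops=cfg.max_hops,
        ion_mode=cfg.ion_mode,
        bounds=cfg.bounds,
    )
    annotations.update(propagated)

    satellites = label_isotopologues(
        units, annotations, tolerance_rel=cfg.tolerance_rel
    )

    n_iso = sum(1 for a in annotations.values() if a.route == ROUTE_ISOTOPE)
    n_block = sum(1 for a in annotations.values() if a.route == ROUTE_BLOCK)
    qc = {
        "config": cfg.to_dict(),
        "units_entering_annotation": len(units),
        "units_isotope_verified": n_iso,
        "units_block_propagated": n_block,
        "units_with_formula": n_iso + n_block,
        "isotopologue_satellite_units": len(satellites),
        "molecule_inventory": n_iso + n_block - sum(
            1 for uid in satellites
            if annotations.get(uid) is not None and annotations[uid].formula is not None
        ),
    }
    return annotations, qc


def annotations_table(annotations: dict[int, Annotation], units: list[OperationalUnit]):
    """Tidy annotation table (one row per unit)."""
    import pandas as pd

    rep = {u.unit_id: u.representative_mz for u in units}
    rows = []
    for uid in sorted(annotations):
        a = annotations[uid]
        rows.append(
            {
                "unit_id": uid,
                "representative_mz": rep.get(uid, np.nan),
                "formula": str(a.formula) if a.formula is not None else "",
                "route": a.route,
                "mass_error_ppm": a.mass_error_ppm,
                "c_dev": a.c_dev,
                "scaffold_unit_id": a.scaffold_unit_id,
                "block_path": ";".join(a.block_path),
                "isotopologue_links": ";".join(
                    f"{lab}:{pid}" for lab, pid in a.isotopologue_links
                ),
            }
        )
    return pd.DataFrame(rows)
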