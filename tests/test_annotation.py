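"""Formula enumeration, isotope-ratio carbon verification, block
propagation, and isotopologue labelling."""

import numpy as np
import pytest

from fticrdom.alignment import OperationalUnit, cluster_peaks, drop_singletons, filter_units
from fticrdom.annotation import (
    Annotation,
    AnnotationConfig,
    ROUTE_BLOCK,
    ROUTE_ISOTOPE,
    annotate_dataset,
    enumerate_formulas,
    estimate_carbon_number,
    isotopologue_table,
    label_isotopologues,
    mz_of,
    neutral_mass,
    propagate_blocks,
    select_formula,
)
from fticrdom.chem_core import ELEMENTS, BUILDING_BLOCKS, MolecularFormula, monoisotopic_mass
from fticrdom.spectra_io import SampleSpectrum
from fticrdom.synthetic import SyntheticDesign, render_study
from fticrdom.cli import run_pipeline

from _oracles import enumerate_oracle, formula_space

D13C = ELEMENTS.isotope_shifts["13C"]


def make_unit(uid, mz, intensities_by_sample):
    sids = np.array(list(intensities_by_sample), dtype=object)
    intens = np.array(list(intensities_by_sample.values()), dtype=float)
    return OperationalUnit(
        unit_id=uid,
        representative_mz=mz,
        sample_ids=sids,
        mzs=np.full(len(sids), mz),
        intensities=intens,
    )


class TestNeutralMass:
    def test_round_trip_identity(self):
        for m in (100.0, 500.123456, 1999.0):
            assert neutral_mass(mz_of(m)) == pytest.approx(m, abs=1e-9)

    def test_glucose_ion(self):
        glucose = monoisotopic_mass(MolecularFormula(c=6, h=12, o=6))
        assert neutral_mass(179.056112) == pytest.approx(glucose, abs=1e-6)

    def test_positive_mz_required(self):
        with pytest.raises(ValueError):
            neutral_mass(-1.0)

    def test_unsupported_mode(self):
        with pytest.raises(ValueError, match="ion mode"):
            neutral_mass(100.0, ion_mode="[M+H]+")


class TestEnumerate:
    def test_glucose_found_at_one_ppm(self):
        cands = enumerate_formulas(180.063388, 1.0)
        assert MolecularFormula(c=6, h=12, o=6) in [c.formula for c in cands]

    def test_too_light_mass_yields_nothing(self):
        assert enumerate_formulas(1.0, 10.0) == []

    def test_sorted_by_abs_error_then_formula(self):
        cands = enumerate_formulas(300.0, 20.0)
        errs = [abs(c.mass_error_ppm) for c in cands]
        assert errs == sorted(errs)

    @pytest.mark.parametrize("tolerance_ppm", [1.0, 5.0])
    def test_equals_brute_force_oracle(self, tolerance_ppm):
        counts, masses = formula_space(510.0)
        rng = np.random.default_rng(11)
        for m in rng.uniform(50, 500, 30):
            got = {c.formula.counts() for c in enumerate_formulas(m, tolerance_ppm)}
            assert got == enumerate_oracle(counts, masses, m, tolerance_ppm)

    def test_all_candidates_within_tolerance_and_valid(self):
        from fticrdom.chem_core import validate_formula

        for c in enumerate_formulas(350.1, 5.0):
            assert abs(c.mass_error_ppm) <= 5.0
            assert validate_formula(c.formula)[0]


class TestCarbonEstimate:
    def test_printed_ratio_arithmetic(self):
        mono = make_unit(0, 400.0, {"s1": 1000.0})
        iso = make_unit(1, 400.0 + D13C, {"s1": 64.2})
        c_est = estimate_carbon_number(mono, [mono, iso])
        assert c_est == pytest.approx(6.0)

    def test_no_satellite_gives_undefined(self):
        mono = make_unit(0, 400.0, {"s1": 1000.0})
        far = make_unit(1, 402.0, {"s1": 50.0})
        assert estimate_carbon_number(mono, [mono, far]) is None

    def test_zero_satellite_intensity_gives_zero(self):
        mono = make_unit(0, 400.0, {"s1": 1000.0})
        iso = make_unit(1, 400.0 + D13C, {"s1": 0.0})
        assert estimate_carbon_number(mono, [mono, iso]) == 0.0

    def test_median_aggregation_ignores_outlier_sample(self):
        mono = make_unit(0, 400.0, {"s1": 1000.0, "s2": 1000.0, "s3": 1000.0})
        iso = make_unit(
            1, 400.0 + D13C, {"s1": 64.2, "s2": 64.2, "s3": 642.0}
        )
        c_med = estimate_carbon_number(mono, [mono, iso], aggregation="median")
        assert c_med == pytest.approx(6.0)


class TestSelectFormula:
    def test_candidate_outside_window_discarded(self):
        from fticrdom.annotation import FormulaCandidate

        c6 = FormulaCandidate(MolecularFormula(c=6, h=12, o=6), 180.063388, 0.2)
        c9 = FormulaCandidate(MolecularFormula(c=9, h=8, o=4), 180.042259, 0.1)
        chosen = select_formula([c6, c9], c_est=6.5)
        assert chosen.formula.c == 6 and chosen.c_dev == pytest.approx(-0.5)

    def test_open_interval_excludes_boundary(self):
        from fticrdom.annotation import FormulaCandidate

        cand = FormulaCandidate(MolecularFormula(c=7, h=14, o=6), 194.079038, 0.0)
        assert select_formula([cand], c_est=6.0) is None       # c_dev == 1.0
        assert select_formula([cand], c_est=10.0) is None      # c_dev == -3.0
        assert select_formula([cand], c_est=9.9) is not None   # c_dev == -2.9

    def test_smallest_absolute_cdev_wins(self):
        from fticrdom.annotation import FormulaCandidate

        a = FormulaCandidate(MolecularFormula(c=10, h=20, o=2), 200.0, 0.5)
        b = FormulaCandidate(MolecularFormula(c=13, h=14, o=1), 200.0, 0.1)
        # c_est such that c_dev are -2.9 (a) and +0.1 (b)
        chosen = select_formula([a, b], c_est=12.9)
        assert chosen.formula.c == 13 and abs(chosen.c_dev) == pytest.approx(0.1)


class TestPropagation:
    def _scaffold_setup(self):
        glucose = MolecularFormula(c=6, h=12, o=6)
        scaffold_mz = mz_of(monoisotopic_mass(glucose))
        units = [
            make_unit(0, scaffold_mz, {"s1": 100.0}),
            make_unit(1, scaffold_mz + 14.015650, {"s1": 50.0}),
        ]
        ann = {
            0: Annotation(unit_id=0, formula=glucose, route=ROUTE_ISOTOPE, c_dev=0.0)
        }
        return units, ann

    def test_homologue_annotated_via_ch2(self):
        units, ann = self._scaffold_setup()
        new = propagate_blocks(ann, units)
        assert new[1].formula == MolecularFormula(c=7, h=14, o=6)
        assert new[1].route == ROUTE_BLOCK
        assert new[1].block_path == ("+CH2",)
        assert new[1].scaffold_unit_id == 0

    def test_off_tolerance_mass_not_annotated(self):
        units, ann = self._scaffold_setup()
        units[1] = make_unit(1, units[0].representative_mz + 14.0110, {"s1": 50.0})
        assert propagate_blocks(ann, units) == {}

    def test_no_unannotated_units_no_change(self):
        units, ann = self._scaffold_setup()
        assert propagate_blocks(ann, units[:1]) == {}

    def test_max_hops_limits_chain_depth(self):
        # oxygen ladder: no combination of fewer blocks equals k x O,
        # so each rung genuinely costs one hop
        scaffold = MolecularFormula(c=10, h=16, o=2)
        base = mz_of(monoisotopic_mass(scaffold))
        d_o = 15.994915
        units = [make_unit(i, base + i * d_o, {"s1": 10.0}) for i in range(5)]
        ann = {0: Annotation(unit_id=0, formula=scaffold, route=ROUTE_ISOTOPE)}
        new = propagate_blocks(ann, units, max_hops=2)
        assert set(new) == {1, 2}
        deeper = propagate_blocks(ann, units, max_hops=4)
        assert set(deeper) == {1, 2, 3, 4}
        assert deeper[4].block_path == ("+O",) * 4
        assert deeper[4].scaffold_unit_id == 0

    def test_confluent_under_scaffold_order(self):
        glucose = MolecularFormula(c=6, h=12, o=6)
        other = MolecularFormula(c=7, h=14, o=6)
        u0 = make_unit(0, mz_of(monoisotopic_mass(glucose)), {"s1": 10.0})
        u1 = make_unit(1, mz_of(monoisotopic_mass(other)), {"s1": 10.0})
        target = MolecularFormula(c=7, h=14, o=7)  # glucose+CH2O? via two routes
        u2 = make_unit(2, mz_of(monoisotopic_mass(target)), {"s1": 10.0})
        ann_a = {
            0: Annotation(0, glucose, ROUTE_ISOTOPE),
            1: Annotation(1, other, ROUTE_ISOTOPE),
        }
        ann_b = dict(reversed(list(ann_a.items())))
        res_a = propagate_blocks(ann_a, [u0, u1, u2])
        res_b = propagate_blocks(ann_b, [u2, u1, u0])
        assert res_a[2].formula == res_b[2].formula == target


class TestIsotopologues:
    def test_13c_link_created(self):
        glucose = MolecularFormula(c=6, h=12, o=6)
        units = [
            make_unit(0, 400.0, {"s1": 100.0}),
            make_unit(1, 400.0 + D13C, {"s1": 6.4}),
        ]
        ann = {0: Annotation(0, glucose, ROUTE_ISOTOPE)}
        linked = label_isotopologues(units, ann)
        assert ("13C", 1) in ann[0].isotopologue_links
        assert linked == {1}

    def test_element_gate_blocks_sulfur_satellite(self):
        glucose = MolecularFormula(c=6, h=12, o=6)  # S = 0
        d34s = ELEMENTS.isotope_shifts["34S"]
        units = [
            make_unit(0, 400.0, {"s1": 100.0}),
            make_unit(1, 400.0 + d34s, {"s1": 4.0}),
        ]
        ann = {0: Annotation(0, glucose, ROUTE_ISOTOPE)}
        linked = label_isotopologues(units, ann)
        assert linked == set() and ann[0].isotopologue_links == []

    def test_no_satellite_peaks_no_links(self):
        glucose = MolecularFormula(c=6, h=12, o=6)
        units = [make_unit(0, 400.0, {"s1": 100.0})]
        ann = {0: Annotation(0, glucose, ROUTE_ISOTOPE)}
        assert label_isotopologues(units, ann) == set()

    def test_composite_shifts_are_sums(self):
        t = isotopologue_table()
        assert t["13C2"] == pytest.approx(2 * t["13C"], abs=1e-9)
        assert t["13C3"] == pytest.approx(3 * t["13C"], abs=1e-9)
        assert t["13C34S"] == pytest.approx(t["13C"] + t["34S"], abs=1e-9)


class TestAnnotateDataset:
    def test_no_satellites_means_no_scaffolds(self, benchmark_study):
        # strip all isotopologue satellites from the rendered spectra
        sat = benchmark_study.truth_peaks["kind"].str.startswith(("13C", "34S"))
        sat_keys = {
            (r.sample_id, r.mz)
            for r in benchmark_study.truth_peaks[sat].itertuples(index=False)
        }
        stripped = []
        for spec in benchmark_study.samples:
            keep = np.array(
                [(spec.sample_id, m) not in sat_keys for m in spec.mz]
            )
            stripped.append(
                SampleSpectrum(
                    spec.sample_id, spec.mz[keep], spec.intensity[keep], spec.snr[keep]
                )
            )
        units = filter_units(drop_singletons(cluster_peaks(stripped)), min_peaks=10)
        annotations, qc = annotate_dataset(units, AnnotationConfig())
        assert qc["units_isotope_verified"] == 0
        assert qc["units_block_propagated"] == 0

    def test_qc_funnel_is_monotone(self, benchmark_result):
        _, _, qc = benchmark_result
        assert (
            qc["units_with_formula"]
            <= qc["units_entering_annotation"]
            <= qc["n_units_non_singleton"]
        )

    def test_every_formula_valid_and_within_tolerance(self, benchmark_result):
        from fticrdom.chem_core import validate_formula

        units, annotations, _ = benchmark_result
        rep = {u.unit_id: u.representative_mz for u in units}
        for uid, ann in annotations.items():
            if ann.formula is None:
                continue
            assert validate_formula(ann.formula)[0]
            theo = monoisotopic_mass(ann.formula)
            err = (neutral_mass(rep[uid]) - theo) / theo * 1e6
            assert abs(err) <= 1.0 + 1e-9

    def test_isotope_verified_cdev_strictly_inside_window(self, benchmark_result):
        _, annotations, _ = benchmark_result
        routes = [a for a in annotations.values() if a.route == ROUTE_ISOTOPE]
        assert routes, "benchmark should isotope-verify some units"
        for ann in routes:
            assert -3.0 < ann.c_dev < 1.0
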