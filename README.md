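# fticrdom

Annotation and chemodiversity analysis of ultrahigh-resolution mass spectra
of dissolved organic matter (DOM).

Direct-infusion FT-ICR mass spectrometry resolves thousands of molecular
species in a single soil- or water-extract spectrum, but the peaks are
useless until each is bound to an elemental formula and the formulas are
compared across samples. `fticrdom` implements that workflow as a library
plus CLI for researchers characterizing DOM in soils, sediments, and
natural waters:

- **Peak processing** — signal-to-noise filtering (S/N > 5), blank
  subtraction, optional linear ppm recalibration, mzML or delimited-text
  input.
- **Cross-sample alignment** — peaks are clustered into *operational
  units* (the mass-spectrometric analogue of OTUs) at a relative m/z
  tolerance of 1×10⁻⁶; singleton and low-occupancy clusters are removed.
- **Formula assignment with carbon-isotope verification** — candidate
  formulas are enumerated inside C₁₋₁₀₀H₁₋₁₅₀O₀₋₅₀N₀₋₄P₀₋₁S₀₋₁ under
  twelve valence/heteroatom exclusion rules. The carbon number is estimated
  independently from the ¹³C isotopologue satellite,

  C_est = (I_iso / I_mono) / 0.0107,

  and the candidate minimising |C_dev| = |C − C_est| is accepted when
  C_dev ∈ (−3, 1). Verified formulas seed a *chemical building block*
  propagation (CH₂, C₂H₂, C₂H₄, H₂, H₂O, O, CO₂, NH, S, CH₄−O) that
  annotates neighbouring units, and ¹³C/¹⁵N/³⁴S/³³S/¹⁸O/¹⁷O/²H/¹³C₂/¹³C₃/
  ¹³C³⁴S satellites are labelled and excluded from the molecule inventory.
- **Compound classification** — each formula lands in one of six
  stoichiometric classes from the aromaticity index
  AI = (1 + C − O − S − H/2)/(C − O − S − N − P) and the H/C, O/C, N
  thresholds (polycyclic aromatics AI > 0.66; polyphenols
  0.50 < AI ≤ 0.66; …), plus weighted van Krevelen kernel densities with
  median molecular abundances as weights.
- **Chemodiversity statistics** — rarefaction, observed richness, Chao1,
  Shannon, Bray-Curtis dissimilarity, Mantel tests, and PERMANOVA on the
  samples × units intensity matrix.
- **Synthetic ground truth** — a generator that renders [M−H]⁻ DOM-like
  spectra with isotopologue satellites, noise, and blanks from known
  formulas, so the whole pipeline is testable without instrument data.

## Worked example

Simulate a ground-truth study (100 formulas, two groups × 6 samples,
0.5 ppm mass jitter), run it through the pipeline, and score recovery:

```python
from fticrdom.synthetic import SyntheticDesign, render_study, recovery_report
from fticrdom.cli import run_pipeline

study = render_study(SyntheticDesign(seed=42))
units, annotations, qc = run_pipeline(study.samples, study.blanks)
print({k: v for k, v in qc.items() if k != "config"})
print(recovery_report(study, units, annotations))
```

```
{'n_input_peaks': 3975, 'n_peaks_after_snr': 3149, 'n_units_non_singleton': 208,
 'units_entering_annotation': 207, 'units_isotope_verified': 99,
 'units_block_propagated': 0, 'units_with_formula': 99,
 'isotopologue_satellite_units': 108, 'molecule_inventory': 99}
{'n_truth_formulas': 100, 'n_recoverable': 99, 'n_recovered': 99,
 'recovery_rate': 1.0, 'n_isotope_verified': 99,
 'isotope_verified_correct_rate': 1.0, 'cdev_within_bounds_rate': 1.0}
```

Reading: of 3,975 simulated peaks, 3,149 survive the S/N > 5 filter; they
cluster into 208 non-singleton units, of which 207 carry ≥ 10 member
peaks and enter annotation. 99 units are isotope-verified molecular
formulas (one of the 100 truth formulas collided with another peak and is
not cleanly recoverable); a further 108 units are recognised as
isotopologue satellites and removed from the molecule inventory. All 99
recoverable formulas are recovered exactly, and every isotope-verified
assignment has C_dev inside (−3, 1).

The same pipeline is available from the shell:

```bash
fticrdom simulate --seed 42 --out-dir sim/
fticrdom filter sim/A*.csv sim/B*.csv --out-dir filtered/
fticrdom cluster filtered/*.csv --out-dir clustered/
fticrdom annotate --cluster-dir clustered/ --out-dir annotated/
fticrdom classify --annotations annotated/annotations.tsv --out-dir classified/
```

Each step writes TSV outputs plus a `*_provenance.json` with the full
configuration, input hashes, and seed.

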