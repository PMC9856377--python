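# epibarrier

Quantification of colonic epithelial transport and barrier function from
Ussing-chamber measurements, written for electrophysiology and mucosal
barrier labs analysing endoscopic biopsies (e.g. irritable bowel syndrome
or IBD cohorts versus controls).

A biopsy mounted in an Ussing chamber yields several raw data streams per
specimen; `epibarrier` turns each into its standard physiological metric
and compares two study arms:

* **Impedance spectroscopy** — the complex impedance over 48 frequencies
  (1.3 Hz–65 kHz) is fitted with the one-path equivalent circuit
  `Z(f) = R_sub + R_epi / (1 + j·2πf·R_epi·C)`, decomposing the transmural
  resistance `R_t = R_sub + R_epi` into subepithelial and epithelial
  parts (Ω·cm²) plus the epithelial capacitance.
* **Short-circuit current (Isc)** — baseline Isc, bumetanide-sensitive
  ΔIsc (electrogenic Cl⁻ secretion; max before vs 20 min after serosal
  bumetanide) and amiloride-sensitive ΔIsc (ENaC Na⁺ absorption, plateau
  difference), with conversion to molar flux `J = ΔIsc·3600/(zF)`.
* **Tracer fluxes** — timed basolateral fluorescein / FITC-dextran-4000
  samples through a fluorescence calibration give the flux `J` (OLS slope
  of amount vs time over the exposed area) and the apparent permeability
  `P = J/Δc` in cm·s⁻¹.
* **Tricellular tight junctions** — from junctional intensity line
  profiles, the tTJ/bTJ ratio: intensity at the tricellular anchor over
  the bicellular intensity 2 µm away (low ratios = tricellulin
  delocalization).
* **Morphometry** — mucosal/serosal surface ratio `1 + nπdL` from crypt
  diameter, length and density; apoptosis rate from TUNEL/DAPI counts.
* **Upstream regulators** — Fisher-exact overlap p-values and activation
  z-scores `(n_agree − n_disagree)/√n` over a DESeq2-style results table
  and a signed regulator→target network.
* **Cohort statistics** — per-subject metric tables and two-group
  Student's t-tests (pooled or Welch) with the n.s./*/**/*** convention.

A synthetic-data module simulates every modality for a two-arm cohort
with known ground truth, so the whole chain is testable end to end
without patient data.

## Worked example

```python
import epibarrier as eb

# fit one noisy impedance spectrum (true values: 15, 35 Ω·cm², 3 µF·cm⁻²)
spec = eb.simulate_impedance_spectrum(15.0, 35.0, 3e-6, noise_sd=0.01, seed=42)
fit = eb.OnePathModel(spec).fit()
print(fit.summary())
```

```
One-path equivalent-circuit fit
---------------------------------------
method            ls
converged         True
R_t   (Ohm cm^2)  50
R_sub (Ohm cm^2)  15.02
R_epi (Ohm cm^2)  34.98
C     (uF cm^-2)  2.989
f_c   (Hz)        1522
residual norm     2.264
```

With 1% measurement noise the fit recovers the epithelial resistance to
0.1% here; `fit.plot_nyquist()` draws the data and the fitted semicircle
(apex −Im(Z) = R_epi/2 at the characteristic frequency f_c).

A full simulated cohort (11 controls vs 7 patients, group means/SDs
mirroring a published IBS-M study):

```python
cohort, truth = eb.simulate_cohort(eb.default_config(seed=7))
report = eb.analyze_cohort(cohort)
print(report.summary())
```

```
Cohort group comparison (control vs IBS-M)
------------------------------------------------------------------------------
metric                           control             IBS-M         p  label
baseline_isc                176.2 ± 99.1        67.47 ± 29.3    0.0129  *
delta_isc_bumetanide        70.35 ± 16.8        32.56 ± 12.1  9.98e-05  ***
j_na                       0.5733 ± 0.253      0.5019 ± 0.18     0.527  n.s.
r_epi                       37.14 ± 11.8        37.61 ± 8.97     0.929  n.s.
p_fluorescein           6.586e-07 ± 2.26e-07  2.161e-06 ± 7.56e-071.14e-05  ***
ttj_ratio                   2.635 ± 0.236       1.164 ± 0.117  6.2e-11  ***
surface_ratio               4.566 ± 0.876       4.801 ± 0.713    0.562  n.s.
...
```

The pattern is the expected disease signature under the packaged study
conditions: reduced bumetanide-sensitive Cl⁻ secretion, unchanged
epithelial resistance and Na⁺ absorption, increased macromolecule
permeability, and a collapsed tTJ/bTJ ratio, while morphometry and
apoptosis stay unchanged. `report.write("report/")` emits
`metrics_per_subject.tsv`, `group_comparisons.tsv`, `summary.json` and
`run.log`.

The same works from the shell on a cohort directory:

```bash
epibarrier simulate --out cohort/ --seed 7
epibarrier run --cohort cohort/ --out report/
epibarrier impedance fit --input cohort/subjects/C01/impedance.csv
epibarrier enrich --de cohort/de_results.tsv --network cohort/network.tsv
```

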