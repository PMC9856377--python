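# Methods

`epibarrier` quantifies colonic epithelial transport and barrier function
from Ussing-chamber measurements: equivalent-circuit impedance analysis,
pharmacological dissection of the short-circuit current, tracer-flux
permeability, tricellular-tight-junction (tTJ) localization, crypt
morphometry, and upstream-regulator enrichment statistics. A synthetic
cohort generator with known ground truth stands in for patient biopsies,
so every stage and the end-to-end two-group comparison are testable.

## One-path impedance model

The tissue is modelled as a subepithelial ohmic resistor R_sub in series
with a parallel RC element (epithelial resistance R_epi, capacitance C):

    Z(f) = R_sub + R_epi / (1 + j 2πf R_epi C)

Assumptions: a single dominant RC time constant (no constant-phase element,
no two-path paracellular/transcellular separation), capacitive sign
convention Im(Z) ≤ 0. The Nyquist locus is a semicircle of diameter R_epi
centred on the real axis; Re(Z) → R_sub + R_epi = R_t as f → 0 and → R_sub
as f → ∞, and the apex of −Im(Z) is R_epi/2 at f_c = 1/(2π R_epi C).

Estimation is complex nonlinear least squares on (Re, Im) jointly,
unweighted because the measurement-noise model is unknown. Start values
come from the data (R_sub from the highest-frequency real part, R_t from
the lowest, C from the apex frequency); parameters are bounded positive
and the optimizer runs to tight tolerances (1e-15), so noiseless spectra
invert to machine precision. A frequency-end intercept reading
(`fit_intercept`, mean real part over the 3 lowest / 3 highest
frequencies; 3 is a package choice) is provided as the assumption-light
fallback. Spectra with no measurable reactive component raise a
degenerate-input error rather than returning an arbitrary (R_sub, R_epi)
split. A brute-force cross-check (`grid_search_one_path`: coarse
log-spaced lattice plus Nelder–Mead polish, independent of the
least-squares path) is shipped for validation.

The default frequency grid is 48 log-spaced points on 1.3 Hz – 65 kHz,
matching the measurement protocol the package targets. Bath-solution
series resistance is subtracted from the real part before fitting;
double correction is a state error, and a correction exceeding the
smallest real part is rejected.

## Short-circuit current dissection

Isc (µA·cm⁻²) is the clamp current for zero transepithelial voltage.
Quantifications:

* **Baseline Isc** — mean over all samples before the first drug event.
* **Bumetanide-sensitive ΔIsc** (electrogenic Cl⁻ secretion) — maximum
  Isc before serosal bumetanide minus the Isc 20 min after addition
  (nearest sample within ±1 min, else linear interpolation; the tolerance
  is a package default).
* **Amiloride-sensitive ΔIsc → J_Na** (ENaC Na⁺ absorption, after
  aldosterone stimulation) — plateau difference: mean of the last 5
  pre-event samples minus mean of samples +5 to +15 min post-event.
  The plateau windows are package defaults; negative values are returned
  signed and flagged. ΔIsc converts to molar flux via
  J = ΔIsc·1e-6·3600/(zF) (0.0373 µmol·h⁻¹·cm⁻² per µA·cm⁻² for z = 1).

Both ΔIsc definitions are invariant to adding a constant to the trace.

## Tracer permeability

Under sink conditions (basolateral ≪ apical concentration) the
basolateral tracer amount grows linearly; the ordinary-least-squares
slope of amount vs time is the appearance rate. Then J = rate·60/area
(mol·h⁻¹·cm⁻²) and P = J/Δc. The field's mixed units are dimensionally
inconsistent without conversion, so the package converts explicitly:
J → mol·s⁻¹·cm⁻² (÷3600) and Δc mol·L⁻¹ → mol·cm⁻³ (×1e-3), giving P in
cm·s⁻¹. Worked reference: slope 2 nmol·h⁻¹ on 0.049 cm² at Δc = 100 µM
gives J = 40.8 nmol·h⁻¹·cm⁻² and P = 1.134e-4 cm·s⁻¹.

Fluorescence is converted to concentration through an OLS calibration
line over ≥ 3 dilution points (duplicates averaged first; non-positive
gain rejected). All samples including t = 0 enter the slope by default
(`skip_first` handles lag phases); sampled volume is assumed not replaced
(`replaced_volume_ml` adds the cumulative withdrawn amount back).
Negative slopes beyond noise tolerance are flagged, not raised.
Defaults: exposed area 0.049 cm², fluorescein 100 µM apical with samples
at 0/15/30/45/60 min, FITC-dextran-4000 0.4 mM with 30-min sampling.
The basolateral chamber volume is not part of the protocol record and
defaults to 1.0 mL (arbitrary; results are volume-consistent as long as
the declared value matches the experiment).

## Tricellular-junction ratio

From a uniform 1-D intensity profile along the junction with a
tricellular anchor point, the statistic is I(anchor) / I(anchor ± 2 µm),
the bicellular reference being the mean of both sides when available
(one-sided readings are flagged). Sub-sample positions are linearly
interpolated; anchor-pixel reading is the default with an optional
local-maximum search (`local_max_radius_um`). No background subtraction
is applied by default. The ratio is exactly scale-invariant.

Aggregation over the 3 measurements × 3–7 sections scheme: the subject
mean is the flat mean over all measurements (default); per-section means
and their average are also reported because the two differ for
unbalanced sections. Group comparisons use subject means (n = subjects).

## Crypt morphometry and apoptosis

Crypts are modelled as right circular cylinders (inner diameter d,
length L, density n per cm² serosal area): surface ratio = 1 + nπdL,
since crypt openings cancel against flat bottoms. This is the minimal
shape determined by the three measured quantities; a hemispherical-bottom
variant (adds nπd²/4) is provided because the section data cannot
distinguish the two. Openings exceeding the reference plane are a
geometry error. A triangulated-mesh integration of the same surface is
shipped as an independent numerical cross-check (agreement < 0.1%).
Apoptosis rate is 100·apoptotic/total DAPI-positive nuclei.

## Upstream-regulator statistics

Over a DESeq2-style results table and a signed regulator→target network:
DE membership uses |log2FC| and (adjusted by default) p thresholds; the
overlap p-value is the one-sided hypergeometric tail P(X ≥ overlap) with
the universe defaulting to the table's gene count (override available);
the activation z-score is (n_agree − n_disagree)/√n over DE-overlapping
targets with unit edge weights — literature-confidence weighting used by
commercial implementations is intentionally not reproduced, since no
weights are available to the package. No overlap yields an undefined
result (distinct from z = 0). Regulators are ranked by overlap p
ascending, ties by |z| descending, then lexicographically. An
exact-fraction enumeration of the hypergeometric tail serves as the
oracle for validation.

## Group statistics

Student's t-test, pooled-variance by default (Welch by option), two-sided,
values reported as mean ± SD with the star convention (n.s. / * p<0.05 /
** p<0.01 / *** p<0.001). A summary-statistic path (mean, SD, n per group)
is algebraically identical to the raw-data pooled test. No
multiple-testing correction is applied across metrics, matching the
reporting convention the package mirrors. Note: recomputing the pooled
test from the rounded published baseline-Isc summaries (138 ± 75, n = 10
vs 74 ± 35, n = 6) gives p ≈ 0.072, while the original analysis of the
unrounded raw data reports p = 0.0839; the package asserts only the
summary-based value.

## Synthetic cohort generator

Per-subject true parameters are drawn from group-level Gaussians
(rejection-sampled into physical ranges: resistances positive, enrichment
≥ 1, apoptosis fraction in [0, 1]); modalities are generated from those
truths with simple noise models:

* impedance — exact circuit curve with multiplicative Gaussian
  perturbation (default 1%) on Re and Im;
* Isc traces — first-order exponential approach to the post-drug plateau
  (a generator choice; the real kinetics are not specified by the
  protocol), additive Gaussian noise (default 2 µA·cm⁻²); the ENaC run is
  a separate aldosterone-annotated trace, its full 6–8 h stimulation not
  simulated;
* fluxes — linear sink-condition accumulation read through a linear
  fluorescence gain with duplicate calibration readings (1% relative
  noise);
* profiles — flat background plus a Gaussian tTJ peak of amplitude
  (enrichment − 1)·background, width 0.5 µm, sampled at 0.05 µm (5%
  relative noise);
* morphometry — direct draws; nuclei — binomial apoptotic counts out of
  ~10³ DAPI nuclei;
* DE table — targets of "active" regulators receive signed log2FC effects
  with small p-values, everything else is null; BH-adjusted p-values.

Gaussian noise everywhere is the simplest model consistent with
mean ± SD reporting. Modalities are independent across and within
subjects (no between-modality correlation is modelled, since none is
reported); real biopsies likely correlate (e.g. low tTJ enrichment with
high macromolecule permeability), so passing tests demonstrate correct
computation and statistical behaviour under the stated model, not
biological realism of joint distributions.

The packaged default configuration (`default_config`, 11 control vs
7 IBS-M subjects) mirrors the published group summaries where printed:
baseline Isc 138 ± 75 vs 74 ± 35 µA·cm⁻²; R_epi, R_sub, capacitance and
J_Na identical between arms (35 ± 10, 15 ± 5 Ω·cm², 3 ± 0.8 µF·cm⁻²,
0.5 ± 0.25 µmol·h⁻¹·cm⁻²); fluorescein permeability 0.5e-6 ± 0.2e-6 cm/s
control with a 4-fold IBS-M increase and FITC-dextran-4000
0.1e-6 ± 0.05e-6 with a 3-fold increase; tTJ enrichment 2.5 ± 0.3 vs
1.2 ± 0.3; crypt geometry 50 µm × 400 µm × 5700 cm⁻² (surface ratio 4.58)
with IBS-M crypt length 444 µm (ratio ≈ 4.97); apoptosis 1.0 ± 0.7 vs
1.1 ± 0.6 %. Magnitudes not printed in the source report (ΔIsc_bumetanide
60 ± 20 vs 25 ± 12 µA·cm⁻², J_Na level, resistance components, absolute
permeabilities, ENaC-run baseline 50 ± 10 µA·cm⁻²) were fixed once at
physiologically plausible human-sigmoid values and are not tuned.

## Validation problem sizes and numerical choices

The shipped validation (tests and `scripts/acceptance.py`) uses: 50
noiseless + 100 noisy circuits for impedance recovery; 20 instances for
the fit-vs-grid oracle; the full hypergeometric enumeration for universes
≤ 25 (~24k configurations); 100 random geometries for the mesh oracle;
200 replicates of the 3-vs-3 tTJ cohort comparison; 1000 random t-test
instances against scipy; 50 study-mirroring seeds for directional
reproduction and 200 identical-group seeds for per-metric type-I control
(each metric n.s. in ≥ 90% of seeds at α = 0.05). These sizes make the
whole validation run in about a minute on one CPU while keeping the
Monte-Carlo margins comfortable.

Tie-breaks and degenerate inputs: zero-variance amounts give r² = 1 with
zero slope (perfectly explained by a flat line); zero-SD groups with
distinct means give p = 0; identical regulator scores order
lexicographically; missing modality files skip their metric with a logged
warning rather than failing the pipeline run.

## Known limitations

* One RC time constant only; tissues with pronounced constant-phase
  behaviour will show structured residuals (the residual norm is
  reported for exactly this check).
* Sink-condition linearity is assumed for fluxes; no back-flux or
  two-compartment correction.
* Unit-weight z-scores and depth-1 networks only; results are not
  comparable in absolute terms to knowledge-base-weighted commercial
  scores.
* The generator's independence assumptions understate real
  between-modality correlation (see above).
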