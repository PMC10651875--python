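# Methods

## The model

Resting EEG power spectra are modeled in log10-power space over a fixed
fit range (default 0.5–30 Hz) as the sum of an aperiodic component and a
small number of Gaussian oscillation peaks:

    L(f) = offset − χ · log10(f) + Σₙ hₙ · exp(−(f − cₙ)² / (2 σₙ²))

`offset` is the log10 power at 1 Hz; χ (the aperiodic exponent) is the
log10-power lost per decade of frequency, the slope of the spectrum in
log-log coordinates; each peak has a center frequency cₙ (Hz), a height
hₙ in log10-power units *above the aperiodic component* (reported as
oscillation power), and a Gaussian width σₙ. No spectral knee is
modeled: over 0.5–30 Hz resting scalp EEG is adequately described by a
single power law, and all default analyses fit "fixed" (knee-free)
aperiodic components.

The scientific point of the decomposition: canonical band power (mean
log10 power across a band's bins) conflates the two components. A
steeper χ raises low-frequency power without any oscillation, so
"clinical slowing" measured by delta band power is ambiguous. The
model separates it into χ changes, peak-height changes, and peak
*emergence* (abundance: the fraction of electrodes whose fit contains
an in-band peak).

## Fitting procedure

Fitting is nonlinear and unidentified in the worst case, so the
implementation works in stages, each convex or low-dimensional:

1. **Robust aperiodic seed.** An ordinary least-squares line in
   (log10 f, log10 P), refit twice using only points whose residual is
   below the 33rd percentile. Peaks only add power, so the underside of
   the spectrum traces the aperiodic component. The underside fit sits
   roughly one noise-sd low; the residual is re-centered by its median
   before peak detection so noise does not ride above the peak
   threshold.
2. **Iterative peak extraction.** The largest residual — detected on a
   5-bin moving average so single noisy bins cannot seed peaks — is fit
   with one Gaussian (initialized by the half-height width, refined by a
   bounded local least-squares fit) and subtracted. Extraction stops at
   `max_n_peaks` (12) or when the largest smoothed residual falls below
   max(peak_threshold, 2 × residual SD).
3. **Joint re-fit.** All extracted Gaussians are re-fit simultaneously
   against the flattened spectrum; the aperiodic line is then re-fit on
   the peak-subtracted spectrum. One more alternation polishes both.
4. **Full simultaneous fit.** A final joint fit of
   (offset, χ, all peak parameters) with analytic Jacobian, warm-started
   from stage 3. This step is what achieves machine-precision
   round-trips on noiseless inputs and the tightest χ estimates.

Peaks below the height threshold after the joint re-fit are discarded
(the threshold is applied both at extraction and after re-fitting).
Gaussian σ is bounded to [0.5, 4] Hz, i.e. full width 2σ within the
1–8 Hz bandwidth limits. Fit quality is the squared Pearson correlation
between model and data log10 power; non-convergence never raises — the
fit is flagged with R² = 0 so the downstream quality filter removes it.

Numerical notes: the height threshold of 0.05 is interpreted in
log10-power units, the model's native space, treating the µV² unit
label sometimes attached to such thresholds as notational. "Bandwidth"
is taken as 2σ. Tolerances on the final optimizer are 1e-12; typical
per-spectrum cost is ~15 ms at 0.25 Hz resolution.

## Features, exclusion, and averaging

Electrode retention requires R² ≥ 0.8 at *both* timepoints; a failing
fit removes the electrode from both, and a patient with no retained
electrode is dropped with a logged reason. Band power uses closed
intervals on bins; peak-to-band assignment is closed-left/open-right
(a peak at exactly 4 Hz is theta, not delta) except alpha, which closes
at 12 Hz — a deterministic convention for boundary ties. Oscillation
power averages only over peak-bearing electrodes and is absent (NaN,
never zero-imputed) when no retained electrode has an in-band peak;
consequently a patient enters a band's oscillation-power paired test
only with at least one in-band peak at both timepoints. Abundance and
exponent use all retained electrodes. All differences are pre − post,
so post-treatment increases appear negative.

## Statistics

* **Gate.** Shapiro–Wilk on the paired differences at 0.05: normal →
  two-sided paired t with Cohen's d_z = mean(d)/sd(d) and mean ± sd
  descriptives; otherwise Wilcoxon signed-rank with Cliff's δ and
  median (IQR) descriptives.
* **Wilcoxon.** Zero differences dropped; W = min(W⁺, W⁻) on midranks.
  For n ≤ 25 the p-value is exact and tie-aware, computed from the full
  null distribution of W⁺ by the generating-polynomial recursion (ranks
  doubled so midranks become integers); above, a normal approximation
  with continuity correction and the exact rank variance Σrᵢ²/4.
* **Cliff's δ** over all n² cross pairs (the classical definition; no
  paired variant is used).
* **Holm–Bonferroni.** Ascending p-values, rank-k threshold
  α/(m−k+1), step-down rejection stopping at the first failure. Ties
  keep the declared family order. Both the step-down decision and the
  per-rank threshold comparison are reported, since printed results can
  be consistent with either. The eight-test EEG family (exponent; delta
  band power; delta/theta/alpha oscillation power; delta/theta/alpha
  abundance) yields the threshold ladder 0.00625 … 0.05; the three
  main effects of each band-power regression yield a lowest threshold
  of 0.0167.
* **Band-power regressions.** Δband power on Δexponent, Δabundance,
  Δoscillation power, all z-scored (so coefficients are standardized β),
  ordinary covariance, with Holm over the three main effects. Only
  oscillation-paired patients enter; n > 5 required.
* **Outcome model.** Normalized post HAM-D (score / scale maximum; 52
  for the 17-item, 76 for the 24-item scale) regressed on two fixed
  effects — normalized pre HAM-D and treatment type coded ECT = 0,
  MST = 1 — plus EEG candidates chosen by exhaustive search over
  {baseline exponent, baseline delta/theta abundance, Δexponent,
  Δdelta/Δtheta abundance, number of treatments}. Subsets are scored by
  adjusted R²; the default searches single added features, matching the
  one-extra-main-effect form of the published outcome model (full
  subset enumeration is available via `max_features=None`, but adjusted
  R² then admits any noise feature whose partial |t| > 1, which is why
  it is not the default). The winner is re-fit with an HC3
  heteroskedasticity-consistent covariance — squared residuals weighted
  by (1−hᵢᵢ)⁻² — with t-based inference on n−p degrees of freedom,
  appropriate for n < 250. Continuous predictors and the response are
  z-scored; the binary treatment indicator stays 0/1 (its β is a
  group-difference in response-SD units).
* **Remission** is a ≥ 50 % decrease from a positive baseline
  (boundary cases count as remitted); **topography** runs the same
  gated paired test per electrode, uncorrected, flagging electrodes
  missing in more than half the patients.

## The synthetic cohort generator

The generator is the validation instrument: it produces cohorts whose
every spectrum has known (offset, χ, peaks), so recovery and calibration
claims are checked against ground truth rather than against another
fitting tool.

* **Spectra** are the model evaluated on a 0.5–30 Hz grid at 0.25 Hz
  (a 4 s Welch window's resolution), with i.i.d. Gaussian noise added
  in log10 space — the same space as the fitting objective, so residual
  assumptions match. Default bin noise sd is 0.05, the scale of Welch
  scatter for ~10-minute recordings after log transform.
* **Recordings** are synthesized by coloring white Gaussian noise in
  the frequency domain with the full target PSD (aperiodic plus peak
  bumps), giving exact control of the expected Welch PSD; narrowband
  colored noise is intrinsically amplitude-modulated, so planted
  oscillations wax and wane like real ones. Below the grid the
  aperiodic trend is capped at its 0.5 Hz value; amplitudes are scaled
  so the PSD is in V²/Hz.
* **Exponent changes rotate the spectrum about a 30 Hz pivot** (power
  there is anchored), so steepening raises low-frequency power — the
  signature that makes aperiodic change masquerade as slowing.
* **Cohort presets.** The ECT-like arm draws baseline χ ~ N(0.88,
  0.21²) with a post-minus-pre shift N(0.37, 0.18²) (a d_z ≈ 2 planted
  effect), HAMD-17 baselines 20–28 reduced by ~12 ± 5 points; the
  MST-like arm uses χ ~ N(0.98, 0.18²), shift N(0.16, 0.20²), HAMD-24
  baselines 23–30 reduced by ~6 ± 5. Peak emergence is hierarchical —
  a patient-level presence gate times a per-channel Bernoulli — so
  roughly half of ECT-like patients lack any delta peak at baseline
  (zero-inflated abundance, and a delta-oscillation paired subset of
  roughly half the cohort), delta/theta peaks emerge after the ECT-like
  treatment but not the MST-like one, and alpha is near-ubiquitous
  throughout. Post HAM-D optionally depends linearly on baseline χ
  (default slope 0; the planted-model harness uses 12 score points per
  unit χ, a clearly recoverable effect at n = 33). Clinical scores are
  integers clipped to the scale.
* A fixed cohort seed reproduces the cohort bit-for-bit; the pipeline
  report is byte-identical across reruns of the same configuration.

What the generator does **not** emulate: artifacts (blinks, muscle),
electrode geometry and volume conduction, spectral knees,
within-recording nonstationarity, or correlated noise across channels
(channels are independent draws around patient-level parameters).
Passing calibrations therefore demonstrate the pipeline's statistical
behavior under the model's own assumptions — correct recovery, sign
conventions, family-wise error control, power at published effect
sizes — not robustness to real-world recording pathology, which the
quality filter only partially addresses.

## Problem sizes and runtime

Calibration experiments are sized to run on one CPU in minutes: power
and null calibrations use 50 replicate cohorts of 22 patients with 6
electrodes (patient-level features are electrode averages, so electrode
count affects only within-patient averaging noise and the granularity
of abundance); recovery uses 100 single-channel spectra with up to 3
resolvable peaks (centers 3–26 Hz, σ 0.6–1.0 Hz, separation at least
2.5× the summed widths — blended bumps closer than that are not
identifiable as distinct oscillations by any method). The full test
suite runs in roughly ten minutes; `scripts/acceptance.py` in roughly
the same.

## Known limitations

* Peaks near the fit-range edges (< 2 Hz or > 27 Hz centers) are
  truncated Gaussians and recover less accurately; the delta band's
  lower edge is inherently hard at 0.25 Hz resolution.
* Peaks of height ≈ 0.1 at bin-noise sd 0.05 sit at the detection
  floor; individual noise realizations can suppress them. Satellite
  peaks (small spurious Gaussians shouldering a true peak) occur at a
  rate of ~0.5 per noisy spectrum; they rarely affect band-level
  features because oscillation power takes the tallest in-band peak and
  abundance only asks whether any in-band peak exists.
* The Wilcoxon exact distribution is computed for n ≤ 25; beyond that
  the normal approximation is standard but approximate.
* EDF recordings are read via mne (optional extra); recordings are
  written as numeric CSV with a JSON sidecar rather than EDF.
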