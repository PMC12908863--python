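# Methods note

This note documents the model implemented by `wfoi`, the parameters and
their defaults, what the phantom does and does not emulate, the
numerical choices, and the known limitations. Every quantitative claim
here is computed by the test suite or by `scripts/acceptance.py`.

## Signal model

### Acquisition

A camera records an interleaved LED cycle, by default
470 → 530 → 470 → 656 nm at a camera frame rate of 20 Hz, i.e. each
channel is sampled at 5 Hz except 470 nm (two slots per cycle, 10 Hz).
Frame *i* of the raw stack belongs to cycle slot *i* mod *L*
(`stack_io.demultiplex`); gaps larger than 1.5× the median inter-frame
interval raise a dropped-frame warning. Dark counts are subtracted with
a floor of 1 count (a dark level above the stack median raises a
warning, since it usually indicates a channel-assignment error).

### Haemoglobin inversion (reflectance channels)

Relative intensity is computed against a baseline — either the
full-record mean or a `[t0, t1]` window (`stack_io.relative_series`);
pixels with non-positive baseline are flagged invalid and become NaN.
The modified Beer–Lambert law converts the ratio to an absorption
change at each wavelength:

    Δμa(λ) = −(1/X(λ)) · ln(I/I₀)        [cm⁻¹]

where X(λ) is the wavelength-dependent differential pathlength in cm.
With molar extinction coefficients ε (cm⁻¹ M⁻¹) converted to natural-log
form ζ = ln(10)·ε, the two-wavelength system is solved in closed form:

    det      = ζ_HbO(λ₁)·ζ_HHb(λ₂) − ζ_HbO(λ₂)·ζ_HHb(λ₁)
    Δ[HHb]   = (ζ_HbO(λ₁)·Δμa(λ₂) − ζ_HbO(λ₂)·Δμa(λ₁)) / det
    Δ[HbO]   = (ζ_HHb(λ₁)·Δμa(λ₂) − ζ_HHb(λ₂)·Δμa(λ₁)) / (−det)

Outputs are reported in µM (molar × 1e6); Δ[HbT] = Δ[HbO] + Δ[HHb]
exactly. The closed form agrees with a generic linear solver to
≤ 1e-10 µM over 1000 random inputs (tested). A condition number above
1e5 (e.g. two nearly equal wavelengths) raises a near-singular error.
With only one reflectance wavelength, a single-wavelength proxy
100·(I/I₀ − 1) is available; it warns unless the wavelength is within
5 nm of an isosbestic point, where HbO and HHb absorb equally and the
signal reflects total haemoglobin.

### Fluorescence correction (excitation channel)

Raw relative fluorescence confounds calcium-indicator activity with
haemoglobin absorption at the excitation (~470 nm) and emission
(~530 nm) bands. Two corrections are implemented plus a control:

* **MBLL**: `F_corr = F_raw · exp(Δμa_ex·X_ex + Δμa_em·X_em)`. With
  matched pathlengths this inverts the attenuation exactly (verified to
  ≤ 1e-10 relative error on the noise-free phantom).
* **LSR**: per pixel, ordinary least squares
  `F_raw = β0 + β1·Hb + ε` against a haemodynamic predictor (Δ[HbT], or
  the isosbestic proxy); the corrected trace is the residual + 1.
  Residuals are guaranteed to have zero mean (≤ 1e-10) and zero
  correlation with the predictor (≤ 1e-8) at every fitted pixel; a
  zero-variance predictor marks the pixel failed and falls back to
  β1 = 0 (mean-centred trace).
* **none**: identity control.

### Registration

Bregma and lambda annotations define a similarity transform
`p' = s·R·(p − bregma) + bregma_ref` that maps bregma to a reference
point and puts lambda caudal on the same image column; scale is fixed at
1 unless a reference axis length is given. Warping uses nearest or
bilinear interpolation; the identity transform is a bit-identical copy.

### Response metrics and statistics

ROI traces are cut into per-train epochs aligned to stimulus-train
onsets, baseline-subtracted over the pre-onset window. Metrics per
trial:

* **AUC**: trapezoidal area over an integration window — the
  stimulation epoch for calcium, 0–10 s after onset for haemoglobin,
  0–5 s for cumulative maps;
* **t90**: time at which the trace has recovered 90% of its peak
  deviation, measured from stimulus-train offset (the train of
  *n* pulses at rate *r* with pulse duration *d* lasts
  (n−1)/r + d seconds), linearly interpolated between samples; +inf if
  never recovered in-window, NaN if no peak exceeds the noise floor;
* **|PostAUC|**: absolute area of the below-baseline lobe over 0–2 s
  after train offset;
* **cumulative maps**: per-pixel integrals summed across trains,
  min–max normalised over the brain mask.

Rest/locomotion comparisons use Welch's unequal-variance t with
Welch–Satterthwaite df, pooled-SD Cohen's d, Levene's test
(mean-centred), Kruskal–Wallis, and Bonferroni-corrected pairwise
Mann–Whitney (p × number of pairs, capped at 1). Welch's t and Cohen's
d also accept (mean, sd, n) summaries, so published group tables can be
checked directly; the remaining tests are delegated to scipy.

## Parameters, units, defaults

| Parameter | Default | Unit | Rationale |
| --- | --- | --- | --- |
| wavelength pair | 530, 656 | nm | green/red reflectance LEDs; well-conditioned inversion |
| excitation / emission | 470 / 530 | nm | GCaMP-class indicator bands |
| X(λ) (pathlengths) | 0.056–0.30 | cm | literature-typical rodent-cortex values; **must be confirmed per preparation** (`data/pathlengths_default.yaml`) |
| extinction table | packaged synthetic CSV | cm⁻¹ M⁻¹ | see below |
| baseline | full-record mean (or window) | — | robust when stimulation occupies a small duty cycle |
| epoch window | (−2, +15) | s | covers the haemodynamic return to baseline |
| calcium AUC window | stimulation epoch | s | indicator kinetics are fast |
| Hb AUC window | 0–10 | s | haemodynamic response breadth |
| undershoot window | 0–2 after train offset | s | immediate post-stimulus lobe |
| t90 anchor | train offset | — | comparable across protocols |
| condition-number limit | 1e5 | — | guards degenerate wavelength pairs |

The packaged extinction table is a **synthetic stand-in**: PCHIP
interpolation through literature-anchored knots on a 1-nm grid
(450–700 nm), constructed so the HbO/HHb difference changes sign at the
five green-band isosbestic wavelengths. The tests verify five crossings
in 490–600 nm within ±6 nm of 500/530/545/570/584 nm (measured maximum
deviation ≈ 1 nm). Absolute magnitudes are approximate; users with a
calibrated table can load their own CSV (`ExtinctionTable.from_csv`).

## Phantom: what it emulates and what it does not

The phantom prescribes a separable ground truth — a stimulus-locked
time profile times a raised-cosine responsive disc — and renders camera
frames through the same Beer–Lambert forward model the analysis
inverts:

* haemodynamics: double-gamma kernel (peak 2 s, undershoot at 8 s,
  fraction 0.2) scaled to Δ[HbO] = +10 µM, Δ[HHb] = −3 µM at the disc
  centre;
* calcium: per-pulse rise/decay transients (τ_rise 50 ms, τ_decay
  400 ms), amplitude 5% ΔF/F;
* trial structure: multiplicative log-free amplitude jitter (CV 0.25);
  designated locomotion trials are scaled ×3.5 (calcium) and ×9.6
  (haemoglobin) — both ratios taken from published rest/locomotion AUC
  means (3.16/0.90 and 48.91/5.11);
* optics/nuisance: radial vignetting, optional slow sinusoidal drift,
  optional Gaussian read noise and Poisson shot noise.

Determinism contract: `seed` drives measurement noise only;
`amplitude_seed` drives the truth jitter, so different noise seeds share
identical ground truth and a fixed config is bit-reproducible.

Haemoglobin truth is held constant within each LED cycle
(`hemo_hold_per_cycle=True`). Haemodynamics are slow relative to one
0.2-s cycle, and the hold makes the interleaved forward model exactly
invertible channel-by-channel; the noise-free round trip then recovers
the prescribed fields to ~1e-13 µM and the fluorescence to ~4e-16
relative error (computed by the acceptance script).

Not emulated: spatially varying pathlengths, wavelength-dependent
scattering changes, indicator nonlinearity and photobleaching, motion,
vascular anatomy, and any departure of the real extinction spectra from
the synthetic table. The phantom validates the *inverse machinery*, not
biological realism.

## Numerical choices

* Trapezoidal integration for all areas (matches brute-force sums to
  1e-12; tested).
* Linear interpolation for extinction lookups and t90 crossings; no
  extrapolation outside the table range (raises).
* Closed-form 2×2 inversion instead of a per-pixel solver call (exact,
  vectorised; equivalence tested).
* Sessions are stored as float32 TIFF; this bounds on-disk round-trip
  recovery to ~1e-3 µM while in-memory identities hold at 1e-9 µM.
* Per-trial, per-pixel computations are fully vectorised over pixels;
  the 60-trial behaviour phantom runs end-to-end in a few seconds on one
  CPU.

## Limitations

* Pathlength defaults are literature-typical, not measured; absolute µM
  values scale inversely with X(λ) and should be treated as
  semi-quantitative until X is calibrated for the preparation.
* The synthetic extinction table preserves crossing structure, not
  exact magnitudes; quantitative oximetry requires a calibrated table.
* LSR removes only the component of fluorescence linear in the
  predictor; nonlinear or lagged haemodynamic coupling leaves residual
  artefact (the phantom comparison shows MBLL is exact and LSR
  approximate when the true coupling is exponential).
* Two-wavelength inversion assumes haemoglobin dominates absorption
  changes; other chromophores alias into Δ[HbO]/Δ[HHb].
* Behaviour statistics treat trials as independent; slow physiological
  state changes violate this and widen true error bars.
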