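# Methods

This note records the models behind `aoldv`, the parameter choices that
matter, what the synthetic generators do and do not emulate, and the
numerical decisions taken where the procedure left genuine freedom.

## Bidirectional Doppler velocimetry

A probing beam focused on a vessel is backscattered by moving red blood
cells; light collected along two directions separated by the angle
α = arctan(x/L) at the eye carries two Doppler cutoff frequencies whose
difference is independent of the (unknowable) angle between the incident beam
and the flow:

v_max = λ |f_A − f_B| / (n α cos β).

Assumptions: laminar flow with a parabolic (Poiseuille) velocity profile, so
the fastest scatterers sit on the axis and define a sharp spectral edge;
scatterer density uniform over the lumen cross-section, which makes the
Doppler shift uniformly distributed on [0, f_cut] and the spectrum a step.

Parameters (defaults in `OpticalConfig`):

| parameter | default | role |
| --- | --- | --- |
| `wavelength` | 830 nm | probing laser |
| `refractive_index` | 1.33 | plasma around the cells; standard aqueous value at NIR |
| `beam_separation_x` | 2.4 mm | aperture separation at the pupil; sets α ≈ 0.1 rad and keeps physiological Doppler differences (≤ ~5 kHz) far inside the 60 kHz Nyquist band |
| `axial_length_assumed` | 23.95 mm | population value used for α for **all** subjects; a subject's measured length enters only the pixel calibration |
| `sampling_rate`, `doppler_window` | 120 kHz, 30 ms | one spectrum pair per 100 ms frame; 33.3 Hz bins |
| `frames_per_acquisition` | 40 | one recording = 40 paired (image, spectrum) frames |

β defaults to zero: the instrument nulls it optically, and the residual error
is second-order (1/cos β − 1 ≈ 1.5 % at 10°). Sensitivity to the assumed eye
length is first-order but small: since flow ∝ 1/α, a +1 mm error in L changes
flow by α(L)/α(L+1) − 1 ≈ 1/L ≈ 4 %.

## Cutoff detection

The cutoff is located on the normalised cumulative spectrum
r_c(i) = Σ_{k≤i} s_k / Σ_{k≤N} s_k rather than on the raw spectrum, which
averages out per-bin fluctuation. Procedure: ordinary least-squares "plateau"
line over the last third of the bins (noise-only region by assumption);
k_x = the largest bin whose r_c lies at least 10 % below the plateau line's
local value; OLS "rise" line over bins 1..k_x; cutoff = intersection abscissa,
converted to Hz as f₁ + (i* − 1)·Δf. On a noise-free step the recovered
cutoff bin is *exact* for any step position ≥ 10 bins that leaves a third of
the band as plateau.

Numerical decisions:

- The normalisation of the cumulative sum is fixed by requiring r_c(N) = 1;
  the intersection abscissa is invariant to any positive rescaling, so this
  choice carries no consequences.
- The 10 % rule is read as *relative to the plateau line's local value* (not
  to the full r_c range); a 1e-9 relative tolerance absorbs float round-off
  when r_c sits exactly on the threshold.
- Quality flags: `no_cutoff` when the spectrum is all-zero, when no bin
  qualifies under the 10 % rule (k_x < 2), or when the rise slope does not
  exceed 5× the plateau slope (near-parallel lines — flat or noise-only
  spectra; the factor is configurable); `out_of_band` when the intersection
  falls outside (0, Nyquist]. Flagged spectra propagate as missing frames,
  never as numbers.
- Fits are unweighted OLS; bins are 1-based in the formulas and converted to
  Hz only at the boundary.

**Precision limit.** A single 30 ms spectrum has fully developed speckle:
each bin's power is exponentially distributed about its mean no matter how
many scatterers contribute. Monte-Carlo at a 5 kHz cutoff and SNR 20 shows
the single-spectrum cutoff estimator is unbiased with an error sd of ≈ 6–7
bins (≈ 220 Hz). Instrument-level precision therefore comes from averaging
the frames of an acquisition, which every acquisition-level routine here does
— identically biased channels also cancel in |f_A − f_B|.

## Diameter measurement

Pipeline per frame: spot detection (threshold at 80 % of the maximal
intensity, largest 8-connected component, intensity-weighted centroid) →
360×360 px ROI around the centroid, shifted inward at borders → second-order
polynomial illumination fit subtracted → orientation by normalised
cross-correlation with synthetic dark-bar templates → profiles perpendicular
to the centreline every 2 px (180 px long, bilinear interpolation) →
half-depth edge distance per profile → single-pass rejection outside
mean ± 3 sd → mean width, converted by d = n_px · 19.269 (L − 1.82)/373.87 µm
with the subject's measured axial length L.

Choices made where the procedure is underdetermined:

- **Templates.** Dark bars 60 px wide (a mid-range vein under the
  calibration), full-ROI length, Gaussian-smoothed edges (σ = 3 px), at 24
  angles in 15° increments; bars are 180°-symmetric, so 12 distinct
  correlations cover the grid and the winner is reported in [0, 180). The
  perpendicular offset is searched within ±60 px of the spot centroid at 1 px
  steps. The correlation is computed exactly from per-distance-bin sums
  (pixels binned by rounded perpendicular distance), which makes the search
  O(pixels) per angle. A peak correlation below 0.2 means no vessel.
- **Spot exclusion.** Pixels within 1.5 spot-FWHM (≈ 47 px) of the centroid
  are excluded from both the illumination fit and the template correlation:
  the beam is an instrument artifact, not illumination, and its bright core
  otherwise drags the polynomial upward exactly where the vessel is measured
  and repels the dark-bar template.
- **Centreline refinement.** A 60 px bar inside a wider vessel correlates
  equally well over a range of offsets, leaving the offset unidentified to
  roughly ±(vessel − bar)/2. After a first profile pass the centreline is
  re-centred on the median trough midpoint (when it is off by > 2 px) and the
  profiles re-measured once.
- **Edge criterion.** Half-depth crossings, located by linear interpolation,
  between a baseline and the profile minimum. The baseline is the profile's
  85th percentile rather than its median: a 120 px vessel occupies two thirds
  of the 180 px profile, putting the median *inside* the trough and
  collapsing the measured depth; a high percentile stays on true baseline up
  to ~145 px vessels while costing only ~1σ of noise bias (≈ 0.4 px at
  contrast-to-noise 20). The percentile and the max-gradient alternative are
  both exposed as parameters of `measure_edge_distance`.
- **Profile QC.** A profile is unusable (excluded, not fatal) when its trough
  depth is below 5× a difference-based robust noise estimate, when a bright
  intrusion rises above baseline by ≥ 25 % of the trough depth (the probing
  beam crossing the profile), or when an edge leaves the 180 px window.
- **Outlier pass.** The mean ± 3 sd rejection is a single pass with the n−1
  sd. Note a sample-size fact: a single outlier among n widths cannot exceed
  3 sample sd unless (n−1)/√n > 3, i.e. n ≥ 11 — with the ~100+ profiles of a
  real ROI this is immaterial, but tiny width lists cannot reject anything.

## Flow and conservation

F = π (d/2)² v_max/2 in µL/min (1 m³/s = 6×10¹⁰ µL/min; comparisons read at
0.1 µL/min). The ½ is the Poiseuille mean-velocity factor. An alternative
`in_vitro` convention without the ½ (F = π r² v_max) is exposed because
published capillary validation ranges follow that form; the linearity
experiment closes under either convention, and r² is unaffected by the
choice. Acquisition flow is the mean of per-frame flows over QC-passing
frames — flow is nonlinear in d, and each frame pairs one image with one
spectrum pair, so frame flows are averaged rather than averaged inputs
combined. Conservation at a junction is reported as
ΔF = F_PV − (F_DV1 + F_DV2) and ΔF/F_PV in percent, the caption-formula sign
convention; the published six-subject verification row is shipped as data
(`BIFURCATION_STUDY_*`) with its printed (sign-flipped) error row preserved
as printed, not "corrected".

## Synthetic generators

**Doppler records.** Each channel is a sum of 2000 unit tones with
independent random phases and frequencies uniform on [0, f_cut] — the exact
frequency law of Poiseuille flow with uniform scatterers — plus white
Gaussian noise at the prescribed signal-to-noise power ratio. The lower
channel's cutoff sits at `f_base` (default 1 kHz) and the upper at
`f_base + Δf(v_max)`; only the difference enters the velocity formula.
Frequencies are quantised to the window's 33.3 Hz spectral grid, which lets
the record be synthesised exactly with one inverse FFT; the realised signal
power is pinned to the tone-power target so the area under the spectrum is
independent of velocity (the same total scattered intensity reaches the
detector whatever the flow). An optional `edge_sigma_bins` jitter blurs the
spectral edge.

**Capillary mode** weights tone amplitudes by a Gaussian beam profile across
the capillary: Poiseuille maps radius to frequency (r²/R² = 1 − f/f_cut), so
a beam brightest on the axis enhances the spectrum just below the cutoff —
the characteristic in-vitro spectral peak. `beam_sigma_fraction` (beam σ as a
fraction of the capillary radius) defaults to 2.0, at which the deterministic
bias the convex cumulative spectrum induces in the two-line intersection
stays below 2 % (and cancels almost entirely in the two-channel difference);
as the fraction → ∞ the uniform spectrum is recovered.

**Fundus phantoms.** 16-bit frames composed of a quadratic illumination
surface + background (20000 counts), minus a dark vessel band (depth 8000)
whose cross-section is a bar of the nominal width with Gaussian-smoothed
edges (difference of Gaussian CDFs, σ = 3 px) — its half-depth points sit
exactly at the nominal edges, so the edge criterion recovers the nominal
width by construction and alternative criteria can be benchmarked against
the same truth — plus a Gaussian probing-beam spot (31 px FWHM ≈ 50 µm,
amplitude 40000) offset perpendicular to the centreline, plus white noise.
"Image SNR 20" means vessel contrast depth / noise sd = 20 (noise σ = 400).

**Bifurcations.** `make_conserved_bifurcation` solves the daughter
velocities from chosen diameters and a split fraction so parent and daughter
flows agree to 1e-9 relative before any measurement noise;
`simulate_bifurcation` then renders full paired acquisitions per vessel. All
randomness flows from one integer seed through splittable seed sequences;
identical seeds give bit-identical outputs.

**What the phantoms do not emulate:** speckle texture and photon statistics
of AO imaging, eye motion and blinks, residual wavefront error, vessel
curvature and taper, wall reflections (the central light reflex), multiple
vessels in the ROI, and pulsatility within an acquisition. Passing the
recovery tests therefore demonstrates correctness of the analysis chain on
idealised single-vessel scenes, not clinical robustness; the frame-exclusion
machinery (QC statuses per frame) is exercised by construction but its
real-world rejection rates cannot be reproduced in silico.

## Study sizes in the test suite

End-to-end checks run at sizes chosen to keep the default suite fast while
preserving the statistics they probe: phantom frames are rendered at
420×420 px (the analysed ROI is 360×360 either way, and the canonical
1040×1392 sensor frame is exercised separately), synthetic acquisitions use
10 frames per vessel (velocity precision scales as 1/√frames from the
speckle limit; 10 frames keep the 50-seed conservation median comfortably
inside its bound), and the linearity experiment uses the full 40-frame
acquisitions at 10 flow levels.

## Known limitations

- The cutoff detector assumes a single vessel in the beam; bimodal spectra
  (two vessels) are out of scope and will yield a single merged estimate or a
  `no_cutoff` flag.
- Single-spectrum velocity precision is speckle-limited (see above); per-frame
  velocities should never be interpreted individually.
- The diameter pipeline assumes a dark vessel on a brighter background with a
  single dominant trough per profile; arteries with a strong central reflex
  would need a two-trough edge criterion.
- The 15° template grid quantises orientation; the induced width error is
  ≤ 1/cos(7.5°) − 1 ≈ 0.9 %, negligible against the ±2 px recovery band but
  present.
- Flow assumes a circular lumen and fully developed Poiseuille flow; both are
  approximations near junctions, exactly where conservation is evaluated.
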