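# Methods

This note documents the models, parameter choices and numerical decisions
behind `phasorsted`, and what the synthetic data do and do not show about
real measurements.

## Acquisition model

The instrument is an 80 MHz pulsed-excitation laser-scanning microscope
with TCSPC detection: per pixel, photon micro-arrival times relative to
the sync pulse are histogrammed into `n_bins = 132` bins over the 12.5 ns
repetition period (≈95 ps bins, typical commercial TCSPC resolution). The
instrument response (IRF) is a Gaussian of FWHM 0.2 ns — matching a
~200 ps excitation pulse — centered 3σ after the sync edge and folded at
zero; the same IRF serves all channels. Excitation is a 2D Gaussian PSF
(σ = 100 nm, i.e. ≈235 nm FWHM, a realistic oil-immersion confocal spot at
these wavelengths); the scan pixel is 25 nm, as in typical STED recordings
(21–26 nm).

## Depletion model

Stimulated depletion is modeled as an extra decay channel with rate

    k_dep(r) = sted_power × depletion_cross_section × D(r)

active only during the depletion window `[0.2, 0.85] ns` after excitation
(200 ps pulse delay, 650 ps pulse width). The donut profile is
`D(r) = (2e·r²/w²)·exp(−2r²/w²)` — zero on axis, peak 1 at `r = w/√2` —
with waist `w = 300 nm`. Photons emitted before the window escape
depletion entirely; this reproduces the experimentally important
short-lifetime, confocal-resolution escape component. During the window
the decay races at rate `1/τ + k_dep` and only the fluorescence branch is
detected; after the window the natural rate resumes. The detected-photon
expectation per emitter/pixel pair is the product of excitation weight,
brightness and total fluorescence yield of this race, so a STED image
shows both a smaller effective PSF and a shorter mean lifetime from the
same mechanism — there is no separate "resolution knob".

The default `depletion_cross_section = 8 ns⁻¹` per unit power makes the
crest depletion rate ≈8–16 ns⁻¹ at powers 1–2, i.e. near-complete
depletion at the crest within the window. Together with the PSF and donut
geometry this puts the simulated STED/confocal FRC resolution ratio in the
2–2.5× range and compresses lifetime differences strongly — the operating
regime the analysis is designed for. An optional `donut_fill` adds a
constant floor to `D(r)` to mimic the depth-induced donut degradation that
makes lifetimes drift through a z-stack; it is 0 by default and only
qualitative. Anti-Stokes excitation by the depletion beam is an extra
excitation term proportional to the donut intensity, emitting with the
dye's natural lifetime during the depletion window; it is off for all dyes
except the CF680R preset (coefficient 0.02), where it produces the
characteristic haze.

## Scenes and photon budgets

Scene geometry is statistical, not anatomical: cytoskeletal filaments are
smoothed random walks (emitter every 0.4 px, ~12 nm transverse jitter),
mitochondria are elongated emitter blobs, nuclear pores are ~24-emitter
puncta on and inside an ellipse, and the plasma membrane is a perturbed
closed contour. Fiber generation keeps drawing until each structure holds
roughly its requested number of full field crossings, so no structure is
starved of signal by an early field exit. Structures sharing a spectral
channel cross spatially, so separation is never trivially solved by
geometry.

Per-emitter brightness values were chosen once so that simulated confocal
channels have brightest pixels in the several-hundred-to-~1500-photon
range typical of the targeted experiments (the five-color presets land at
≈1500/1580/700 for the near-red/far-red/red-shifted channels at 256²).
The red-shifted channel additionally carries a zero-lifetime reflection
hotspot in the lower-right corner (no notch filter available at that
excitation) and every channel has a weak 0.5 photon/pixel autofluorescence
background with a 1 ns lifetime.

Preset lifetimes are the published confocal values of the dye conjugates
they emulate: five_color = {STAR635P-ab 2.2, ATTO647N-phall 3.2, AF594-ab
2.6, WGA-CF594 1.8, CF680R-ab 1.7 ns}; the conjugate pairs
{phalloidin 3.4 / antibody 2.3} (STAR635P) and {3.6 / 2.5} (ATTO647N); the
three-dye far-red preset {2.0, 1.2, 3.5 ns}.

All randomness flows from one root seed through named child streams
(CRC32-keyed `SeedSequence`), so every artifact is bit-reproducible.

## Phasor pipeline

The transform uses bin centers `(k+½)·Δ` (unbiased for uniform within-bin
arrival) and harmonic 1 by default; higher harmonics are exposed but
refuse settings that alias (`ω·Δ > π`). Zero-intensity pixels carry NaN
and are excluded everywhere rather than mapped to (0, 0), which would
fabricate long-lifetime mass.

Calibration is standard phasor referencing: the complex correction
`z_analytic(τ_ref) / centroid(reference)` is applied multiplicatively.
Because IRF convolution and binning act (to first order) as common
multiplicative factors, this cancels both; the residual procedure bias is
below 1e-4 in G and S. The reference is a simulated uniform 2.5 ns
specimen with ~2×10⁶ photons, keeping the statistical calibration error
below ~5×10⁻⁴ so that peak lifetimes are stable at the one-decimal level.

Filtering smooths G and S independently (intensity untouched): a 3×3
NaN-aware median per pass (default, two passes) or stationary-wavelet
soft-threshold shrinkage for very low photon counts. The phasor histogram
spans the fixed window G ∈ [0, 1.05], S ∈ [−0.05, 0.6] (256² bins) so
reflection and noise remain visible; pixels below an intensity threshold
(default 25% of the channel's 99th intensity percentile) are excluded so
background pixels cannot form spurious clouds. Peak lifetimes are phase
lifetimes at histogram maxima, rounded to one decimal — the precision at
which such readouts are robust; ties break deterministically toward
smaller G, then smaller S. Multi-cloud readout takes the strongest local
maxima of the lightly smoothed histogram (σ = 2 bins, minimum separation
12 bins).

## Separation

Component positions come either from the analytic position of a nominal
lifetime, optionally snapped to the nearest histogram maximum within a
0.08 radius (a reproducible stand-in for interactively clicking cloud
centers), or directly from histogram peaks (used for STED arms, where
clouds sit far from the natural positions). Two-component unmixing is an
orthogonal projection onto the chord with the position parameter clamped
to [0, 1]; three components use barycentric coordinates with negative
weights clamped to zero and renormalized; clamped-pixel counts and
per-pixel residual distances are recorded so out-of-gamut behavior stays
auditable. Component images are `fraction × intensity`, with the last
component absorbing float rounding so per-pixel conservation is exact.
Three nearly collinear components trigger a warning and a low-confidence
flag (threshold 0.05 on triangle area over squared longest edge). Point-in-
polygon exclusion is boundary-inclusive.

The Tau-STED-style filter is a documented stand-in for proprietary vendor
filtering, in the spirit of lifetime-based background rejection under
continuous depletion: each pixel's phasor is projected onto the dye's STED
trajectory polyline; intensity is weighted by `u^center_weight` (u = 1 at
the natural-lifetime end, which corresponds to the donut center) times a
Gaussian kernel in off-trajectory distance (scale 0.05 by default), with
exclusion polygons zeroing reflection or bleed-through regions. Filtering
each photon half independently improves the measured FRC resolution of
simulated STED images.

## Metrics

Contribution follows the formula literally: percentiles (linear
interpolation) over the whole background-corrected images including
zeros; high threshold default 97th percentile, low threshold 60th (the
midpoint of the 50–70 band the procedure is designed around); ROIs smaller
than 10 pixels are flagged and excluded from aggregate means. Both raw
bleed-through and the P99-normalized contribution are reported, since the
normalization direction matters when channel brightnesses differ. With
overlapping biology the statistic is an upper bound on true optical
spillover — the simulator reproduces this: crossing structures with zero
injected spillover still yield positive contributions.

FRC uses one block per image, a Tukey window (α = 0.25) to stop structures
cut by the field of view from leaking broadband power through the periodic
FFT boundary, integer-radius rings, the fixed 1/7 threshold and linear
interpolation between rings; no curve smoothing. Input pairs are binomial
photon splits of a single acquisition — a deliberate, declared deviation
from acquiring matched image pairs, exact for Poisson data. Non-square
images are zero-padded after mean subtraction.

## Pipeline

The five-color run processes channels frame-sequentially with no
cross-channel state. The CF680R channel is handled by exclusion filtering
of the reflection corner rather than unmixing, since only one color needs
extraction there. STED-arm unmixing includes a background component at
(1, 0). For FRC of separated components, each photon half is separately
phasor-transformed and unmixed with shared component positions, keeping
the two inputs independent. Problem sizes default to 256² for the
five-color scene and 128² for the pairs; the full test suite and the
acceptance script run the complete chain at these sizes in a few minutes
on one CPU.

## What passing tests do and do not show

The simulator realizes Poisson counting statistics, IRF blur, incomplete
decay wrap-around, depletion physics, reflection, haze and crossing
structures — the features that make phasor separation hard in practice.
It does not model detector afterpulsing or dead time, fluorophore
blinking and bleaching, vectorial/3D PSFs, refractive-index-dependent
donut distortion (beyond the scalar fill), spectral bleed-through between
detection windows, or multi-exponential conjugate decays (presets are
monoexponential; the machinery supports multi-exponential dyes).
Recovery of the preset lifetimes therefore validates the analysis chain
and its noise robustness, not the photophysics of any particular dye on
any particular microscope; absolute FRC values are sample- and
budget-dependent and only the confocal/STED ratio is meaningful here.

## Known limitations

Three-component separation of near-collinear dyes is intrinsically
ill-conditioned — reproduced here as a documented failure (the
middle-lifetime component is recovered worse than either component of a
two-dye separation). STED-arm separation of conjugate pairs fails a 0.15
fraction-RMSE gate that the confocal arm passes, mirroring the compressed
lifetime differences under depletion. The exclusion-triangle geometry for
the reflection corner is fixed rather than fitted; the Tau-STED weighting
law is a declared approximation, not a reverse-engineered vendor
algorithm.
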