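# phasorsted

Phasor-based fluorescence-lifetime separation for multi-color confocal and
STED microscopy, with a photon-level TCSPC simulator, crosstalk
quantification and FRC resolution estimation.

## The problem

STED microscopes reach super-resolution by depleting fluorescence around a
diffraction-limited excitation spot with a donut-shaped beam. Using a
single depletion wavelength (775 nm) avoids alignment and bleaching
problems but limits the number of usable spectral channels to about three.
Fluorescence lifetime offers a second axis: two dyes with similar emission
spectra but different excited-state lifetimes can share a spectral channel
and be separated computationally, doubling the number of distinguishable
labels — five colors from three channels, with room for more.

This package implements that analysis chain for people who want to study,
test or extend it quantitatively: a simulator that generates time-resolved
(TCSPC) image stacks with known ground truth, the phasor transform and its
calibration, linear unmixing in phasor space, a Tau-STED-style trajectory
filter, and the two quantitative read-outs used to judge such experiments —
a crosstalk "contribution" statistic and Fourier ring correlation (FRC).

## The core math

Each pixel's micro-arrival-time histogram `c_k` (bin centers `t_k`) maps to
a point in the phasor plane at the laser repetition frequency
`ω = 2πf_rep`:

    G = Σ c_k cos(ω t_k) / Σ c_k        S = Σ c_k sin(ω t_k) / Σ c_k

A monoexponential decay with lifetime τ sits on the **universal circle**
at `G = 1/(1+(ωτ)²)`, `S = ωτ/(1+(ωτ)²)`; multiexponential decays fall
inside; zero lifetime (reflection) is at (1, 0). A pixel mixing photons
from two species lies on the chord between the pure positions, at the
photon-weighted fraction — the *linear property*. Separation is therefore
a projection: onto the chord for two components (fraction = position
parameter) or barycentric coordinates for three. Phase lifetime is read
back as `τ_φ = S/(Gω)`.

Under stimulated depletion the decay gains an extra rate `k_dep`, so the
observed lifetime is `1/(1/τ + k_dep)`. Because the donut intensity varies
across the focal spot, each dye traces a *STED trajectory* along the
universal circle from its natural position toward (1, 0); photons
off-trajectory (reflection, haze, bleed-through) or near its depleted end
(donut-crest periphery) can be filtered out.

Crosstalk between separated channels is measured on background-corrected
images: `bleed_through` = mean neighbor / mean home intensity over an ROI
holding strong home signal but no neighbor structure (high-percentile home
mask minus low-percentile neighbor mask), and
`contribution = bleed_through × P99(home)/P99(neighbor)` normalizes for
staining brightness. FRC correlates two independent photon halves of the
same image ring by ring in Fourier space; the first crossing below 1/7
estimates resolution.

## Worked example

`python examples/five_color_separation.py` simulates the far-red channel
of the five-color scene — STAR635P-antibody on mitochondria (2.2 ns) and
ATTO647N-phalloidin on actin (3.2 ns) — and separates it:

```
simulated far-red channel: 8,371,489 photons, brightest pixel 1578
recovered cloud lifetimes: [2.2, 3.2] ns (ground truth: 2.2 antibody conjugate, 3.2 phalloidin conjugate)
  mitochondria: 1,887,787 photons
         actin: 6,483,702 photons
component images sum exactly to the channel intensity: True
```

The two phasor clouds read back the dye lifetimes at one decimal, and the
unmixed component images conserve the channel's photons exactly. Other
examples cover the lifetime shortening under increasing STED power
(`sted_lifetime_shift.py`), crosstalk recovery of an injected 8% spillover
(`crosstalk_contribution.py`), the ~2.3× FRC resolution gain of STED over
confocal (`frc_resolution.py`), and the full five-color pipeline with its
CSV reports (`run_full_pipeline.py`).

A thin CLI mirrors the library:
`phasorsted simulate|phasor|separate|crosstalk|frc|run-five-color --help`.

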