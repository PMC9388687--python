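"""Phasor transform, calibration, filtering, histograms and peak readout.

Each pixel's micro-time histogram maps to a point (G, S) — the cosine and
sine Fourier coefficients at the (harmonic of the) laser repetition
frequency.  Monoexponential decays lie on the universal circle
(g - 1/2)^2 + s^2 = 1/4; multiexponential decays fall inside; a mixture of
two species lies on the chord between them, weighted by photon fractions.
Short lifetimes sit to the right (toward (1, 0), zero lifetime), long
lifetimes to the left; the scale is non-linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .simulate import TCSPCImage

__all__ = [
    "PhasorField",
    "CalibrationFactor",
    "analytic_phasor",
    "phase_lifetime",
    "phasor_transform",
    "compute_calibration",
    "apply_calibration",
    "calibrate",
    "spatial_filter",
    "PhasorHistogram",
    "phasor_histogram",
    "peak_lifetime",
    "peak_lifetimes",
    "histogram_peaks",
]

# histogram domain: slightly beyond the physical range so reflection at
# (1, 0) and noise excursions remain visible
HIST_G_RANGE = (0.0, 1.05)
HIST_S_RANGE = (-0.05, 0.6)


def analytic_phasor(tau, omega) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form phasor of a monoexponential decay: the point on the
    universal circle at g = 1/(1+(wt)^2), s = wt/(1+(wt)^2)."""
    tau = np.asarray(tau, dtype=float)
    wt = omega * tau
    den = 1.0 + wt**2
    return 1.0 / den, wt / den


def phase_lifetime(g, s, omega):
    """Phase lifetime tau_phi = s / (g * omega)."""
    return np.asarray(s) / (np.asarray(g) * omega)


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates with photon totals.

    Zero-intensity (or otherwise invalid) pixels carry NaN in g and s and
    are excluded from histograms, calibration centroids and separation.
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    omega: float  # rad/ns
    harmonic: int = 1

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (self.g.shape == self.s.shape == self.intensity.shape):
            raise ValueError("g, s, intensity must share a shape")
        if self.harmonic < 1:
            raise ValueError("harmonic must be >= 1")

    @property
    def valid(self) -> np.ndarray:
        return (self.intensity > 0) & np.isfinite(self.g) & np.isfinite(self.s)

    @property
    def z(self) -> np.ndarray:
        """Complex phasor g + i s."""
        return self.g + 1j * self.s

    def centroid(self) -> complex:
        """Intensity-weighted mean phasor over valid pixels."""
        m = self.valid
        wsum = self.intensity[m].sum()
        if wsum == 0:
            raise ValueError("no valid pixels")
        return complex((self.intensity[m] * self.z[m]).sum() / wsum)


@dataclass(frozen=True)
class CalibrationFactor:
    """Multiplicative phasor correction: rotation + modulation scaling."""

    phase_shift: float  # radians
    modulation_scale: float

    def __post_init__(self) -> None:
        if self.modulation_scale <= 0:
            raise ValueError("modulation_scale must be > 0")

    @property
    def factor(self) -> complex:
        return self.modulation_scale * np.exp(1j * self.phase_shift)

    def inverse(self) -> "CalibrationFactor":
        return CalibrationFactor(-self.phase_shift, 1.0 / self.modulation_scale)


def phasor_transform(img: TCSPCImage, harmonic: int = 1) -> PhasorField:
    """Per-pixel phasor of a TCSPC image.

    With bin centers t_k = (k + 1/2) * bin_width and counts c_k:
    g = sum c_k cos(w t_k) / sum c_k, s = sum c_k sin(w t_k) / sum c_k.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    inst = img.instrument
    omega = harmonic * 2.0 * np.pi / inst.rep_period
    if omega * inst.bin_width > np.pi:
        raise ValueError(
            f"harmonic {harmonic} aliases at {inst.n_bins} bins "
            "(omega * bin_width > pi)")
    t = img.bin_centers
    cosw = np.cos(omega * t)
    sinw = np.sin(omega * t)
    c = img.counts.astype(float)
    total = c.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (c @ cosw) / total
        s = (c @ sinw) / total
    empty = total == 0
    g[empty] = np.nan
    s[empty] = np.nan
    return PhasorField(g=g, s=s, intensity=total, omega=omega, harmonic=harmonic)


def compute_calibration(reference: PhasorField, tau_ref: float) -> CalibrationFactor:
    """Correction that moves the reference centroid onto the analytic phasor
    of its known lifetime, compensating IRF phase delay and modulation loss."""
    cen = reference.centroid()
    if abs(cen) < 1e-12:
        raise ValueError("reference centroid at the origin; cannot calibrate")
    gt, st = analytic_phasor(tau_ref, reference.omega)
    corr = complex(gt, st) / cen
    return CalibrationFactor(phase_shift=float(np.angle(corr)),
                             modulation_scale=float(abs(corr)))


def apply_calibration(field: PhasorField, cal: CalibrationFactor) -> PhasorField:
    zc = field.z * cal.factor
    return replace(field, g=zc.real, s=zc.imag)


def calibrate(field: PhasorField, reference: PhasorField, tau_ref: float) -> PhasorField:
    """Calibrate ``field`` against a uniform known-lifetime reference
    measured with the same instrument settings."""
    if reference.omega != field.omega:
        raise ValueError("reference and field must share omega")
    return apply_calibration(field, compute_calibration(reference, tau_ref))


# ---------------------------------------------------------------------------
# filtering


def _nanmedian3(a: np.ndarray) -> np.ndarray:
    """3x3 NaN-aware median via shifted stacking (edges use the available
    neighbors)."""
    h, w = a.shape
    pad = np.full((h + 2, w + 2), np.nan)
    pad[1:-1, 1:-1] = a
    stack = np.empty((9, h, w))
    idx = 0
    for dy in (0, 1, 2):
        for dx in (0, 1, 2):
            stack[idx] = pad[dy:dy + h, dx:dx + w]
            idx += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(stack, axis=0)


def _wavelet_denoise(a: np.ndarray) -> np.ndarray:
    """One pass of stationary (a-trous) wavelet soft-threshold shrinkage."""
    import pywt

    nan = ~np.isfinite(a)
    filled = a.copy()
    if nan.any():
        filled[nan] = np.nanmedian(a) if np.isfinite(a).any() else 0.0
    # pad to even shape for swt2
    h, w = filled.shape
    ph, pw = h + h % 2, w + w % 2
    padded = np.pad(filled, ((0, ph - h), (0, pw - w)), mode="edge")
    coeffs = pywt.swt2(padded, "sym4", level=1, norm=True)
    (ca, (ch, cv, cd)), = coeffs
    sigma = np.median(np.abs(cd - np.median(cd))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(cd.size))
    shrink = lambda c: np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)
    out = pywt.iswt2([(ca, (shrink(ch), shrink(cv), shrink(cd)))], "sym4", norm=True)
    out = out[:h, :w]
    out[nan] = np.nan
    return out


def spatial_filter(field: PhasorField, method: str = "median", passes: int = 1) -> PhasorField:
    """Smooth g and s independently; intensity is untouched.

    ``median`` applies a 3x3 NaN-aware median per pass; ``wavelet`` applies
    stationary-wavelet soft-threshold shrinkage, which preserves structure
    at the very low photon counts typical of STED.
    """
    if passes < 0:
        raise ValueError("passes must be >= 0")
    if method not in ("median", "wavelet"):
        raise ValueError(f"unknown filter method {method!r}")
    g, s = field.g.copy(), field.s.copy()
    invalid = ~field.valid
    for _ in range(passes):
        if method == "median":
            g = _nanmedian3(g)
            s = _nanmedian3(s)
        else:
            g = _wavelet_denoise(g)
            s = _wavelet_denoise(s)
    g[invalid] = np.nan
    s[invalid] = np.nan
    return replace(field, g=g, s=s)


# ---------------------------------------------------------------------------
# histogram and peak readout


@dataclass
class PhasorHistogram:
    """2D pixel-count histogram over the phasor plane."""

    counts: np.ndarray  # (bins_g, bins_s)
    g_edges: np.ndarray
    s_edges: np.ndarray
    omega: float

    @property
    def g_centers(self) -> np.ndarray:
        return 0.5 * (self.g_edges[:-1] + self.g_edges[1:])

    @property
    def s_centers(self) -> np.ndarray:
        return 0.5 * (self.s_edges[:-1] + self.s_edges[1:])


def phasor_histogram(field: PhasorField, bins: int = 256,
                     intensity_threshold: float = 0.0) -> PhasorHistogram:
    """Histogram of valid pixels with intensity >= threshold over the fixed
    domain g in [0, 1.05], s in [-0.05, 0.6]."""
    if bins < 32:
        raise ValueError("bins must be >= 32")
    m = field.valid & (field.intensity >= intensity_threshold)
    counts, ge, se = np.histogram2d(field.g[m], field.s[m], bins=bins,
                                    range=[HIST_G_RANGE, HIST_S_RANGE])
    return PhasorHistogram(counts=counts, g_edges=ge, s_edges=se, omega=field.omega)


def _peak_tau(gc: float, sc: float, omega: float) -> float:
    if gc <= 0:
        raise ValueError("histogram peak at g <= 0: lifetime undefined")
    tau = phase_lifetime(gc, sc, omega)
    # bins straddling (1, 0) read as zero lifetime by convention
    return round(float(max(tau, 0.0)), 1)


def peak_lifetime(hist: PhasorHistogram) -> float:
    """Phase lifetime (ns, one decimal) at the most occupied histogram bin.

    Ties break deterministically toward the smallest g, then smallest s.
    """
    if hist.counts.sum() == 0:
        raise ValueError("empty phasor histogram")
    flat = np.argmax(hist.counts)  # row-major: first = smallest g, then s
    i, j = np.unravel_index(flat, hist.counts.shape)
    return _peak_tau(hist.g_centers[i], hist.s_centers[j], hist.omega)


def histogram_peaks(hist: PhasorHistogram, n_peaks: int = 2,
                    smooth_sigma: float = 2.0, min_distance: int = 12):
    """(g, s, count) of the ``n_peaks`` strongest local maxima of the
    lightly smoothed histogram, strongest first."""
    from skimage.feature import peak_local_max

    if hist.counts.sum() == 0:
        raise ValueError("empty phasor histogram")
    smoothed = ndimage.gaussian_filter(hist.counts, smooth_sigma)
    coords = peak_local_max(smoothed, min_distance=min_distance,
                            num_peaks=n_peaks, exclude_border=False)
    return [(float(hist.g_centers[i]), float(hist.s_centers[j]),
             float(smoothed[i, j])) for i, j in coords]


def peak_lifetimes(hist: PhasorHistogram, n_peaks: int = 2,
                   smooth_sigma: float = 2.0, min_distance: int = 12):
    """Lifetimes (ns, one decimal) of the ``n_peaks`` strongest local maxima
    of the smoothed histogram, sorted ascending.

    The multi-cloud analogue of :func:`peak_lifetime`: each cloud of a
    two-dye channel yields one peak.
    """
    peaks = histogram_peaks(hist, n_peaks, smooth_sigma, min_distance)
    return sorted(_peak_tau(g, s, hist.omega) for g, s, _ in peaks)
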