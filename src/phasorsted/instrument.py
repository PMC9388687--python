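"""Instrument and dye descriptions.

The instrument model is an 80 MHz pulsed-excitation TCSPC detector: photon
micro-arrival times relative to the excitation pulse are histogrammed into
``n_bins`` bins spanning one repetition period.  STED depletion is a pulsed
775 nm donut beam arriving ``sted_delay`` after excitation and acting for
``sted_pulse_width``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List

__all__ = ["InstrumentConfig", "DyeSpec"]


@dataclass(frozen=True)
class InstrumentConfig:
    """Acquisition geometry and timing.

    Parameters
    ----------
    rep_period : float
        Laser repetition period in ns (12.5 ns = 80 MHz).
    n_bins : int
        Micro-time bins per period (132 bins ≈ 95 ps at the default period).
    irf_fwhm : float
        FWHM of the Gaussian instrument response, ns.
    sted_delay, sted_pulse_width : float
        Depletion-pulse arrival (after excitation) and duration, ns.
    exc_psf_sigma : float
        Gaussian excitation PSF sigma, nm.
    donut_waist : float
        Depletion donut waist parameter w, nm; the crest sits at w/sqrt(2).
    pixel_size : float
        Scan pixel size, nm.
    """

    rep_period: float = 12.5
    n_bins: int = 132
    irf_fwhm: float = 0.2
    sted_delay: float = 0.2
    sted_pulse_width: float = 0.65
    exc_psf_sigma: float = 100.0
    donut_waist: float = 300.0
    pixel_size: float = 25.0

    def __post_init__(self) -> None:
        if self.rep_period <= 0:
            raise ValueError("rep_period must be > 0")
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")
        for name in ("irf_fwhm", "sted_delay", "sted_pulse_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sted_delay + self.sted_pulse_width >= self.rep_period:
            raise ValueError("STED pulse must end within the repetition period")
        if self.exc_psf_sigma <= 0 or self.donut_waist <= 0 or self.pixel_size <= 0:
            raise ValueError("PSF widths and pixel size must be > 0")

    @property
    def bin_width(self) -> float:
        """Micro-time bin width, ns."""
        return self.rep_period / self.n_bins

    @property
    def irf_sigma(self) -> float:
        """Gaussian IRF sigma, ns."""
        return self.irf_fwhm / 2.3548200450309493

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        return cls(**d)


@dataclass(frozen=True)
class DyeSpec:
    """Photophysics of one fluorochrome conjugate.

    ``lifetimes``/``amplitudes`` describe a (multi-)exponential decay; the
    amplitudes are photon fractions and must sum to 1.  ``brightness`` is the
    expected number of detected photons per emitter at unit exposure when the
    scan beam is centred on it.  ``depletion_cross_section`` converts STED
    beam intensity (``sted_power`` times the donut profile) into an extra
    de-excitation rate in ns^-1.  ``anti_stokes_coeff`` adds haze from direct
    excitation by the depletion beam, emitting with the natural lifetime.
    """

    label: str
    lifetimes: List[float] = field(default_factory=lambda: [2.5])
    amplitudes: List[float] = field(default_factory=lambda: [1.0])
    brightness: float = 10.0
    depletion_cross_section: float = 8.0
    anti_stokes_coeff: float = 0.0

    def __post_init__(self) -> None:
        if len(self.lifetimes) != len(self.amplitudes) or not self.lifetimes:
            raise ValueError("lifetimes and amplitudes must be equal-length, non-empty")
        if any(t <= 0 for t in self.lifetimes):
            raise ValueError("all lifetimes must be > 0")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")
        if abs(sum(self.amplitudes) - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")
        if self.depletion_cross_section < 0 or self.anti_stokes_coeff < 0:
            raise ValueError("rates must be >= 0")

    @property
    def mean_lifetime(self) -> float:
        return float(sum(a * t for a, t in zip(self.amplitudes, self.lifetimes)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DyeSpec":
        return cls(**d)
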