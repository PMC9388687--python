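"""Crosstalk ("contribution") statistic and Fourier ring correlation.

Crosstalk between separated channels is measured on background-corrected
intensity images: an ROI is built from the pixels above a high percentile
of the home channel, minus the pixels above a low percentile of the
neighboring channel (so the ROI holds strong home signal where no neighbor
structure should be).  Bleed-through is the ratio of mean neighbor to mean
home intensity over that ROI; the contribution value additionally
normalizes by the ratio of the channels' 99th intensity percentiles, so
that the number is comparable across differently bright stainings.  With
spatially overlapping biology the statistic is an upper bound on true
optical spillover.

FRC correlates the Fourier transforms of two independent realizations of
the same field ring by ring; the first crossing of the 1/7 threshold
estimates the resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "subtract_background",
    "contribution_pair",
    "ContributionReport",
    "contribution_matrix",
    "FRCResult",
    "frc_curve",
]

MIN_ROI_PIXELS = 10


def subtract_background(image: np.ndarray, bg_region: np.ndarray) -> np.ndarray:
    """Subtract the mean over a structure-free region, flooring at 0.

    ``bg_region`` is a boolean mask shared by all channels of an image set.
    """
    image = np.asarray(image, dtype=float)
    bg_region = np.asarray(bg_region, dtype=bool)
    if bg_region.shape != image.shape:
        raise ValueError("bg_region mask must match the image shape")
    if not bg_region.any():
        raise ValueError("background region is empty")
    return np.maximum(image - image[bg_region].mean(), 0.0)


def contribution_pair(home: np.ndarray, neighbor: np.ndarray,
                      high_pct: float = 97.0, low_pct: float = 60.0) -> Dict[str, float]:
    """Bleed-through and contribution of the home channel's ROI signal into
    a neighboring channel.

    ROI = {home >= P_high(home)} minus {neighbor >= P_low(neighbor)};
    bleed_through = mean(neighbor | ROI) / mean(home | ROI);
    contribution = bleed_through * P99(home) / P99(neighbor).
    Percentiles are taken over the whole background-corrected images,
    zeros included.  An ROI below ``MIN_ROI_PIXELS`` pixels (or a zero home
    mean) is flagged and excluded from aggregates.
    """
    home = np.asarray(home, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if home.shape != neighbor.shape:
        raise ValueError("home and neighbor must share a shape")
    if not (90.0 <= high_pct <= 100.0):
        raise ValueError("high_pct should be a high percentile (>= 90)")
    if not (40.0 <= low_pct <= 80.0):
        raise ValueError("low_pct should be a mid percentile (40-80)")
    roi = (home >= np.percentile(home, high_pct)) \
        & ~(neighbor >= np.percentile(neighbor, low_pct))
    n_roi = int(roi.sum())
    p99_home = float(np.percentile(home, 99.0))
    p99_neigh = float(np.percentile(neighbor, 99.0))
    flagged = n_roi < MIN_ROI_PIXELS or home[roi].sum() == 0 or p99_neigh == 0
    if flagged:
        return {"bleed_through": np.nan, "contribution": np.nan,
                "roi_pixel_count": n_roi, "flagged": True}
    bleed = float(neighbor[roi].mean() / home[roi].mean())
    contribution = bleed * p99_home / p99_neigh
    return {"bleed_through": bleed, "contribution": contribution,
            "roi_pixel_count": n_roi, "flagged": False}


@dataclass
class ContributionReport:
    """Per-pair crosstalk over one or more image sets."""

    per_set: pd.DataFrame   # columns: set, home, neighbor, bleed_through, contribution, roi_pixel_count, flagged, lifetime_separated
    summary: pd.DataFrame   # per pair: mean/SD of bleed_through and contribution, n
    high_pct: float
    low_pct: float

    def pair_mean(self, home: str, neighbor: str, column: str = "contribution") -> float:
        row = self.summary[(self.summary.home == home) & (self.summary.neighbor == neighbor)]
        if row.empty:
            raise KeyError((home, neighbor))
        return float(row[f"{column}_mean"].iloc[0])


def contribution_matrix(sets: Sequence[Dict[str, np.ndarray]],
                        high_pct: float = 97.0, low_pct: float = 60.0,
                        spectral_groups: Optional[Dict[str, int]] = None,
                        ) -> ContributionReport:
    """All ordered channel pairs of every image set, plus across-set
    mean +/- SD per pair.

    ``sets`` maps channel label -> background-corrected image, with
    identical labels in every set.  ``spectral_groups`` (label -> spectral
    channel index) tags pairs that were generated by lifetime separation
    from the same raw spectral image.
    """
    if not sets:
        raise ValueError("need at least one image set")
    labels = list(sets[0].keys())
    rows = []
    for i_set, chans in enumerate(sets):
        if list(chans.keys()) != labels:
            raise ValueError("inconsistent channel labels across sets")
        for home in labels:
            for neighbor in labels:
                if home == neighbor:
                    continue
                res = contribution_pair(chans[home], chans[neighbor], high_pct, low_pct)
                same_spectral = bool(
                    spectral_groups is not None
                    and spectral_groups.get(home) == spectral_groups.get(neighbor))
                rows.append({"set": i_set, "home": home, "neighbor": neighbor,
                             **res, "lifetime_separated": same_spectral})
    per_set = pd.DataFrame(rows)
    ok = per_set[~per_set.flagged]
    summary = (ok.groupby(["home", "neighbor"], sort=False)
               .agg(bleed_through_mean=("bleed_through", "mean"),
                    bleed_through_sd=("bleed_through", "std"),
                    contribution_mean=("contribution", "mean"),
                    contribution_sd=("contribution", "std"),
                    n=("contribution", "size"),
                    lifetime_separated=("lifetime_separated", "first"))
               .reset_index())
    return ContributionReport(per_set=per_set, summary=summary,
                              high_pct=high_pct, low_pct=low_pct)


# ---------------------------------------------------------------------------
# Fourier ring correlation


@dataclass
class FRCResult:
    """Ring-wise Fourier correlation and the threshold-crossing resolution."""

    spatial_frequencies: np.ndarray  # 1/nm, ring centers
    correlation: np.ndarray
    resolution: float                # nm; NaN if the curve never crosses
    threshold: float = 1.0 / 7.0

    @property
    def crossed(self) -> bool:
        return bool(np.isfinite(self.resolution))


def frc_curve(img_a: np.ndarray, img_b: np.ndarray, pixel_size: float,
              threshold: float = 1.0 / 7.0, tukey_alpha: float = 0.25) -> FRCResult:
    """Fourier ring correlation of two independent realizations.

    Whole images are analyzed (one block per image).  Non-square inputs are
    zero-padded to square after mean subtraction.  A Tukey window
    (``tukey_alpha`` taper fraction) apodizes the edges so structures cut by
    the field of view do not leak broadband power through the periodic FFT
    boundary.  The resolution is the inverse of the frequency at the first
    crossing below ``threshold``, linearly interpolated between rings; no
    smoothing is applied beyond the ring averaging.
    """
    from scipy.signal.windows import tukey

    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if a.ndim != 2:
        raise ValueError("images must be 2D")
    a = a - a.mean()
    b = b - b.mean()
    if a.shape[0] != a.shape[1]:
        n = max(a.shape)
        pa = np.zeros((n, n))
        pb = np.zeros((n, n))
        pa[: a.shape[0], : a.shape[1]] = a
        pb[: b.shape[0], : b.shape[1]] = b
        a, b = pa, pb
    n = a.shape[0]
    if tukey_alpha > 0:
        win = np.outer(tukey(n, tukey_alpha), tukey(n, tukey_alpha))
        a = a * win
        b = b * win
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    yy, xx = np.indices((n, n))
    c = n // 2
    r = np.rint(np.hypot(yy - c, xx - c)).astype(int)
    n_rings = n // 2
    num = np.bincount(r.ravel(), weights=(fa * np.conj(fb)).real.ravel(), minlength=n_rings)
    den_a = np.bincount(r.ravel(), weights=(np.abs(fa) ** 2).ravel(), minlength=n_rings)
    den_b = np.bincount(r.ravel(), weights=(np.abs(fb) ** 2).ravel(), minlength=n_rings)
    rings = np.arange(1, n_rings)  # ring 0 is DC
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num[rings] / np.sqrt(den_a[rings] * den_b[rings])
    corr = np.nan_to_num(corr, nan=0.0)
    freqs = rings / (n * pixel_size)

    resolution = np.nan
    below = corr < threshold
    if below.any():
        i = int(np.argmax(below))
        if i == 0:
            resolution = 1.0 / freqs[0]
        else:
            f0, f1 = freqs[i - 1], freqs[i]
            c0, c1 = corr[i - 1], corr[i]
            fc = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
            resolution = 1.0 / fc
    return FRCResult(spatial_frequencies=freqs, correlation=corr,
                     resolution=float(resolution), threshold=threshold)
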