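"""Linear phasor unmixing, exclusion polygons and the STED-trajectory filter.

The linear property of the phasor — a pixel mixing photons from several
species sits at the photon-weighted average of the species' phasors — makes
separation a geometric projection: onto the chord between two component
positions, or barycentric coordinates in a triangle of three.  Component
positions are reference points in the phasor plane, placed either at the
analytic position of a nominal lifetime or snapped to histogram peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import shapely

from .phasor import PhasorField, PhasorHistogram, analytic_phasor

__all__ = [
    "Component",
    "UnmixResult",
    "ExclusionPolygon",
    "component_from_lifetime",
    "snap_components",
    "unmix",
    "apply_exclusion",
    "sted_trajectory",
    "tau_sted_filter",
    "reflection_exclusion_triangle",
]

_BOUNDS_G = (-0.05, 1.05)
_BOUNDS_S = (-0.05, 0.7)


@dataclass(frozen=True)
class Component:
    """A labeled reference position in phasor space.

    Only the center matters for the separation (a cursor radius would not
    change the projection).
    """

    label: str
    g: float
    s: float
    nominal_tau: Optional[float] = None

    def __post_init__(self) -> None:
        if not (_BOUNDS_G[0] <= self.g <= _BOUNDS_G[1]
                and _BOUNDS_S[0] <= self.s <= _BOUNDS_S[1]):
            raise ValueError(f"component {self.label!r} outside the phasor domain")

    @property
    def z(self) -> complex:
        return complex(self.g, self.s)


def component_from_lifetime(label: str, tau: float, omega: float) -> Component:
    """Component at the analytic universal-circle position of ``tau``."""
    g, s = analytic_phasor(tau, omega)
    return Component(label=label, g=float(g), s=float(s), nominal_tau=tau)


def snap_components(components: Sequence[Component], hist: PhasorHistogram,
                    radius: float = 0.08) -> List[Component]:
    """Snap each component to the nearest phasor-histogram local maximum.

    A reproducible stand-in for interactive cloud clicking: within
    ``radius`` of the nominal position the most occupied (smoothed) bin
    becomes the new center.  Components with no counts nearby stay put.
    """
    from scipy import ndimage

    smoothed = ndimage.gaussian_filter(hist.counts, 2.0)
    gc, sc = np.meshgrid(hist.g_centers, hist.s_centers, indexing="ij")
    out = []
    for comp in components:
        d2 = (gc - comp.g) ** 2 + (sc - comp.s) ** 2
        local = np.where(d2 <= radius**2, smoothed, -np.inf)
        if np.isfinite(local).any() and local.max() > 0:
            i, j = np.unravel_index(np.argmax(local), local.shape)
            out.append(replace(comp, g=float(gc[i, j]), s=float(sc[i, j])))
        else:
            out.append(comp)
    return out


@dataclass
class UnmixResult:
    """Per-pixel component fractions and photon-conserving component images."""

    fractions: np.ndarray        # (n_components, H, W), in [0, 1], sum 1 on valid pixels
    component_images: np.ndarray  # (n_components, H, W) photons
    residual: np.ndarray          # (H, W) distance in the phasor plane
    components: List[Component]
    low_confidence: bool = False
    n_clamped: int = 0

    def image(self, label: str) -> np.ndarray:
        for comp, img in zip(self.components, self.component_images):
            if comp.label == label:
                return img
        raise KeyError(label)


@dataclass
class ExclusionPolygon:
    """A zero-intensity ruler: pixels whose phasor falls inside are zeroed."""

    vertices: np.ndarray  # (n, 2) of (g, s)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 (g, s) vertices")
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        self._poly = poly

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership test."""
        gf = np.nan_to_num(np.asarray(g, dtype=float), nan=-10.0)
        sf = np.nan_to_num(np.asarray(s, dtype=float), nan=-10.0)
        return shapely.intersects_xy(self._poly, gf, sf)


def reflection_exclusion_triangle(size: float = 0.18) -> ExclusionPolygon:
    """Triangular ruler around the zero-lifetime corner (1, 0), where
    excitation reflection accumulates."""
    return ExclusionPolygon(np.array([
        [1.0 - size, -0.05], [1.05, -0.05], [1.05, size]]))


# ---------------------------------------------------------------------------
# unmixing


def _collinearity(components: Sequence[Component]) -> float:
    (a, b, c) = [np.array([k.g, k.s]) for k in components]
    u, v = b - a, c - a
    area2 = abs(u[0] * v[1] - u[1] * v[0])
    longest = max(np.linalg.norm(b - a), np.linalg.norm(c - a), np.linalg.norm(c - b))
    return area2 / max(longest**2, 1e-12)


def unmix(field: PhasorField, components: Sequence[Component],
          collinear_tol: float = 0.05) -> UnmixResult:
    """Decompose a phasor field into per-component fraction and photon maps.

    Two components: orthogonal projection of each pixel phasor onto the
    segment between them; the clamped position parameter is the fraction.
    Three components: barycentric coordinates in their triangle; negative
    weights are clamped to zero and the rest renormalized (clamped pixels
    are counted so out-of-gamut behavior stays auditable).  Per valid pixel
    the component images sum exactly to the pixel intensity.
    """
    components = list(components)
    if len(components) not in (2, 3):
        raise ValueError("unmix needs 2 or 3 components")
    pts = np.array([[c.g, c.s] for c in components])
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.linalg.norm(pts[i] - pts[j]) < 1e-9:
                raise ValueError("components must be non-coincident")
    valid = field.valid
    if not valid.any():
        raise ValueError("all pixels invalid")
    h, w = field.g.shape
    g = np.where(valid, field.g, 0.0)
    s = np.where(valid, field.s, 0.0)
    low_confidence = False
    n_clamped = 0

    if len(components) == 2:
        a, b = pts
        ab = b - a
        t = ((g - a[0]) * ab[0] + (s - a[1]) * ab[1]) / (ab @ ab)
        n_clamped = int(((t < 0) | (t > 1))[valid].sum())
        t = np.clip(t, 0.0, 1.0)
        frac = np.stack([1.0 - t, t])
        proj_g = a[0] + t * ab[0]
        proj_s = a[1] + t * ab[1]
        residual = np.hypot(g - proj_g, s - proj_s)
    else:
        if _collinearity(components) < collinear_tol:
            warnings.warn(
                "components are nearly collinear in phasor space; "
                "three-way separation is ill-conditioned and the result is "
                "flagged low-confidence", stacklevel=2)
            low_confidence = True
        # barycentric coordinates: solve [[g],[s],[1]] = M w
        M = np.vstack([pts.T, np.ones(3)])
        Minv = np.linalg.pinv(M)  # tolerates (near-)collinear components
        rhs = np.stack([g.ravel(), s.ravel(), np.ones(g.size)])
        wgt = (Minv @ rhs)  # (3, H*W)
        neg = wgt < 0
        n_clamped = int(neg.any(axis=0).reshape(h, w)[valid].sum())
        wgt = np.where(neg, 0.0, wgt)
        wsum = wgt.sum(axis=0)
        wsum[wsum == 0] = 1.0
        frac = (wgt / wsum).reshape(3, h, w)
        proj = np.tensordot(pts.T, frac.reshape(3, -1), axes=(1, 0))
        residual = np.hypot(g.ravel() - proj[0], s.ravel() - proj[1]).reshape(h, w)

    frac = np.where(valid[None], frac, 0.0)
    residual = np.where(valid, residual, 0.0)
    imgs = frac * field.intensity[None]
    # exact conservation: the last component absorbs rounding residue
    imgs[-1] = np.where(valid, field.intensity - imgs[:-1].sum(axis=0), 0.0)
    return UnmixResult(fractions=frac, component_images=imgs, residual=residual,
                       components=components, low_confidence=low_confidence,
                       n_clamped=n_clamped)


def apply_exclusion(field: PhasorField,
                    polygons: Sequence[ExclusionPolygon]) -> PhasorField:
    """Zero the intensity of pixels whose phasor falls inside any polygon
    (points on an edge count as inside); other pixels are untouched."""
    if not polygons:
        return replace(field)
    inside = np.zeros(field.g.shape, dtype=bool)
    for poly in polygons:
        inside |= poly.contains(field.g, field.s)
    inside &= field.valid
    intensity = np.where(inside, 0.0, field.intensity)
    g = np.where(inside, np.nan, field.g)
    s = np.where(inside, np.nan, field.s)
    return replace(field, g=g, s=s, intensity=intensity)


# ---------------------------------------------------------------------------
# STED trajectory and Tau-STED-style filtering


def sted_trajectory(natural_component: Component, k_dep_max: float,
                    n_points: int, omega: float) -> np.ndarray:
    """Phasor path of a dye under increasing depletion rate.

    Depletion adds a decay channel, so the observed lifetime is
    1/(1/tau + k); the trajectory samples k evenly in [0, k_dep_max] and
    runs along the universal circle from the natural position toward the
    zero-lifetime point (1, 0).
    """
    if natural_component.nominal_tau is None:
        raise ValueError("natural component needs a nominal_tau")
    if k_dep_max < 0:
        raise ValueError("k_dep_max must be >= 0")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    k = np.linspace(0.0, k_dep_max, n_points)
    taus = 1.0 / (1.0 / natural_component.nominal_tau + k)
    g, s = analytic_phasor(taus, omega)
    return np.stack([g, s], axis=1)


def _project_polyline(g: np.ndarray, s: np.ndarray, traj: np.ndarray):
    """Nearest point on the polyline: arc-length parameter (0 at the start,
    1 at the end) and off-trajectory distance, per pixel."""
    pts = np.stack([g.ravel(), s.ravel()], axis=1)
    seg_a = traj[:-1]
    seg_v = np.diff(traj, axis=0)
    seg_len = np.linalg.norm(seg_v, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate trajectory")
    best_d = np.full(pts.shape[0], np.inf)
    best_arc = np.zeros(pts.shape[0])
    for i in range(len(seg_v)):
        v = seg_v[i]
        L2 = max(v @ v, 1e-18)
        t = np.clip(((pts - seg_a[i]) @ v) / L2, 0.0, 1.0)
        proj = seg_a[i] + t[:, None] * v
        d = np.linalg.norm(pts - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_arc[better] = cum[i] + t[better] * seg_len[i]
    return (best_arc / total).reshape(g.shape), best_d.reshape(g.shape)


def tau_sted_filter(field: PhasorField, trajectory: np.ndarray,
                    exclusions: Sequence[ExclusionPolygon] = (),
                    center_weight: float = 1.0,
                    kernel_scale: Optional[float] = 0.05) -> np.ndarray:
    """Reweight intensity by position along the STED trajectory.

    Photons whose phasor sits near the start of the trajectory (the natural
    lifetime, i.e. the weakly-depleted donut center) are up-weighted by
    u**center_weight, where u = 1 at the natural position and 0 at maximum
    depletion; off-trajectory contributions (reflection, haze, bleed-through)
    are down-weighted by a Gaussian kernel in phasor distance
    (``kernel_scale=None`` disables it) and removed outright inside the
    exclusion polygons.  Returns the filtered intensity image.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.ndim != 2 or trajectory.shape[0] < 2:
        raise ValueError("trajectory needs >= 2 points")
    valid = field.valid
    g = np.where(valid, field.g, trajectory[-1, 0])
    s = np.where(valid, field.s, trajectory[-1, 1])
    arc, dist = _project_polyline(g, s, trajectory)
    u = 1.0 - arc  # 1 = natural lifetime / donut center
    weight = u**center_weight if center_weight != 0 else np.ones_like(u)
    if kernel_scale is not None:
        weight = weight * np.exp(-(dist**2) / (2.0 * kernel_scale**2))
    out = field.intensity * weight
    for poly in exclusions:
        out = np.where(poly.contains(field.g, field.s), 0.0, out)
    return np.where(valid, out, 0.0)
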