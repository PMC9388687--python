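"""Ground-truth scenes for the simulator.

A :class:`Scene` is a list of labeled structures — each a set of continuous
emitter positions tied to one dye conjugate and one spectral detection
channel — plus per-pixel expected reflection and autofluorescence photon
rates.  Geometry is statistical stand-ins for the cell biology being imaged:
cytoskeletal filaments are smoothed random walks, mitochondria elongated
blobs, nuclear pores puncta on and inside an ellipse, the plasma membrane a
closed perturbed contour.  Pixel centers sit at integer + 0.5; emitter
coordinates are continuous (row, col) in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._rng import child_rng
from .instrument import DyeSpec

__all__ = ["Structure", "Scene", "build_scene", "PRESETS"]

PRESETS = (
    "five_color",
    "conjugate_pair_star635p",
    "conjugate_pair_atto647n",
    "three_dye_far_red",
)


@dataclass
class Structure:
    """One labeled structure: emitters + the dye conjugate that stains it."""

    name: str
    emitter_positions: np.ndarray  # (N, 2) float, (row, col) pixel units
    dye: DyeSpec
    spectral_channel: int

    def __post_init__(self) -> None:
        self.emitter_positions = np.asarray(self.emitter_positions, dtype=float)
        if self.emitter_positions.ndim != 2 or self.emitter_positions.shape[1] != 2:
            raise ValueError("emitter_positions must be (N, 2)")


@dataclass
class Scene:
    """Ground truth handed to the simulator and to recovery tests."""

    size: Tuple[int, int]
    structures: List[Structure]
    reflection_map: np.ndarray
    background_rate: np.ndarray
    background_tau: float = 1.0
    seed: int = 0
    preset: str = ""
    channel_labels: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, w = self.size
        self.reflection_map = np.broadcast_to(
            np.asarray(self.reflection_map, dtype=float), (h, w)
        ).copy()
        self.background_rate = np.broadcast_to(
            np.asarray(self.background_rate, dtype=float), (h, w)
        ).copy()
        if (self.reflection_map < 0).any() or (self.background_rate < 0).any():
            raise ValueError("expected photon rates must be >= 0")
        for s in self.structures:
            p = s.emitter_positions
            if p.size and ((p < 0).any() or (p[:, 0] >= h).any() or (p[:, 1] >= w).any()):
                raise ValueError(f"emitters of {s.name!r} fall outside the field")

    @property
    def n_channels(self) -> int:
        return 1 + max((s.spectral_channel for s in self.structures), default=0)

    def channel_structures(self, channel: int) -> List[Structure]:
        return [s for s in self.structures if s.spectral_channel == channel]


# ---------------------------------------------------------------------------
# geometry primitives


def _clip_inside(pos: np.ndarray, h: int, w: int) -> np.ndarray:
    keep = (pos[:, 0] >= 0.1) & (pos[:, 0] < h - 0.1) & (pos[:, 1] >= 0.1) & (pos[:, 1] < w - 0.1)
    return pos[keep]


def _fiber(rng: np.random.Generator, h: int, w: int, step: float = 0.4,
           wiggle: float = 0.08, width: float = 0.5) -> np.ndarray:
    """A smoothed random walk crossing the field, emitters every ``step`` px."""
    side = rng.integers(4)
    margin = 2.0
    if side == 0:
        pos = np.array([margin, rng.uniform(0, w)]); heading = rng.uniform(0.25, 0.75) * np.pi
    elif side == 1:
        pos = np.array([h - margin, rng.uniform(0, w)]); heading = rng.uniform(-0.75, -0.25) * np.pi
    elif side == 2:
        pos = np.array([rng.uniform(0, h), margin]); heading = rng.uniform(-0.25, 0.25) * np.pi
    else:
        pos = np.array([rng.uniform(0, h), margin + w - 2 * margin]); heading = np.pi + rng.uniform(-0.25, 0.25) * np.pi
    pts = []
    max_steps = int(3 * (h + w) / step)
    for _ in range(max_steps):
        heading += rng.normal(0.0, wiggle)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if not (0 <= pos[0] < h and 0 <= pos[1] < w):
            break
        pts.append(pos.copy())
    if not pts:
        return np.empty((0, 2))
    pts = np.asarray(pts)
    pts += rng.normal(0.0, width / 2.355, size=pts.shape)  # finite fiber width
    return _clip_inside(pts, h, w)


def _blob(rng: np.random.Generator, h: int, w: int, length: float, width: float,
          density: float) -> np.ndarray:
    """Elongated blob (mitochondrion-like): emitters along a random spine."""
    margin = max(length, 8.0)
    center = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
    theta = rng.uniform(0, np.pi)
    axis = np.array([np.sin(theta), np.cos(theta)])
    perp = np.array([-axis[1], axis[0]])
    n = rng.poisson(density * length * width)
    u = rng.uniform(-length / 2, length / 2, size=n)
    v = rng.normal(0.0, width / 2.355, size=n)
    pts = center[None, :] + u[:, None] * axis[None, :] + v[:, None] * perp[None, :]
    return _clip_inside(pts, h, w)


def _puncta_on_ellipse(rng: np.random.Generator, h: int, w: int, n_puncta: int,
                       emitters_per_punctum: int) -> np.ndarray:
    """Nuclear-pore-like puncta on the rim and face of an ellipse."""
    cy, cx = h * rng.uniform(0.35, 0.65), w * rng.uniform(0.35, 0.65)
    ry, rx = h * rng.uniform(0.18, 0.28), w * rng.uniform(0.18, 0.28)
    pts = []
    for _ in range(n_puncta):
        phi = rng.uniform(0, 2 * np.pi)
        # projection of pores on the nuclear envelope: rim-heavy radial profile
        rad = np.sqrt(rng.uniform(0.15, 1.0))
        c = np.array([cy + rad * ry * np.sin(phi), cx + rad * rx * np.cos(phi)])
        pts.append(c + rng.normal(0.0, 0.35, size=(emitters_per_punctum, 2)))
    return _clip_inside(np.concatenate(pts, axis=0), h, w)


def _membrane(rng: np.random.Generator, h: int, w: int, step: float = 0.4,
              width: float = 0.6) -> np.ndarray:
    """Closed, harmonically perturbed contour (plasma membrane)."""
    cy, cx = h * rng.uniform(0.45, 0.55), w * rng.uniform(0.45, 0.55)
    r0 = 0.38 * min(h, w)
    n_harm = 4
    amp = rng.uniform(-0.08, 0.08, size=n_harm) * r0
    phase = rng.uniform(0, 2 * np.pi, size=n_harm)
    circumference = 2 * np.pi * r0
    phi = np.linspace(0, 2 * np.pi, int(circumference / step), endpoint=False)
    r = r0 + sum(amp[k] * np.sin((k + 2) * phi + phase[k]) for k in range(n_harm))
    pts = np.stack([cy + r * np.sin(phi), cx + r * np.cos(phi)], axis=1)
    pts = pts + rng.normal(0.0, width / 2.355, size=pts.shape)
    return _clip_inside(pts, h, w)


def _corner_reflection(h: int, w: int, peak: float) -> np.ndarray:
    """Excitation-reflection hotspot in the lower-right corner."""
    yy, xx = np.mgrid[0:h, 0:w] + 0.5
    d2 = ((yy - 0.95 * h) / (0.22 * h)) ** 2 + ((xx - 0.95 * w) / (0.22 * w)) ** 2
    return peak * np.exp(-0.5 * d2)


# ---------------------------------------------------------------------------
# presets


def _scaled(size: Tuple[int, int], per_256: int, lo: int = 1) -> int:
    return max(lo, round(per_256 * min(size) / 256))


def build_scene(preset: str, size: int | Tuple[int, int] = 256, seed: int = 0) -> Scene:
    """Build a ground-truth scene from a named preset.

    Presets carry the confocal lifetimes of the dye conjugates they emulate:

    - ``five_color``: five conjugates in three spectral channels — near red
      (Alexa Fluor 594 antibody / vimentin, 2.6 ns; WGA-CF594 / membrane,
      1.8 ns), far red (Abberior STAR 635P antibody / mitochondria, 2.2 ns;
      ATTO 647N phalloidin / actin, 3.2 ns) and a red-shifted channel
      (CF680R antibody / nuclear pores, 1.7 ns) that also carries excitation
      reflection (zero lifetime) and anti-Stokes haze.
    - ``conjugate_pair_star635p``: one spectral channel, the same dye on two
      carriers — phalloidin/actin 3.4 ns vs antibody/vimentin 2.3 ns.
    - ``conjugate_pair_atto647n``: phalloidin/actin 3.6 ns vs antibody/
      nuclear pores 2.5 ns.
    - ``three_dye_far_red``: three conjugates in one channel at 2.0, 1.2 and
      3.5 ns — deliberately near-collinear in phasor space.

    Structures in a shared channel cross spatially so separation is
    non-trivial.  Rebuilding with the same seed is bit-exact.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if isinstance(size, int):
        size = (size, size)
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("size too small to place structures (minimum 64x64)")

    structures: List[Structure] = []
    reflection = np.zeros((h, w))
    background = np.full((h, w), 0.5)  # weak autofluorescence everywhere
    labels: Dict[int, str] = {}

    def fibers(rng, n):
        # keep drawing until ~n full field crossings worth of emitters, so
        # early field exits cannot starve a structure of signal
        target = n * int(2.3 * min(h, w))
        out, total = [], 0
        for _ in range(8 * n):
            f = _fiber(rng, h, w)
            if len(f) > 10:
                out.append(f)
                total += len(f)
            if total >= target:
                break
        return np.concatenate(out, axis=0) if out else np.empty((0, 2))

    if preset == "five_color":
        labels = {0: "near_red", 1: "far_red", 2: "red_680"}
        r = child_rng(seed, "scene", preset)
        vim = fibers(r, _scaled(size, 4, 2))
        mem = _membrane(r, h, w)
        mito = np.concatenate(
            [_blob(r, h, w, length=r.uniform(12, 30), width=r.uniform(3, 5), density=2.2)
             for _ in range(_scaled(size, 12, 3))], axis=0)
        act = fibers(r, _scaled(size, 5, 2))
        pores = _puncta_on_ellipse(r, h, w, _scaled(size, 140, 30), 24)
        structures = [
            Structure("vimentin", vim,
                      DyeSpec("AF594-ab", [2.6], [1.0], brightness=20.0), 0),
            Structure("membrane", mem,
                      DyeSpec("WGA-CF594", [1.8], [1.0], brightness=20.0), 0),
            Structure("mitochondria", mito,
                      DyeSpec("STAR635P-ab", [2.2], [1.0], brightness=5.0), 1),
            Structure("actin", act,
                      DyeSpec("ATTO647N-phall", [3.2], [1.0], brightness=22.0), 1),
            Structure("pores", pores,
                      DyeSpec("CF680R-ab", [1.7], [1.0], brightness=16.0,
                              anti_stokes_coeff=0.02), 2),
        ]
        reflection = _corner_reflection(h, w, peak=60.0)
    elif preset == "conjugate_pair_star635p":
        labels = {0: "far_red"}
        r = child_rng(seed, "scene", preset)
        act = fibers(r, _scaled(size, 6, 2))
        vim = fibers(r, _scaled(size, 6, 2))
        structures = [
            Structure("actin", act,
                      DyeSpec("STAR635P-phall", [3.4], [1.0], brightness=20.0), 0),
            Structure("vimentin", vim,
                      DyeSpec("STAR635P-ab", [2.3], [1.0], brightness=20.0), 0),
        ]
    elif preset == "conjugate_pair_atto647n":
        labels = {0: "far_red"}
        r = child_rng(seed, "scene", preset)
        act = fibers(r, _scaled(size, 6, 2))
        pores = _puncta_on_ellipse(r, h, w, _scaled(size, 140, 30), 24)
        structures = [
            Structure("actin", act,
                      DyeSpec("ATTO647N-phall", [3.6], [1.0], brightness=20.0), 0),
            Structure("pores", pores,
                      DyeSpec("ATTO647N-ab", [2.5], [1.0], brightness=16.0), 0),
        ]
    elif preset == "three_dye_far_red":
        labels = {0: "far_red"}
        r = child_rng(seed, "scene", preset)
        vim = fibers(r, _scaled(size, 5, 2))
        mito = np.concatenate(
            [_blob(r, h, w, length=r.uniform(12, 30), width=r.uniform(3, 5), density=2.2)
             for _ in range(_scaled(size, 12, 3))], axis=0)
        act = fibers(r, _scaled(size, 5, 2))
        structures = [
            Structure("vimentin", vim,
                      DyeSpec("STAR635P-ab", [2.0], [1.0], brightness=20.0), 0),
            Structure("mitochondria", mito,
                      DyeSpec("AF647-ab", [1.2], [1.0], brightness=5.0), 0),
            Structure("actin", act,
                      DyeSpec("ATTO647N-phall", [3.5], [1.0], brightness=20.0), 0),
        ]

    return Scene(size=(h, w), structures=structures, reflection_map=reflection,
                 background_rate=background, seed=seed, preset=preset,
                 channel_labels=labels)
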