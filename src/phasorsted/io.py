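"""TIFF + JSON-sidecar readers and writers.

A TCSPC image is stored as a TIFF hyperstack with axes (T-bins, H, W) and a
versioned JSON sidecar carrying timing metadata; a phasor field as a
3-plane TIFF (g, s, intensity) with its own sidecar.  Scenes serialize to
JSON (emitter coordinates included) so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import tifffile

from .instrument import DyeSpec, InstrumentConfig
from .phasor import PhasorField
from .scenes import Scene, Structure
from .simulate import TCSPCImage

__all__ = [
    "write_tcspc", "read_tcspc",
    "write_phasor_field", "read_phasor_field",
    "write_scene", "read_scene",
]

SIDECAR_SCHEMA = "phasorsted.tcspc/1"
PHASOR_SCHEMA = "phasorsted.phasor/1"
SCENE_SCHEMA = "phasorsted.scene/1"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_tcspc(img: TCSPCImage, path) -> Path:
    """Write a TCSPC image as a (T, H, W) TIFF plus JSON sidecar."""
    path = Path(path)
    stack = np.moveaxis(img.counts, 2, 0).astype(np.uint32)
    tifffile.imwrite(path, stack, metadata={"axes": "THW"})
    meta = {
        "schema": SIDECAR_SCHEMA,
        "rep_period_ns": img.instrument.rep_period,
        "bin_width_ns": img.instrument.bin_width,
        "channel_label": img.channel_label,
        "mode": img.mode,
        "sted_power": img.sted_power,
        "instrument": img.instrument.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_tcspc(path) -> TCSPCImage:
    """Read a TCSPC image written by :func:`write_tcspc`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar} next to {path}")
    meta = json.loads(sidecar.read_text())
    if meta.get("schema") != SIDECAR_SCHEMA:
        raise ValueError(
            f"sidecar schema {meta.get('schema')!r} does not match "
            f"{SIDECAR_SCHEMA!r}")
    stack = tifffile.imread(path)
    if stack.ndim != 3:
        raise ValueError(
            f"{path} is not a (T, H, W) hyperstack: shape {stack.shape}; "
            "this reader needs a micro-time axis")
    inst = InstrumentConfig.from_dict(meta["instrument"])
    if stack.shape[0] != inst.n_bins:
        raise ValueError(
            f"time axis length {stack.shape[0]} does not match the sidecar "
            f"n_bins {inst.n_bins}")
    return TCSPCImage(counts=np.moveaxis(stack, 0, 2).astype(np.int64),
                      channel_label=meta["channel_label"], mode=meta["mode"],
                      sted_power=meta["sted_power"], instrument=inst)


def write_phasor_field(field: PhasorField, path) -> Path:
    path = Path(path)
    planes = np.stack([field.g, field.s, field.intensity]).astype(np.float32)
    tifffile.imwrite(path, planes, photometric="minisblack",
                     metadata={"axes": "CHW"})
    meta = {"schema": PHASOR_SCHEMA, "omega": field.omega,
            "harmonic": field.harmonic, "planes": ["g", "s", "intensity"]}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_phasor_field(path) -> PhasorField:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("schema") != PHASOR_SCHEMA:
        raise ValueError(f"unexpected sidecar schema {meta.get('schema')!r}")
    planes = tifffile.imread(path).astype(float)
    return PhasorField(g=planes[0], s=planes[1], intensity=planes[2],
                       omega=meta["omega"], harmonic=meta["harmonic"])


def write_scene(scene: Scene, path) -> Path:
    path = Path(path)
    doc = {
        "schema": SCENE_SCHEMA,
        "size": list(scene.size),
        "seed": scene.seed,
        "preset": scene.preset,
        "background_tau": scene.background_tau,
        "channel_labels": {str(k): v for k, v in scene.channel_labels.items()},
        "reflection_map": scene.reflection_map.tolist(),
        "background_rate": scene.background_rate.tolist(),
        "structures": [
            {"name": s.name, "spectral_channel": s.spectral_channel,
             "dye": s.dye.to_dict(),
             "emitter_positions": s.emitter_positions.tolist()}
            for s in scene.structures
        ],
    }
    path.write_text(json.dumps(doc))
    return path


def read_scene(path) -> Scene:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != SCENE_SCHEMA:
        raise ValueError(f"unexpected scene schema {doc.get('schema')!r}")
    structures = [
        Structure(name=s["name"],
                  emitter_positions=np.asarray(s["emitter_positions"], dtype=float).reshape(-1, 2),
                  dye=DyeSpec.from_dict(s["dye"]),
                  spectral_channel=s["spectral_channel"])
        for s in doc["structures"]
    ]
    return Scene(size=tuple(doc["size"]), structures=structures,
                 reflection_map=np.asarray(doc["reflection_map"], dtype=float),
                 background_rate=np.asarray(doc["background_rate"], dtype=float),
                 background_tau=doc["background_tau"], seed=doc["seed"],
                 preset=doc["preset"],
                 channel_labels={int(k): v for k, v in doc["channel_labels"].items()})
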