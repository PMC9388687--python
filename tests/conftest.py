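"""Shared fixtures: instrument constants and session-scoped simulations.

Expensive TCSPC simulations are session-scoped so recovery, physics and
metric tests share the same realizations.
"""

from __future__ import annotations

import numpy as np
import pytest

import phasorsted as ps
from phasorsted.instrument import InstrumentConfig
from phasorsted.phasor import compute_calibration, phasor_transform

OMEGA = 2.0 * np.pi / 12.5  # rad/ns at 80 MHz, harmonic 1


@pytest.fixture(scope="session")
def instrument() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture(scope="session")
def reference():
    """Uniform tau = 2.5 ns calibration specimen (~2e6 photons)."""
    return ps.simulate_reference(seed=3)


@pytest.fixture(scope="session")
def calibration(reference):
    return compute_calibration(phasor_transform(reference), 2.5)


@pytest.fixture(scope="session")
def five_color_scene_256():
    return ps.build_scene("five_color", 256, seed=1)


@pytest.fixture(scope="session")
def five_color_confocal_256(five_color_scene_256):
    """The three confocal spectral channels of the 256^2 five-color scene."""
    return {ch: ps.simulate_channel(five_color_scene_256, ch, "confocal",
                                    0.0, 1.0, seed=2)
            for ch in (0, 1, 2)}


@pytest.fixture(scope="session")
def five_color_sted_ch1_256(five_color_scene_256):
    return ps.simulate_channel(five_color_scene_256, 1, "sted", 1.5, 1.0, seed=2)


@pytest.fixture(scope="session")
def five_color_scene_128():
    return ps.build_scene("five_color", 128, seed=1)


@pytest.fixture(scope="session")
def conjugate_runs(reference):
    """Confocal + STED far-red channels of both conjugate-pair presets."""
    out = {}
    for preset, seed in (("conjugate_pair_star635p", 7),
                         ("conjugate_pair_atto647n", 8)):
        scene = ps.build_scene(preset, 128, seed=seed)
        out[preset] = {
            "scene": scene,
            "confocal": ps.simulate_channel(scene, 0, "confocal", 0.0, 1.0,
                                            seed=seed + 100),
            "sted": ps.simulate_channel(scene, 0, "sted", 1.5, 1.0,
                                        seed=seed + 100),
        }
    return out


def analytic_binned_histogram(tau: float, instrument: InstrumentConfig,
                              total: float = 1e9) -> np.ndarray:
    """Exact expected bin contents of a wrapped monoexponential decay
    (no IRF), scaled to ``total`` photons and rounded to integers.

    Independent closed form: bin k of the wrapped density holds
    (exp(-k d/tau) - exp(-(k+1) d/tau)) / (1 - exp(-T/tau)).
    """
    dt = instrument.bin_width
    k = np.arange(instrument.n_bins)
    p = (np.exp(-k * dt / tau) - np.exp(-(k + 1) * dt / tau))
    p /= 1.0 - np.exp(-instrument.rep_period / tau)
    return np.rint(p * total).astype(np.int64)


def image_from_hist(hist: np.ndarray, instrument: InstrumentConfig,
                    shape=(1, 1)) -> ps.TCSPCImage:
    counts = np.broadcast_to(hist, (*shape, hist.size)).copy()
    return ps.TCSPCImage(counts=counts, channel_label="ideal", mode="confocal",
                         sted_power=0.0, instrument=instrument)
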