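"""Shared fixtures: small simulated acquisitions and constructed streams."""

import math
import warnings

import numpy as np
import pytest

from evfccs import (
    PhotonStream,
    PIEGateConfig,
    SimConfig,
    SpeciesSpec,
    apply_pie_gating,
    make_scenario,
    simulate_photon_stream,
)

warnings.filterwarnings("ignore", message="duration .* shorter than 10x")


def make_poisson_stream(
    rate: float, duration: float, seed: int, detector: int = 0,
    sync_rate: float = 40e6,
) -> PhotonStream:
    """Homogeneous Poisson photon stream (constructed, no diffusion)."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, n))
    ticks_per_sync = int(round(1.0 / sync_rate / 1e-9))
    macro = (t / (1.0 / sync_rate)).astype(np.int64) * ticks_per_sync
    gate_lo = 0.0 if detector == 0 else 12.5e-9
    nano = ((gate_lo + rng.uniform(0, 12.4e-9, n)) / 5e-12).astype(np.int64)
    return PhotonStream(
        macrotimes=macro,
        nanotimes=nano,
        detector_ids=np.full(n, detector, dtype=np.int64),
        tick_s=1e-9,
        tcspc_bin_s=5e-12,
        sync_rate_hz=sync_rate,
        duration_s=duration,
    )


def grid_stream(spacing_s: float, duration: float, detector: int = 0) -> PhotonStream:
    """Exactly periodic photon stream (constructed)."""
    t = np.arange(0.0, duration, spacing_s)
    macro = np.round(t / 1e-9).astype(np.int64)
    return PhotonStream(
        macrotimes=macro,
        nanotimes=np.zeros(len(t), dtype=np.int64),
        detector_ids=np.full(len(t), detector, dtype=np.int64),
        tick_s=1e-9,
        duration_s=duration,
    )


@pytest.fixture(scope="session")
def sim90():
    """120 s monodisperse 90 nm dual-labeled vesicle acquisition + gating."""
    cfg = make_scenario("monodisperse_90nm", duration=120.0, seed=42)
    stream, gt = simulate_photon_stream(cfg)
    gates = PIEGateConfig()
    gated = apply_pie_gating(stream, gates)
    return {"cfg": cfg, "stream": stream, "gt": gt, "gated": gated, "gates": gates}


@pytest.fixture(scope="session")
def sim_sparse():
    """Sparse-transit stream: 200 cps background plus rare vesicle bursts."""
    v_eff_g = math.pi**1.5 * (287e-9) ** 2 * 1435e-9
    cfg = SimConfig(
        species=[
            SpeciesSpec(
                name="ev", diameter=90e-9, n_green_labels=2, n_red_labels=8,
                brightness_green=12000.0, brightness_red=2000.0,
                concentration=0.002 / v_eff_g,
            )
        ],
        duration=60.0,
        seed=77,
    )
    stream, gt = simulate_photon_stream(cfg)
    gated = apply_pie_gating(stream, PIEGateConfig())
    return {"cfg": cfg, "stream": stream, "gt": gt, "gated": gated}


def gated_particle_ids(stream, gt, gates, channel):
    """Ground-truth particle ids of the photons surviving PIE gating."""
    nan_s = stream.nanotimes * stream.tcspc_bin_s
    det = 0 if channel == "green" else 1
    lo, hi = gates.gate_for_detector(det)
    mask = (stream.detector_ids == det) & (nan_s >= lo) & (nan_s < hi)
    return gt.photon_particle[mask], gt.photon_origin[mask]
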