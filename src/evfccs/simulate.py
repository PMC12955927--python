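"""Brownian-dynamics photon-emission simulator with per-photon ground truth.

Particles of each species perform periodic-boundary Brownian motion in a
cuboid box containing two overlapped 3D-Gaussian detection volumes (green and
red, the red one optionally shifted axially). Per time step each label emits
detected photons as a Poisson draw with mean

    brightness * n_labels * I_c(r) * dt,
    I_c(r) = exp(-2 (x^2 + y^2) / w_xy,c^2 - 2 (z - z_c)^2 / w_z,c^2)

where ``brightness`` is the detected count rate per label at beam center.
Each photon receives an absolute time (uniform within its step) snapped to
the sync grid (macrotime = start tick of its sync period, mirroring TCSPC
hardware), a nanotime drawn from the exciting laser's gate start plus an
exponential fluorescence decay truncated to the gate, and a detector id
(green-label photons land on the red detector with the configured crosstalk
probability). Homogeneous Poisson background is added per channel with
nanotimes uniform inside that channel's gate, so the configured background
rate is the rate surviving PIE gating.

Every photon carries a ground-truth record (particle id, species, origin),
which is what makes each downstream analysis stage independently checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from evfccs.photon_data import (
    GREEN_DET,
    RED_DET,
    ConfigurationError,
    PhotonStream,
)
from evfccs.physics import (
    DEFAULT_TEMPERATURE_K,
    WATER_VISCOSITY_PA_S,
    diffusion_coefficient_from_diameter,
    diffusion_time,
)

ORIGIN_SIGNAL_GREEN = 0
ORIGIN_SIGNAL_RED = 1
ORIGIN_BACKGROUND = 2
ORIGIN_CROSSTALK = 3


@dataclass
class SpeciesSpec:
    """One diffusing species: size/mobility, labeling and brightness.

    Exactly one of ``diameter`` (m) or ``diffusion_coefficient`` (m^2/s) must
    be given; the other is derived through Stokes-Einstein at the simulation
    temperature/viscosity. Brightnesses are detected counts/s per label at
    beam center.
    """

    name: str
    diameter: float | None = None
    diffusion_coefficient: float | None = None
    n_green_labels: int = 0
    n_red_labels: int = 0
    brightness_green: float = 0.0
    brightness_red: float = 0.0
    lifetime_green: float = 2.5e-9
    lifetime_red: float = 1.5e-9
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if (self.diameter is None) == (self.diffusion_coefficient is None):
            raise ConfigurationError(
                f"species {self.name!r}: exactly one of diameter / "
                "diffusion_coefficient must be specified"
            )
        if self.n_green_labels < 0 or self.n_red_labels < 0:
            raise ConfigurationError("label counts must be >= 0")
        if self.brightness_green < 0 or self.brightness_red < 0:
            raise ConfigurationError("brightnesses must be >= 0")
        if self.concentration < 0:
            raise ConfigurationError("concentration must be >= 0")

    def d_coefficient(self, temperature: float, viscosity: float) -> float:
        if self.diffusion_coefficient is not None:
            return self.diffusion_coefficient
        return diffusion_coefficient_from_diameter(self.diameter, temperature, viscosity)

    def hydrodynamic_diameter(self, temperature: float, viscosity: float) -> float:
        if self.diameter is not None:
            return self.diameter
        # Stokes-Einstein inverted for a species specified by D
        from evfccs.physics import BOLTZMANN_J_PER_K

        return BOLTZMANN_J_PER_K * temperature / (
            3.0 * math.pi * viscosity * self.diffusion_coefficient
        )

    @property
    def is_dual_labeled(self) -> bool:
        return self.n_green_labels > 0 and self.n_red_labels > 0


@dataclass
class SimConfig:
    """Full specification of one synthetic acquisition."""

    species: list[SpeciesSpec]
    box: tuple[float, float, float] = (3.8e-6, 3.8e-6, 1.9e-5)
    waist_xy_green: float = 287e-9
    waist_z_green: float = 1435e-9
    waist_xy_red: float = 372e-9
    waist_z_red: float = 1860e-9
    axial_offset_red: float = 300e-9
    temperature: float = DEFAULT_TEMPERATURE_K
    viscosity: float = WATER_VISCOSITY_PA_S
    background_rate_green: float = 200.0
    background_rate_red: float = 200.0
    crosstalk_green_into_red: float = 0.0
    sync_rate: float = 40e6
    interleave_delay: float = 12.5e-9
    time_step: float | None = None
    duration: float = 60.0
    seed: int | None = None
    tick_s: float = 1e-9
    tcspc_bin_s: float = 5e-12
    scenario_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in (self.waist_xy_green, self.waist_z_green, self.waist_xy_red, self.waist_z_red):
            if w <= 0:
                raise ConfigurationError("waists must be > 0")
        lat = 10.0 * max(self.waist_xy_green, self.waist_xy_red)
        axi = 10.0 * max(self.waist_z_green, self.waist_z_red)
        if self.box[0] < lat or self.box[1] < lat or self.box[2] < axi:
            raise ConfigurationError(
                f"box {self.box} too small: lateral dims must be >= {lat:.2e} m "
                f"and the axial dim >= {axi:.2e} m"
            )
        for r in (self.background_rate_green, self.background_rate_red):
            if r < 0:
                raise ConfigurationError("background rates must be >= 0")
        if not (0.0 <= self.crosstalk_green_into_red <= 1.0):
            raise ConfigurationError("crosstalk must be a probability")
        # time_step None means automatic per-species steps (each species'
        # lateral transit / 20); an explicit global step must satisfy the
        # same bound for the fastest species
        if self.time_step is not None and (
            self.time_step > self.min_transit_time() / 20.0 * (1 + 1e-9)
        ):
            raise ConfigurationError(
                f"time_step {self.time_step:.3e} s too coarse; must be <= "
                f"{self.min_transit_time() / 20.0:.3e} s (shortest transit / 20)"
            )
        if self.seed is None:
            raise ConfigurationError("a seed is required for reproducibility")

    def species_time_step(self, sp: "SpeciesSpec") -> float:
        """Integration step for one species: explicit step or transit/20."""
        if self.time_step is not None:
            return self.time_step
        w = min(self.waist_xy_green, self.waist_xy_red)
        return diffusion_time(sp.d_coefficient(self.temperature, self.viscosity), w) / 20.0

    def min_transit_time(self) -> float:
        """Shortest lateral dwell time over all species (smaller waist)."""
        w = min(self.waist_xy_green, self.waist_xy_red)
        taus = [
            diffusion_time(s.d_coefficient(self.temperature, self.viscosity), w)
            for s in self.species
            if s.concentration > 0
        ]
        if not taus:
            return math.inf
        return min(taus)

    @property
    def box_volume(self) -> float:
        return self.box[0] * self.box[1] * self.box[2]

    # -- effective detection volumes -------------------------------------
    def v_eff_green(self) -> float:
        return math.pi**1.5 * self.waist_xy_green**2 * self.waist_z_green

    def v_eff_red(self) -> float:
        return math.pi**1.5 * self.waist_xy_red**2 * self.waist_z_red

    def v_eff_cross(self) -> float:
        """Effective dual-color volume, including the axial offset penalty."""
        wxy2 = 0.5 * (self.waist_xy_green**2 + self.waist_xy_red**2)
        wz2 = 0.5 * (self.waist_z_green**2 + self.waist_z_red**2)
        overlap = math.exp(
            -2.0 * self.axial_offset_red**2 / (self.waist_z_green**2 + self.waist_z_red**2)
        )
        return math.pi**1.5 * wxy2 * math.sqrt(wz2) / overlap


@dataclass
class GroundTruth:
    """Per-photon provenance and per-particle truth for oracle tests."""

    photon_particle: np.ndarray  # particle id, -1 for background
    photon_species: np.ndarray  # species index, -1 for background
    photon_origin: np.ndarray  # ORIGIN_* codes
    particle_species: np.ndarray  # species index per particle
    particle_diameter: np.ndarray  # true hydrodynamic diameter (m)
    particle_n_green: np.ndarray
    particle_n_red: np.ndarray
    n_photons: int = 0

    def __post_init__(self) -> None:
        self.n_photons = len(self.photon_particle)
        if not (len(self.photon_species) == len(self.photon_origin) == self.n_photons):
            raise ValueError("ground-truth per-photon arrays must have equal length")


def simulate_photon_stream(config: SimConfig) -> tuple[PhotonStream, GroundTruth]:
    """Run the Brownian/photon simulation described in the module docstring.

    Returns the macrotime-sorted :class:`~evfccs.photon_data.PhotonStream`
    and the matching :class:`GroundTruth` (one record per photon).
    """
    rng = np.random.default_rng(config.seed)
    lx, ly, lz = config.box
    dims = np.array([lx, ly, lz])

    # --- particles -------------------------------------------------------
    sp_idx_parts: list[np.ndarray] = []
    for i, sp in enumerate(config.species):
        n_p = rng.poisson(sp.concentration * config.box_volume)
        sp_idx_parts.append(np.full(n_p, i, dtype=np.int64))
    particle_species = (
        np.concatenate(sp_idx_parts) if sp_idx_parts else np.zeros(0, dtype=np.int64)
    )
    n_particles = len(particle_species)
    d_coeffs = np.array(
        [s.d_coefficient(config.temperature, config.viscosity) for s in config.species]
    )
    diam = np.array(
        [s.hydrodynamic_diameter(config.temperature, config.viscosity) for s in config.species]
    )
    rate_g = np.array([s.n_green_labels * s.brightness_green for s in config.species])
    rate_r = np.array([s.n_red_labels * s.brightness_red for s in config.species])
    life_g = np.array([s.lifetime_green for s in config.species])
    life_r = np.array([s.lifetime_red for s in config.species])

    times: list[np.ndarray] = []
    particles: list[np.ndarray] = []
    origins: list[np.ndarray] = []

    # Species do not interact, so each is integrated with its own time step
    # (fast free dyes need ~us steps, slow vesicles get away with ~0.1 ms).
    dims32 = dims.astype(np.float32)
    for i_sp, sp in enumerate(config.species):
        group = np.nonzero(particle_species == i_sp)[0]
        n_grp = group.size
        if n_grp == 0 or (rate_g[i_sp] == 0.0 and rate_r[i_sp] == 0.0):
            continue
        dt = config.species_time_step(sp)
        n_steps = int(math.ceil(config.duration / dt))
        pos = (rng.uniform(-0.5, 0.5, size=(n_grp, 3)) * dims).astype(np.float32)
        sigma32 = np.float32(math.sqrt(2.0 * d_coeffs[i_sp] * dt))
        channels = (
            (ORIGIN_SIGNAL_GREEN, config.waist_xy_green**2, config.waist_z_green**2,
             0.0, rate_g[i_sp]),
            (ORIGIN_SIGNAL_RED, config.waist_xy_red**2, config.waist_z_red**2,
             config.axial_offset_red, rate_r[i_sp]),
        )
        # chunk so the (particles x steps) work arrays stay ~tens of MB;
        # trajectories in float32 (position error << waist over a chunk)
        chunk = max(1, int(4_000_000 // n_grp))
        step0 = 0
        while step0 < n_steps:
            s_chunk = min(chunk, n_steps - step0)
            # layout (particles, axis, steps): cumsum runs along the
            # contiguous axis, which is several times faster
            incr = rng.standard_normal((n_grp, 3, s_chunk), dtype=np.float32)
            incr *= sigma32
            incr[:, :, 0] += pos
            traj = np.cumsum(incr, axis=2)
            # periodic wrap (box centered at origin)
            traj += 0.5 * dims32[None, :, None]
            traj %= dims32[None, :, None]
            traj -= 0.5 * dims32[None, :, None]
            pos = traj[:, :, -1].copy()
            rho2 = traj[:, 0, :] ** 2 + traj[:, 1, :] ** 2
            for origin, wxy2, wz2, zc, center_rate in channels:
                if center_rate == 0.0:
                    continue
                log_i = rho2 * np.float32(-2.0 / wxy2)
                log_i += (traj[:, 2, :] - np.float32(zc)) ** 2 * np.float32(-2.0 / wz2)
                part_i, step_i = np.nonzero(log_i > -25.0)
                if step_i.size == 0:
                    continue
                # Poisson(mu) == 0 a.s. for the masked-out (mu ~ 0) entries,
                # so drawing only visible entries is exact
                mu = np.exp(log_i[part_i, step_i].astype(np.float64))
                mu *= center_rate * dt
                counts = rng.poisson(mu)
                emitted = counts > 0
                if not emitted.any():
                    continue
                c = counts[emitted]
                rep_step = np.repeat(step_i[emitted] + step0, c)
                rep_part = np.repeat(group[part_i[emitted]], c)
                t = (rep_step + rng.random(rep_step.size)) * dt
                times.append(t)
                particles.append(rep_part)
                origins.append(np.full(t.size, origin, dtype=np.int64))
            step0 += s_chunk

    # --- background ------------------------------------------------------
    for origin_det, rate in ((GREEN_DET, config.background_rate_green),
                             (RED_DET, config.background_rate_red)):
        n_bg = rng.poisson(rate * config.duration)
        t = rng.uniform(0.0, config.duration, n_bg)
        times.append(t)
        particles.append(np.full(n_bg, -1, dtype=np.int64))
        # encode detector in the origin list temporarily via offset
        origins.append(np.full(n_bg, 100 + origin_det, dtype=np.int64))

    if times:
        t_all = np.concatenate(times)
        part_all = np.concatenate(particles)
        orig_all = np.concatenate(origins)
    else:
        t_all = np.zeros(0)
        part_all = np.zeros(0, dtype=np.int64)
        orig_all = np.zeros(0, dtype=np.int64)

    order = np.argsort(t_all, kind="stable")
    t_all, part_all, orig_all = t_all[order], part_all[order], orig_all[order]
    # clip photons past the nominal duration (can occur in the last step)
    keep = t_all < config.duration
    t_all, part_all, orig_all = t_all[keep], part_all[keep], orig_all[keep]

    # --- detectors, crosstalk, nanotimes, grid snapping ------------------
    n_ph = t_all.size
    detector = np.empty(n_ph, dtype=np.int64)
    origin_final = np.empty(n_ph, dtype=np.int64)
    nanotime_s = np.empty(n_ph)

    sync_period = 1.0 / config.sync_rate
    gate_green = (0.0, config.interleave_delay)
    gate_red = (config.interleave_delay, sync_period)

    is_bg_g = orig_all == 100 + GREEN_DET
    is_bg_r = orig_all == 100 + RED_DET
    is_sig_g = orig_all == ORIGIN_SIGNAL_GREEN
    is_sig_r = orig_all == ORIGIN_SIGNAL_RED

    detector[is_bg_g] = GREEN_DET
    detector[is_bg_r] = RED_DET
    origin_final[is_bg_g | is_bg_r] = ORIGIN_BACKGROUND
    nanotime_s[is_bg_g] = rng.uniform(*gate_green, is_bg_g.sum())
    nanotime_s[is_bg_r] = rng.uniform(*gate_red, is_bg_r.sum())

    # green signal: nanotime in the green gate; detector green unless crosstalk
    sp_g = part_all[is_sig_g]
    life = life_g[particle_species[sp_g]] if sp_g.size else np.zeros(0)
    nanotime_s[is_sig_g] = gate_green[0] + _truncated_exponential(
        rng, life, gate_green[1] - gate_green[0]
    )
    xtalk = rng.random(int(is_sig_g.sum())) < config.crosstalk_green_into_red
    det_g = np.where(xtalk, RED_DET, GREEN_DET)
    detector[is_sig_g] = det_g
    origin_final[is_sig_g] = np.where(xtalk, ORIGIN_CROSSTALK, ORIGIN_SIGNAL_GREEN)

    sp_r = part_all[is_sig_r]
    life = life_r[particle_species[sp_r]] if sp_r.size else np.zeros(0)
    nanotime_s[is_sig_r] = gate_red[0] + _truncated_exponential(
        rng, life, gate_red[1] - gate_red[0]
    )
    detector[is_sig_r] = RED_DET
    origin_final[is_sig_r] = ORIGIN_SIGNAL_RED

    ticks_per_sync = int(round(sync_period / config.tick_s))
    macrotimes = (t_all / sync_period).astype(np.int64) * ticks_per_sync
    nanotimes = np.minimum(
        (nanotime_s / config.tcspc_bin_s).astype(np.int64),
        int(sync_period / config.tcspc_bin_s) - 1,
    )

    stream = PhotonStream(
        macrotimes=macrotimes,
        nanotimes=nanotimes,
        detector_ids=detector,
        tick_s=config.tick_s,
        tcspc_bin_s=config.tcspc_bin_s,
        sync_rate_hz=config.sync_rate,
        duration_s=config.duration,
    )
    if n_particles:
        photon_species = np.where(part_all >= 0, particle_species[part_all], -1)
    else:
        photon_species = np.full(n_ph, -1, dtype=np.int64)
    gt = GroundTruth(
        photon_particle=part_all,
        photon_species=photon_species,
        photon_origin=origin_final,
        particle_species=particle_species,
        particle_diameter=diam[particle_species] if n_particles else np.zeros(0),
        particle_n_green=np.array([config.species[i].n_green_labels for i in particle_species], dtype=np.int64),
        particle_n_red=np.array([config.species[i].n_red_labels for i in particle_species], dtype=np.int64),
    )
    return stream, gt


def _truncated_exponential(rng: np.random.Generator, scale: np.ndarray, upper: float) -> np.ndarray:
    """Exponential(scale) truncated to [0, upper) via inverse CDF."""
    scale = np.asarray(scale, dtype=float)
    if scale.size == 0:
        return np.zeros(0)
    u = rng.random(scale.size)
    return -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))


def ground_truth_summary(gt: GroundTruth, config: SimConfig) -> dict:
    """Closed-form expected observables for the configuration behind ``gt``.

    Occupancies are concentration x effective volume; the dual-color
    occupancy uses the effective cross volume (unequal waists and the red
    axial offset included). The loading fraction is concentration-based:
    dual-labeled concentration over total red-labeled concentration.
    """
    if gt.n_photons and gt.particle_species.size:
        if gt.particle_species.max(initial=-1) >= len(config.species):
            raise ValueError("ground truth does not match config: unknown species index")
    v_g, v_r, v_rg = config.v_eff_green(), config.v_eff_red(), config.v_eff_cross()
    n_g = n_r = n_rg = 0.0
    c_dual = c_red = 0.0
    transit: dict[str, dict[str, float]] = {}
    brightness: dict[str, dict[str, float]] = {}
    for sp in config.species:
        d = sp.d_coefficient(config.temperature, config.viscosity)
        transit[sp.name] = {
            "green": diffusion_time(d, config.waist_xy_green),
            "red": diffusion_time(d, config.waist_xy_red),
        }
        brightness[sp.name] = {
            "green": sp.n_green_labels * sp.brightness_green,
            "red": sp.n_red_labels * sp.brightness_red,
        }
        if sp.n_green_labels > 0:
            n_g += sp.concentration * v_g
        if sp.n_red_labels > 0:
            n_r += sp.concentration * v_r
            c_red += sp.concentration
        if sp.is_dual_labeled:
            n_rg += sp.concentration * v_rg
            c_dual += sp.concentration
    half = (math.pi / 2.0) ** 1.5
    rate_g = config.background_rate_green + sum(
        sp.concentration * sp.n_green_labels * sp.brightness_green
        * half * config.waist_xy_green**2 * config.waist_z_green
        * (1.0 - config.crosstalk_green_into_red)
        for sp in config.species
    )
    rate_r = config.background_rate_red + sum(
        sp.concentration * sp.n_red_labels * sp.brightness_red
        * half * config.waist_xy_red**2 * config.waist_z_red
        for sp in config.species
    ) + sum(
        sp.concentration * sp.n_green_labels * sp.brightness_green
        * half * config.waist_xy_green**2 * config.waist_z_green
        * config.crosstalk_green_into_red
        for sp in config.species
    )
    # realized (per-run) quantities from the actual Poisson particle draw
    n_parts = np.bincount(gt.particle_species, minlength=len(config.species)) \
        if gt.particle_species.size else np.zeros(len(config.species), dtype=int)
    real_dual = sum(
        int(n_parts[i]) for i, sp in enumerate(config.species) if sp.is_dual_labeled
    )
    real_red = sum(
        int(n_parts[i]) for i, sp in enumerate(config.species) if sp.n_red_labels > 0
    )
    real_n_g = sum(
        int(n_parts[i]) / config.box_volume * v_g
        for i, sp in enumerate(config.species) if sp.n_green_labels > 0
    )
    real_n_r = sum(
        int(n_parts[i]) / config.box_volume * v_r
        for i, sp in enumerate(config.species) if sp.n_red_labels > 0
    )
    real_n_rg = sum(
        int(n_parts[i]) / config.box_volume * v_rg
        for i, sp in enumerate(config.species) if sp.is_dual_labeled
    )
    return {
        "true_n_g": n_g,
        "true_n_r": n_r,
        "true_n_rg": n_rg,
        "true_loading_fraction": c_dual / c_red if c_red > 0 else 0.0,
        "realized_loading_fraction": real_dual / real_red if real_red else 0.0,
        "realized_n_g": real_n_g,
        "realized_n_r": real_n_r,
        "realized_n_rg": real_n_rg,
        "realized_particle_counts": {sp.name: int(n_parts[i]) for i, sp in enumerate(config.species)},
        "true_transit_times_s": transit,
        "true_particle_brightness_cps": brightness,
        "expected_rate_green_cps": rate_g,
        "expected_rate_red_cps": rate_r,
        "v_eff_green_m3": v_g,
        "v_eff_red_m3": v_r,
        "v_eff_cross_m3": v_rg,
    }


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

_EGFP_BRIGHTNESS = 12_000.0  # detected cps per label at beam center
_MEMBRANE_BRIGHTNESS = 2_000.0  # per membrane label (dim far-red FP)
_N_MEMBRANE_LABELS = 8
_FREE_DYE_D = 8e-11  # m^2/s, free labeled protein


def make_scenario(name: str, duration: float | None = None, seed: int = 0) -> SimConfig:
    """Preset simulation scenarios.

    ``undifferentiated_like`` / ``partially_differentiated_like`` mirror the
    measured study conditions with the dual-labeled occupancy scaled up 100x
    so that desk-scale acquisitions collect meaningful statistics (the
    scaling is recorded in ``scenario_meta``). ``calibration_free_dye`` is a
    single fast green species for brightness calibration and
    ``independent_species`` is the null (no co-diffusion) control. Three
    package-defined scenarios support recovery experiments: a 30%%
    dual-labeled mixture and monodisperse 90/120 nm vesicle samples.
    """
    cfg_kwargs: dict = {}
    meta: dict = {"name": name}

    v_eff_g = math.pi**1.5 * (287e-9) ** 2 * 1435e-9
    v_eff_r = math.pi**1.5 * (372e-9) ** 2 * 1860e-9

    def ev(name_, diam_nm, n_green, c):
        return SpeciesSpec(
            name=name_,
            diameter=diam_nm * 1e-9,
            n_green_labels=n_green,
            n_red_labels=_N_MEMBRANE_LABELS,
            brightness_green=_EGFP_BRIGHTNESS,
            brightness_red=_MEMBRANE_BRIGHTNESS,
            concentration=c,
        )

    if name == "calibration_free_dye":
        species = [
            SpeciesSpec(
                name="free_cargo",
                diffusion_coefficient=_FREE_DYE_D,
                n_green_labels=1,
                brightness_green=_EGFP_BRIGHTNESS,
                concentration=0.3 / v_eff_g,
            )
        ]
        default_duration = 15.0
        meta["target_occupancy_green"] = 0.3
    elif name == "independent_species":
        species = [
            SpeciesSpec(
                name="green_only_ev",
                diameter=100e-9,
                n_green_labels=2,
                brightness_green=_EGFP_BRIGHTNESS,
                concentration=0.05 / v_eff_g,
            ),
            SpeciesSpec(
                name="red_only_ev",
                diameter=100e-9,
                n_red_labels=_N_MEMBRANE_LABELS,
                brightness_red=_MEMBRANE_BRIGHTNESS,
                concentration=0.05 / v_eff_r,
            ),
        ]
        default_duration = 200.0
        meta["true_n_rg"] = 0.0
    elif name in ("undifferentiated_like", "partially_differentiated_like"):
        # measured dual occupancies 1.8e-4 / 2.8e-4 scaled up 100x for desk
        # scale. The red-only vesicle population is a fixed baseline (same
        # secretion level in both conditions) chosen to keep the red channel
        # in the single-vesicle-per-burst regime (burst rate < ~5/s); the
        # resulting loading fractions preserve the conditions' ordering but
        # not the unscaled 3.1% / 4.4% values.
        occ_dual = 0.018 if name == "undifferentiated_like" else 0.028
        occ_red_only = 0.045
        occ_free = 0.05 if name == "undifferentiated_like" else 0.08
        c_dual = occ_dual / v_eff_g
        c_red = occ_red_only / v_eff_g
        species = [
            ev("loaded_ev", 90.0, 2, c_dual),
            ev("red_only_ev", 90.0, 0, c_red),
            SpeciesSpec(
                name="free_cargo",
                diffusion_coefficient=_FREE_DYE_D,
                n_green_labels=1,
                brightness_green=_EGFP_BRIGHTNESS,
                concentration=occ_free / v_eff_g,
            ),
        ]
        default_duration = 300.0
        meta.update(
            occupancy_scaling=100.0,
            loading_fraction=c_dual / (c_dual + c_red),
            n_components_green=2,
        )
    elif name == "mixture_dual30":
        c_tot = 0.05 / v_eff_g
        species = [
            ev("loaded_ev", 100.0, 2, 0.30 * c_tot),
            ev("red_only_ev", 100.0, 0, 0.70 * c_tot),
        ]
        default_duration = 300.0
        meta["loading_fraction"] = 0.30
    elif name in ("monodisperse_90nm", "monodisperse_120nm"):
        diam = 90.0 if name == "monodisperse_90nm" else 120.0
        # occupancy kept low enough for the single-vesicle-per-burst regime
        # (burst rates stay below ~5/s)
        species = [ev("loaded_ev", diam, 2, 0.05 / v_eff_g)]
        default_duration = 300.0
        meta["diameter_nm"] = diam
    else:
        raise ConfigurationError(f"unknown scenario {name!r}")

    return SimConfig(
        species=species,
        crosstalk_green_into_red=0.02,
        duration=duration if duration is not None else default_duration,
        seed=seed,
        scenario_meta=meta,
        **cfg_kwargs,
    )
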