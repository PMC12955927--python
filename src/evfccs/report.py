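"""Condition-level statistics and the end-to-end analysis pipeline.

For significance testing between culture conditions the acquisition is
split into consecutive subsets of a fixed number of coincident events
(default 20, last partial subset dropped); per-subset coincident rates and
loading yields feed Welch's unequal-variance t-test (two-sided, with
Welch-Satterthwaite degrees of freedom). Error bars in summaries are the
standard deviation across subsets.

:func:`run_pipeline` chains every stage — PIE gating, correlation, diffusion
fits, occupancies, background estimation, calibrated burst search,
tolerance window, coincidence, sizing/cargo, gamma fits, subset metrics —
into one structured, JSON-serializable condition report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from evfccs.bursts import (
    BurstSearchParams,
    BurstSet,
    InsufficientDataError,
    calibrate_burst_params,
    detect_bursts,
    estimate_background,
)
from evfccs.coincidence import (
    CoincidentEvent,
    SizeEstimationConfig,
    annotate_events,
    chance_coincidence_rate,
    coincidence_metrics,
    compute_tolerance_window,
    fit_gamma_size_distribution,
    match_coincident_bursts,
)
from evfccs.correlate import (
    DetectionVolumes,
    burst_referred_brightness,
    correlate_with_errors,
    fit_diffusion_model,
    occupancy_from_amplitudes,
)
from evfccs.photon_data import ConfigurationError, PhotonStream, PIEGateConfig, apply_pie_gating

_pkg_version = "0.1.0"


@dataclass
class SubsetMetrics:
    """Per-subset coincident rate and loading yield."""

    index: int
    t_start: float
    t_stop: float
    coincident_rate_per_min: float
    loading_yield: float
    n_coincident: int
    n_red_bursts: int

    @property
    def span(self) -> float:
        return self.t_stop - self.t_start


def split_into_subsets(
    events: list[CoincidentEvent], red: BurstSet, per_subset: int = 20
) -> list[SubsetMetrics]:
    """Consecutive blocks of ``per_subset`` events; last partial block dropped.

    Each subset's time span runs from its first event's start to its last
    event's stop; the subset yield divides the event count by the number of
    red bursts whose centers fall inside the span.
    """
    if len(events) < per_subset:
        raise InsufficientDataError(
            f"need >= {per_subset} coincident events, got {len(events)}"
        )
    red_centers = red.center_times
    out: list[SubsetMetrics] = []
    n_full = len(events) // per_subset
    for i in range(n_full):
        block = events[i * per_subset: (i + 1) * per_subset]
        t0 = block[0].start_time
        t1 = block[-1].stop_time
        span = t1 - t0
        n_red = int(np.sum((red_centers >= t0) & (red_centers <= t1)))
        out.append(
            SubsetMetrics(
                index=i,
                t_start=t0,
                t_stop=t1,
                coincident_rate_per_min=60.0 * per_subset / span if span > 0 else 0.0,
                loading_yield=per_subset / n_red if n_red else 0.0,
                n_coincident=per_subset,
                n_red_bursts=n_red,
            )
        )
    return out


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Welch's two-sided unequal-variance t-test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate zero-variance samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class ConditionComparison:
    """Welch-test comparison of two measured conditions."""

    condition_a: str
    condition_b: str
    rate_t: float
    rate_df: float
    rate_p: float
    yield_t: float
    yield_df: float
    yield_p: float
    means: dict = field(default_factory=dict)


def compare_conditions(report_a: dict, report_b: dict) -> ConditionComparison:
    """Welch tests on subset coincident rates and loading yields."""
    ra = [s["coincident_rate_per_min"] for s in report_a["subsets"]]
    rb = [s["coincident_rate_per_min"] for s in report_b["subsets"]]
    ya = [s["loading_yield"] for s in report_a["subsets"]]
    yb = [s["loading_yield"] for s in report_b["subsets"]]
    t_r, df_r, p_r = welch_t_test(ra, rb)
    t_y, df_y, p_y = welch_t_test(ya, yb)
    return ConditionComparison(
        condition_a=report_a["condition"],
        condition_b=report_b["condition"],
        rate_t=t_r, rate_df=df_r, rate_p=p_r,
        yield_t=t_y, yield_df=df_y, yield_p=p_y,
        means={
            "rate_a": float(np.mean(ra)), "rate_a_sd": float(np.std(ra, ddof=1)),
            "rate_b": float(np.mean(rb)), "rate_b_sd": float(np.std(rb, ddof=1)),
            "yield_a": float(np.mean(ya)), "yield_a_sd": float(np.std(ya, ddof=1)),
            "yield_b": float(np.mean(yb)), "yield_b_sd": float(np.std(yb, ddof=1)),
        },
    )


# ---------------------------------------------------------------------------
# Event-level power simulation
# ---------------------------------------------------------------------------


def simulate_coincident_process(
    rate_per_min: float,
    red_rate_per_s: float,
    n_events: int,
    rng: np.random.Generator,
) -> tuple[list[CoincidentEvent], BurstSet]:
    """Draw coincident events and red bursts as Poisson processes.

    Event-level model for statistical power studies: coincident events occur
    at ``rate_per_min`` and red bursts at ``red_rate_per_s``; burst objects
    carry nominal millisecond durations. The acquisition runs until
    ``n_events`` events have occurred.
    """
    from evfccs.bursts import Burst, BurstSearchParams

    gaps = rng.exponential(60.0 / rate_per_min, n_events)
    centers = np.cumsum(gaps)
    duration = float(centers[-1]) + 1e-3
    n_red = rng.poisson(red_rate_per_s * duration)
    red_centers = np.sort(rng.uniform(0.0, duration, n_red))
    red_centers = np.unique(np.concatenate([red_centers, centers]))
    # enforce disjoint nominal burst intervals (+-1 ms around each center)
    if red_centers.size > 1:
        keep = np.concatenate([[True], np.diff(red_centers) > 2.1e-3])
        red_centers = red_centers[keep]

    def mk_burst(c: float, ch: str) -> Burst:
        return Burst(channel=ch, start_time=c - 1e-3, stop_time=c + 1e-3,
                     n_photons=25, first_photon=0, last_photon=24)

    events = [
        CoincidentEvent(
            green_burst=mk_burst(c, "green"), red_burst=mk_burst(c, "red"),
            center_offset=0.0,
        )
        for c in centers
    ]
    params = BurstSearchParams(m=10, big_k=6.0, background_rate=200.0, min_photons=20)
    red_set = BurstSet(
        channel="red", params=params,
        bursts=[mk_burst(c, "red") for c in red_centers],
        duration=duration,
    )
    return events, red_set


def welch_power(
    rate_a_per_min: float,
    rate_b_per_min: float,
    n_subsets: int = 8,
    per_subset: int = 20,
    red_rate_per_s: float = 1.5,
    n_replicates: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of replicates where Welch's test separates two conditions.

    Each replicate draws both conditions' coincident events as Poisson
    processes (enough for ``n_subsets`` subsets of ``per_subset`` events),
    splits them with :func:`split_into_subsets` and Welch-tests the subset
    coincident rates.
    """
    rng = np.random.default_rng(seed)
    n_events = n_subsets * per_subset
    hits = 0
    p_values = []
    for _ in range(n_replicates):
        ev_a, red_a = simulate_coincident_process(rate_a_per_min, red_rate_per_s, n_events, rng)
        ev_b, red_b = simulate_coincident_process(rate_b_per_min, red_rate_per_s, n_events, rng)
        sub_a = split_into_subsets(ev_a, red_a, per_subset=per_subset)
        sub_b = split_into_subsets(ev_b, red_b, per_subset=per_subset)
        _, _, p = welch_t_test(
            [s.coincident_rate_per_min for s in sub_a],
            [s.coincident_rate_per_min for s in sub_b],
        )
        p_values.append(p)
        hits += p < alpha
    return {
        "power": hits / n_replicates,
        "n_replicates": n_replicates,
        "p_values": p_values,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_REPORT_REQUIRED_KEYS = (
    "condition", "software_version", "duration_s", "parameters",
    "occupancies", "loading_yield_fccs", "loading_yield_burst",
    "coincident_rate_per_min", "n_coincident_events", "size_fit_green",
    "cargo_quantiles", "subsets",
)


@dataclass
class AnalysisConfig:
    """Every tunable of the end-to-end analysis, with study defaults."""

    condition: str = "condition"
    gates: PIEGateConfig = field(default_factory=PIEGateConfig)
    base_bin: float = 2e-6
    points_per_level: int = 8
    n_levels: int = 22
    n_segments: int = 5
    n_components_green: int = 1
    kappa: float = 5.0
    size_cfg: SizeEstimationConfig = field(default_factory=SizeEstimationConfig)
    waist_z_green: float = 1435e-9
    waist_z_red: float = 1860e-9
    axial_offset: float = 300e-9
    background_green: float | None = None  # None -> estimate from data
    background_red: float | None = None
    # fixed burst-search parameters (from a one-time calibration on a
    # reference condition); K is rescaled so K*B stays fixed when the
    # background differs. None -> calibrate on this acquisition.
    burst_params_green: "BurstSearchParams | None" = None
    burst_params_red: "BurstSearchParams | None" = None
    brightness_cps: float | None = None  # free-cargo molecular brightness
    tolerance_rule: str = "q10_difference"
    min_photons: int = 20
    per_subset: int = 20
    volume_correction: bool = True
    seed: int | None = None

    def volumes(self) -> DetectionVolumes | None:
        if not self.volume_correction:
            return None
        return DetectionVolumes(
            waist_xy_green=self.size_cfg.waist_green,
            waist_z_green=self.waist_z_green,
            waist_xy_red=self.size_cfg.waist_red,
            waist_z_red=self.waist_z_red,
            axial_offset=self.axial_offset,
        )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception, hint: str = ""):
        self.stage = stage
        msg = f"pipeline stage {stage!r} failed: {exc}"
        if hint:
            msg += f" ({hint})"
        super().__init__(msg)


def _stage(name: str, fn, hint: str = ""):
    try:
        return fn()
    except Exception as exc:
        raise PipelineError(name, exc, hint) from exc


def run_pipeline(stream: PhotonStream, config: AnalysisConfig) -> dict:
    """Gate -> correlate -> fit -> occupancies -> bursts -> coincidence ->
    sizes/cargo -> gamma fit -> subsets; returns the condition report dict.

    The report is JSON-serializable and deterministic for a given input
    stream and configuration.
    """
    gated = _stage("gate", lambda: apply_pie_gating(stream, config.gates))
    green, red = gated.green, gated.red

    bg_g = config.background_green
    bg_r = config.background_red
    if bg_g is None:
        bg_g = _stage("background_green", lambda: estimate_background(green, n_passes=12))
    if bg_r is None:
        bg_r = _stage("background_red", lambda: estimate_background(red, n_passes=12))
    # degenerate-channel guard: a signal-free channel can show a measured
    # rate at or below the configured background (Poisson fluctuation)
    bg_g = min(bg_g, 0.95 * green.mean_rate) if len(green) else bg_g
    bg_r = min(bg_r, 0.95 * red.mean_rate) if len(red) else bg_r

    corr_kwargs = dict(
        base_bin=config.base_bin,
        points_per_level=config.points_per_level,
        n_levels=config.n_levels,
    )
    curve_g = _stage("correlate_gg", lambda: correlate_with_errors(
        green, n_segments=config.n_segments, **corr_kwargs))
    curve_r = _stage("correlate_rr", lambda: correlate_with_errors(
        red, n_segments=config.n_segments, **corr_kwargs))
    curve_rg = _stage("correlate_rg", lambda: correlate_with_errors(
        red, green, n_segments=config.n_segments, **corr_kwargs))

    fit_g = _stage("fit_gg", lambda: fit_diffusion_model(
        curve_g, n_components=config.n_components_green, kappa=config.kappa,
        background_rate=bg_g))
    fit_r = _stage("fit_rr", lambda: fit_diffusion_model(
        curve_r, n_components=1, kappa=config.kappa, background_rate=bg_r))
    fit_rg = _stage("fit_rg", lambda: fit_diffusion_model(
        curve_rg, n_components=1, kappa=config.kappa))

    from evfccs.correlate import NoSignalError, OccupancyResult

    try:
        occ = occupancy_from_amplitudes(fit_g, fit_r, fit_rg, volumes=config.volumes())
    except NoSignalError as exc:
        # single-color input: one autocorrelation has no amplitude
        occ = OccupancyResult(
            n_g=float("nan"), n_r=float("nan"), n_rg=0.0,
            loading_yield_fccs=0.0, bound_fraction_green=0.0,
            warnings=[f"occupancies unavailable: {exc}"],
        )

    tau_g = fit_g.tau_d  # slow component for EV samples
    tau_r = fit_r.tau_d

    def calibrated_bursts(stream_, tau, bg, channel, fixed):
        from evfccs.bursts import BurstSearchParams

        if fixed is not None:
            # one-time calibration carried across acquisitions: K*B and m
            # stay fixed, K rescales with this acquisition's background
            params = fixed.with_background(bg)
        else:
            try:
                params = calibrate_burst_params(
                    stream_, tau, bg, min_photons=config.min_photons, channel=channel
                )
            except InsufficientDataError:
                # single-color or burst-free channel: default parameters
                params = BurstSearchParams(
                    background_rate=bg, min_photons=config.min_photons
                )
        return params, detect_bursts(stream_, params, channel=channel)

    params_g, bursts_g = _stage(
        "bursts_green",
        lambda: calibrated_bursts(green, tau_g, bg_g, "green", config.burst_params_green))
    params_r, bursts_r = _stage(
        "bursts_red",
        lambda: calibrated_bursts(red, tau_r, bg_r, "red", config.burst_params_red))

    try:
        window = compute_tolerance_window(bursts_g, bursts_r, rule=config.tolerance_rule)
    except InsufficientDataError:
        # too few bursts in one channel: no meaningful coincidence search
        from evfccs.coincidence import ToleranceWindow

        window = ToleranceWindow(value=0.0, q10_green=0.0, q10_red=0.0,
                                 rule=config.tolerance_rule)
    events, unmatched = match_coincident_bursts(bursts_g, bursts_r, window)
    # cargo counting divides by the burst-referred brightness (the FCS
    # calibration brightness rescaled to the burst-average intensity scale)
    eps_burst = (
        burst_referred_brightness(config.brightness_cps)
        if config.brightness_cps is not None else None
    )
    annotate_events(
        events, config.size_cfg, brightness=eps_burst,
        background_green=bg_g,
    )
    rate, yield_burst = coincidence_metrics(events, bursts_r, stream.duration_s)

    sizes_g = np.array([e.size_green_nm for e in events], dtype=float)
    sizes_r = np.array([e.size_red_nm for e in events], dtype=float)
    size_fit_g = size_fit_r = None
    if sizes_g.size >= 30:
        size_fit_g = fit_gamma_size_distribution(sizes_g)
        size_fit_r = fit_gamma_size_distribution(sizes_r)
    # per-channel distributions over ALL bursts: free of the coincidence
    # selection bias (matching prefers pairs of similar duration, which
    # reads the wider channel's sizes low)
    from evfccs.coincidence import ev_size_from_burst

    size_fit_g_all = size_fit_r_all = None
    all_g = np.array([ev_size_from_burst(b, config.size_cfg) for b in bursts_g.bursts])
    all_r = np.array([ev_size_from_burst(b, config.size_cfg) for b in bursts_r.bursts])
    if all_g.size >= 30:
        size_fit_g_all = fit_gamma_size_distribution(all_g)
    if all_r.size >= 30:
        size_fit_r_all = fit_gamma_size_distribution(all_r)

    cargo = np.array(
        [e.cargo_count for e in events if e.cargo_count is not None], dtype=float
    )
    cargo_q = (
        {q: float(np.quantile(cargo, q / 100)) for q in (10, 25, 50, 75, 90)}
        if cargo.size else {}
    )

    subsets: list[SubsetMetrics] = []
    if len(events) >= config.per_subset:
        subsets = split_into_subsets(events, bursts_r, per_subset=config.per_subset)

    report = {
        "condition": config.condition,
        "software_version": _pkg_version,
        "seed": config.seed,
        "duration_s": stream.duration_s,
        "parameters": {
            "base_bin_s": config.base_bin,
            "n_components_green": config.n_components_green,
            "kappa": config.kappa,
            "background_green_cps": bg_g,
            "background_red_cps": bg_r,
            "burst_green": {"m": params_g.m, "K": params_g.big_k,
                            "min_photons": params_g.min_photons},
            "burst_red": {"m": params_r.m, "K": params_r.big_k,
                          "min_photons": params_r.min_photons},
            "tolerance_window_s": window.value,
            "tolerance_rule": window.rule,
            "brightness_cps": config.brightness_cps,
            "volume_correction": config.volume_correction,
            "discarded_photons": gated.discarded_counts,
        },
        "occupancies": {
            "n_g": occ.n_g, "n_r": occ.n_r, "n_rg": occ.n_rg,
            "bound_fraction_green": occ.bound_fraction_green,
        },
        "diffusion_times_s": {"green": tau_g, "red": tau_r},
        "loading_yield_fccs": occ.loading_yield_fccs,
        "loading_yield_burst": yield_burst,
        "coincident_rate_per_min": rate,
        "chance_rate_per_min": 60.0 * chance_coincidence_rate(
            bursts_g.burst_rate, bursts_r.burst_rate, window.value),
        "n_coincident_events": len(events),
        "n_green_bursts": len(bursts_g),
        "n_red_bursts": len(bursts_r),
        "unmatched": unmatched,
        "size_fit_green": _size_fit_dict(size_fit_g),
        "size_fit_red": _size_fit_dict(size_fit_r),
        "size_fit_green_all_bursts": _size_fit_dict(size_fit_g_all),
        "size_fit_red_all_bursts": _size_fit_dict(size_fit_r_all),
        "cargo_quantiles": cargo_q,
        "subsets": [dataclasses.asdict(s) for s in subsets],
        "occupancy_warnings": occ.warnings,
    }
    validate_report(report)
    return report


def calibrate_brightness(seed: int = 0, duration: float | None = None) -> float:
    """FCS molecular brightness (cps/molecule) from a free-cargo scenario.

    Simulates the single-species calibration measurement, fits its gated
    green autocorrelation and returns (F - B)/N.
    """
    from evfccs.correlate import molecular_brightness
    from evfccs.simulate import make_scenario, simulate_photon_stream

    cfg = make_scenario("calibration_free_dye", duration=duration, seed=seed)
    stream, _ = simulate_photon_stream(cfg)
    green = apply_pie_gating(stream, PIEGateConfig()).green
    curve = correlate_with_errors(green, base_bin=2e-6, n_levels=16)
    fit = fit_diffusion_model(
        curve, 1, kappa=5.0, background_rate=cfg.background_rate_green
    )
    return molecular_brightness(green.mean_rate, fit, cfg.background_rate_green)


def analyze_simulated_scenario(
    name: str,
    seed: int,
    duration: float | None = None,
    brightness_cps: float | None = None,
    condition: str | None = None,
    burst_params_green: BurstSearchParams | None = None,
    burst_params_red: BurstSearchParams | None = None,
) -> tuple[dict, dict]:
    """Simulate a preset scenario and run the full pipeline on it.

    The analysis configuration mirrors an experiment with an independently
    measured background (the scenario's configured rates) and a calibrated
    beam geometry. Returns ``(condition report, ground-truth summary)``.
    """
    from evfccs.simulate import ground_truth_summary, make_scenario, simulate_photon_stream

    cfg = make_scenario(name, duration=duration, seed=seed)
    stream, gt = simulate_photon_stream(cfg)
    acfg = AnalysisConfig(
        condition=condition or name,
        n_components_green=int(cfg.scenario_meta.get("n_components_green", 1)),
        background_green=cfg.background_rate_green,
        background_red=cfg.background_rate_red,
        brightness_cps=brightness_cps,
        burst_params_green=burst_params_green,
        burst_params_red=burst_params_red,
        seed=seed,
    )
    report = run_pipeline(stream, acfg)
    return report, ground_truth_summary(gt, cfg)


def _size_fit_dict(fit) -> dict | None:
    if fit is None:
        return None
    return {"alpha": fit.alpha, "lambda_per_nm": fit.lam, "mean_nm": fit.mean,
            "n": fit.n_samples}


def validate_report(report: dict) -> None:
    """Schema check: every required field present (incomplete-report error)."""
    missing = [k for k in _REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ConfigurationError(f"incomplete report, missing: {missing}")


def summarize_condition(report: dict) -> str:
    """Human-readable one-condition summary (report must validate)."""
    validate_report(report)
    lines = [
        f"condition: {report['condition']}",
        f"duration: {report['duration_s']:.1f} s",
        f"occupancies: N_g={report['occupancies']['n_g']:.3g} "
        f"N_r={report['occupancies']['n_r']:.3g} N_rg={report['occupancies']['n_rg']:.3g}",
        f"loading yield (FCCS): {report['loading_yield_fccs']:.3f}",
        f"loading yield (bursts): {report['loading_yield_burst']:.3f}",
        f"coincident rate: {report['coincident_rate_per_min']:.2f} events/min "
        f"({report['n_coincident_events']} events)",
    ]
    if report["size_fit_green"]:
        lines.append(
            f"size (gamma mean): green {report['size_fit_green']['mean_nm']:.0f} nm, "
            f"red {report['size_fit_red']['mean_nm']:.0f} nm"
        )
    if report["cargo_quantiles"]:
        lines.append(f"cargo median: {report['cargo_quantiles'][50]:.0f} molecules")
    if report["subsets"]:
        rates = [s["coincident_rate_per_min"] for s in report["subsets"]]
        lines.append(
            f"subsets: {len(rates)} x {report['subsets'][0]['n_coincident']} events, "
            f"rate {np.mean(rates):.2f} +- {np.std(rates, ddof=1):.2f} events/min"
        )
    return "\n".join(lines)


def report_to_json(report: dict, path=None) -> str:
    """Serialize a report deterministically (sorted keys)."""
    txt = json.dumps(_jsonify(report), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(txt + "\n")
    return txt


def _jsonify(obj: Any):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
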