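"""Sliding-window photon-burst search and burst-parameter calibration.

A burst is a transient photon cluster produced by one particle transiting
the focal volume. The detector follows the classic minimum-local-rate rule:
photon ``i`` is *hot* when the ``m``-photon window centered on it spans at
most ``m / (K B)`` seconds, i.e. the local count rate over ``m`` consecutive
photons is at least ``K`` times the background rate ``B``. Maximal runs of
hot photons form bursts (start/stop = first/last photon of the run); runs
with fewer than ``min_photons`` photons are discarded, so bursts are
disjoint by construction.

``calibrate_burst_params`` grid-searches ``K`` and ``m`` so that the median
burst duration matches a target diffusion time from an FCCS fit — the same
closing-the-loop calibration used to make burst durations interpretable as
focal transits for Stokes-Einstein sizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from evfccs.photon_data import ConfigurationError, PhotonStream


class InsufficientDataError(RuntimeError):
    pass


@dataclass
class BurstSearchParams:
    """Sliding-window burst-search parameters.

    ``m``: photons per local-rate window; ``K``: rate threshold factor over
    background; ``background_rate``: B in counts/s; ``min_photons``: minimum
    photons for a valid burst. The detection threshold rate is ``K * B``.
    """

    m: int = 10
    big_k: float = 6.0
    background_rate: float = 200.0
    min_photons: int = 20

    def __post_init__(self) -> None:
        if self.m < 3:
            raise ConfigurationError("m must be >= 3")
        if self.big_k <= 1.0:
            raise ConfigurationError("K must be > 1")
        if self.background_rate < 0:
            raise ConfigurationError("background rate must be >= 0")
        if self.big_k * self.background_rate <= 0:
            raise ConfigurationError("threshold rate K*B must be > 0")

    @property
    def threshold_rate(self) -> float:
        return self.big_k * self.background_rate

    def with_background(self, background_rate: float) -> "BurstSearchParams":
        """Same threshold rate K*B, K rescaled for a new background estimate."""
        return BurstSearchParams(
            m=self.m,
            big_k=self.threshold_rate / background_rate,
            background_rate=background_rate,
            min_photons=self.min_photons,
        )


@dataclass
class Burst:
    """One detected single-particle transit."""

    channel: str
    start_time: float
    stop_time: float
    n_photons: int
    first_photon: int  # index into the source stream
    last_photon: int

    def __post_init__(self) -> None:
        if self.stop_time < self.start_time:
            raise ValueError("burst stop before start")

    @property
    def duration(self) -> float:
        return self.stop_time - self.start_time

    @property
    def center_time(self) -> float:
        """Midpoint of the burst interval."""
        return 0.5 * (self.start_time + self.stop_time)

    @property
    def mean_rate(self) -> float:
        """Raw mean count rate over the burst, counts/s."""
        return self.n_photons / self.duration if self.duration > 0 else float("inf")

    def intensity(self, background_rate: float) -> float:
        """Background-subtracted mean rate, counts/s."""
        return max(self.mean_rate - background_rate, 0.0)


@dataclass
class BurstSet:
    """Time-ordered, non-overlapping bursts from one channel."""

    channel: str
    params: BurstSearchParams
    bursts: list[Burst]
    duration: float
    background_rate: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.background_rate == 0.0:
            self.background_rate = self.params.background_rate
        for prev, cur in zip(self.bursts, self.bursts[1:]):
            if cur.start_time < prev.stop_time:
                raise ValueError("bursts must be disjoint and sorted")

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def burst_rate(self) -> float:
        """Total burst rate, bursts/s."""
        return len(self.bursts) / self.duration if self.duration > 0 else 0.0

    @property
    def durations(self) -> np.ndarray:
        return np.array([b.duration for b in self.bursts])

    @property
    def center_times(self) -> np.ndarray:
        return np.array([b.center_time for b in self.bursts])


def estimate_background(
    stream: PhotonStream,
    params: BurstSearchParams | None = None,
    n_passes: int = 2,
    rel_tol: float = 0.01,
) -> float:
    """Iterative background-rate estimate, counts/s.

    Start from the global mean rate, detect bursts at that rate and
    re-estimate from the photons (and time) outside bursts; by default one
    refinement pass of the same procedure. For signal-heavy streams the
    two-pass estimate is biased high (the first threshold is far above the
    background, so dim signal leaks into the "outside" photons); passing a
    larger ``n_passes`` iterates to a fixed point (stops early once the
    relative change drops below ``rel_tol``).
    """
    if len(stream) == 0 or stream.duration_s <= 0:
        raise InsufficientDataError("cannot estimate background of an empty stream")
    base = params or BurstSearchParams()
    rate = stream.n_photons / stream.duration_s
    for _ in range(n_passes):
        p = BurstSearchParams(
            m=base.m, big_k=base.big_k, background_rate=rate, min_photons=base.min_photons
        )
        bs = detect_bursts(stream, p, channel="bg")
        burst_time = float(sum(b.duration for b in bs.bursts))
        burst_photons = int(sum(b.n_photons for b in bs.bursts))
        out_time = stream.duration_s - burst_time
        out_photons = stream.n_photons - burst_photons
        if out_time <= 0 or out_photons <= 0:
            raise InsufficientDataError("all photons fall inside bursts")
        new_rate = out_photons / out_time
        converged = abs(new_rate - rate) <= rel_tol * rate
        rate = new_rate
        if converged:
            break
    return rate


def detect_bursts(
    stream: PhotonStream, params: BurstSearchParams, channel: str = ""
) -> BurstSet:
    """Sliding-window burst search (see module docstring for the rule)."""
    t = stream.macrotimes_s
    n = len(t)
    m = params.m
    max_span = m / params.threshold_rate
    hot = np.zeros(n, dtype=bool)
    if n >= m:
        # window centered on photon i: [i - h1, i + h2], h1 + h2 = m - 1
        h1 = (m - 1) // 2
        h2 = m - 1 - h1
        spans = t[m - 1:] - t[: n - m + 1]  # span of window starting at j
        hot[h1: n - h2] = spans <= max_span
    bursts: list[Burst] = []
    if hot.any():
        edges = np.diff(hot.astype(np.int8))
        starts = np.nonzero(edges == 1)[0] + 1
        stops = np.nonzero(edges == -1)[0] + 1  # exclusive
        if hot[0]:
            starts = np.concatenate([[0], starts])
        if hot[-1]:
            stops = np.concatenate([stops, [n]])
        for a, b in zip(starts, stops):
            if b - a < params.min_photons:
                continue
            bursts.append(
                Burst(
                    channel=channel,
                    start_time=float(t[a]),
                    stop_time=float(t[b - 1]),
                    n_photons=int(b - a),
                    first_photon=int(a),
                    last_photon=int(b - 1),
                )
            )
    return BurstSet(
        channel=channel, params=params, bursts=bursts, duration=stream.duration_s,
        background_rate=params.background_rate,
    )


def burst_statistics(bs: BurstSet) -> dict:
    """Duration quantiles, rate histogram and inter-burst intervals.

    Quantiles use linear interpolation between order statistics. Returns an
    ``{"empty": True}`` flag (no exception) for an empty set.
    """
    if len(bs) == 0:
        return {"empty": True, "n_bursts": 0}
    durations = bs.durations
    rates = np.array([b.mean_rate for b in bs.bursts])
    centers = bs.center_times
    out = {
        "empty": False,
        "n_bursts": len(bs),
        "duration_median": float(np.quantile(durations, 0.5)),
        "duration_q10": float(np.quantile(durations, 0.1)),
        "duration_q90": float(np.quantile(durations, 0.9)),
        "duration_mean": float(durations.mean()),
        "rate_hist": np.histogram(rates, bins=20),
        "inter_burst_intervals": np.diff(centers),
        "burst_rate": bs.burst_rate,
    }
    return out


def calibrate_burst_params(
    stream: PhotonStream,
    target_tau_d: float,
    background_rate: float,
    k_grid: np.ndarray | list[float] | None = None,
    m_grid: np.ndarray | list[int] | None = None,
    min_photons: int = 20,
    min_bursts: int = 20,
    channel: str = "",
) -> BurstSearchParams:
    """Choose (K, m) whose median burst duration best matches ``target_tau_d``.

    Grid search minimizing |median duration - target|; ties break toward the
    larger (stricter) K. Candidates producing fewer than ``min_bursts``
    bursts are skipped; if none qualifies an
    :class:`InsufficientDataError` is raised.
    """
    if target_tau_d <= 0:
        raise ConfigurationError("target diffusion time must be positive")
    if k_grid is None:
        k_grid = [2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 13.0, 16.0, 20.0, 26.0, 32.0, 45.0, 64.0]
    if m_grid is None:
        m_grid = [5, 8, 10, 15, 20, 30]
    best: tuple[float, float, BurstSearchParams] | None = None
    for m in m_grid:
        for k in k_grid:
            p = BurstSearchParams(
                m=int(m), big_k=float(k), background_rate=background_rate,
                min_photons=min_photons,
            )
            bs = detect_bursts(stream, p, channel=channel)
            if len(bs) < min_bursts:
                continue
            med = float(np.quantile(bs.durations, 0.5))
            dev = abs(med - target_tau_d)
            # ties (within float tolerance) break toward larger K
            if best is None or dev < best[0] - 1e-15 or (
                abs(dev - best[0]) <= 1e-15 and k > best[1]
            ):
                best = (dev, float(k), p)
    if best is None:
        raise InsufficientDataError(
            f"no (K, m) candidate produced >= {min_bursts} bursts"
        )
    return best[2]
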