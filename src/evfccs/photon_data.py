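"""Time-tagged photon streams, file I/O and PIE nanotime gating.

A :class:`PhotonStream` is the universal input of the pipeline: three equal
length per-photon arrays (macrotime in integer clock ticks, TCSPC nanotime in
integer bins, detector id) plus the metadata needed to interpret them (tick
duration, TCSPC bin width, laser sync rate, acquisition duration).

Pulsed interleaved excitation (PIE) alternates the two excitation lasers
within one sync period; :func:`apply_pie_gating` keeps, for each detector,
only the photons whose nanotime falls inside the gate of the laser assigned
to that detector, which removes spectral crosstalk from the gated streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import h5py
import numpy as np

GREEN_DET = 0
RED_DET = 1

Dialect = Literal["photon_hdf5", "columnar_text"]


class DataIntegrityError(ValueError):
    """Per-photon arrays violate a stream invariant."""


class ConfigurationError(ValueError):
    """Metadata or analysis configuration is missing or inconsistent."""


@dataclass
class PhotonStream:
    """Two-channel time-tagged photon record.

    Attributes
    ----------
    macrotimes : ndarray of int64
        Arrival time of each photon in clock ticks, non-decreasing.
    nanotimes : ndarray of int
        Time since the last sync pulse, in TCSPC bins.
    detector_ids : ndarray of int
        Detector index per photon (0 = green detector, 1 = red detector).
    tick_s, tcspc_bin_s : float
        Duration of one macrotime tick / one TCSPC bin, seconds.
    sync_rate_hz : float
        Laser synchronization frequency.
    duration_s : float
        Acquisition length in seconds.
    """

    macrotimes: np.ndarray
    nanotimes: np.ndarray
    detector_ids: np.ndarray
    tick_s: float = 1e-9
    tcspc_bin_s: float = 5e-12
    sync_rate_hz: float = 40e6
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.macrotimes = np.asarray(self.macrotimes, dtype=np.int64)
        self.nanotimes = np.asarray(self.nanotimes, dtype=np.int64)
        self.detector_ids = np.asarray(self.detector_ids, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.tick_s <= 0:
            raise ConfigurationError("tick duration must be > 0")
        if self.tcspc_bin_s <= 0:
            raise ConfigurationError("TCSPC bin width must be > 0")
        if self.sync_rate_hz <= 0:
            raise ConfigurationError("sync rate must be > 0")
        n = len(self.macrotimes)
        if len(self.nanotimes) != n or len(self.detector_ids) != n:
            raise DataIntegrityError(
                "per-photon arrays must have equal length: "
                f"{n}, {len(self.nanotimes)}, {len(self.detector_ids)}"
            )
        if n:
            steps = np.diff(self.macrotimes)
            bad = np.nonzero(steps < 0)[0]
            if bad.size:
                raise DataIntegrityError(
                    f"macrotimes must be non-decreasing; first violation at index {bad[0] + 1}"
                )
            period = 1.0 / self.sync_rate_hz
            if self.nanotimes.max() * self.tcspc_bin_s >= period:
                raise DataIntegrityError(
                    "nanotime exceeds the sync period: "
                    f"max {self.nanotimes.max() * self.tcspc_bin_s:.3e} s >= {period:.3e} s"
                )
            if self.nanotimes.min() < 0:
                raise DataIntegrityError("nanotimes must be non-negative")

    def __len__(self) -> int:
        return len(self.macrotimes)

    @property
    def n_photons(self) -> int:
        return len(self.macrotimes)

    @property
    def macrotimes_s(self) -> np.ndarray:
        """Arrival times in seconds (float)."""
        return self.macrotimes * self.tick_s

    @property
    def mean_rate(self) -> float:
        """Mean detected count rate over the acquisition, counts/s."""
        if self.duration_s <= 0:
            raise ConfigurationError("stream has no positive duration")
        return self.n_photons / self.duration_s

    def select(self, mask: np.ndarray) -> "PhotonStream":
        """Sub-stream of the photons where ``mask`` is True; metadata kept."""
        return replace(
            self,
            macrotimes=self.macrotimes[mask],
            nanotimes=self.nanotimes[mask],
            detector_ids=self.detector_ids[mask],
        )


@dataclass
class PIEGateConfig:
    """Nanotime gates assigning photons to their exciting laser.

    Gates are half-open intervals ``[start, end)`` in seconds within one sync
    period. By default the green laser owns the first half-period and the red
    laser the second, i.e. a 12.5 ns interleave delay at 40 MHz; ``offset_s``
    shifts both gates to accommodate a trigger delay.
    """

    sync_rate_hz: float = 40e6
    green_gate: tuple[float, float] | None = None
    red_gate: tuple[float, float] | None = None
    detector_to_dye: dict[int, str] = field(
        default_factory=lambda: {GREEN_DET: "green", RED_DET: "red"}
    )
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        period = 1.0 / self.sync_rate_hz
        if self.green_gate is None:
            self.green_gate = (self.offset_s, self.offset_s + period / 2.0)
        if self.red_gate is None:
            self.red_gate = (self.offset_s + period / 2.0, self.offset_s + period)
        for name, (a, b) in (("green", self.green_gate), ("red", self.red_gate)):
            if not (0.0 <= a < b <= period):
                raise ConfigurationError(
                    f"{name} gate {(a, b)} must lie within [0, {period:.3e}) s"
                )
        g0, g1 = self.green_gate
        r0, r1 = self.red_gate
        if max(g0, r0) < min(g1, r1):
            raise ConfigurationError("green and red gates must be disjoint")

    @property
    def interleave_delay_s(self) -> float:
        """Red-gate start minus green-gate start."""
        return self.red_gate[0] - self.green_gate[0]

    def gate_for_detector(self, det: int) -> tuple[float, float]:
        dye = self.detector_to_dye[det]
        return self.green_gate if dye == "green" else self.red_gate


@dataclass
class GatedStreams:
    """Result of PIE gating: crosstalk-suppressed per-channel streams."""

    green: PhotonStream
    red: PhotonStream
    discarded_counts: dict[int, int]

    @property
    def total_discarded(self) -> int:
        return int(sum(self.discarded_counts.values()))


def apply_pie_gating(stream: PhotonStream, gates: PIEGateConfig) -> GatedStreams:
    """Split a stream into gated green/red sub-streams.

    A photon is kept iff its nanotime lies in the half-open gate assigned to
    its detector; photons on the right gate edge or outside any gate are
    discarded and counted per detector. Photon counts partition exactly:
    ``len(green) + len(red) + total discarded == len(stream)``.
    """
    if abs(gates.sync_rate_hz - stream.sync_rate_hz) > 1e-6 * stream.sync_rate_hz:
        raise ConfigurationError(
            f"gate sync rate {gates.sync_rate_hz} Hz != stream sync rate {stream.sync_rate_hz} Hz"
        )
    nan_s = stream.nanotimes * stream.tcspc_bin_s
    masks: dict[str, np.ndarray] = {}
    discarded: dict[int, int] = {}
    for det in sorted(set(gates.detector_to_dye)):
        on_det = stream.detector_ids == det
        lo, hi = gates.gate_for_detector(det)
        in_gate = on_det & (nan_s >= lo) & (nan_s < hi)
        masks[gates.detector_to_dye[det]] = in_gate
        discarded[det] = int(on_det.sum() - in_gate.sum())
    unknown = ~np.isin(stream.detector_ids, list(gates.detector_to_dye))
    if unknown.any():
        discarded[-1] = int(unknown.sum())
    return GatedStreams(
        green=stream.select(masks.get("green", np.zeros(len(stream), bool))),
        red=stream.select(masks.get("red", np.zeros(len(stream), bool))),
        discarded_counts=discarded,
    )


def count_rate_trace(
    stream: PhotonStream, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Time-binned intensity trace.

    Returns ``(counts, bin_centers_s)`` with ``len == ceil(duration/bin_width)``
    and ``counts.sum() == len(stream)``.
    """
    if bin_width <= 0:
        raise ConfigurationError("bin width must be > 0")
    if stream.duration_s <= 0:
        raise ConfigurationError("stream duration must be > 0")
    if bin_width > stream.duration_s:
        raise ConfigurationError("bin width exceeds acquisition duration")
    n_bins = int(np.ceil(stream.duration_s / bin_width))
    idx = np.minimum((stream.macrotimes_s / bin_width).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return counts, centers


def slice_stream(stream: PhotonStream, t0: float, t1: float) -> PhotonStream:
    """Photons with macrotime in ``[t0, t1)`` seconds; duration = t1 - t0."""
    if not (0.0 <= t0 < t1 <= stream.duration_s + 1e-12):
        raise ConfigurationError(f"invalid slice interval [{t0}, {t1})")
    t = stream.macrotimes_s
    out = stream.select((t >= t0) & (t < t1))
    out.macrotimes = out.macrotimes - int(round(t0 / stream.tick_s))
    out.duration_s = t1 - t0
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_TEXT_META_KEYS = ("tick_s", "tcspc_bin_s", "sync_rate_hz", "duration_s")


def write_photon_file(stream: PhotonStream, path: str | Path, dialect: Dialect = "photon_hdf5") -> Path:
    """Write a stream losslessly; readable back with :func:`read_photon_file`."""
    stream.validate()
    path = Path(path)
    if dialect == "photon_hdf5":
        with h5py.File(path, "w") as f:
            pd = f.create_group("photon_data")
            pd.create_dataset("timestamps", data=stream.macrotimes, dtype=np.int64)
            pd.create_dataset("nanotimes", data=stream.nanotimes, dtype=np.int64)
            pd.create_dataset("detectors", data=stream.detector_ids, dtype=np.int64)
            pd.create_group("timestamps_specs").create_dataset(
                "timestamps_unit", data=stream.tick_s
            )
            pd.create_group("nanotimes_specs").create_dataset(
                "tcspc_unit", data=stream.tcspc_bin_s
            )
            setup = f.create_group("setup")
            setup.create_dataset("excitation_sync_rate", data=stream.sync_rate_hz)
            f.create_group("acquisition").create_dataset(
                "duration", data=stream.duration_s
            )
    elif dialect == "columnar_text":
        with open(path, "w") as fh:
            for key in _TEXT_META_KEYS:
                fh.write(f"#{key}={getattr(stream, key)!r}\n")
            fh.write("#columns=macrotime_tick\tnanotime_bin\tdetector\n")
            np.savetxt(
                fh,
                np.column_stack([stream.macrotimes, stream.nanotimes, stream.detector_ids]),
                fmt="%d",
                delimiter="\t",
            )
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    return path


def read_photon_file(path: str | Path, dialect: Dialect = "photon_hdf5") -> PhotonStream:
    """Read a photon stream written by :func:`write_photon_file`.

    Raises :class:`ConfigurationError` for missing resolution metadata and
    :class:`DataIntegrityError` (naming the first offending index) for
    non-monotone macrotimes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "photon_hdf5":
        with h5py.File(path, "r") as f:
            try:
                pd = f["photon_data"]
                tick = float(pd["timestamps_specs/timestamps_unit"][()])
                tcspc = float(pd["nanotimes_specs/tcspc_unit"][()])
                sync = float(f["setup/excitation_sync_rate"][()])
            except KeyError as exc:
                raise ConfigurationError(f"missing resolution metadata in {path}: {exc}")
            duration = float(f["acquisition/duration"][()]) if "acquisition" in f else 0.0
            return PhotonStream(
                macrotimes=pd["timestamps"][()],
                nanotimes=pd["nanotimes"][()],
                detector_ids=pd["detectors"][()],
                tick_s=tick,
                tcspc_bin_s=tcspc,
                sync_rate_hz=sync,
                duration_s=duration,
            )
    elif dialect == "columnar_text":
        meta: dict[str, float] = {}
        rows: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "=" in line:
                        key, _, val = line[1:].partition("=")
                        if key in _TEXT_META_KEYS:
                            meta[key] = float(val)
                else:
                    rows.append(line)
        missing = [k for k in _TEXT_META_KEYS if k not in meta]
        if missing:
            raise ConfigurationError(f"missing metadata keys in {path}: {missing}")
        if rows:
            data = np.loadtxt(rows, dtype=np.int64, ndmin=2)
        else:
            data = np.zeros((0, 3), dtype=np.int64)
        return PhotonStream(
            macrotimes=data[:, 0],
            nanotimes=data[:, 1],
            detector_ids=data[:, 2],
            **meta,  # type: ignore[arg-type]
        )
    raise ConfigurationError(f"unknown dialect {dialect!r}")
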