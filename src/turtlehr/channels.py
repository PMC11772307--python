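"""Core time-series containers and plain-text I/O.

A deployment is a bundle of uniformly sampled channels sharing one clock:
time zero is the moment the loggers start recording, and the time of sample
``i`` of a channel is ``t0 + i / rate`` seconds.  Channels are stored on disk
in an inspectable CSV dialect — a ``# key: value`` header block (name,
rate_hz, units, t0_s) followed by one numeric sample per line — and a
deployment is a YAML manifest naming the animal, the electrode placement and
the per-channel files.

Missing data are not representable: loaders reject non-finite samples rather
than silently interpolating, because the downstream minute grid and the
handling-exclusion rule assume gap-free records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .exceptions import (
    ChannelFormatError,
    ChannelParseError,
    IncompleteDeploymentError,
    ValidationError,
)

__all__ = [
    "Channel",
    "DeploymentRecord",
    "RunConfig",
    "read_channel",
    "write_channel",
    "load_deployment",
    "save_deployment",
    "PLACEMENTS",
    "REQUIRED_CHANNELS",
]

#: Electrode placements on the plastron: A = humeral scute (the loggerhead
#: convention), B = gular scute, C = intergular scute (closest to the neck).
PLACEMENTS = ("A", "B", "C")

REQUIRED_CHANNELS = ("ecg", "accel_long")

_HEADER_KEYS = ("name", "rate_hz", "units", "t0_s")


@dataclass(eq=False)
class Channel:
    """One uniformly sampled signal.

    Parameters
    ----------
    name : str
        Channel label, e.g. ``"ecg"`` or ``"accel_long"``.
    values : ndarray
        Finite float samples in recording order.
    rate : float
        Sampling rate in samples per second; strictly positive.
    units : str
        Physical unit string (``mV``, ``m s^-2``, ``degC``, ``m``).
    t0 : float
        Offset in seconds of the first sample from the deployment clock
        origin (default 0, i.e. the channel starts with the record).
    """

    name: str
    values: np.ndarray
    rate: float
    units: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError(f"channel '{self.name}': values must be 1-D")
        if not (self.rate > 0) or not math.isfinite(self.rate):
            raise ValidationError(
                f"channel '{self.name}': rate must be a positive finite number, got {self.rate!r}"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValidationError(
                f"channel '{self.name}': non-finite sample at index {bad} "
                "(missing data are not representable)"
            )

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        """Span covered by the samples, ``n / rate`` seconds."""
        return self.n / self.rate

    def times(self) -> np.ndarray:
        """Sample times on the deployment clock: ``t0 + i / rate``."""
        return self.t0 + np.arange(self.n) / self.rate

    def __eq__(self, other) -> bool:
        if not isinstance(other, Channel):
            return NotImplemented
        return (
            self.name == other.name
            and self.rate == other.rate
            and self.units == other.units
            and self.t0 == other.t0
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Channel(name={self.name!r}, n={self.n}, rate={self.rate} Hz, "
            f"units={self.units!r}, t0={self.t0})"
        )


@dataclass
class DeploymentRecord:
    """A single animal's channel bundle plus metadata.

    ``channels`` must contain at least ``ecg`` and ``accel_long``; optional
    channels (``temperature``, ``depth``) ride along untouched.  All channels
    share the deployment clock origin (staggered starts are expressed through
    each channel's ``t0``).
    """

    turtle_id: str
    placement: str
    channels: dict[str, Channel]
    body_mass_kg: float | None = None
    scl_cm: float | None = None

    def __post_init__(self):
        if self.placement not in PLACEMENTS:
            raise ValidationError(
                f"unknown placement {self.placement!r}; expected one of {PLACEMENTS}"
            )
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise IncompleteDeploymentError(
                f"deployment {self.turtle_id!r} is missing required channel(s): {missing}"
            )
        for mname in ("body_mass_kg", "scl_cm"):
            v = getattr(self, mname)
            if v is not None and not v > 0:
                raise ValidationError(f"{mname} must be positive, got {v}")

    @property
    def ecg(self) -> Channel:
        return self.channels["ecg"]

    @property
    def accel(self) -> Channel:
        return self.channels["accel_long"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable analysis parameters, with the published defaults.

    The defaults encode the analysis protocol: a band-pass filter before
    R-wave detection, a 0.5 m s^-2 threshold on per-minute acceleration SD
    separating resting from moving, phases of at least 2 minutes, a 12-hour
    post-handling exclusion, and quality grades cut at 30% / 70% of windows
    with a detectable signal.  Detector and quality internals (threshold
    quantile, SNR floor, plausible-rate bounds) are implementation parameters
    exposed here so they are never applied silently.
    """

    # band-pass filter
    band_low_hz: float = 5.0
    band_high_hz: float = 30.0
    filter_order: int = 2
    # R-wave detector
    refractory_s: float = 1.0
    threshold_quantile: float = 0.999
    threshold_scale: float = 0.45
    detector_window_s: float = 60.0
    # signal-quality grading
    quality_window_s: float = 60.0
    quality_cuts: tuple[float, float] = (0.30, 0.70)
    snr_floor: float = 5.0
    rr_bounds_bpm: tuple[float, float] = (1.0, 60.0)
    # behavior classification
    behavior_threshold_ms2: float = 0.5
    min_phase_minutes: int = 2
    # handling exclusion
    handling_exclusion_h: float = 12.0
    # reproducibility
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValidationError(
                f"filter band must satisfy 0 < low < high, got "
                f"({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.filter_order < 1:
            raise ValidationError("filter_order must be >= 1")
        for name in ("refractory_s", "detector_window_s", "quality_window_s"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.threshold_quantile < 1):
            raise ValidationError("threshold_quantile must be in (0, 1)")
        if not (0 < self.threshold_scale <= 1):
            raise ValidationError("threshold_scale must be in (0, 1]")
        lo, hi = self.quality_cuts
        if not (0 < lo < hi < 1):
            raise ValidationError(
                f"quality cut points must be strictly increasing in (0,1), got {self.quality_cuts}"
            )
        if not self.behavior_threshold_ms2 > 0:
            raise ValidationError("behavior_threshold_ms2 must be positive")
        if self.min_phase_minutes < 1:
            raise ValidationError("min_phase_minutes must be >= 1")
        if self.handling_exclusion_h < 0:
            raise ValidationError("handling_exclusion_h must be >= 0")
        blo, bhi = self.rr_bounds_bpm
        if not (0 < blo < bhi):
            raise ValidationError("rr_bounds_bpm must satisfy 0 < low < high")

    def validate_against_rate(self, ecg_rate: float) -> None:
        """Check the filter band against the ECG channel's Nyquist limit."""
        if not self.band_high_hz < ecg_rate / 2:
            raise ValidationError(
                f"band high edge {self.band_high_hz} Hz must be below the ECG "
                f"Nyquist frequency {ecg_rate / 2} Hz"
            )

    def replace(self, **changes) -> "RunConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config file; every field is optional and defaults apply."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# channel CSV I/O
# ---------------------------------------------------------------------------

def write_channel(ch: Channel, path: str | Path, force: bool = False) -> None:
    """Write a channel to the plain-text CSV dialect.

    Values are printed with :func:`repr` so a read-back is bit-for-bit equal.
    Refuses to overwrite an existing file unless ``force`` is set.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(
            f"{path} exists; pass force=True to overwrite"
        )
    with open(path, "w") as fh:
        fh.write(f"# name: {ch.name}\n")
        fh.write(f"# rate_hz: {ch.rate!r}\n")
        fh.write(f"# units: {ch.units}\n")
        fh.write(f"# t0_s: {ch.t0!r}\n")
        fh.write("\n".join(repr(float(v)) for v in ch.values))
        if ch.n:
            fh.write("\n")


def read_channel(path: str | Path) -> Channel:
    """Read a channel file written by :func:`write_channel`.

    Raises
    ------
    ChannelFormatError
        Missing or duplicate header keys.
    ChannelParseError
        A non-numeric sample line (carries the 1-based line number).
    ValidationError
        Non-positive rate or non-finite samples.
    """
    path = Path(path)
    header: dict[str, str] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        body_start = i + 1
        stripped = line.lstrip("#").strip()
        if not stripped:
            continue
        if ":" not in stripped:
            raise ChannelFormatError(f"{path}: malformed header line {i + 1}: {line!r}")
        key, _, value = stripped.partition(":")
        key = key.strip()
        if key in header:
            raise ChannelFormatError(f"{path}: duplicate header key {key!r}")
        header[key] = value.strip()
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ChannelFormatError(f"{path}: missing header key(s): {missing}")

    try:
        rate = float(header["rate_hz"])
        t0 = float(header["t0_s"])
    except ValueError as exc:
        raise ChannelFormatError(f"{path}: non-numeric rate_hz/t0_s header") from exc

    raw: list[float] = []
    for offset, line in enumerate(lines[body_start:]):
        s = line.strip()
        if not s:
            continue
        try:
            raw.append(float(s))
        except ValueError:
            lineno = body_start + offset + 1
            raise ChannelParseError(
                f"{path}: non-numeric sample {s!r} at line {lineno}", line_number=lineno
            ) from None
    values = np.asarray(raw, dtype=np.float64)
    return Channel(name=header["name"], values=values, rate=rate, units=header["units"], t0=t0)


# ---------------------------------------------------------------------------
# deployment manifest I/O
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.yaml"


def load_deployment(dir_or_manifest: str | Path, cfg: RunConfig | None = None) -> DeploymentRecord:
    """Load a deployment from a manifest file or a directory containing one.

    The manifest maps channel names to file paths (relative paths are
    resolved against the manifest's directory) and carries turtle metadata.
    Sample values are never altered on load — no resampling, no unit
    conversion.  When ``cfg`` is given, its filter band is checked against
    the ECG rate up front so misconfiguration fails at load time.
    """
    p = Path(dir_or_manifest)
    manifest_path = p / MANIFEST_NAME if p.is_dir() else p
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    with open(manifest_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ChannelFormatError(f"{manifest_path}: manifest must be a mapping")
    chan_map = meta.get("channels")
    if not isinstance(chan_map, dict) or not chan_map:
        raise IncompleteDeploymentError(f"{manifest_path}: manifest lists no channels")
    base = manifest_path.parent
    channels = {
        name: read_channel(base / rel) for name, rel in sorted(chan_map.items())
    }
    record = DeploymentRecord(
        turtle_id=str(meta.get("turtle_id", "")),
        placement=meta.get("placement", ""),
        channels=channels,
        body_mass_kg=meta.get("body_mass_kg"),
        scl_cm=meta.get("scl_cm"),
    )
    if cfg is not None:
        cfg.validate_against_rate(record.ecg.rate)
    return record


def save_deployment(record: DeploymentRecord, out_dir: str | Path, force: bool = False) -> Path:
    """Write every channel as a CSV plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chan_map = {}
    for name, ch in sorted(record.channels.items()):
        fname = f"{name}.csv"
        write_channel(ch, out / fname, force=force)
        chan_map[name] = fname
    meta = {
        "turtle_id": record.turtle_id,
        "placement": record.placement,
        "body_mass_kg": record.body_mass_kg,
        "scl_cm": record.scl_cm,
        "channels": chan_map,
    }
    manifest_path = out / MANIFEST_NAME
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return manifest_path
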