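"""Synthetic deployments with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be tested without real recordings:

* behavior as an alternating-renewal process over whole minutes, with
  geometric dwell times in the resting and moving states — runs both shorter
  and longer than the 2-minute phase rule occur naturally;
* a cardiac event train whose RR intervals are drawn around ``60 / HR`` of
  the current state (resting 8.6 beats min^-1, moving 12.2 beats min^-1 by
  default) with a configurable coefficient of variation, each beat rendered
  as a biphasic (Mexican-hat) template of small amplitude — plastron-surface
  R waves are roughly one-tenth the size of conventional recordings;
* additive noise: white sensor noise, slow baseline wander, and band-limited
  EMG bursts confined to moving minutes, mimicking muscle-contraction
  artifacts during locomotion;
* longitudinal acceleration as flipper-stroke sinusoids in moving minutes
  over sensor noise, built so per-minute SD falls on the correct side of the
  0.5 m s^-2 classification threshold at default amplitudes (a full-minute
  sinusoid of amplitude A has SD A / sqrt(2)).

Every generator is deterministic under a fixed seed, and
:func:`generate_deployment` records the full parameter set and seed in the
returned :class:`GroundTruth`.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .channels import Channel, DeploymentRecord
from .exceptions import GenerationError, ValidationError

__all__ = [
    "RESTING",
    "MOVING",
    "BehaviorModel",
    "CardiacModel",
    "NoiseModel",
    "GroundTruth",
    "simulate_status_sequence",
    "simulate_rr_and_ecg",
    "simulate_accel",
    "generate_deployment",
    "write_ground_truth",
    "read_ground_truth",
]

RESTING = "resting"
MOVING = "moving"


@dataclass(frozen=True)
class BehaviorModel:
    """Two-state alternating-renewal behavior over whole minutes.

    Dwell times in each state are geometric with the given means (support
    >= 1 minute), so the long-run resting fraction is
    ``resting_dwell / (resting_dwell + moving_dwell)``.  An infinite dwell
    mean pins the process in that state for the whole record.
    """

    resting_dwell_min: float = 20.0
    moving_dwell_min: float = 10.0
    initial_state: str = RESTING
    duration_min: int = 60

    def __post_init__(self):
        for name in ("resting_dwell_min", "moving_dwell_min"):
            if not getattr(self, name) >= 1:
                raise ValidationError(f"{name} must be >= 1 minute")
        if self.initial_state not in (RESTING, MOVING):
            raise ValidationError(f"initial_state must be {RESTING!r} or {MOVING!r}")
        if not self.duration_min >= 1:
            raise ValidationError("duration_min must be >= 1")


@dataclass(frozen=True)
class CardiacModel:
    """Per-state heart rates and beat morphology.

    ``rr_cv`` is the coefficient of variation of RR intervals within a state;
    the beat template is a Mexican-hat pulse of total width
    ``template_width_s`` and peak height ``r_amplitude`` (relative units; the
    small default reflects surface-electrode attenuation).
    """

    resting_hr_bpm: float = 8.6
    moving_hr_bpm: float = 12.2
    rr_cv: float = 0.1
    template_width_s: float = 0.12
    r_amplitude: float = 0.05

    def __post_init__(self):
        if not (self.resting_hr_bpm > 0 and self.moving_hr_bpm > 0):
            raise ValidationError("heart rates must be positive")
        if self.rr_cv < 0:
            raise ValidationError("rr_cv must be >= 0")
        if not self.template_width_s > 0:
            raise ValidationError("template_width_s must be positive")
        shortest_mean_rr = 60.0 / max(self.resting_hr_bpm, self.moving_hr_bpm)
        if self.template_width_s >= shortest_mean_rr:
            raise GenerationError(
                "beat template wider than the shortest mean RR interval: "
                f"{self.template_width_s} s vs {shortest_mean_rr} s"
            )

    def hr_for(self, status: str) -> float:
        return self.resting_hr_bpm if status == RESTING else self.moving_hr_bpm


@dataclass(frozen=True)
class NoiseModel:
    """Additive ECG noise components.

    ``emg_sd`` scales band-limited (20-60 Hz) bursts with Poisson onsets that
    occur only inside moving minutes; white noise and baseline wander apply
    everywhere.  All amplitudes in the same relative units as the R wave.
    """

    white_sd: float = 0.004
    wander_amplitude: float = 0.02
    wander_freq_hz: float = 0.1
    emg_sd: float = 0.01
    emg_bursts_per_min: float = 3.0
    emg_burst_s: float = 2.0

    def __post_init__(self):
        for f in ("white_sd", "wander_amplitude", "wander_freq_hz",
                  "emg_sd", "emg_bursts_per_min", "emg_burst_s"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        """A noise-free model (all components zero)."""
        return cls(white_sd=0.0, wander_amplitude=0.0, emg_sd=0.0,
                   emg_bursts_per_min=0.0)


@dataclass
class GroundTruth:
    """What the generator actually produced: true R times (seconds on the
    deployment clock, strictly increasing), true per-minute statuses, the
    full parameter set and the seed."""

    r_times: np.ndarray
    statuses: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        self.r_times = np.asarray(self.r_times, dtype=np.float64)
        self.statuses = np.asarray(self.statuses)
        if self.r_times.size and not np.all(np.diff(self.r_times) > 0):
            raise ValidationError("ground-truth R times must be strictly increasing")

    def rate_for(self, status: str) -> float:
        """Empirical event rate (beats min^-1) over minutes in ``status``."""
        mask = self.statuses == status
        n_min = int(mask.sum())
        if n_min == 0:
            return math.nan
        minute_of = np.floor(self.r_times / 60.0).astype(int)
        valid = minute_of < len(self.statuses)
        count = int(np.count_nonzero(mask[minute_of[valid]]))
        return count / n_min


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_status_sequence(bm: BehaviorModel, seed=None) -> np.ndarray:
    """Draw per-minute statuses from the alternating-renewal model.

    Returns an array of length ``bm.duration_min`` with values ``"resting"``
    / ``"moving"``; reproducible under a fixed seed.
    """
    rng = _rng(seed)
    n = int(bm.duration_min)
    if n < 1:
        raise ValidationError("duration must be >= 1 minute")
    out: list[str] = []
    state = bm.initial_state
    means = {RESTING: bm.resting_dwell_min, MOVING: bm.moving_dwell_min}
    while len(out) < n:
        m = means[state]
        if math.isinf(m):
            dwell = n - len(out)
        else:
            dwell = int(rng.geometric(1.0 / m))  # support >= 1, mean m
        out.extend([state] * min(dwell, n - len(out)))
        state = MOVING if state == RESTING else RESTING
    return np.asarray(out)


def _beat_template(width_s: float, rate: float):
    """Mexican-hat beat shape evaluated on the sample grid.

    Returns ``(offsets, shape_fn)`` where ``shape_fn(dt)`` gives the unit-peak
    template value at time offset ``dt`` seconds from the R time.
    """
    sigma = width_s / 8.0  # +-4 sigma support inside the stated width

    def shape(dt: np.ndarray) -> np.ndarray:
        z = dt / sigma
        return (1.0 - z * z) * np.exp(-0.5 * z * z)

    half = int(round(width_s / 2 * rate))
    return half, sigma, shape


def simulate_rr_and_ecg(
    statuses: np.ndarray,
    cm: CardiacModel,
    nm: NoiseModel,
    rate: float = 250.0,
    seed=None,
) -> tuple[Channel, np.ndarray]:
    """Simulate the ECG channel and return it with the true R times.

    RR intervals are truncated-normal around ``60 / HR(status)`` with SD
    ``rr_cv`` times the mean, truncated below at the template width; the
    status of the minute containing each interval's *start* decides its rate.
    Each R wave is the beat template evaluated at exact sample-time offsets
    (so the rendered peak sits at the true event time, not a snapped sample).
    EMG bursts are clipped to the moving minute that spawned them.
    """
    statuses = np.asarray(statuses)
    if rate < 100:
        raise ValidationError("ECG rate must be >= 100 Hz to resolve the beat template")
    rr_rng, white_rng, emg_rng, phase_rng = _rng(seed).spawn(4)
    n_min = len(statuses)
    duration_s = n_min * 60.0
    n = int(round(duration_s * rate))

    # --- event train -------------------------------------------------------
    r_times: list[float] = []
    t = 0.0
    while True:
        minute = min(int(t // 60.0), n_min - 1)
        mean_rr = 60.0 / cm.hr_for(statuses[minute])
        if cm.rr_cv == 0:
            rr = mean_rr
        else:
            sd = cm.rr_cv * mean_rr
            rr = rr_rng.normal(mean_rr, sd)
            tries = 0
            while rr <= cm.template_width_s:  # truncate at template width
                rr = rr_rng.normal(mean_rr, sd)
                tries += 1
                if tries > 1000:
                    raise GenerationError(
                        "cannot draw an RR interval wider than the beat template; "
                        "parameters are implausible"
                    )
        t += rr
        if t >= duration_s:
            break
        r_times.append(t)
    r_arr = np.asarray(r_times)

    # --- render beats ------------------------------------------------------
    sig = np.zeros(n)
    half, _sigma, shape = _beat_template(cm.template_width_s, rate)
    for rt in r_times:
        c = int(round(rt * rate))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        idx = np.arange(lo, hi)
        sig[lo:hi] += cm.r_amplitude * shape(idx / rate - rt)

    # --- noise -------------------------------------------------------------
    if nm.white_sd > 0:
        sig += white_rng.normal(0.0, nm.white_sd, n)
    if nm.wander_amplitude > 0:
        tt = np.arange(n) / rate
        sig += nm.wander_amplitude * np.sin(
            2 * np.pi * nm.wander_freq_hz * tt + phase_rng.uniform(0, 2 * np.pi)
        )
    if nm.emg_sd > 0 and nm.emg_bursts_per_min > 0 and nm.emg_burst_s > 0:
        moving_minutes = np.flatnonzero(statuses == MOVING)
        if moving_minutes.size:
            mask = np.zeros(n, dtype=bool)
            spm = int(round(60 * rate))
            for m in moving_minutes:
                k = emg_rng.poisson(nm.emg_bursts_per_min)
                if k == 0:
                    continue
                onsets = emg_rng.uniform(0.0, 60.0, k)
                for onset in onsets:
                    lo = m * spm + int(onset * rate)
                    hi = min(lo + int(nm.emg_burst_s * rate), (m + 1) * spm)
                    mask[lo:hi] = True
            if mask.any():
                band = emg_rng.normal(0.0, 1.0, n)
                sos = butter(2, [20.0, min(60.0, 0.45 * rate)], btype="bandpass",
                             fs=rate, output="sos")
                band = sosfiltfilt(sos, band)
                band *= nm.emg_sd / band.std()
                sig[mask] += band[mask]

    return Channel(name="ecg", values=sig, rate=rate, units="mV"), r_arr


def simulate_accel(
    statuses: np.ndarray,
    stroke_freq_hz: float = 0.4,
    stroke_amplitude: float = 1.0,
    resting_noise_sd: float = 0.1,
    rate: float = 16.0,
    seed=None,
) -> Channel:
    """Simulate the longitudinal-acceleration channel.

    Moving minutes carry a flipper-stroke sinusoid of the given amplitude on
    top of sensor noise; resting minutes are noise only.  With the defaults
    the per-minute SD lands above 0.5 m s^-2 in moving minutes
    (sqrt(1/2 + noise^2) ~ 0.71) and below it in resting minutes (~0.1).
    """
    if stroke_amplitude < 0:
        raise ValidationError("stroke_amplitude must be >= 0")
    if resting_noise_sd < 0:
        raise ValidationError("resting_noise_sd must be >= 0")
    if not rate > 0:
        raise ValidationError("rate must be positive")
    statuses = np.asarray(statuses)
    rng = _rng(seed)
    n = int(round(len(statuses) * 60 * rate))
    tt = np.arange(n) / rate
    sig = rng.normal(0.0, resting_noise_sd, n) if resting_noise_sd > 0 else np.zeros(n)
    if stroke_amplitude > 0:
        minute_of = np.minimum((tt // 60.0).astype(int), len(statuses) - 1)
        moving = statuses[minute_of] == MOVING
        sig = sig + np.where(moving, stroke_amplitude * np.sin(2 * np.pi * stroke_freq_hz * tt), 0.0)
    return Channel(name="accel_long", values=sig, rate=rate, units="m s^-2")


def generate_deployment(
    bm: BehaviorModel | None = None,
    cm: CardiacModel | None = None,
    nm: NoiseModel | None = None,
    ecg_rate: float = 250.0,
    accel_rate: float = 16.0,
    stroke_freq_hz: float = 0.4,
    stroke_amplitude: float = 1.0,
    resting_noise_sd: float = 0.1,
    seed: int | None = None,
    turtle_id: str = "SIM001",
    placement: str = "C",
) -> tuple[DeploymentRecord, GroundTruth]:
    """Compose behavior, cardiac and acceleration generators into a full
    deployment (with 1 Hz temperature and depth channels riding along) and
    the matching ground truth."""
    bm = bm or BehaviorModel()
    cm = cm or CardiacModel()
    nm = nm if nm is not None else NoiseModel()
    ss_beh, ss_ecg, ss_acc, ss_env = np.random.SeedSequence(seed).spawn(4)
    statuses = simulate_status_sequence(bm, np.random.default_rng(ss_beh))
    ecg, r_times = simulate_rr_and_ecg(statuses, cm, nm, rate=ecg_rate,
                                       seed=np.random.default_rng(ss_ecg))
    accel = simulate_accel(statuses, stroke_freq_hz=stroke_freq_hz,
                           stroke_amplitude=stroke_amplitude,
                           resting_noise_sd=resting_noise_sd,
                           rate=accel_rate, seed=np.random.default_rng(ss_acc))
    env_rng = np.random.default_rng(ss_env)
    n_sec = int(bm.duration_min * 60)
    temperature = Channel("temperature", 23.4 + env_rng.normal(0, 0.05, n_sec),
                          rate=1.0, units="degC")
    depth = Channel("depth", np.abs(env_rng.normal(0.5, 0.1, n_sec)), rate=1.0, units="m")
    record = DeploymentRecord(
        turtle_id=turtle_id,
        placement=placement,
        channels={"ecg": ecg, "accel_long": accel,
                  "temperature": temperature, "depth": depth},
    )
    params = {
        "behavior": asdict(bm),
        "cardiac": asdict(cm),
        "noise": asdict(nm),
        "ecg_rate": ecg_rate,
        "accel_rate": accel_rate,
        "stroke_freq_hz": stroke_freq_hz,
        "stroke_amplitude": stroke_amplitude,
        "resting_noise_sd": resting_noise_sd,
    }
    truth = GroundTruth(r_times=r_times, statuses=statuses, params=params, seed=seed)
    return record, truth


def write_ground_truth(gt: GroundTruth, out_dir: str | Path, force: bool = False) -> None:
    """Write R times and minute statuses one per line, plus a YAML parameter
    record including the seed."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fname in ("r_times.txt", "statuses.txt", "truth_params.yaml"):
        if (out / fname).exists() and not force:
            raise FileExistsError(f"{out / fname} exists; pass force=True to overwrite")
    (out / "r_times.txt").write_text(
        "".join(f"{t!r}\n" for t in gt.r_times.tolist())
    )
    (out / "statuses.txt").write_text("".join(f"{s}\n" for s in gt.statuses))
    with open(out / "truth_params.yaml", "w") as fh:
        yaml.safe_dump({"seed": gt.seed, "params": gt.params}, fh, sort_keys=False)


def read_ground_truth(in_dir: str | Path) -> GroundTruth:
    import yaml

    p = Path(in_dir)
    r_times = np.array(
        [float(s) for s in (p / "r_times.txt").read_text().split()], dtype=np.float64
    )
    statuses = np.array((p / "statuses.txt").read_text().split())
    with open(p / "truth_params.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    return GroundTruth(r_times=r_times, statuses=statuses,
                       params=meta.get("params", {}), seed=meta.get("seed"))
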