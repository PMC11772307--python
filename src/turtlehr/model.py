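"""The fitting interface: a model object over a deployment, a results
object carrying estimates and diagnostics.

:class:`HeartRateModel` bundles a :class:`~turtlehr.channels.DeploymentRecord`
with a :class:`~turtlehr.channels.RunConfig`; :meth:`HeartRateModel.fit` runs
the analysis chain in its fixed order —

    band-pass filter -> R-wave detection -> quality grading ->
    per-minute acceleration SD -> resting/moving classification ->
    phase segmentation -> handling exclusion -> per-phase rates ->
    per-status grand means

— and returns a :class:`HeartRateResults` holding the estimates (per-status
grand-mean heart rates with SD and n), their diagnostics (signal-quality
grade, phase table, per-stage record counts) and the fully resolved
configuration, so no default is ever applied silently.  Simulation
(:meth:`HeartRateModel.from_simulation`) and plotting
(:meth:`HeartRateResults.plot_activity`, :meth:`HeartRateResults.plot_ecg`)
hang off these two objects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import MinuteSDSeries, Phase, classify_minutes, minute_sd, segment_phases
from .channels import Channel, DeploymentRecord, RunConfig, load_deployment
from .ecg import QualityAssessment, RWaveTrain, assess_quality, bandpass_filter, detect_r_waves
from .exceptions import StageError
from .heartrate import HeartRateSummary, PhaseHeartRate, exclude_handling, phase_heart_rate, summarize
from .simulate import BehaviorModel, CardiacModel, GroundTruth, NoiseModel, generate_deployment

__all__ = ["HeartRateModel", "HeartRateResults", "run_pipeline"]

logger = logging.getLogger("turtlehr")


class HeartRateModel:
    """Phase-conditioned heart-rate model for one deployment.

    Parameters
    ----------
    deployment : DeploymentRecord
        The animal's channel bundle (must contain ``ecg`` and ``accel_long``).
    config : RunConfig, optional
        Analysis parameters; defaults encode the standard protocol.
    ground_truth : GroundTruth, optional
        Attached automatically by :meth:`from_simulation`; lets diagnostics
        compare against the generator's true events and statuses.
    """

    def __init__(
        self,
        deployment: DeploymentRecord,
        config: RunConfig | None = None,
        ground_truth: GroundTruth | None = None,
    ):
        self.deployment = deployment
        self.config = config or RunConfig()
        self.ground_truth = ground_truth
        self.config.validate_against_rate(deployment.ecg.rate)

    @classmethod
    def from_manifest(cls, path, config: RunConfig | None = None) -> "HeartRateModel":
        """Build the model from a deployment manifest (or its directory)."""
        cfg = config or RunConfig()
        return cls(load_deployment(path, cfg), cfg)

    @classmethod
    def from_simulation(
        cls,
        behavior: BehaviorModel | None = None,
        cardiac: CardiacModel | None = None,
        noise: NoiseModel | None = None,
        seed: int | None = None,
        config: RunConfig | None = None,
        **gen_kwargs,
    ) -> "HeartRateModel":
        """Build the model on a freshly generated synthetic deployment; the
        generator's ground truth is kept on the model for diagnostics."""
        record, truth = generate_deployment(
            bm=behavior, cm=cardiac, nm=noise, seed=seed, **gen_kwargs
        )
        cfg = (config or RunConfig()).replace(seed=seed)
        return cls(record, cfg, ground_truth=truth)

    def fit(self) -> "HeartRateResults":
        """Run the full analysis chain and return the results object.

        Any stage failure is re-raised as :class:`StageError` naming the
        stage.  An "undetectable" quality grade does not abort the fit; the
        results are produced but flagged.
        """
        cfg = self.config
        dep = self.deployment
        counts: dict[str, int] = {"ecg_samples": dep.ecg.n, "accel_samples": dep.accel.n}

        def stage(name, fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, exc) from exc

        filtered = stage("bandpass_filter", bandpass_filter, dep.ecg,
                         cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order)
        train = stage("detect_r_waves", detect_r_waves, filtered,
                      refractory_s=cfg.refractory_s,
                      threshold_quantile=cfg.threshold_quantile,
                      window_s=cfg.detector_window_s,
                      threshold_scale=cfg.threshold_scale)
        counts["r_waves_detected"] = train.n
        quality = stage("assess_quality", assess_quality, filtered, train,
                        window_s=cfg.quality_window_s, snr_floor=cfg.snr_floor,
                        rr_bounds_bpm=cfg.rr_bounds_bpm, cuts=cfg.quality_cuts)
        sds = stage("minute_sd", minute_sd, dep.accel)
        counts["minutes_classified"] = sds.n
        statuses = stage("classify_minutes", classify_minutes, sds,
                         cfg.behavior_threshold_ms2)
        phases = stage("segment_phases", segment_phases, statuses,
                       cfg.min_phase_minutes)
        counts["phases_kept"] = len(phases)
        kept_train, kept_phases = stage("exclude_handling", exclude_handling,
                                        train, phases, cfg.handling_exclusion_h)
        counts["phases_after_exclusion"] = len(kept_phases)
        counts["r_waves_after_exclusion"] = kept_train.n
        phase_rates = [
            stage("phase_heart_rate", phase_heart_rate, kept_train, p, dep.turtle_id)
            for p in kept_phases
        ]
        summary = stage("summarize", summarize, phase_rates,
                        exclusion_hours=cfg.handling_exclusion_h)
        for k, v in counts.items():
            logger.info("stage counts: %s = %d", k, v)
        if quality.grade == "undetectable":
            logger.warning(
                "signal quality is 'undetectable' (fraction %.2f); heart-rate "
                "estimates are flagged unreliable", quality.fraction
            )
        return HeartRateResults(
            model=self,
            config=cfg,
            filtered_ecg=filtered,
            r_train=train,
            quality=quality,
            minute_sds=sds,
            statuses=statuses,
            phases=phases,
            kept_phases=kept_phases,
            kept_train=kept_train,
            phase_rates=phase_rates,
            hr_summary=summary,
            stage_counts=counts,
        )


@dataclass
class HeartRateResults:
    """Estimates and diagnostics from a fitted :class:`HeartRateModel`."""

    model: HeartRateModel
    config: RunConfig
    filtered_ecg: Channel
    r_train: RWaveTrain
    quality: QualityAssessment
    minute_sds: MinuteSDSeries
    statuses: np.ndarray
    phases: list[Phase]
    kept_phases: list[Phase]
    kept_train: RWaveTrain
    phase_rates: list[PhaseHeartRate]
    hr_summary: HeartRateSummary
    stage_counts: dict = field(default_factory=dict)
    version: str = __version__

    @property
    def flagged(self) -> bool:
        """True when the quality grade is 'undetectable': the estimates are
        produced but should not be trusted."""
        return self.quality.grade == "undetectable"

    def heart_rate(self, status: str) -> float:
        """Grand-mean heart rate (beats min^-1) for a status; NaN if no
        phase of that status survived."""
        st = self.hr_summary.stats.get(status)
        return st.mean_bpm if st is not None else math.nan

    def phase_table(self) -> pd.DataFrame:
        rows = [
            {
                "status": ph.phase.status,
                "start_min": ph.phase.start_min,
                "end_min": ph.phase.end_min,
                "duration_min": ph.phase.duration_min,
                "r_wave_count": ph.count,
                "heart_rate_bpm": ph.heart_rate_bpm,
            }
            for ph in self.phase_rates
        ]
        return pd.DataFrame(
            rows,
            columns=["status", "start_min", "end_min", "duration_min",
                     "r_wave_count", "heart_rate_bpm"],
        )

    def summary(self) -> str:
        """Human-readable report: provenance, quality, and the per-status
        grand means."""
        dep = self.model.deployment
        lines = [
            f"turtlehr {self.version} — phase-conditioned heart-rate analysis",
            f"turtle {dep.turtle_id!r}, electrode placement {dep.placement}, "
            f"ECG {dep.ecg.rate:g} Hz / accel {dep.accel.rate:g} Hz, "
            f"record {dep.ecg.duration_s / 3600:.1f} h",
            "",
            f"signal quality : {self.quality.grade} "
            f"({self.quality.fraction:.1%} of {self.quality.n_windows} windows detectable)"
            + ("   ** FLAGGED: heart rates unreliable **" if self.flagged else ""),
            f"R waves        : {self.r_train.n} detected, "
            f"{self.kept_train.n} after {self.config.handling_exclusion_h:g}-h exclusion",
            f"phases         : {len(self.phases)} segmented, "
            f"{len(self.kept_phases)} analyzable",
            "",
            f"{'status':<10}{'mean bpm':>10}{'sd':>8}{'n':>7}",
        ]
        for status, st in self.hr_summary.stats.items():
            sd = f"{st.sd_bpm:.1f}" if not math.isnan(st.sd_bpm) else "--"
            lines.append(f"{status:<10}{st.mean_bpm:>10.1f}{sd:>8}{st.n:>7}")
        if not self.hr_summary.stats:
            lines.append("(no analyzable phases)")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, out_dir, keep_intermediates: bool = False, force: bool = False) -> Path:
        """Write the result bundle as plain text: resolved config + summary
        (result.yaml), the phase table (TSV), R-wave times (one per line),
        and optionally the intermediate artifacts."""
        from .channels import write_channel

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def _target(name: str) -> Path:
            p = out / name
            if p.exists() and not force:
                raise FileExistsError(f"{p} exists; pass force=True to overwrite")
            return p

        result = {
            "tool": "turtlehr",
            "version": self.version,
            "turtle_id": self.model.deployment.turtle_id,
            "placement": self.model.deployment.placement,
            "config": self.config.to_dict(),
            "quality": {
                "fraction": self.quality.fraction,
                "grade": self.quality.grade,
                "n_windows": self.quality.n_windows,
            },
            "flagged": bool(self.flagged),
            "stage_counts": self.stage_counts,
            "summary": {
                s: {"mean_bpm": st.mean_bpm, "sd_bpm": st.sd_bpm, "n": st.n}
                for s, st in self.hr_summary.stats.items()
            },
        }
        with open(_target("result.yaml"), "w") as fh:
            yaml.safe_dump(result, fh, sort_keys=False)
        self.phase_table().to_csv(_target("phase_rates.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                {"status": p.status, "start_minute": p.start_min,
                 "end_minute": p.end_min, "duration_min": p.duration_min}
                for p in self.phases
            ],
            columns=["status", "start_minute", "end_minute", "duration_min"],
        ).to_csv(_target("phases.tsv"), sep="\t", index=False)
        _target("r_times.txt").write_text(
            "".join(f"{t!r}\n" for t in self.r_train.times.tolist())
        )
        if keep_intermediates:
            write_channel(self.filtered_ecg, _target("ecg_filtered.csv"), force=force)
            pd.DataFrame(
                {"minute": np.arange(self.minute_sds.n) + self.minute_sds.start_minute,
                 "sd_ms2": self.minute_sds.values,
                 "status": self.statuses}
            ).to_csv(_target("minute_sd.tsv"), sep="\t", index=False)
        return out

    # ------------------------------------------------------------------
    # plotting
    # ------------------------------------------------------------------
    def plot_activity(self, ax=None):
        """Minute-SD trace with the classification threshold and the kept
        phases shaded by status."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        m = np.arange(self.minute_sds.n) + self.minute_sds.start_minute
        ax.plot(m, self.minute_sds.values, lw=0.8, color="k")
        ax.axhline(self.config.behavior_threshold_ms2, color="r", ls="--",
                   label=f"threshold {self.config.behavior_threshold_ms2} m/s$^2$")
        for p in self.kept_phases:
            ax.axvspan(p.start_min, p.end_min, alpha=0.15,
                       color="tab:blue" if p.status == "resting" else "tab:orange")
        ax.set_xlabel("minute from record start")
        ax.set_ylabel("accel SD (m s$^{-2}$)")
        ax.legend(loc="upper right", fontsize=8)
        return ax

    def plot_ecg(self, start_s: float = 0.0, duration_s: float = 30.0, ax=None):
        """A stretch of filtered ECG with detected R waves marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        ch = self.filtered_ecg
        i0 = int(max(0, (start_s - ch.t0) * ch.rate))
        i1 = int(min(ch.n, i0 + duration_s * ch.rate))
        t = ch.t0 + np.arange(i0, i1) / ch.rate
        ax.plot(t, ch.values[i0:i1], lw=0.6, color="k")
        sel = (self.r_train.times >= t[0]) & (self.r_train.times <= t[-1]) if t.size else []
        for rt in self.r_train.times[sel] if t.size else []:
            ax.axvline(rt, color="r", alpha=0.5, lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(f"ECG ({ch.units})")
        return ax


def run_pipeline(
    manifest,
    config: RunConfig | None = None,
    out_dir=None,
    keep_intermediates: bool = False,
    force: bool = False,
) -> HeartRateResults:
    """Load a deployment, fit the model, optionally save the result bundle.

    Thin orchestration wrapper used by the command-line interface; identical
    inputs and configuration reproduce identical outputs (processing is
    fully deterministic)."""
    results = HeartRateModel.from_manifest(manifest, config).fit()
    if out_dir is not None:
        results.save(out_dir, keep_intermediates=keep_intermediates, force=force)
    return results
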