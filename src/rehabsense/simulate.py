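"""Synthetic cohort generator for all four sensor streams.

Generates motion, skin-conductance, activity and clinical-change data with
the statistical structure the analysis pipeline assumes, so that every
stage can be exercised and its parameter recovery tested without any real
recording:

* motion — each participant p has a latent daily mean velocity per sensor
  s, ``v(p, s, d) = v0(s) + beta(p) * d`` with a participant-level
  improvement slope ``beta(p) ~ Normal(mean, sd)`` shared across sensors.
  Task ("action") segments move around a scaled baseline
  ``ratio * v0(s) + beta(p) * d`` — faster task movement, same daily
  improvement — so the action-only trend fit recovers beta directly.
  Segment trajectories are random walks whose per-step displacement
  magnitude matches the segment's target mean speed (only speed statistics
  matter downstream, so no explicit kinematics);
* clinical — each participant's latent movement change
  ``m(p) = beta(p) * n_study_days`` is linearly mixed with independent
  noise to hit a target correlation (``clinical_link_strength``) between
  movement change and each endpoint change, with signs negative for the
  kinesiophobia and EQ-5D index changes and positive for the VAS change,
  then rounded to the endpoints' integer scales;
* EDA — slow tonic sinusoid plus sparse phasic pulses (Poisson arrivals,
  instant rise, exponential decay) plus white noise; the treatment arm can
  be given a higher pulse rate than the comparator arm;
* activity — daily steps as baseline plus an arm-specific weekly trend
  plus noise, truncated at zero.

Everything is deterministic under a fixed ``seed``; the four generators
draw from independent child streams of that seed, so each can be called on
its own and still reproduce.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .types import (
    ACTION,
    ARM_DTXP,
    ARM_SHAM,
    ARM_STANDARD_CARE,
    NO_ACTION_BETWEEN,
    NO_ACTION_END_OF_DAY,
    NO_ACTION_START_OF_DAY,
    ActivityDay,
    ClinicalChange,
    EdaSegment,
    EdaSeries,
    MotionSegment,
    ParticipantMotionSeries,
    SENSORS,
    SpecError,
)

#: Metadata tags emitted by the motion generator; the pipeline classifies
#: segments from these via its tag map.
ACTION_TAG = "task"
NO_ACTION_TAG = "idle"

_ENDPOINTS = (
    # (field, direction of link to movement improvement, scale, offset)
    ("tampa", -1.0, 4.0, -6.0),
    ("vas", +1.0, 25.0, 20.0),
    ("eq5d", -1.0, 2.5, -2.0),
)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults are a desk-scale version of the trial's treatment arm: 12
    participants over 30 VR study days, 10 task segments and 3 no-task
    segments per day, 60 s segments at 30 Hz motion / 4 Hz EDA sampling.
    """

    n_participants: int = 12
    n_sham: int = 17
    n_standard_care: int = 10
    n_study_days: int = 30
    action_segments_per_day: int = 10
    noaction_segments_per_day: int = 3
    segment_duration_s: float = 60.0
    sample_rate_motion: float = 30.0
    sensors: tuple[str, ...] = SENSORS
    baseline_velocity: dict[str, float] = field(
        default_factory=lambda: {"head": 0.10, "left": 0.20, "right": 0.22}
    )
    improvement_slope_mean: float = 0.003  # m/s per study day
    improvement_slope_sd: float = 0.001
    action_vs_noaction_velocity_ratio: float = 2.0
    segment_velocity_sd: float = 0.03  # m/s, segment-to-segment spread
    within_segment_speed_cv: float = 0.3  # per-step speed jitter; 0 = exact
    clinical_link_strength: float = 0.6  # target rho, movement vs endpoints
    # EDA stream
    sample_rate_eda: float = 4.0
    eda_days: int = 5
    eda_segments_per_day: int = 5
    eda_segment_duration_s: float = 60.0
    eda_pulse_rate: float = 3.0  # pulses/minute, treatment arm
    eda_pulse_rate_sham: float = 1.0
    eda_pulse_amplitude: float = 0.5  # microsiemens
    eda_pulse_tau: float = 2.0  # decay time constant, seconds
    eda_tonic_amplitude: float = 0.1
    eda_tonic_period_s: float = 60.0
    eda_baseline: float = 1.0
    eda_noise_sd: float = 0.02
    # activity stream
    steps_baseline: float = 5000.0
    weekly_step_trend: dict[str, float] = field(
        default_factory=lambda: {ARM_DTXP: 200.0, ARM_SHAM: 0.0, ARM_STANDARD_CARE: 0.0}
    )
    step_noise_sd: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise SpecError("n_participants must be >= 2")
        if self.action_segments_per_day < 1:
            raise SpecError("need at least one action segment per day")
        if self.n_study_days < 1 or self.eda_days < 1:
            raise SpecError("day counts must be positive")
        for name in (
            "segment_duration_s",
            "sample_rate_motion",
            "sample_rate_eda",
            "eda_segment_duration_s",
            "action_vs_noaction_velocity_ratio",
        ):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if abs(self.clinical_link_strength) > 1:
            raise SpecError("clinical_link_strength must lie in [-1, 1]")
        if not (1 <= self.eda_segments_per_day):
            raise SpecError("eda_segments_per_day must be >= 1")
        unknown = set(self.sensors) - set(SENSORS)
        if unknown or not self.sensors:
            raise SpecError(f"invalid sensor list {self.sensors}")
        for s in self.sensors:
            if s not in self.baseline_velocity:
                raise SpecError(f"no baseline velocity for sensor {s!r}")

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


def _streams(spec: CohortSpec) -> dict[str, np.random.Generator]:
    """Independent child generators per stream, all derived from the seed."""
    children = np.random.SeedSequence(spec.seed).spawn(5)
    names = ("slopes", "motion", "clinical", "eda", "activity")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _participant_slopes(spec: CohortSpec) -> np.ndarray:
    """Latent improvement slopes beta(p), shared across sensors."""
    rng = _streams(spec)["slopes"]
    return rng.normal(
        spec.improvement_slope_mean, spec.improvement_slope_sd, spec.n_participants
    )


def _day_layout(spec: CohortSpec) -> list[bool]:
    """Within-day segment order as is-action flags.

    One no-action segment opens and (if available) one closes the day; any
    remaining no-action segments sit between the first action segments.
    """
    n_a, n_n = spec.action_segments_per_day, spec.noaction_segments_per_day
    layout: list[bool] = []
    if n_n >= 1:
        layout.append(False)
    n_between = max(n_n - 2, 0)
    for i in range(n_a):
        layout.append(True)
        if i < n_between:
            layout.append(False)
    if n_n >= 2:
        layout.append(False)
    return layout


def simulate_motion(spec: CohortSpec) -> list[ParticipantMotionSeries]:
    """Generate per-participant motion segment series.

    Each segment's samples form a random walk: per-step displacement is
    ``speed * dt`` in a uniformly random 3-D direction, with per-step speed
    equal to the segment target mean times a unit-mean gamma jitter (exact
    when ``within_segment_speed_cv`` is 0), so the segment's arithmetic
    mean point speed is an unbiased draw around its target.
    """
    spec.validate()
    betas = _participant_slopes(spec)
    rng = _streams(spec)["motion"]
    n = max(int(round(spec.segment_duration_s * spec.sample_rate_motion)), 2)
    dt = 1.0 / spec.sample_rate_motion
    layout = _day_layout(spec)
    cv = spec.within_segment_speed_cv
    out = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:03d}"
        beta = float(betas[p])
        segments: list[MotionSegment] = []
        for sensor in spec.sensors:
            v0 = spec.baseline_velocity[sensor]
            n_seg_day = len(layout)
            n_seg = spec.n_study_days * n_seg_day
            # per-segment target mean speeds, vectorized over the series
            days = np.repeat(np.arange(1, spec.n_study_days + 1), n_seg_day)
            is_action = np.tile(np.array(layout, dtype=bool), spec.n_study_days)
            base = np.where(
                is_action, spec.action_vs_noaction_velocity_ratio * v0, v0
            ) + beta * days
            if spec.segment_velocity_sd > 0:
                base = base + rng.normal(0, spec.segment_velocity_sd, n_seg)
            targets = np.maximum(base, 5e-3)
            # per-step speeds (n_seg, n-1)
            if cv > 0:
                shape = 1.0 / cv**2
                jitter = rng.gamma(shape, 1.0 / shape, size=(n_seg, n - 1))
            else:
                jitter = np.ones((n_seg, n - 1))
            speeds = targets[:, None] * jitter
            # random 3-D unit directions
            dirs = rng.normal(size=(n_seg, n - 1, 3))
            dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
            steps = dirs * (speeds * dt)[:, :, None]
            starts = rng.uniform(-1.0, 1.0, size=(n_seg, 1, 3))
            xyz = np.concatenate(
                [starts, starts + np.cumsum(steps, axis=1)], axis=1
            )
            t0 = np.arange(n_seg).reshape(-1, 1) * (spec.segment_duration_s + 1.0)
            t = t0 + np.arange(n) * dt
            for i in range(n_seg):
                # sequence-numbered tags, as a VR program log would emit;
                # the numbering also keeps adjacent same-kind segments
                # separable in a flat record stream
                base = ACTION_TAG if is_action[i] else NO_ACTION_TAG
                segments.append(
                    MotionSegment(
                        segment_id=f"{pid}-{sensor}-{i + 1}",
                        sensor=sensor,
                        tag=f"{base}:{i % n_seg_day + 1}",
                        study_day=int(days[i]),
                        t=t[i],
                        xyz=xyz[i],
                    )
                )
        out.append(
            ParticipantMotionSeries(
                participant_id=pid,
                arm=ARM_DTXP,
                segments=segments,
                true_slopes={s: beta for s in spec.sensors},
            )
        )
    return out


def latent_movement_changes(
    spec: CohortSpec, motion: list[ParticipantMotionSeries]
) -> np.ndarray:
    """True movement change m(p) = beta(p) * study days, per participant."""
    out = []
    for series in motion:
        if not series.true_slopes:
            raise SpecError(
                f"series {series.participant_id} carries no true slopes; "
                "simulate_clinical needs simulator-generated motion"
            )
        beta = next(iter(series.true_slopes.values()))
        out.append(beta * spec.n_study_days)
    return np.asarray(out)


def simulate_clinical(
    spec: CohortSpec,
    motion: list[ParticipantMotionSeries],
    round_to_int: bool = True,
) -> list[ClinicalChange]:
    """Map latent movement changes to correlated clinical endpoint changes.

    The standardized latent change z(p) is mixed with independent standard
    normal noise as ``rho * z + sqrt(1 - rho^2) * eps`` (rho =
    ``clinical_link_strength``), scaled and signed per endpoint, so the
    population correlation between movement change and each endpoint change
    equals rho up to integer rounding.
    """
    spec.validate()
    if len(motion) != spec.n_participants:
        raise SpecError(
            f"motion has {len(motion)} participants, spec says {spec.n_participants}"
        )
    rng = _streams(spec)["clinical"]
    m = latent_movement_changes(spec, motion)
    sd = float(np.std(m))
    z = (m - m.mean()) / sd if sd > 0 else np.zeros_like(m)
    rho = spec.clinical_link_strength
    out = []
    values = {}
    for key, sign, scale, offset in _ENDPOINTS:
        eps = rng.standard_normal(len(m))
        a = offset + sign * scale * (rho * z + np.sqrt(1.0 - rho**2) * eps)
        if round_to_int:
            a = np.round(a)
        values[key] = a
    lim = {"tampa": 68.0, "vas": 100.0, "eq5d": np.inf}
    for i, series in enumerate(motion):
        out.append(
            ClinicalChange(
                participant_id=series.participant_id,
                tampa_chg=float(np.clip(values["tampa"][i], -lim["tampa"], lim["tampa"])),
                vas_chg=float(np.clip(values["vas"][i], -lim["vas"], lim["vas"])),
                eq5d_chg=float(values["eq5d"][i]),
            )
        )
    return out


def _eda_day_labels(n: int) -> list[str | None]:
    """Action-class labels for one treatment-arm day of n EDA segments."""
    if n == 1:
        return [ACTION]
    labels: list[str | None] = [NO_ACTION_START_OF_DAY]
    for i in range(n - 2):
        labels.append(ACTION if i % 2 == 0 else NO_ACTION_BETWEEN)
    labels.append(NO_ACTION_END_OF_DAY)
    return labels


def simulate_eda(spec: CohortSpec) -> list[EdaSeries]:
    """Generate skin-conductance series for treatment and comparator arms.

    Per segment: tonic sinusoid around a baseline level, Poisson-arriving
    phasic pulses with instant rise and exponential decay, white noise.
    Treatment-arm segments carry context labels (the start-of-day filter
    needs them); comparator-arm segments are unlabeled no-action data.
    """
    spec.validate()
    rng = _streams(spec)["eda"]
    n = max(int(round(spec.eda_segment_duration_s * spec.sample_rate_eda)), 2)
    t = np.arange(n) / spec.sample_rate_eda
    duration = float(t[-1])
    out = []
    cohorts = [
        (ARM_DTXP, spec.n_participants, "P", spec.eda_pulse_rate),
        (ARM_SHAM, spec.n_sham, "S", spec.eda_pulse_rate_sham),
    ]
    labels = _eda_day_labels(spec.eda_segments_per_day)
    for arm, n_part, prefix, rate in cohorts:
        for p in range(n_part):
            pid = f"{prefix}{p + 1:03d}"
            segments = []
            for day in range(1, spec.eda_days + 1):
                for j in range(spec.eda_segments_per_day):
                    phase = rng.uniform(0, 2 * np.pi)
                    signal = spec.eda_baseline + spec.eda_tonic_amplitude * np.sin(
                        2 * np.pi * t / spec.eda_tonic_period_s + phase
                    )
                    n_pulses = rng.poisson(rate * duration / 60.0)
                    for t0 in rng.uniform(0, duration, n_pulses):
                        amp = spec.eda_pulse_amplitude * rng.uniform(0.8, 1.2)
                        mask = t >= t0
                        signal = signal + np.where(
                            mask, amp * np.exp(-(t - t0) / spec.eda_pulse_tau), 0.0
                        )
                    if spec.eda_noise_sd > 0:
                        signal = signal + rng.normal(0, spec.eda_noise_sd, n)
                    segments.append(
                        EdaSegment(
                            segment_id=f"{pid}-e{day}-{j + 1}",
                            study_day=day,
                            t=t.copy(),
                            values=signal,
                            action_class=labels[j] if arm == ARM_DTXP else None,
                        )
                    )
            out.append(EdaSeries(pid, arm, segments))
    return out


def simulate_activity(spec: CohortSpec) -> list[ActivityDay]:
    """Generate daily step/heart-rate/sleep aggregates for all three arms.

    Steps follow ``baseline + weekly_trend/7 * (day - 1) + noise``,
    truncated at zero and rounded to integer counts.
    """
    spec.validate()
    rng = _streams(spec)["activity"]
    out = []
    cohorts = [
        (ARM_DTXP, spec.n_participants, "P"),
        (ARM_SHAM, spec.n_sham, "S"),
        (ARM_STANDARD_CARE, spec.n_standard_care, "C"),
    ]
    for arm, n_part, prefix in cohorts:
        daily_trend = spec.weekly_step_trend.get(arm, 0.0) / 7.0
        for p in range(n_part):
            pid = f"{prefix}{p + 1:03d}"
            days = np.arange(1, spec.n_study_days + 1)
            steps = spec.steps_baseline + daily_trend * (days - 1)
            if spec.step_noise_sd > 0:
                steps = steps + rng.normal(0, spec.step_noise_sd, len(days))
            steps = np.maximum(np.round(steps), 0).astype(int)
            hr = np.round(rng.normal(75, 5, len(days)), 1)
            sleep = np.round(np.maximum(rng.normal(440, 60, len(days)), 0), 0)
            for d, s, h, sl in zip(days, steps, hr, sleep):
                out.append(
                    ActivityDay(
                        participant_id=pid,
                        arm=arm,
                        study_day=int(d),
                        steps=int(s),
                        heart_rate_mean=float(h),
                        sleep_minutes=float(sl),
                    )
                )
    return out
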