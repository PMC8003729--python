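"""Synthetic rewarming cohorts for primary Raynaud's phenomenon.

The generator emulates a standardized cold-challenge protocol: after a
pre-cooling baseline recording, both hands are immersed in 10 °C water for
60 s and then left to passively rewarm under an infrared camera, recording
until the fingers approach their pre-cooling temperature or 60 minutes have
elapsed. Each of the eight ulnar fingers yields one rewarming curve.

Two curve morphologies are produced, matching what is seen clinically:

* **S-shaped** — a logistic rise from the post-cooling temperature ``t_0``
  toward a plateau ``t_end``, with steepness ``rate`` (1/min) and half-rise
  time ``midpoint`` (min after the end of cooling);
* **horizontal** — essentially flat traces with a small residual linear
  drift, typical of patients whose fingers fail to rewarm.

Group-level defaults encode the clinical picture: patients have colder
baselines, longer times to plateau, incomplete recovery, and a much higher
share of horizontal curves than healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .series import FINGERS, HANDS, EllipseROI, ROIError, TemperatureSeries

S_SHAPED = "S_shaped"
HORIZONTAL = "horizontal"


class ProfileError(ValueError):
    """A curve profile violates one of its invariants."""


@dataclass(frozen=True)
class CurveProfile:
    """Generating parameters for a single finger's rewarming curve.

    Temperatures in °C, times in minutes. For S-shaped curves the rewarming
    segment follows ``t_0 + (t_end - t_0) * logistic(rate * (tau - midpoint))``
    with ``tau`` minutes after the end of cooling; horizontal curves follow
    ``t_0 + drift * tau``.
    """

    t_base: float
    t_0: float
    t_end: float
    rate: float = 1.0
    midpoint: float = 5.0
    curve_type: str = S_SHAPED
    drift: float = 0.02  # °C/min residual slope of horizontal curves
    noise_sd: float = 0.0
    sampling_interval: float = 0.1
    max_duration: float = 60.0
    baseline_duration: float = 1.0
    cooling_duration: float = 1.0
    stop_epsilon: float = 0.5  # "approached pre-cooling temperature"
    t_end_tolerance: float = 0.5

    def validate(self) -> None:
        if self.curve_type not in (S_SHAPED, HORIZONTAL):
            raise ProfileError(f"unknown curve_type {self.curve_type!r}")
        if not self.t_0 < self.t_base:
            raise ProfileError("invariant violated: t_0 < t_base")
        if not (self.t_0 <= self.t_end <= self.t_base + self.t_end_tolerance):
            raise ProfileError("invariant violated: t_0 <= t_end <= t_base + tolerance")
        if self.curve_type == S_SHAPED and not self.rate > 0:
            raise ProfileError("invariant violated: rate > 0 for S-shaped curves")
        if self.noise_sd < 0:
            raise ProfileError("invariant violated: noise_sd >= 0")
        if not self.max_duration > 0:
            raise ProfileError("invariant violated: max_duration > 0")
        if not self.sampling_interval > 0:
            raise ProfileError("invariant violated: sampling_interval > 0")


def generate_rewarming_curve(profile: CurveProfile, seed: int) -> TemperatureSeries:
    """Simulate one finger's recording: baseline, cooling drop, rewarming.

    The trace covers a baseline window at ``t_base``, a linear drop to ``t_0``
    during the cold challenge, and the rewarming phase, truncated when the
    noiseless curve comes within ``stop_epsilon`` of ``t_base`` or at
    ``max_duration``. Gaussian noise of SD ``noise_sd`` is added after the
    stopping rule is applied, so truncation is deterministic in the profile.
    """
    profile.validate()
    dt = profile.sampling_interval
    b, c = profile.baseline_duration, profile.cooling_duration
    t_total = b + c + profile.max_duration
    times = np.arange(0.0, t_total + dt / 2, dt)
    temps = np.empty_like(times)

    base_m = times < b
    cool_m = (times >= b) & (times < b + c)
    rew_m = times >= b + c
    temps[base_m] = profile.t_base
    temps[cool_m] = profile.t_base + (profile.t_0 - profile.t_base) * (
        (times[cool_m] - b) / c
    )
    tau = times[rew_m] - (b + c)
    if profile.curve_type == S_SHAPED:
        rise = profile.t_end - profile.t_0
        temps[rew_m] = profile.t_0 + rise * expit(profile.rate * (tau - profile.midpoint))
    else:
        temps[rew_m] = profile.t_0 + profile.drift * tau

    # stopping rule on the noiseless rewarming segment
    rew_idx = np.flatnonzero(rew_m)
    reached = temps[rew_idx] >= profile.t_base - profile.stop_epsilon
    if reached.any():
        stop = rew_idx[np.argmax(reached)]
        times = times[: stop + 1]
        temps = temps[: stop + 1]

    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        temps = temps + rng.normal(0.0, profile.noise_sd, size=temps.size)

    return TemperatureSeries(
        times=times,
        temps=temps,
        baseline_window=(0.0, b),
        cooling_end=b + c,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Population distribution of curve parameters for one diagnostic group.

    ``t_0`` is drawn as ``t_base - cooling_drop`` and ``t_end`` as
    ``t_base - recovery_deficit`` (clipped above ``t_0``), so the invariants
    ``t_0 < t_base`` and ``t_0 <= t_end <= t_base`` hold by construction.
    Finger-level values jitter around subject-level draws, which induces the
    within-subject clustering seen in real hands.
    """

    t_base_mean: float
    t_base_sd: float
    cooling_drop_mean: float
    cooling_drop_sd: float
    recovery_deficit_mean: float
    recovery_deficit_sd: float
    midpoint_mean: float
    midpoint_sd: float
    log_rate_mean: float
    log_rate_sd: float
    p_horizontal: float
    finger_sd: float = 0.3  # °C jitter of t_base/t_0/t_end across fingers
    midpoint_finger_sd: float = 0.15  # lognormal jitter of midpoint across fingers

    def validate(self) -> None:
        if not 0.0 <= self.p_horizontal <= 1.0:
            raise ProfileError("p_horizontal must be in [0, 1]")
        for name in (
            "t_base_sd",
            "cooling_drop_sd",
            "recovery_deficit_sd",
            "midpoint_sd",
            "log_rate_sd",
            "finger_sd",
            "midpoint_finger_sd",
        ):
            if getattr(self, name) < 0:
                raise ProfileError(f"{name} must be >= 0")


#: Healthy controls: warm baseline, fast near-complete recovery, rare flat curves.
CONTROL_PARAMS = GroupParams(
    t_base_mean=31.5,
    t_base_sd=1.2,
    cooling_drop_mean=10.0,
    cooling_drop_sd=1.0,
    recovery_deficit_mean=0.8,
    recovery_deficit_sd=0.5,
    midpoint_mean=4.5,
    midpoint_sd=2.0,
    log_rate_mean=0.0,  # median rate 1.0 /min
    log_rate_sd=0.3,
    p_horizontal=0.05,
)

#: Patients: colder baseline, slow incomplete recovery, frequent flat curves.
#: Effects sized for substantial between-group overlap, as seen clinically.
PATIENT_PARAMS = GroupParams(
    t_base_mean=30.2,
    t_base_sd=1.4,
    cooling_drop_mean=9.0,
    cooling_drop_sd=1.0,
    recovery_deficit_mean=2.2,
    recovery_deficit_sd=1.4,
    midpoint_mean=12.0,
    midpoint_sd=6.0,
    log_rate_mean=-0.4,  # median rate ~0.7 /min
    log_rate_sd=0.3,
    p_horizontal=0.30,
)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort (group sizes and distributions)."""

    n_patients: int = 22
    n_controls: int = 57
    patients: GroupParams = field(default_factory=lambda: PATIENT_PARAMS)
    controls: GroupParams = field(default_factory=lambda: CONTROL_PARAMS)
    fingers_per_subject: int = 8  # 4 ulnar fingers per hand
    seed: int = 0
    noise_sd: float = 0.1
    sampling_interval: float = 0.1
    max_duration: float = 60.0
    age_mean: float = 57.0
    age_sd: float = 11.0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ProfileError("group sizes must be >= 1")
        if self.fingers_per_subject < 1 or self.fingers_per_subject > 8:
            raise ProfileError("fingers_per_subject must be in 1..8")
        if self.noise_sd < 0:
            raise ProfileError("noise_sd must be >= 0")
        self.patients.validate()
        self.controls.validate()


@dataclass(frozen=True)
class SubjectData:
    """One simulated subject: metadata plus per-finger series."""

    subject_id: str
    diagnosis: int  # 1 = Raynaud's phenomenon, 0 = healthy control
    age: float
    series: dict  # {(hand, finger): TemperatureSeries}


def _finger_labels(n: int) -> list[tuple[str, int]]:
    labels = [(h, f) for h in HANDS for f in FINGERS]
    return labels[:n]


def _subject_profiles(
    group: GroupParams, spec: CohortSpec, rng: np.random.Generator
) -> list[CurveProfile]:
    """Draw subject-level parameters, then per-finger profiles around them."""
    t_base = rng.normal(group.t_base_mean, group.t_base_sd)
    drop = max(rng.normal(group.cooling_drop_mean, group.cooling_drop_sd), 3.0)
    deficit = max(rng.normal(group.recovery_deficit_mean, group.recovery_deficit_sd), 0.0)
    midpoint = max(rng.normal(group.midpoint_mean, group.midpoint_sd), 1.0)
    rate = float(np.exp(rng.normal(group.log_rate_mean, group.log_rate_sd)))
    horizontal = rng.random() < group.p_horizontal

    profiles = []
    for _ in range(spec.fingers_per_subject):
        fb = t_base + rng.normal(0.0, group.finger_sd)
        f0 = fb - max(drop + rng.normal(0.0, group.finger_sd), 2.0)
        fe = fb - max(deficit + rng.normal(0.0, group.finger_sd), 0.0)
        fe = min(max(fe, f0 + 0.1), fb)
        fm = midpoint * float(np.exp(rng.normal(0.0, group.midpoint_finger_sd)))
        profiles.append(
            CurveProfile(
                t_base=fb,
                t_0=f0,
                t_end=fe,
                rate=rate,
                midpoint=fm,
                curve_type=HORIZONTAL if horizontal else S_SHAPED,
                noise_sd=spec.noise_sd,
                sampling_interval=spec.sampling_interval,
                max_duration=spec.max_duration,
            )
        )
    return profiles


def generate_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Simulate ``n_patients + n_controls`` subjects with per-finger series.

    Deterministic in ``spec.seed``: per-subject random streams are spawned
    from a single seed sequence, so the output is bit-identical across runs.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    groups = [(1, spec.n_patients, spec.patients), (0, spec.n_controls, spec.controls)]
    n_total = spec.n_patients + spec.n_controls
    children = ss.spawn(n_total)
    subjects = []
    i = 0
    for diagnosis, n, params in groups:
        prefix = "P" if diagnosis else "C"
        for k in range(n):
            rng = np.random.default_rng(children[i])
            i += 1
            age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.0, 90.0))
            profiles = _subject_profiles(params, spec, rng)
            series = {}
            for label, prof in zip(_finger_labels(spec.fingers_per_subject), profiles):
                curve_seed = int(rng.integers(0, 2**31 - 1))
                s = generate_rewarming_curve(prof, curve_seed)
                sid = f"{prefix}{k + 1:03d}"
                series[label] = replace(s, label=(sid, label[0], label[1]))
            subjects.append(
                SubjectData(
                    subject_id=f"{prefix}{k + 1:03d}",
                    diagnosis=diagnosis,
                    age=age,
                    series=series,
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# Frame-stack rendering
# ---------------------------------------------------------------------------


def default_roi_layout(
    n: int, shape: tuple[int, int] = (48, 160), labels: Sequence[tuple] | None = None
) -> list[EllipseROI]:
    """Lay out ``n`` non-overlapping ellipses in a row across the frame."""
    ny, nx = shape
    labels = list(labels) if labels is not None else _finger_labels(n)
    step = nx / n
    a = min(step * 0.3, 12.0)
    b = min(ny * 0.3, 12.0)
    return [
        EllipseROI(
            center_x=step * (i + 0.5),
            center_y=ny / 2,
            semi_axis_x=a,
            semi_axis_y=b,
            label=labels[i],
        )
        for i in range(n)
    ]


def generate_frame_stack(
    series: Sequence[TemperatureSeries],
    rois: Sequence[EllipseROI] | None = None,
    *,
    shape: tuple[int, int] = (48, 160),
    background: float = 23.0,
    render_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[EllipseROI]]:
    """Render per-finger series into a thermal frame stack.

    Every frame is a temperature image with one elliptical blob per finger
    whose interior pixels equal that finger's series value at the frame time
    (plus optional rendering noise); the background sits at room temperature.
    Returns ``(stack, timestamps, rois)``.
    """
    if not series:
        raise ValueError("no series to render")
    times0 = series[0].times
    for s in series[1:]:
        if s.times.shape != times0.shape or not np.allclose(s.times, times0):
            raise ValueError("all series must share a common time grid")
    if rois is None:
        rois = default_roi_layout(
            len(series), shape, labels=[s.label[1:] if s.label else None for s in series]
        ) if all(s.label for s in series) else default_roi_layout(len(series), shape)
    if len(rois) != len(series):
        raise ValueError("need exactly one ROI per series")

    masks = [r.mask(shape) for r in rois]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                raise ROIError(
                    f"ROIs {rois[i].label} and {rois[j].label} overlap"
                )

    n_frames = times0.size
    stack = np.full((n_frames, *shape), background, dtype=float)
    for s, mask in zip(series, masks):
        stack[:, mask] = s.temps[:, None]
    if render_noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, render_noise_sd, size=stack.shape)
    return stack, times0.copy(), list(rois)
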