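"""Synthetic cohorts of chemotherapy patients with pendant-sensor activity streams.

The generator emulates a 14-day remote-monitoring window that starts on the
first day of a bi-weekly chemotherapy cycle.  Each subject carries a latent
functional-capacity trajectory: capacity dips to a nadir around day 2-3,
resilient subjects recover to baseline by about day 6, non-resilient subjects
plateau below baseline and may drift further down late in the cycle.  Daily
activity (posture bouts, steps, postural transitions) is drawn from a
semi-Markov bout process whose volume parameters scale with capacity.

States are encoded as small integers (``LYING``, ``SITTING``, ``STANDING``,
``WALKING``).  Activity days are stored run-length encoded; the dense
86 400-element per-second label vector is materialised on demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LYING",
    "SITTING",
    "STANDING",
    "WALKING",
    "STATE_NAMES",
    "SECONDS_PER_DAY",
    "ConfigurationError",
    "TrajectoryParams",
    "RESILIENT_DEFAULT",
    "NONRESILIENT_DEFAULT",
    "CohortConfig",
    "SubjectProfile",
    "ActivityDay",
    "RawAccelDay",
    "capacity",
    "synth_activity_day",
    "generate_cohort",
    "synth_raw_accel",
]

LYING, SITTING, STANDING, WALKING = 0, 1, 2, 3
STATE_NAMES = {LYING: "lying", SITTING: "sitting", STANDING: "standing", WALKING: "walking"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}
SECONDS_PER_DAY = 86_400
ACCEL_HZ = 50


class ConfigurationError(ValueError):
    """Invalid configuration; ``field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# latent capacity trajectory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryParams:
    """Piecewise-linear functional-capacity trajectory over the monitoring window.

    Capacity is a dimensionless multiplier of the subject's pre-chemotherapy
    activity level: 1.0 on day 1 (baseline), linear descent to
    ``1 - nadir_depth`` on ``nadir_day``, linear recovery to ``plateau_level``
    on ``recovery_day``, then linear drift at ``late_slope`` per day.
    """

    nadir_day: float = 3.0
    nadir_depth: float = 0.3
    recovery_day: float = 6.0
    plateau_level: float = 1.0
    late_slope: float = 0.0

    def validate(self, n_days: int | None = None) -> None:
        if not 0 <= self.nadir_depth < 1:
            raise ConfigurationError("nadir_depth", "must be in [0, 1)")
        if self.plateau_level <= 0:
            raise ConfigurationError("plateau_level", "must be > 0")
        if self.nadir_day < 1:
            raise ConfigurationError("nadir_day", "must be >= 1")
        if self.recovery_day < self.nadir_day:
            raise ConfigurationError("recovery_day", "must be >= nadir_day")
        if n_days is not None and self.nadir_day > n_days:
            raise ConfigurationError("nadir_day", f"must be <= n_days ({n_days})")


#: Defaults reproduce the qualitative two-group contrast: resilient subjects
#: recover fully by day 6; non-resilient subjects plateau at 70% of baseline
#: and deteriorate slowly afterwards.
RESILIENT_DEFAULT = TrajectoryParams(3.0, 0.3, 6.0, 1.0, 0.0)
NONRESILIENT_DEFAULT = TrajectoryParams(3.0, 0.4, 6.0, 0.7, -0.01)


def capacity(day: float, params: TrajectoryParams, n_days: int | None = None) -> float:
    """Functional-capacity multiplier for a (1-based) monitoring day.

    Piecewise linear: baseline 1.0 on day 1, nadir ``1 - nadir_depth`` on
    ``nadir_day``, recovery to ``plateau_level`` on ``recovery_day``, then
    drift at ``late_slope`` per day.  Output is floored at a small positive
    value so downstream volume parameters stay valid.
    """
    if day < 1 or (n_days is not None and day > n_days):
        raise ValueError(f"day {day} outside monitoring window")
    params.validate()
    nadir_val = 1.0 - params.nadir_depth
    if day <= params.nadir_day:
        if params.nadir_day <= 1:
            out = 1.0 if day <= 1 else nadir_val
        else:
            out = 1.0 + (nadir_val - 1.0) * (day - 1.0) / (params.nadir_day - 1.0)
    elif day <= params.recovery_day:
        span = params.recovery_day - params.nadir_day
        frac = 1.0 if span == 0 else (day - params.nadir_day) / span
        out = nadir_val + (params.plateau_level - nadir_val) * frac
    else:
        out = params.plateau_level + params.late_slope * (day - params.recovery_day)
    return max(out, 0.05)


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

_TABLE_ECOG_RESILIENT = (0.571, 0.357, 0.072)
_TABLE_ECOG_NONRESILIENT = (0.167, 0.500, 0.333)

# ECOG-graded activity baselines: expected daily steps, walking cadence
# (steps/min), and sit<->stand cycles per day for an unimpaired day (capacity 1).
_BASE_STEPS = {0: 6500.0, 1: 4200.0, 2: 2800.0}
_BASE_CADENCE = {0: 95.0, 1: 85.0, 2: 75.0}
_BASE_CYCLES = {0: 45.0, 1: 38.0, 2: 30.0}

# Subject-level lognormal heterogeneity (coefficient of variation).
_SUBJECT_CV_STEPS = 0.20
_SUBJECT_CV_CADENCE = 0.05
_SUBJECT_CV_CYCLES = 0.15


@dataclass
class CohortConfig:
    """Study-design knobs for a synthetic monitoring cohort.

    ``noise_sd`` is the day-to-day lognormal coefficient of variation of step
    volume; cadence and transition-count day noise are scaled fractions of it
    (0.48 and 0.40 respectively), so a single dial controls within-subject
    variability.
    """

    n_subjects: int = 27
    prop_nonresilient: float = 13 / 27
    n_days: int = 14
    ecog_probs_by_group: dict[str, Sequence[float]] = field(
        default_factory=lambda: {
            "resilient": _TABLE_ECOG_RESILIENT,
            "nonresilient": _TABLE_ECOG_NONRESILIENT,
        }
    )
    trajectory_params: dict[str, TrajectoryParams] = field(
        default_factory=lambda: {
            "resilient": RESILIENT_DEFAULT,
            "nonresilient": NONRESILIENT_DEFAULT,
        }
    )
    noise_sd: float = 0.38
    seed: int = 0
    sleep_start_h: float = 23.0
    sleep_end_h: float = 7.0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects", "must be >= 0")
        if not 0.0 <= self.prop_nonresilient <= 1.0:
            raise ConfigurationError("prop_nonresilient", "must be in [0, 1]")
        if self.n_days < 2:
            raise ConfigurationError("n_days", "must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd", "must be >= 0")
        for group in ("resilient", "nonresilient"):
            if group not in self.ecog_probs_by_group:
                raise ConfigurationError("ecog_probs_by_group", f"missing group {group!r}")
            probs = np.asarray(self.ecog_probs_by_group[group], dtype=float)
            if probs.shape != (3,) or (probs < 0).any():
                raise ConfigurationError("ecog_probs_by_group", f"{group}: need 3 nonneg probs")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    "ecog_probs_by_group", f"{group}: probabilities sum to {probs.sum()}, not 1"
                )
            if group not in self.trajectory_params:
                raise ConfigurationError("trajectory_params", f"missing group {group!r}")
            self.trajectory_params[group].validate(self.n_days)


# ---------------------------------------------------------------------------
# subjects and activity days
# ---------------------------------------------------------------------------


@dataclass
class SubjectProfile:
    """Covariates, outcome flags and derived group label for one subject.

    ``group`` is ``"nonresilient"`` exactly when at least one adverse-event
    flag (dose reduction/discontinuation, cancer-related hospitalization
    within 4 weeks, or death within 6 months) is set.
    """

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    bmi: float
    ecog: int  # 0, 1 or 2
    group: str  # "resilient" | "nonresilient"
    dose_event: bool
    hospitalization_4wk: bool
    death_6mo: bool
    baselines: dict[str, float] | None = None

    @property
    def ecog_dichot(self) -> int:
        """ECOG coded for analysis: 0 vs 1 (meaning ECOG 1-2)."""
        return 0 if self.ecog == 0 else 1

    def validate(self) -> None:
        any_event = self.dose_event or self.hospitalization_4wk or self.death_6mo
        if (self.group == "nonresilient") != any_event:
            raise ValueError(
                f"{self.subject_id}: group {self.group!r} inconsistent with adverse-event flags"
            )
        if self.ecog not in (0, 1, 2):
            raise ValueError(f"{self.subject_id}: ECOG must be 0/1/2")


@dataclass
class ActivityDay:
    """One subject-day of second-resolution posture states plus step events.

    The posture stream is stored run-length encoded (``bout_starts``,
    ``bout_durations``, ``bout_states``); bouts tile ``[0, 86400)`` seconds
    without gaps.  ``step_times`` are seconds-within-day of individual steps,
    strictly increasing, and each step falls inside a WALKING second.  The
    dense per-second label vector is available as :attr:`states`.
    """

    subject_id: str
    day_index: int
    bout_starts: np.ndarray
    bout_durations: np.ndarray
    bout_states: np.ndarray
    step_times: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def states(self) -> np.ndarray:
        """Dense int8 vector of 86 400 per-second posture labels."""
        return np.repeat(self.bout_states.astype(np.int8), self.bout_durations)

    @property
    def total_seconds(self) -> int:
        return int(self.bout_durations.sum())

    @classmethod
    def from_dense(
        cls,
        subject_id: str,
        day_index: int,
        states: np.ndarray,
        step_times: np.ndarray,
        meta: dict | None = None,
    ) -> "ActivityDay":
        states = np.asarray(states, dtype=np.int8)
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate(([0], change)).astype(np.int64)
        ends = np.concatenate((change, [states.size])).astype(np.int64)
        return cls(
            subject_id=subject_id,
            day_index=day_index,
            bout_starts=starts,
            bout_durations=ends - starts,
            bout_states=states[starts].copy(),
            step_times=np.asarray(step_times, dtype=float),
            meta=meta or {},
        )

    def validate(self) -> None:
        if self.total_seconds != SECONDS_PER_DAY:
            raise ValueError(f"day covers {self.total_seconds} s, expected {SECONDS_PER_DAY}")
        ends = self.bout_starts + self.bout_durations
        if self.bout_starts[0] != 0 or not np.array_equal(ends[:-1], self.bout_starts[1:]):
            raise ValueError("bouts must tile the day without gaps")
        if np.any(np.diff(self.step_times) <= 0):
            raise ValueError("step_times must be strictly increasing")
        if self.step_times.size:
            sec = np.floor(self.step_times).astype(np.int64)
            idx = np.searchsorted(self.bout_starts, sec, side="right") - 1
            if np.any(self.bout_states[idx] != WALKING):
                raise ValueError("steps must fall inside WALKING seconds")


@dataclass
class RawAccelDay:
    """Raw 50 Hz tri-axial accelerometry (units g) plus the ground truth day.

    Device frame: z runs along the trunk (vertical when upright), y is
    anterior, x lateral.  ``samples`` has shape ``(86400 * 50, 3)`` ordered
    (x, y, z).
    """

    subject_id: str
    day_index: int
    samples: np.ndarray
    fs: int
    truth: ActivityDay


# ---------------------------------------------------------------------------
# daily activity synthesis
# ---------------------------------------------------------------------------


def _lognorm_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one lognormal multiplicative noise with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def derive_baselines(profile: SubjectProfile, rng: np.random.Generator | None = None) -> dict:
    """Subject-level activity baselines keyed off ECOG grade.

    With an rng, lognormal subject heterogeneity is applied; without one the
    ECOG-group means are returned.
    """
    ecog = profile.ecog
    out = {
        "steps": _BASE_STEPS[ecog],
        "cadence": _BASE_CADENCE[ecog],
        "cycles": _BASE_CYCLES[ecog],
    }
    if rng is not None:
        out["steps"] *= _lognorm_factor(rng, _SUBJECT_CV_STEPS)
        out["cadence"] *= _lognorm_factor(rng, _SUBJECT_CV_CADENCE)
        out["cycles"] *= _lognorm_factor(rng, _SUBJECT_CV_CYCLES)
    return out


def synth_activity_day(
    profile: SubjectProfile,
    multiplier: float,
    day_index: int,
    rng: np.random.Generator,
    noise_sd: float = 0.38,
    sleep_start_h: float = 23.0,
    sleep_end_h: float = 7.0,
) -> ActivityDay:
    """Draw one day of posture bouts and steps at a given capacity multiplier.

    Volume quantities (expected steps, sit<->stand cycles) scale linearly with
    the multiplier; walking cadence scales with sqrt(multiplier), so walking
    speed declines less than walking volume.  The sleep window is spent LYING;
    waking time is tiled by sit/stand cycles that embed walking bouts, with an
    optional nap whose probability rises as capacity falls.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    base = profile.baselines or derive_baselines(profile)

    cv_steps = noise_sd
    cv_cad = 0.48 * noise_sd
    cv_cyc = 0.40 * noise_sd

    sleep_start = int(sleep_start_h * 3600)
    sleep_end = int(sleep_end_h * 3600)
    wake_len = sleep_start - sleep_end  # seconds awake (sleep window wraps midnight)

    target_steps = base["steps"] * multiplier * _lognorm_factor(rng, cv_steps)
    cadence = base["cadence"] * math.sqrt(multiplier) * _lognorm_factor(rng, cv_cad)
    cadence = max(cadence, 20.0)
    walk_total = min(target_steps / cadence * 60.0, 0.30 * wake_len)

    n_cycles = 1 + rng.poisson(base["cycles"] * multiplier * _lognorm_factor(rng, cv_cyc))
    n_walk = 1 + rng.poisson(12.0 * multiplier)

    # split walking time into bouts (exponential spacings -> Dirichlet shares)
    shares = rng.exponential(size=n_walk)
    walk_durs = walk_total * shares / shares.sum()
    walk_cycle = rng.integers(0, n_cycles, size=n_walk)  # which cycle hosts each bout

    stand_durs = rng.uniform(20.0, 90.0, size=n_cycles + n_walk)
    nap_dur = 0.0
    p_nap = min(max(0.65 - 0.35 * multiplier, 0.0), 0.9)
    if rng.random() < p_nap:
        nap_dur = min(rng.exponential(2400.0), 5400.0)
    nap_cycle = int(rng.integers(0, n_cycles))

    sit_total = wake_len - walk_total - stand_durs.sum() - nap_dur
    if sit_total < 600.0:  # squeeze naps, then walking, to keep some sitting
        nap_dur = max(0.0, nap_dur + sit_total - 600.0)
        sit_total = wake_len - walk_total - stand_durs.sum() - nap_dur
        if sit_total < 600.0:
            walk_total = max(60.0, walk_total + sit_total - 600.0)
            walk_durs = walk_total * shares / shares.sum()
            sit_total = wake_len - walk_total - stand_durs.sum() - nap_dur
    sit_shares = rng.exponential(size=n_cycles)
    sit_durs = sit_total * sit_shares / sit_shares.sum()

    # assemble the waking timeline: SIT [LIE] SIT? -> STAND -> (WALK STAND)*
    states: list[int] = [LYING]
    durs: list[float] = [float(sleep_end)]
    stand_i = 0
    for c in range(n_cycles):
        if nap_dur > 0 and c == nap_cycle:
            states += [SITTING, LYING, SITTING]
            durs += [0.5 * sit_durs[c], nap_dur, 0.5 * sit_durs[c]]
        else:
            states.append(SITTING)
            durs.append(sit_durs[c])
        states.append(STANDING)
        durs.append(stand_durs[stand_i])
        stand_i += 1
        for w in np.flatnonzero(walk_cycle == c):
            states.append(WALKING)
            durs.append(walk_durs[w])
            states.append(STANDING)
            durs.append(stand_durs[stand_i])
            stand_i += 1
    states.append(LYING)
    durs.append(float(SECONDS_PER_DAY - sleep_start))

    # round bout boundaries to integer seconds, preserving the exact total
    bounds = np.round(np.concatenate(([0.0], np.cumsum(durs)))).astype(np.int64)
    bounds[-1] = SECONDS_PER_DAY
    idurs = np.diff(bounds)
    keep = idurs > 0
    bout_states = np.asarray(states, dtype=np.int8)[keep]
    bout_durs = idurs[keep]
    bout_starts = bounds[:-1][keep]

    # collapse adjacent bouts that ended up in the same state after rounding
    same = np.flatnonzero(bout_states[1:] == bout_states[:-1])
    if same.size:
        keep2 = np.ones(bout_states.size, dtype=bool)
        keep2[same + 1] = False
        bout_states = bout_states[keep2]
        bout_starts = bout_starts[keep2]
        bout_durs = np.append(bout_starts[1:], SECONDS_PER_DAY) - bout_starts

    # place steps uniformly within each walking bout at the day's cadence
    step_chunks = []
    step_rate = cadence / 60.0
    for s, d, st in zip(bout_starts, bout_durs, bout_states):
        if st != WALKING or d <= 0:
            continue
        k = int(round(d * step_rate))
        if k <= 0:
            continue
        step_chunks.append(s + (np.arange(k) + 0.5) * (d / k))
    step_times = np.concatenate(step_chunks) if step_chunks else np.empty(0)

    return ActivityDay(
        subject_id=profile.subject_id,
        day_index=day_index,
        bout_starts=bout_starts,
        bout_durations=bout_durs,
        bout_states=bout_states,
        step_times=step_times,
        meta={"multiplier": multiplier, "cadence": cadence},
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Adverse-event marginal rates among non-resilient subjects (dose event,
# hospitalization within 4 weeks, death within 6 months).
_EVENT_PROBS = (0.54, 0.62, 0.85)

_COVARIATES = {
    # group: (age_mean, age_sd, bmi_mean, bmi_sd, p_male)
    "resilient": (64.6, 12.9, 27.9, 6.4, 0.571),
    "nonresilient": (67.2, 15.3, 23.8, 3.1, 0.769),
}


def _draw_profile(subject_id: str, group: str, config: CohortConfig, rng: np.random.Generator) -> SubjectProfile:
    age_m, age_s, bmi_m, bmi_s, p_male = _COVARIATES[group]
    age = float(np.clip(rng.normal(age_m, age_s), 30.0, 95.0))
    bmi = float(np.clip(rng.normal(bmi_m, bmi_s), 15.0, 50.0))
    sex = "male" if rng.random() < p_male else "female"
    ecog = int(rng.choice(3, p=np.asarray(config.ecog_probs_by_group[group], dtype=float)))
    if group == "nonresilient":
        while True:  # at least one adverse event defines the group
            flags = rng.random(3) < np.asarray(_EVENT_PROBS)
            if flags.any():
                break
        dose, hosp, death = (bool(f) for f in flags)
    else:
        dose = hosp = death = False
    profile = SubjectProfile(
        subject_id=subject_id,
        age=age,
        sex=sex,
        bmi=bmi,
        ecog=ecog,
        group=group,
        dose_event=dose,
        hospitalization_4wk=hosp,
        death_6mo=death,
    )
    profile.baselines = derive_baselines(profile, rng)
    profile.validate()
    return profile


def generate_cohort(config: CohortConfig) -> list[tuple[SubjectProfile, list[ActivityDay]]]:
    """Generate a full synthetic cohort: profiles plus per-day activity streams.

    Deterministic given ``config.seed``.  Group assignment is stratified so a
    27-subject cohort at the default mix reproduces the 14 resilient / 13
    non-resilient split exactly.  Each subject-day uses an independent child
    RNG stream spawned from the master seed, so regenerating with more days or
    subjects never reshuffles existing history.
    """
    config.validate()
    n = config.n_subjects
    if n == 0:
        return []
    master = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(master.spawn(1)[0])
    n_non = int(round(n * config.prop_nonresilient))
    groups = np.array(["nonresilient"] * n_non + ["resilient"] * (n - n_non))
    assign_rng.shuffle(groups)

    subject_seeds = master.spawn(n)
    cohort = []
    for i in range(n):
        streams = subject_seeds[i].spawn(config.n_days + 1)
        profile = _draw_profile(f"S{i + 1:03d}", str(groups[i]), config, np.random.default_rng(streams[0]))
        params = config.trajectory_params[profile.group]
        days = []
        for d in range(1, config.n_days + 1):
            m = capacity(d, params, config.n_days)
            days.append(
                synth_activity_day(
                    profile,
                    m,
                    d,
                    np.random.default_rng(streams[d]),
                    noise_sd=config.noise_sd,
                    sleep_start_h=config.sleep_start_h,
                    sleep_end_h=config.sleep_end_h,
                )
            )
        cohort.append((profile, days))
    return cohort


# ---------------------------------------------------------------------------
# raw 50 Hz accelerometry
# ---------------------------------------------------------------------------

# Trunk inclination (degrees from vertical) of the pendant per posture.
_POSTURE_TILT_DEG = {STANDING: 5.0, WALKING: 10.0, SITTING: 20.0, LYING: 90.0}
_WALK_AMPLITUDE_G = 0.35  # vertical oscillation amplitude per step cycle


def synth_raw_accel(
    day: ActivityDay,
    noise_sd: float = 0.05,
    rng: np.random.Generator | None = None,
) -> RawAccelDay:
    """Render an activity day down to a 50 Hz tri-axial waveform (units g).

    Static postures produce the gravity vector in a posture-specific trunk
    orientation plus white noise; each step during WALKING superimposes one
    full period of a vertical sinusoid, so a second containing k steps shows
    exactly k oscillation peaks above the static level.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    n = SECONDS_PER_DAY * ACCEL_HZ
    samples = np.zeros((n, 3), dtype=np.float32)

    # gravity per bout
    for s, d, st in zip(day.bout_starts, day.bout_durations, day.bout_states):
        tilt = math.radians(_POSTURE_TILT_DEG[int(st)])
        sl = slice(int(s) * ACCEL_HZ, int(s + d) * ACCEL_HZ)
        samples[sl, 2] = math.cos(tilt)
        samples[sl, 1] = math.sin(tilt)

    # one vertical sinusoid period per step
    if day.step_times.size:
        sec = np.floor(day.step_times).astype(np.int64)
        counts = np.bincount(sec, minlength=SECONDS_PER_DAY)
        walk_secs = np.flatnonzero(counts)
        tau = (np.arange(ACCEL_HZ) + 0.5) / ACCEL_HZ
        for s in walk_secs:
            k = counts[s]
            sl = slice(int(s) * ACCEL_HZ, int(s + 1) * ACCEL_HZ)
            samples[sl, 2] += (_WALK_AMPLITUDE_G * np.sin(2.0 * np.pi * k * tau)).astype(np.float32)

    if noise_sd > 0:
        samples += rng.normal(0.0, noise_sd, size=samples.shape).astype(np.float32)

    return RawAccelDay(
        subject_id=day.subject_id,
        day_index=day.day_index,
        samples=samples,
        fs=ACCEL_HZ,
        truth=day,
    )
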