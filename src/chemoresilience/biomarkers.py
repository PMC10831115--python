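"""Daily digital frailty biomarkers from pendant-sensor activity streams.

Nine features are computed per subject-day from the second-resolution posture
stream and step events:

========================  =================================================
cadence_p90               90th percentile of steps/min over walking minutes
n_stand_to_sit            stand -> sit postural transitions
n_sit_to_stand            sit -> stand postural transitions
longest_bout_steps        steps in the longest unbroken walking bout
total_steps               total daily walking steps
pct_sitting               % of the 24 h spent sitting
pct_standing              % standing
pct_walking               % walking
pct_lying                 % lying
========================  =================================================

An optional raw-signal tier (:func:`classify_posture`) reconstructs the
posture stream and step events from 50 Hz tri-axial accelerometry; it is a
simple, documented classifier standing in for a commercial device's firmware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .cohort import (
    ACCEL_HZ,
    LYING,
    SECONDS_PER_DAY,
    SITTING,
    STANDING,
    WALKING,
    ActivityDay,
    RawAccelDay,
)

__all__ = [
    "FEATURE_NAMES",
    "DailyBiomarkers",
    "ClassifierParams",
    "extract_daily_biomarkers",
    "cadence_p90",
    "longest_walking_bout",
    "count_postural_transitions",
    "classify_posture",
    "biomarker_table",
    "energy_expenditure_kcal",
]

FEATURE_NAMES = [
    "cadence_p90",
    "n_stand_to_sit",
    "n_sit_to_stand",
    "longest_bout_steps",
    "total_steps",
    "pct_sitting",
    "pct_standing",
    "pct_walking",
    "pct_lying",
]

#: Default walking-bout gap tolerance (s): non-walking longer than this ends a bout.
DEFAULT_MAX_GAP_S = 3.0


@dataclass
class DailyBiomarkers:
    """The nine daily frailty biomarkers for one subject-day."""

    subject_id: str
    day_index: int
    cadence_p90: float
    n_stand_to_sit: int
    n_sit_to_stand: int
    longest_bout_steps: int
    total_steps: int
    pct_sitting: float
    pct_standing: float
    pct_walking: float
    pct_lying: float

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "day_index": self.day_index,
            **{name: getattr(self, name) for name in FEATURE_NAMES},
        }


def _check_duration(day: ActivityDay, allow_partial: bool) -> int:
    total = day.total_seconds
    if total != SECONDS_PER_DAY and not allow_partial:
        raise ValueError(
            f"{day.subject_id} day {day.day_index}: stream covers {total} s, "
            f"expected {SECONDS_PER_DAY}; pass allow_partial=True to accept"
        )
    return total


def cadence_p90(day: ActivityDay) -> float:
    """90th percentile of per-minute step counts over walking minutes.

    A walking minute is any calendar minute of the day containing at least one
    WALKING second; the percentile uses linear interpolation.  Returns 0.0 for
    a day with no walking.
    """
    walk = day.bout_states == WALKING
    if not walk.any():
        return 0.0
    starts = day.bout_starts[walk]
    ends = starts + day.bout_durations[walk]
    minute_ids = np.unique(
        np.concatenate([np.arange(s // 60, (e - 1) // 60 + 1) for s, e in zip(starts, ends)])
    )
    counts = np.bincount(
        (day.step_times // 60).astype(np.int64), minlength=int(minute_ids.max()) + 1
    )
    return float(np.percentile(counts[minute_ids], 90))


def longest_walking_bout(day: ActivityDay, max_gap_s: float = DEFAULT_MAX_GAP_S) -> int:
    """Steps in the longest unbroken walking bout.

    Walking episodes separated by non-walking no longer than ``max_gap_s``
    are merged; a strictly longer interruption ends the bout.  Ties go to the
    earliest bout (irrelevant for the step count returned here).
    """
    if max_gap_s < 0:
        raise ValueError("max_gap_s must be >= 0")
    walk = day.bout_states == WALKING
    if not walk.any():
        return 0
    starts = day.bout_starts[walk].astype(float)
    ends = (day.bout_starts[walk] + day.bout_durations[walk]).astype(float)
    gaps = starts[1:] - ends[:-1]
    breaks = np.flatnonzero(gaps > max_gap_s)
    span_starts = np.concatenate(([starts[0]], starts[breaks + 1]))
    span_ends = np.concatenate((ends[breaks], [ends[-1]]))
    lo = np.searchsorted(day.step_times, span_starts, side="left")
    hi = np.searchsorted(day.step_times, span_ends, side="left")
    return int((hi - lo).max())


def count_postural_transitions(day: ActivityDay) -> tuple[int, int]:
    """(sit -> stand, stand -> sit) transition counts.

    Convention: WALKING is treated as upright (merged into STANDING), so a
    walking interlude between two standing blocks creates no transition and a
    direct SITTING -> WALKING change counts as one sit-to-stand.  LYING
    interrupts the sit/stand alternation without creating transitions.
    """
    merged = np.where(day.bout_states == WALKING, STANDING, day.bout_states)
    change = np.flatnonzero(np.diff(merged)) + 1
    collapsed = merged[np.concatenate(([0], change))]
    prev, nxt = collapsed[:-1], collapsed[1:]
    sit_to_stand = int(np.sum((prev == SITTING) & (nxt == STANDING)))
    stand_to_sit = int(np.sum((prev == STANDING) & (nxt == SITTING)))
    return sit_to_stand, stand_to_sit


def extract_daily_biomarkers(
    day: ActivityDay,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    allow_partial: bool = False,
) -> DailyBiomarkers:
    """Compute all nine daily biomarkers for one subject-day.

    Posture percentages are fractions of the 24 h window (or of the observed
    duration when ``allow_partial`` accepts a short stream).  Deterministic.
    """
    total = _check_duration(day, allow_partial)
    secs = np.zeros(4)
    np.add.at(secs, day.bout_states.astype(int), day.bout_durations)
    pct = secs / total * 100.0
    s2st, st2s = count_postural_transitions(day)
    return DailyBiomarkers(
        subject_id=day.subject_id,
        day_index=day.day_index,
        cadence_p90=cadence_p90(day),
        n_stand_to_sit=st2s,
        n_sit_to_stand=s2st,
        longest_bout_steps=longest_walking_bout(day, max_gap_s),
        total_steps=int(day.step_times.size),
        pct_sitting=float(pct[SITTING]),
        pct_standing=float(pct[STANDING]),
        pct_walking=float(pct[WALKING]),
        pct_lying=float(pct[LYING]),
    )


def biomarker_table(cohort, max_gap_s: float = DEFAULT_MAX_GAP_S):
    """DataFrame of daily biomarkers (one row per subject-day) for a cohort.

    ``cohort`` is an iterable of ``(SubjectProfile, [ActivityDay, ...])`` as
    returned by :func:`chemoresilience.cohort.generate_cohort`.
    """
    import pandas as pd

    rows = []
    for _profile, days in cohort:
        for day in days:
            rows.append(extract_daily_biomarkers(day, max_gap_s).as_dict())
    columns = ["subject_id", "day_index", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# optional MET-based energy expenditure (not part of the default feature set)
# ---------------------------------------------------------------------------

_MET_BY_STATE = {LYING: 1.0, SITTING: 1.3, STANDING: 1.8, WALKING: 3.0}


def energy_expenditure_kcal(day: ActivityDay, weight_kg: float = 70.0) -> float:
    """Crude MET-based daily energy expenditure (kcal), 1 MET = 1 kcal/kg/h."""
    hours = np.zeros(4)
    np.add.at(hours, day.bout_states.astype(int), day.bout_durations / 3600.0)
    return float(sum(_MET_BY_STATE[s] * hours[s] for s in range(4)) * weight_kg)


# ---------------------------------------------------------------------------
# raw-signal tier: posture classification and step detection
# ---------------------------------------------------------------------------


@dataclass
class ClassifierParams:
    """Tunables of the raw-accelerometry posture/step classifier.

    ``sit_stand_rule`` selects how sitting is separated from standing among
    upright seconds; the default ``"tilt"`` rule thresholds the per-second
    trunk inclination at ``sit_tilt_deg`` (pendant hangs more vertically when
    standing).
    """

    upright_angle_deg: float = 45.0
    walk_band_hz: tuple[float, float] = (0.5, 3.0)
    step_peak_min_g: float = 0.15
    walk_rms_min_g: float = 0.08
    sit_stand_rule: str = "tilt"
    sit_tilt_deg: float = 12.0

    def validate(self) -> None:
        if not 0 < self.upright_angle_deg < 90:
            raise ValueError("upright_angle_deg must be in (0, 90)")
        lo, hi = self.walk_band_hz
        if not 0 < lo < hi:
            raise ValueError("walk_band_hz limits must be positive and ordered")
        if self.sit_stand_rule != "tilt":
            raise ValueError(f"unknown sit_stand_rule {self.sit_stand_rule!r}")


def classify_posture(raw: RawAccelDay, params: ClassifierParams | None = None) -> ActivityDay:
    """Classify 50 Hz tri-axial accelerometry into per-second postures + steps.

    Per second: the mean acceleration vector estimates gravity; trunk
    inclination beyond ``upright_angle_deg`` labels LYING.  Upright seconds
    whose band-passed (walk_band_hz) trunk-axis RMS exceeds ``walk_rms_min_g``
    are WALKING; the rest are split sitting/standing by the tilt rule.  Steps
    are peaks of the band-passed trunk axis within walking seconds with
    prominence at least ``step_peak_min_g``.

    A signal whose mean vector magnitude is far below 1 g (pendant not worn /
    corrupt record) is still classified, but the returned day carries
    ``meta["low_confidence"] = True``.
    """
    params = params or ClassifierParams()
    params.validate()
    if raw.fs != ACCEL_HZ:
        raise ValueError(f"expected {ACCEL_HZ} Hz sampling, got {raw.fs}")
    n_sec = raw.samples.shape[0] // raw.fs
    x = raw.samples.reshape(n_sec, raw.fs, 3)

    mean_vec = x.mean(axis=1)  # per-second gravity estimate
    mag = np.linalg.norm(mean_vec, axis=1)
    low_confidence = bool(np.median(mag) < 0.5)
    safe_mag = np.where(mag > 1e-9, mag, 1.0)
    incl = np.degrees(np.arccos(np.clip(mean_vec[:, 2] / safe_mag, -1.0, 1.0)))

    sos = signal.butter(
        4, params.walk_band_hz, btype="bandpass", fs=raw.fs, output="sos"
    )
    z_band = signal.sosfiltfilt(sos, raw.samples[:, 2].astype(float))
    rms = np.sqrt((z_band.reshape(n_sec, raw.fs) ** 2).mean(axis=1))

    states = np.full(n_sec, SITTING, dtype=np.int8)
    lying = incl > params.upright_angle_deg
    states[lying] = LYING
    walking = ~lying & (rms > params.walk_rms_min_g)
    states[walking] = WALKING
    standing = ~lying & ~walking & (incl <= params.sit_tilt_deg)
    states[standing] = STANDING

    # step detection: peaks of the band-passed trunk axis inside walking seconds
    peaks, _ = signal.find_peaks(z_band, prominence=params.step_peak_min_g)
    if peaks.size:
        peak_secs = peaks // raw.fs
        keep = walking[peak_secs]
        step_times = (peaks[keep] + 0.5) / raw.fs
    else:
        step_times = np.empty(0)

    return ActivityDay.from_dense(
        subject_id=raw.subject_id,
        day_index=raw.day_index,
        states=states,
        step_times=step_times,
        meta={"low_confidence": low_confidence, "source": "classified"},
    )
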