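"""Performance measures computed from trial-level response logs.

Pitch identification is scored with the correct response rate (CRR, exact
chroma matches only) and the mean absolute deviation (MAD) on the 12-chroma
circle.  The GIN test yields the gap detection percentage (GDP, out of 60
gaps) and the gap detection threshold (GDT, shortest gap detected at least
4 of 6 times with the criterion maintained at all longer gaps).  The BMT
yields the analogous percent correct (BMTP, out of 48 tone trials) and
tone-detection threshold over the 8 inter-stimulus intervals (BMTT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocols import BMT_ISIS_MS, GIN_GAP_DURATIONS_MS, BmtSession, GinTrack

__all__ = [
    "CENSORED",
    "PitchScores",
    "EarScores",
    "chroma_distance",
    "score_pitch_id",
    "detection_counts",
    "threshold_from_counts",
    "score_gin_ear",
    "score_bmt_ear",
    "average_ears",
]

#: Token for a threshold beyond the tested range (no level meets the rule).
#: Serialised in CSV as the literal string "NA_censored"; never imputed.
CENSORED = "NA_censored"

#: How a missing pitch response is scored; "worst" counts it wrong with the
#: maximal circular deviation of 6 semitones, "exclude" drops the trial.
NO_RESPONSE_POLICIES = ("worst", "exclude")


@dataclass(frozen=True)
class PitchScores:
    """Pitch-identification summary: percent exactly correct and mean
    circular deviation in semitones (0..6)."""

    crr: float
    mad: float


@dataclass(frozen=True)
class EarScores:
    """Per-ear (or ear-averaged) detection scores.

    Thresholds are a tested level in ms or :data:`CENSORED`.  ``censored``
    flags an average in which at least one ear's threshold was censored.
    """

    gdp: float | None = None
    gdt: float | str | None = None
    bmtp: float | None = None
    bmtt: float | str | None = None
    false_alarm_rate: float | None = None
    censored: bool = False


def chroma_distance(a: int, b: int) -> int:
    """Circular distance between two pitch classes, in semitones (0..6)."""
    if not (0 <= a <= 11 and 0 <= b <= 11):
        raise ValueError(f"chroma out of range: {a}, {b}")
    d = abs(a - b) % 12
    return min(d, 12 - d)


def score_pitch_id(log: pd.DataFrame, *, no_response: str = "worst") -> PitchScores:
    """Score a pitch-identification log.

    Parameters
    ----------
    log
        Frame with columns ``target_chroma`` and ``response_chroma``;
        a missing response is a null ``response_chroma``.
    no_response
        Policy for missing responses: ``"worst"`` (incorrect, deviation 6)
        or ``"exclude"`` (trial dropped from both measures).
    """
    if no_response not in NO_RESPONSE_POLICIES:
        raise ValueError(f"no_response must be one of {NO_RESPONSE_POLICIES}")
    if len(log) == 0:
        raise ValueError("empty trial log")
    targets = log["target_chroma"].to_numpy()
    responses = log["response_chroma"]
    answered = responses.notna().to_numpy()
    if no_response == "exclude":
        targets = targets[answered]
        responses = responses[answered]
        answered = np.ones(len(targets), dtype=bool)
        if len(targets) == 0:
            raise ValueError("no answered trials to score")
    distances = np.full(len(targets), 6.0)
    resp_vals = responses.to_numpy()
    for i in np.flatnonzero(answered):
        distances[i] = chroma_distance(int(targets[i]), int(resp_vals[i]))
    crr = 100.0 * float(np.mean(distances == 0))
    mad = float(np.mean(distances))
    return PitchScores(crr=crr, mad=mad)


def detection_counts(track: GinTrack, log: pd.DataFrame) -> dict[int, int]:
    """Tally detections per gap duration.

    ``log`` has one row per gap in presentation order with a boolean
    ``detected`` column.
    """
    durations = track.gap_durations()
    if len(log) != len(durations):
        raise ValueError(
            f"log has {len(log)} gap outcomes for a track with {len(durations)} gaps"
        )
    detected = log["detected"].to_numpy(dtype=bool)
    counts = {d: 0 for d in GIN_GAP_DURATIONS_MS}
    for dur, hit in zip(durations, detected):
        if hit:
            counts[dur] += 1
    return counts


def threshold_from_counts(
    counts: dict[int, int],
    *,
    criterion: int = 4,
    n_per_level: int = 6,
    policy: str = "maintained_criterion",
) -> int | str:
    """Shortest level meeting the 4-of-6 rule with maintained performance.

    Levels are stimulus magnitudes at which detection gets easier as the
    level grows (gap duration, or tone-to-masker ISI).  Under
    ``"maintained_criterion"`` (clinical convention, default) a candidate
    level qualifies when its count reaches ``criterion`` and every easier
    (larger) level also reaches ``criterion``.  Under ``"maintained_rate"``
    every easier level must match or exceed the candidate's own count.
    Returns :data:`CENSORED` when no level qualifies.
    """
    if policy not in ("maintained_criterion", "maintained_rate"):
        raise ValueError(f"unknown policy {policy!r}")
    levels = sorted(counts)
    values = [counts[x] for x in levels]
    if any(not (0 <= v <= n_per_level) for v in values):
        raise ValueError(f"counts must lie in 0..{n_per_level}")
    for i, level in enumerate(levels):
        c = values[i]
        if c < criterion:
            continue
        floor = criterion if policy == "maintained_criterion" else c
        if all(v >= floor for v in values[i + 1 :]):
            return level
    return CENSORED


def score_gin_ear(track: GinTrack, log: pd.DataFrame, **kwargs) -> EarScores:
    """GDP (percent of 60 gaps detected) and GDT for one ear.

    ``log`` carries one boolean ``detected`` row per gap; a ``false_alarms``
    attribute or column total, if present, is carried through as a rate per
    segment but never enters GDP.
    """
    counts = detection_counts(track, log)
    n_gaps = track.n_gaps
    detected_total = int(log["detected"].sum())
    gdp = 100.0 * detected_total / n_gaps
    gdt = threshold_from_counts(counts, **kwargs)
    fa = None
    if "false_alarms" in log.attrs:
        fa = float(log.attrs["false_alarms"]) / len(track.segments)
    return EarScores(gdp=gdp, gdt=gdt, false_alarm_rate=fa, censored=gdt == CENSORED)


def score_bmt_ear(session: BmtSession, log: pd.DataFrame, **kwargs) -> EarScores:
    """BMTP (percent of 48 tone trials pressed), BMTT, and catch-trial
    false-alarm rate for one ear.

    ``log`` has one boolean ``pressed`` row per trial, aligned with the
    session's trial order.
    """
    if len(log) != len(session):
        raise ValueError(f"log has {len(log)} rows for a {len(session)}-trial session")
    pressed = log["pressed"].to_numpy(dtype=bool)
    counts = {isi: 0 for isi in BMT_ISIS_MS}
    n_tone = 0
    hits = 0
    catch_presses = 0
    n_catch = 0
    for trial, p in zip(session.trials, pressed):
        if trial.is_catch:
            n_catch += 1
            catch_presses += int(p)
        else:
            n_tone += 1
            hits += int(p)
            if p:
                counts[trial.isi_ms] += 1
    bmtp = 100.0 * hits / n_tone
    bmtt = threshold_from_counts(counts, **kwargs)
    fa = catch_presses / n_catch if n_catch else 0.0
    return EarScores(bmtp=bmtp, bmtt=bmtt, false_alarm_rate=fa, censored=bmtt == CENSORED)


def _avg_threshold(a, b):
    if a is None or b is None:
        return None, False
    if a == CENSORED or b == CENSORED:
        return CENSORED, True
    return (a + b) / 2.0, False


def _avg(a, b):
    if a is None or b is None:
        return None
    return (a + b) / 2.0


def average_ears(left: EarScores, right: EarScores) -> EarScores:
    """Subject-level score: arithmetic mean of the two ears per measure.

    A censored threshold in either ear makes the averaged threshold
    censored and sets the ``censored`` flag; censored values are never
    replaced by numbers.
    """
    gdt, c1 = _avg_threshold(left.gdt, right.gdt)
    bmtt, c2 = _avg_threshold(left.bmtt, right.bmtt)
    return EarScores(
        gdp=_avg(left.gdp, right.gdp),
        gdt=gdt,
        bmtp=_avg(left.bmtp, right.bmtp),
        bmtt=bmtt,
        false_alarm_rate=_avg(left.false_alarm_rate, right.false_alarm_rate),
        censored=c1 or c2,
    )
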