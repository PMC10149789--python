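"""Seeded generators for the four psychoacoustic test protocols.

Two pitch-identification variants (a 13-note sine-tone test and a 36-note
synthetic-piano test), a gaps-in-noise (GIN) gap-detection track, and a
backward-masking test (BMT) session.  Every generator is a pure function of
its parameters and a seed: the same seed always yields the same protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "PitchStimulus",
    "PitchIdProtocol",
    "NoiseSegment",
    "GinTrack",
    "BmtTrial",
    "BmtSession",
    "CATCH",
    "GIN_GAP_DURATIONS_MS",
    "BMT_ISIS_MS",
    "ProtocolGenerationError",
    "build_pitch_id_protocol",
    "build_gin_track",
    "build_bmt_session",
    "protocol_to_frame",
    "gin_track_to_frame",
    "bmt_session_to_frame",
]

#: Gap durations used by the GIN test (ms), 6 gaps of each per ear.
GIN_GAP_DURATIONS_MS: tuple[int, ...] = (2, 3, 4, 5, 6, 8, 10, 12, 15, 20)

#: Tone-to-masker inter-stimulus intervals used by the BMT (ms).
BMT_ISIS_MS: tuple[int, ...] = (0, 10, 20, 30, 50, 100, 200, 400)

#: Sentinel ISI marking a masker-only catch trial.
CATCH = "catch"

_EXP1_MIDI = tuple(range(54, 67))   # F#3 .. F#4, 13 notes
_EXP2_MIDI = tuple(range(48, 84))   # C3 .. B5, 36 notes


class ProtocolGenerationError(RuntimeError):
    """Raised when constrained randomisation fails within the restart budget."""


class Timbre(str, Enum):
    SINE = "sine"
    SYNTHETIC_PIANO = "synthetic_piano"


@dataclass(frozen=True)
class PitchStimulus:
    """A single pitch-naming stimulus identified by its MIDI note number."""

    midi_note: int
    timbre: Timbre = Timbre.SINE

    @property
    def chroma(self) -> int:
        """Pitch class 0..11 with C=0."""
        return self.midi_note % 12


@dataclass(frozen=True)
class PitchIdProtocol:
    """An ordered pitch-identification trial list.

    ``exp1_sine52``: 13 sine tones F#3..F#4, each presented 4 times (52
    trials, 2 s inter-tone interval), ordered so that a stimulus repeats only
    after all 12 other stimuli have occurred since its last presentation.

    ``exp2_piano72``: 36 synthetic piano tones C3..B5, each presented twice
    (72 trials in 6 blocks of 12, 4.25 s interval), with every consecutive
    pair more than one octave apart to neutralise relative-pitch strategies.
    """

    variant: str
    trials: tuple[PitchStimulus, ...]
    iti_s: float
    level_db_sl: int = 50
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class NoiseSegment:
    """One 6-s white-noise segment carrying 0-3 silent gaps."""

    index: int
    gaps: tuple[tuple[float, int], ...]  # (onset_ms within segment, duration_ms)


@dataclass(frozen=True)
class GinTrack:
    """A GIN track: noise segments totalling 60 gaps, 6 per duration."""

    track_id: str
    segments: tuple[NoiseSegment, ...]
    segment_ms: int = 6000
    inter_segment_s: float = 5.0
    seed: int | None = None

    @property
    def n_gaps(self) -> int:
        return sum(len(s.gaps) for s in self.segments)

    def gap_durations(self) -> list[int]:
        """Durations of all gaps in presentation order."""
        return [d for seg in self.segments for (_, d) in seg.gaps]


@dataclass(frozen=True)
class BmtTrial:
    """A BMT trial: a tone at the given ISI before the masker, or a catch."""

    isi_ms: int | str  # an ISI in ms, or CATCH

    @property
    def is_catch(self) -> bool:
        return self.isi_ms == CATCH


@dataclass(frozen=True)
class BmtSession:
    """One ear's BMT run: 6 tone trials per ISI plus 12 catch trials."""

    trials: tuple[BmtTrial, ...]
    tone_ms: int = 25
    masker_ms: int = 200
    tone_level_db_sl: int = 20
    snr_db: int = -20
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# pitch identification


def _exp1_sequence(rng: np.random.Generator, max_restarts: int) -> list[int]:
    """Sequence of 52 notes, 4 of each of 13, under the full-cycle rule.

    A note may repeat only once all 12 other notes have been presented since
    its previous occurrence.  Built by sequential uniform sampling over the
    currently eligible notes, restarting on dead ends.
    """
    notes = list(_EXP1_MIDI)
    for _ in range(max_restarts):
        remaining = {m: 4 for m in notes}
        seen_since: dict[int, set[int]] = {}  # note -> distinct others since its last use
        seq: list[int] = []
        while len(seq) < 52:
            eligible = [
                m
                for m in notes
                if remaining[m] > 0 and (m not in seen_since or len(seen_since[m]) == 12)
            ]
            if not eligible:
                break
            m = eligible[rng.integers(len(eligible))]
            seq.append(m)
            remaining[m] -= 1
            for other, seen in seen_since.items():
                if other != m:
                    seen.add(m)
            seen_since[m] = set()
        else:
            return seq
    raise ProtocolGenerationError(
        "could not satisfy the full-cycle ordering rule "
        f"within {max_restarts} restarts"
    )


def _exp2_sequence(rng: np.random.Generator, max_restarts: int) -> list[int]:
    """72 notes, 2 of each of 36, consecutive pitches > 12 semitones apart.

    Randomised depth-first backtracking, expanding the most constrained
    candidate notes first (mid-range notes have the fewest >1-octave
    partners and dead-end the search when left for last); restarted with a
    fresh node budget on exhaustion.
    """
    notes = list(_EXP2_MIDI)
    partners = {m: sum(1 for x in notes if abs(x - m) > 12) for m in notes}
    for _ in range(max_restarts):
        remaining = {m: 2 for m in notes}
        seq: list[int] = []
        budget = 20_000

        def extend() -> bool:
            nonlocal budget
            if len(seq) == 72:
                return True
            if budget <= 0:
                return False
            budget -= 1
            candidates = [
                m
                for m in notes
                if remaining[m] > 0 and (not seq or abs(m - seq[-1]) > 12)
            ]
            if not candidates:
                return False
            keys = np.array([partners[m] for m in candidates]) + rng.random(
                len(candidates)
            )
            for i in np.argsort(keys):
                m = candidates[i]
                seq.append(m)
                remaining[m] -= 1
                if extend():
                    return True
                seq.pop()
                remaining[m] += 1
            return False

        if extend():
            return seq
    raise ProtocolGenerationError(
        f"could not satisfy the >1-octave spacing rule within {max_restarts} restarts"
    )


def build_pitch_id_protocol(
    variant: str, seed: int, *, max_restarts: int = 1000
) -> PitchIdProtocol:
    """Generate a pitch-identification protocol.

    Parameters
    ----------
    variant
        ``"exp1_sine52"`` or ``"exp2_piano72"``.
    seed
        Non-negative integer; identical seeds yield identical protocols.
    max_restarts
        Bound on randomised restarts before raising
        :class:`ProtocolGenerationError` (constraints are never relaxed
        silently).
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    if variant == "exp1_sine52":
        seq = _exp1_sequence(rng, max_restarts)
        trials = tuple(PitchStimulus(m, Timbre.SINE) for m in seq)
        return PitchIdProtocol(variant, trials, iti_s=2.0, seed=seed)
    if variant == "exp2_piano72":
        seq = _exp2_sequence(rng, max_restarts)
        trials = tuple(PitchStimulus(m, Timbre.SYNTHETIC_PIANO) for m in seq)
        return PitchIdProtocol(variant, trials, iti_s=4.25, seed=seed)
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# gaps in noise

_GIN_SEGMENTS = {"track1": 35, "track3": 29}


def build_gin_track(
    track_id: str,
    seed: int,
    *,
    min_gap_separation_ms: float = 500.0,
    edge_margin_ms: float = 300.0,
    max_restarts: int = 1000,
) -> GinTrack:
    """Generate a GIN track: 60 gaps (6 per duration) over the track's segments.

    Each 6000-ms segment carries 0-3 gaps placed at uniform random onsets,
    separated by at least ``min_gap_separation_ms`` and at least
    ``edge_margin_ms`` from the segment edges.  The commercial test's fixed
    layouts are not reproduced; only their statistical structure is.
    """
    if track_id not in _GIN_SEGMENTS:
        raise ValueError(f"unknown track_id {track_id!r}; expected one of {sorted(_GIN_SEGMENTS)}")
    n_segments = _GIN_SEGMENTS[track_id]
    if 3 * n_segments < 60:
        raise ProtocolGenerationError(
            f"{n_segments} segments cannot hold 60 gaps at 3 per segment"
        )
    rng = np.random.default_rng(seed)
    durations = np.repeat(GIN_GAP_DURATIONS_MS, 6)
    rng.shuffle(durations)

    # assign the 60 gaps to segments under the 0-3 cap
    counts = np.zeros(n_segments, dtype=int)
    for _ in range(60):
        open_segments = np.flatnonzero(counts < 3)
        counts[open_segments[rng.integers(len(open_segments))]] += 1

    segments: list[NoiseSegment] = []
    cursor = 0
    for idx in range(n_segments):
        k = int(counts[idx])
        durs = durations[cursor : cursor + k]
        cursor += k
        gaps = _place_gaps(rng, durs, 6000.0, min_gap_separation_ms, edge_margin_ms, max_restarts)
        segments.append(NoiseSegment(index=idx, gaps=gaps))
    return GinTrack(track_id=track_id, segments=tuple(segments), seed=seed)


def _place_gaps(
    rng: np.random.Generator,
    durations_ms: np.ndarray,
    segment_ms: float,
    min_sep: float,
    margin: float,
    max_restarts: int,
) -> tuple[tuple[float, int], ...]:
    """Uniform non-overlapping gap onsets with separation and edge margins."""
    if len(durations_ms) == 0:
        return ()
    for _ in range(max_restarts):
        onsets = rng.uniform(margin, segment_ms - margin - durations_ms)
        order = np.argsort(onsets)
        o, d = onsets[order], durations_ms[order]
        if np.all(o[1:] - (o[:-1] + d[:-1]) >= min_sep):
            return tuple((float(x), int(dd)) for x, dd in zip(o, d))
    raise ProtocolGenerationError("could not place gaps with the required separation")


# ---------------------------------------------------------------------------
# backward masking


def build_bmt_session(seed: int) -> BmtSession:
    """Generate one ear's BMT session: 48 tone trials (6 per ISI) + 12 catches,
    in randomised order."""
    rng = np.random.default_rng(seed)
    trials = [BmtTrial(isi) for isi in BMT_ISIS_MS for _ in range(6)]
    trials += [BmtTrial(CATCH) for _ in range(12)]
    order = rng.permutation(len(trials))
    return BmtSession(trials=tuple(trials[i] for i in order), seed=seed)


# ---------------------------------------------------------------------------
# CSV serialisation (lossless round trip; one row per trial or per gap)


def protocol_to_frame(protocol: PitchIdProtocol) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": np.arange(len(protocol)),
            "midi_note": [s.midi_note for s in protocol.trials],
            "chroma": [s.chroma for s in protocol.trials],
            "timbre": [s.timbre.value for s in protocol.trials],
        }
    )


def gin_track_to_frame(track: GinTrack) -> pd.DataFrame:
    rows = [
        {"segment": seg.index, "gap_onset_ms": onset, "gap_duration_ms": dur}
        for seg in track.segments
        for onset, dur in seg.gaps
    ]
    return pd.DataFrame(rows, columns=["segment", "gap_onset_ms", "gap_duration_ms"])


def bmt_session_to_frame(session: BmtSession) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": np.arange(len(session)),
            "isi_ms": [t.isi_ms for t in session.trials],
        }
    )
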