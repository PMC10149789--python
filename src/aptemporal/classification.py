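"""Absolute-pitch group assignment.

A subject is labelled AP when their correct response rate exceeds the chance
level of guessing among 12 chroma labels — formalised as the upper limit of
a 99% confidence interval for the binomial mean under p = 1/12 — and their
mean absolute deviation stays below 1.00 semitone.  Musicians scoring below
50% at the training screening are assigned to the Non-AP group without
taking the main test.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import math

from scipy import stats

from .scoring import PitchScores

__all__ = ["GroupLabel", "ChanceModel", "chance_cutoff", "assign_group"]


class GroupLabel(str, Enum):
    AP = "AP"
    NON_AP = "NonAP"


@dataclass(frozen=True)
class ChanceModel:
    """Binomial chance-level cutoff for an n-trial, k-alternative test.

    ``cutoff_count`` is the smallest number of correct answers that lies
    strictly above the upper limit of the two-sided normal-approximation
    confidence interval around the chance mean n/k.
    """

    n_trials: int
    n_alternatives: int
    confidence: float
    cutoff_count: int

    @property
    def cutoff_percent(self) -> float:
        return 100.0 * self.cutoff_count / self.n_trials


def chance_cutoff(
    n_trials: int,
    n_alternatives: int,
    confidence: float = 0.99,
    *,
    method: str = "normal",
) -> ChanceModel:
    """Smallest correct-answer count above the chance-level confidence band.

    The default normal approximation (mean n·p, SD √(n·p·(1−p)), two-sided
    z quantile) reproduces the published 10-of-52 (19.2%) cutoff for a
    52-trial, 12-alternative test at 99% confidence.  ``method="exact"``
    uses the binomial quantile instead.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_alternatives < 2:
        raise ValueError("n_alternatives must be >= 2 (chance would be certainty)")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    p = 1.0 / n_alternatives
    mean = n_trials * p
    if method == "normal":
        sd = math.sqrt(n_trials * p * (1.0 - p))
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        upper = mean + z * sd
    elif method == "exact":
        upper = stats.binom.ppf(0.5 + confidence / 2.0, n_trials, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    cutoff = int(math.floor(upper)) + 1
    cutoff = min(max(cutoff, 1), n_trials)
    return ChanceModel(n_trials, n_alternatives, confidence, cutoff)


def assign_group(
    pitch: PitchScores | None,
    training_crr: float | None,
    model: ChanceModel,
    *,
    mad_limit: float = 1.00,
    screening_threshold: float = 50.0,
    cutoff_percent: float | None = None,
) -> GroupLabel:
    """Assign a subject to the AP or Non-AP group.

    A training-session CRR below ``screening_threshold`` screens the subject
    out (Non-AP, no main test).  Otherwise the subject is AP iff their CRR
    reaches the chance cutoff and MAD < ``mad_limit``.  ``cutoff_percent``
    overrides the model's derived cutoff with a verbatim constant (used for
    the 72-trial piano variant, published as 20%).
    """
    if training_crr is not None and training_crr < screening_threshold:
        return GroupLabel.NON_AP
    if pitch is None:
        raise ValueError("pitch scores required for a subject passing screening")
    threshold = model.cutoff_percent if cutoff_percent is None else cutoff_percent
    if pitch.crr >= threshold and pitch.mad < mad_limit:
        return GroupLabel.AP
    return GroupLabel.NON_AP
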