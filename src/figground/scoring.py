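"""Outcome scoring: yes/no sensitivity (d') and sentence-in-noise word score.

d' for the figure-detection task is z(hit rate) - z(false-alarm rate) under
the equal-variance Gaussian model. The log-linear rate correction (+0.5 to
each cell, +1 to each denominator) is applied by default on every table, not
only at extreme rates, which removes infinities and keeps the estimator
continuous; 1/(2N) clipping and raw rates are available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtri


@dataclass(frozen=True)
class YesNoCounts:
    """2x2 outcome table of a yes/no detection session."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SpeechScore:
    """Proportion of correctly repeated words across presented sentences."""

    correct_words: int
    total_words: int

    @property
    def proportion(self) -> float:
        return self.correct_words / self.total_words


def dprime_yes_no(counts: YesNoCounts, correction: str = "loglinear") -> float:
    """Sensitivity d' = z(hit rate) - z(false-alarm rate).

    correction:
      "loglinear" (default) — add 0.5 per cell, 1 per denominator, always;
      "clip" — clip rates to [1/(2N), 1 - 1/(2N)];
      "none" — raw rates (infinite at 0/1 rates).
    """
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise ValueError("both signal and noise trial classes must be non-empty")
    if correction == "loglinear":
        hr = (counts.hits + 0.5) / (counts.n_signal + 1)
        fr = (counts.false_alarms + 0.5) / (counts.n_noise + 1)
    elif correction == "clip":
        hr = np.clip(
            counts.hits / counts.n_signal,
            1 / (2 * counts.n_signal),
            1 - 1 / (2 * counts.n_signal),
        )
        fr = np.clip(
            counts.false_alarms / counts.n_noise,
            1 / (2 * counts.n_noise),
            1 - 1 / (2 * counts.n_noise),
        )
    elif correction == "none":
        hr = counts.hits / counts.n_signal
        fr = counts.false_alarms / counts.n_noise
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(ndtri(hr) - ndtri(fr))


def score_speech(correct_words: int, total_words: int) -> SpeechScore:
    """Word-ratio speech score (e.g. 20 sentences in noise)."""
    if total_words <= 0:
        raise ValueError("total_words must be positive")
    if not (0 <= correct_words <= total_words):
        raise ValueError("correct_words must be in [0, total_words]")
    return SpeechScore(correct_words=correct_words, total_words=total_words)


def tabulate_yes_no(
    is_signal: Sequence[bool], said_yes: Sequence[bool]
) -> YesNoCounts:
    """Build the 2x2 table from trial labels and responses."""
    labels = np.asarray(is_signal, dtype=bool)
    resp = np.asarray(said_yes, dtype=bool)
    if labels.shape != resp.shape:
        raise ValueError("labels and responses must have equal length")
    return YesNoCounts(
        hits=int(np.sum(labels & resp)),
        misses=int(np.sum(labels & ~resp)),
        false_alarms=int(np.sum(~labels & resp)),
        correct_rejections=int(np.sum(~labels & ~resp)),
    )


def score_sfg_session(
    is_figure: Sequence[bool],
    said_yes: Sequence[bool],
    correction: str = "loglinear",
) -> tuple[YesNoCounts, float]:
    """Score a figure-detection session: 2x2 table plus d'."""
    counts = tabulate_yes_no(is_figure, said_yes)
    return counts, dprime_yes_no(counts, correction=correction)
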