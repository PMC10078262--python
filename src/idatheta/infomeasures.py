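"""Trial-level information measures over movement sequences.

Two quantities are computed for every retained trial of a categorical
amplitude stream:

*Surprise* — Shannon information of the observed movement under a
sequential Dirichlet-multinomial observer,

    I_t = -log2 p(x_t | x_1..x_{t-1}, alpha),
    p(x | X, alpha) = (k_x(X) + alpha_x) / (|X| + sum(alpha)),

with the unbiased prior alpha = [1, 1] by default: before any evidence,
normal- and high-amplitude movements are equally likely, and each
pseudo-count weighs like one past observation.

*Local redundancy* — a log-factorial count statistic over a moving window
of the last N trials (N = 6 by default),

    R_N = ln(k_normal!) + ln(k_high!),

maximal when the window is pure (low complexity) and minimal when it is
balanced.  High redundancy means the recent stimulus stream was repetitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import AMPLITUDE_LABELS, MovementSequence

DEFAULT_WINDOW = 6


@dataclass(frozen=True)
class PriorSpec:
    """Dirichlet pseudo-counts, one per amplitude label."""

    alpha: Mapping[str, float] = field(
        default_factory=lambda: {"normal": 1.0, "high": 1.0})

    def __post_init__(self) -> None:
        if not self.alpha or any(a <= 0 for a in self.alpha.values()):
            raise ValueError("all Dirichlet pseudo-counts must be positive")

    @property
    def total(self) -> float:
        return float(sum(self.alpha.values()))


def predictive_probability(history: Sequence[str], next_label: str,
                           prior: PriorSpec | None = None) -> float:
    """Posterior-predictive probability of the next movement label.

    Returns (count of next_label in history + alpha_label) divided by
    (len(history) + sum of alphas); strictly inside (0, 1).
    """
    prior = prior or PriorSpec()
    if next_label not in prior.alpha:
        raise ValueError(f"label {next_label!r} outside alphabet {set(prior.alpha)}")
    unknown = set(history) - set(prior.alpha)
    if unknown:
        raise ValueError(f"history contains labels outside alphabet: {sorted(unknown)}")
    k = sum(1 for h in history if h == next_label)
    return (k + prior.alpha[next_label]) / (len(history) + prior.total)


def surprise(history: Sequence[str], next_label: str,
             prior: PriorSpec | None = None) -> float:
    """Shannon information (bits) of observing ``next_label`` after ``history``."""
    return float(-np.log2(predictive_probability(history, next_label, prior)))


def local_redundancy(sequence: Sequence[str], t: int,
                     window: int = DEFAULT_WINDOW) -> float:
    """ln(k_normal!) + ln(k_high!) over the last min(t, window) trials.

    ``t`` is the 1-based trial index; the window ends at and includes trial
    ``t``.  Early trials use the growing window of all available trials.
    """
    if not 1 <= t <= len(sequence):
        raise ValueError(f"trial index {t} out of range 1..{len(sequence)}")
    if window < 1:
        raise ValueError("window must be positive")
    recent = sequence[max(0, t - window):t]
    return float(sum(
        gammaln(sum(1 for r in recent if r == lab) + 1)
        for lab in AMPLITUDE_LABELS))


def build_predictor_table(sequences: Mapping[str, MovementSequence],
                          prior: PriorSpec | None = None,
                          window: int = DEFAULT_WINDOW,
                          unseen_updates_history: bool = False) -> pd.DataFrame:
    """Per-trial predictor table over all conditions of one subject.

    Each condition's stream is processed independently, treating its trials
    as consecutive events.  By default trials the infant did not look at
    are removed from the observed stream *before* computing the
    history-dependent measures (the observer model only sees what the
    infant saw); set ``unseen_updates_history=True`` to let unseen trials
    update the observer's counts while still being dropped from the output.

    The first retained trial of the variable condition carries no
    information about the movement variability and is flagged
    ``included=False``; z-scored columns (mean 0, sd 1) are computed over
    included rows only.

    Columns: condition, trial_overall, label, surprise_bits,
    local_redundancy, k_normal, k_high, included, z_surprise, z_trialnum,
    z_redundancy.
    """
    prior = prior or PriorSpec()
    rows = []
    for condition, seq in sequences.items():
        looked_idx = [i for i in range(len(seq)) if seq.looked[i]]
        if not looked_idx:
            raise ValueError(f"no retained trials in condition {condition!r}")
        if unseen_updates_history:
            stream = list(seq.labels)
            positions = looked_idx
            full = stream
        else:
            stream = [seq.labels[i] for i in looked_idx]
            positions = list(range(len(stream)))
            full = stream
        for out_rank, (orig_i, pos) in enumerate(zip(looked_idx, positions)):
            lab = full[pos]
            p = predictive_probability(full[:pos], lab, prior)
            window_slice = full[max(0, pos + 1 - window):pos + 1]
            k_n = window_slice.count("normal")
            k_h = window_slice.count("high")
            rows.append({
                "condition": condition,
                "trial_overall": orig_i + 1,
                "label": lab,
                "surprise_bits": float(-np.log2(p)),
                "local_redundancy": float(gammaln(k_n + 1) + gammaln(k_h + 1)),
                "k_normal": k_n,
                "k_high": k_h,
                "included": not (condition == "variable" and out_rank == 0),
            })
    table = pd.DataFrame(rows)
    inc = table["included"]
    for col, z in (("surprise_bits", "z_surprise"),
                   ("trial_overall", "z_trialnum"),
                   ("local_redundancy", "z_redundancy")):
        vals = table.loc[inc, col].astype(float)
        sd = vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"cannot z-score constant column {col!r}")
        table[z] = np.nan
        table.loc[inc, z] = (vals - vals.mean()) / sd
    return table
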