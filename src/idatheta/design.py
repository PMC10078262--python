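"""Experimental design: movement-amplitude sequences and counterbalancing.

Infants watch an avatar demonstrate object-directed actions in three
within-subject conditions.  In the *normal* and *high* conditions every
goal-directed movement has the same amplitude; in the *variable* condition
normal- and high-amplitude movements are interleaved.  Each condition is
shown as 4 blocks of one 5-movement video, i.e. 20 movements per condition.
Which action (balls, cups, rings) appears in which condition is
counterbalanced across participants with a Latin-square rotation over the
six possible assignments.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("normal", "high", "variable")
AMPLITUDE_LABELS = ("normal", "high")
ACTIONS = ("balls", "cups", "rings")


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the demonstration-phase design.

    Defaults reproduce the published design: 4 blocks x 5 movements = 20
    goal-directed movements per condition, three conditions, four distinct
    pseudo-randomized orders for the variable condition.
    """

    n_blocks: int = 4
    movements_per_video: int = 5
    conditions: tuple[str, ...] = CONDITIONS
    n_variable_orders: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.movements_per_video < 1:
            raise ValueError("n_blocks and movements_per_video must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be distinct labels")
        if self.n_variable_orders < 1:
            raise ValueError("n_variable_orders must be positive")

    @property
    def n_trials(self) -> int:
        """Total movements per condition (20 with default values)."""
        return self.n_blocks * self.movements_per_video


@dataclass
class MovementSequence:
    """One condition's ordered amplitude-label stream with attention mask.

    ``looked[i]`` is False for trials on which the infant looked away;
    those trials are dropped before any history-dependent measure is
    computed downstream.
    """

    condition: str
    labels: list[str]
    looked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.looked is None:
            self.looked = np.ones(len(self.labels), dtype=bool)
        self.looked = np.asarray(self.looked, dtype=bool)
        if len(self.looked) != len(self.labels):
            raise ValueError("looked mask must match sequence length")
        bad = set(self.labels) - set(AMPLITUDE_LABELS)
        if bad:
            raise ValueError(f"unknown amplitude labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


def _variable_video_order(rng: np.random.Generator, m: int) -> list[str]:
    # Rejection-sample a within-video order: each label 2 or 3 times out of
    # 5 (generalised: counts differ by at most 1) and no run longer than 2.
    lo = m // 2
    counts = (lo, m - lo)
    while True:
        k_normal = int(rng.choice(counts))
        order = ["normal"] * k_normal + ["high"] * (m - k_normal)
        rng.shuffle(order)
        if _max_run(order) <= 2:
            return order


def _max_run(labels: list[str]) -> int:
    longest = run = 1
    for a, b in zip(labels, labels[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest


def generate_condition_sequence(config: DesignConfig, condition: str,
                                order_index: int = 0) -> MovementSequence:
    """Generate the amplitude-label stream for one condition.

    Constant conditions repeat their label for all trials.  The variable
    condition concatenates per-video pseudo-random orders in which each
    label occurs at least twice and no more than two identical labels run
    consecutively (consistent with the published example order
    normal, high, normal, high, high).  ``order_index`` selects one of the
    ``config.n_variable_orders`` counterbalanced variable orders.

    Deterministic given (config.seed, condition, order_index).
    """
    if condition not in config.conditions:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {config.conditions}")
    n = config.n_trials
    if condition in ("normal", "high"):
        return MovementSequence(condition, [condition] * n)
    rng = np.random.default_rng(
        [config.seed % (2**31), zlib.crc32(condition.encode()),
         order_index % config.n_variable_orders])
    labels: list[str] = []
    for _ in range(config.n_blocks):
        labels.extend(_variable_video_order(rng, config.movements_per_video))
    return MovementSequence(condition, labels)


def is_valid_variable_order(labels: list[str], movements_per_video: int = 5) -> bool:
    """Check the variable-order constraints on a label stream.

    Every consecutive video of ``movements_per_video`` labels must contain
    each amplitude label at least twice, and no run of identical labels may
    exceed two.
    """
    m = movements_per_video
    if len(labels) % m:
        return False
    for i in range(0, len(labels), m):
        video = labels[i:i + m]
        if any(video.count(lab) < m // 2 for lab in AMPLITUDE_LABELS):
            return False
        if _max_run(video) > 2:
            return False
    return True


def assign_counterbalancing(n_subjects: int, actions: tuple[str, ...] = ACTIONS,
                            seed: int = 0) -> list[dict[str, str]]:
    """Assign each subject a bijection action -> condition.

    The six possible bijections of three actions onto three conditions are
    cycled in a seeded Latin-square rotation, so across subjects they occur
    as uniformly as ``n_subjects`` allows (n=6 -> each exactly once,
    n=12 -> each exactly twice).
    """
    if len(actions) != 3 or len(set(actions)) != 3:
        raise ValueError("exactly three distinct actions are required")
    perms = list(itertools.permutations(CONDITIONS))
    rng = np.random.default_rng(seed % (2**31))
    rng.shuffle(perms)
    offset = int(rng.integers(6))
    return [
        dict(zip(actions, perms[(offset + i) % 6]))
        for i in range(n_subjects)
    ]


def design_frame(config: DesignConfig, subject_ids: list[str] | None = None,
                 n_subjects: int = 1) -> pd.DataFrame:
    """Tabulate the full design as one row per subject x condition x trial.

    Columns: subject_id, condition, action, block, trial_in_block,
    trial_overall, amplitude_label.
    """
    if subject_ids is None:
        subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    mappings = assign_counterbalancing(len(subject_ids), seed=config.seed)
    rows = []
    m = config.movements_per_video
    for s_idx, (sid, mapping) in enumerate(zip(subject_ids, mappings)):
        cond_to_action = {v: k for k, v in mapping.items()}
        for condition in config.conditions:
            seq = generate_condition_sequence(
                config, condition, order_index=s_idx % config.n_variable_orders)
            for t, lab in enumerate(seq.labels, start=1):
                rows.append({
                    "subject_id": sid,
                    "condition": condition,
                    "action": cond_to_action.get(condition, ""),
                    "block": (t - 1) // m + 1,
                    "trial_in_block": (t - 1) % m + 1,
                    "trial_overall": t,
                    "amplitude_label": lab,
                })
    return pd.DataFrame(rows)
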