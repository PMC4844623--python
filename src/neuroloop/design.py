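"""Block-design generation for bidirectional ROI-regulation neurofeedback runs.

A run is a sequence of 12-TR blocks: an opening rest block followed by
``n_per_condition`` blocks each of UP-regulation, DOWN-regulation, and REST,
pseudo-randomized so that consecutive blocks always differ in condition and
every ordered transition type (UP->DOWN, UP->REST, DOWN->UP, DOWN->REST,
REST->UP, REST->DOWN) occurs equally often.  For the end-of-block feedback
(EoBF) variant, a 2-TR feedback-display window is appended after every block.

Regulation direction (UP/DOWN) is what the subject is asked to do to the ROI
signal; which *screen* direction (left/right arrow) cues it is decided by a
counterbalanced :class:`DirectionMapping` whose only analytical consequence is
the sign of the displayed feedback value.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BLOCK_TRS = 12
EOBF_DISPLAY_TRS = 2

#: label used for EoBF feedback-display TRs in per-volume timelines
DISPLAY_LABEL = "DISPLAY"


class Condition(str, enum.Enum):
    """Regulation condition of a block."""

    UP = "UP"
    DOWN = "DOWN"
    REST = "REST"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FeedbackType(str, enum.Enum):
    """How feedback is presented during a run.

    CF: the dot display is updated every TR.
    EOBF: dots are shown only during a 2-TR window after each block.
    NONE: transfer run, no feedback at all.
    """

    CF = "CF"
    EOBF = "EoBF"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


REGULATION_CONDITIONS = (Condition.UP, Condition.DOWN)
ALL_CONDITIONS = (Condition.UP, Condition.DOWN, Condition.REST)
#: the six ordered transition types between distinct conditions
TRANSITION_TYPES = tuple(
    (a, b) for a in ALL_CONDITIONS for b in ALL_CONDITIONS if a is not b
)


class ScheduleError(ValueError):
    """Raised when a balanced schedule cannot be constructed."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Multi-echo EPI acquisition parameters.

    Defaults are the study protocol: TR 2.54 s, six echoes at
    8.6-57 ms, and an assumed ROI T2* of 30 ms.
    """

    tr_seconds: float = 2.54
    echo_times_ms: tuple[float, ...] = (8.6, 18.3, 28.0, 38.0, 48.0, 57.0)
    t2star_ms: float = 30.0
    volumes_per_run: int | None = None

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        tes = np.asarray(self.echo_times_ms, dtype=float)
        if tes.size == 0 or np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
            raise ValueError("echo_times_ms must be positive and strictly increasing")
        if self.t2star_ms <= 0:
            raise ValueError("t2star_ms must be positive")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)


@dataclass(frozen=True)
class DirectionMapping:
    """Counterbalanced assignment of screen side to regulation direction.

    ``sign`` is the factor applied to the scaled ROI signal before display
    under the convention that a positive displayed value moves the dots to
    the *right* edge of the screen.  If "left" means DOWN-regulation, then
    up-regulation must move the dots right, so sign = +1; if "left" means
    UP, sign = -1.
    """

    left_means: Condition = Condition.UP

    def __post_init__(self) -> None:
        if self.left_means not in REGULATION_CONDITIONS:
            raise ValueError("left_means must be UP or DOWN")

    @property
    def sign(self) -> int:
        return 1 if self.left_means is Condition.DOWN else -1

    @property
    def right_means(self) -> Condition:
        return (
            Condition.DOWN if self.left_means is Condition.UP else Condition.UP
        )

    def screen_side(self, condition: Condition) -> str:
        """Screen side ('LEFT'/'RIGHT'/'REST') cueing a regulation condition."""
        if condition is Condition.REST:
            return "REST"
        return "LEFT" if condition is self.left_means else "RIGHT"

    def flipped(self) -> "DirectionMapping":
        return DirectionMapping(left_means=self.right_means)


def assign_direction_mapping(subject_index: int) -> DirectionMapping:
    """Deterministic, exactly balanced mapping assignment by enrollment index.

    Even indices get LEFT=UP, odd indices LEFT=DOWN, so any even-sized
    cohort splits half/half.
    """
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    return DirectionMapping(
        left_means=Condition.UP if subject_index % 2 == 0 else Condition.DOWN
    )


@dataclass(frozen=True)
class BlockSchedule:
    """An ordered run of condition blocks plus display semantics."""

    blocks: tuple[tuple[Condition, int], ...]
    feedback_type: FeedbackType = FeedbackType.CF
    mapping: DirectionMapping = field(default_factory=DirectionMapping)

    @property
    def display_trs_per_block(self) -> int:
        return EOBF_DISPLAY_TRS if self.feedback_type is FeedbackType.EOBF else 0

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_volumes(self) -> int:
        return sum(trs + self.display_trs_per_block for _, trs in self.blocks)

    @property
    def conditions(self) -> tuple[Condition, ...]:
        return tuple(c for c, _ in self.blocks)

    def with_mapping(self, mapping: DirectionMapping) -> "BlockSchedule":
        return replace(self, mapping=mapping)

    def with_feedback_type(self, feedback_type: FeedbackType) -> "BlockSchedule":
        return replace(self, feedback_type=feedback_type)

    def volume_labels(self) -> list[str]:
        """Per-volume labels: 'UP'/'DOWN'/'REST' plus 'DISPLAY' for EoBF windows."""
        labels: list[str] = []
        for cond, trs in self.blocks:
            labels.extend([cond.value] * trs)
            labels.extend([DISPLAY_LABEL] * self.display_trs_per_block)
        return labels

    def to_frame(self, tr_seconds: float = 2.54) -> pd.DataFrame:
        """Block table with onsets in seconds, one row per block/display window."""
        rows = []
        onset = 0.0
        for cond, trs in self.blocks:
            rows.append(
                {
                    "onset_s": onset,
                    "duration_s": trs * tr_seconds,
                    "condition": self.mapping.screen_side(cond),
                    "regulation": cond.value,
                }
            )
            onset += trs * tr_seconds
            if self.display_trs_per_block:
                rows.append(
                    {
                        "onset_s": onset,
                        "duration_s": self.display_trs_per_block * tr_seconds,
                        "condition": DISPLAY_LABEL,
                        "regulation": DISPLAY_LABEL,
                    }
                )
                onset += self.display_trs_per_block * tr_seconds
        return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Outcome of checking a schedule against the balance constraints."""

    transition_counts: dict[tuple[Condition, Condition], int]
    condition_counts: dict[Condition, int]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_schedule(schedule: BlockSchedule) -> ValidationReport:
    """Report per-transition and per-condition counts and any constraint breaches.

    Never raises: a schedule that breaks the design rules yields a report
    whose ``violations`` list names each breach.
    """
    conds = schedule.conditions
    violations: list[str] = []
    transition_counts = {t: 0 for t in TRANSITION_TYPES}
    condition_counts = {c: 0 for c in ALL_CONDITIONS}

    for c in conds:
        condition_counts[c] += 1
    for a, b in zip(conds, conds[1:]):
        if a is b:
            violations.append(f"condition repeat: {a.value}->{b.value}")
        else:
            transition_counts[(a, b)] += 1

    if not conds:
        violations.append("empty schedule")
        return ValidationReport(transition_counts, condition_counts, violations)

    if conds[0] is not Condition.REST:
        violations.append("first block is not REST")

    for cond, trs in schedule.blocks:
        if trs != BLOCK_TRS:
            violations.append(f"block length {trs} != {BLOCK_TRS} TRs ({cond.value})")

    # excluding the obligatory initial rest block, all conditions must occur
    # equally often
    n_up = condition_counts[Condition.UP]
    n_down = condition_counts[Condition.DOWN]
    n_rest = condition_counts[Condition.REST] - (1 if conds[0] is Condition.REST else 0)
    if not (n_up == n_down == n_rest):
        violations.append(
            f"unbalanced condition counts (UP={n_up}, DOWN={n_down}, REST={n_rest})"
        )
    n = n_up
    if n % 2 == 0 and n_up == n_down == n_rest:
        expected = n // 2
        for t, count in transition_counts.items():
            if count != expected:
                violations.append(
                    f"transition {t[0].value}->{t[1].value} occurs {count} times,"
                    f" expected {expected}"
                )
    return ValidationReport(transition_counts, condition_counts, violations)


def generate_schedule(
    n_per_condition: int,
    feedback_type: FeedbackType | str = FeedbackType.CF,
    seed: int = 0,
    mapping: DirectionMapping | None = None,
    max_retries: int = 100,
) -> BlockSchedule:
    """Sample a transition-balanced pseudo-random block order.

    Backtracking search over condition sequences: starting from the initial
    REST block, each ordered transition type carries a remaining-use budget of
    ``n_per_condition / 2``; feasible next conditions are tried in uniformly
    shuffled order and exhausted budgets force backtracking.  The search is
    complete, so ``max_retries`` is a safety bound that is never reached for
    feasible (even) ``n_per_condition``.

    Parameters
    ----------
    n_per_condition:
        Number of blocks per condition after the initial rest block.  Must be
        even: with 3n transitions spread over 6 ordered types, exact balance
        requires n/2 occurrences of each.
    """
    feedback_type = FeedbackType(feedback_type)
    if mapping is None:
        mapping = DirectionMapping()
    if n_per_condition < 0:
        raise ScheduleError("n_per_condition must be >= 0")
    if n_per_condition % 2 != 0:
        raise ScheduleError(
            f"n_per_condition={n_per_condition} is odd: 3n transitions cannot be"
            " split equally over the 6 ordered transition types"
        )
    if n_per_condition == 0:
        return BlockSchedule(
            blocks=((Condition.REST, BLOCK_TRS),),
            feedback_type=feedback_type,
            mapping=mapping,
        )

    rng = random.Random(seed)
    budget_each = n_per_condition // 2
    total = 3 * n_per_condition

    for _ in range(max_retries):
        need = {t: budget_each for t in TRANSITION_TYPES}
        seq: list[Condition] = [Condition.REST]
        if _extend(seq, need, total, rng):
            blocks = tuple((c, BLOCK_TRS) for c in seq)
            return BlockSchedule(blocks=blocks, feedback_type=feedback_type, mapping=mapping)
    raise ScheduleError(
        f"no balanced schedule found for n_per_condition={n_per_condition}"
        f" after {max_retries} retries"
    )


def _extend(
    seq: list[Condition],
    need: dict[tuple[Condition, Condition], int],
    total: int,
    rng: random.Random,
) -> bool:
    if len(seq) == total + 1:
        return True
    cur = seq[-1]
    candidates = [c for c in ALL_CONDITIONS if c is not cur and need[(cur, c)] > 0]
    rng.shuffle(candidates)
    for c in candidates:
        need[(cur, c)] -= 1
        seq.append(c)
        if _extend(seq, need, total, rng):
            return True
        seq.pop()
        need[(cur, c)] += 1
    return False


def run_duration(schedule: BlockSchedule, acq: AcquisitionParams) -> float:
    """Total run duration in seconds, including EoBF display windows."""
    return schedule.n_volumes * acq.tr_seconds
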