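"""Deterministic 1 Hz state machine for a threshold-based attention game.

The game reads a scalar attention meter (integer 0-100, one sample per
second, as emitted by single-channel consumer EEG headsets) and drives a
five-level progression: each second the player is classified attentive or
inattentive against a fixed meter threshold, earning or losing points on
the current level's score.  A level is cleared when its score reaches the
level target; clearing the last level finishes the session.  Sessions are
capped (default five minutes); a session that does not clear the last
level by the cap is a timeout.

Level difficulty increases: gains shrink and penalties grow with the level
index, so later levels demand longer sustained attention.  The default
schedule gives per-level perfect-play times of 5, 9, 14, 20 and 70 s
(118 s total) for a player whose meter is pinned at 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LevelParams",
    "GameConfig",
    "GameState",
    "SessionLog",
    "default_config",
    "classify_attentive",
    "step",
    "run_session",
    "perfect_play_times",
    "per_level_mean_attention",
    "EVENT_TICK",
    "EVENT_LEVEL_UP",
    "EVENT_FINISHED",
    "EVENT_TIMEOUT",
]

METER_MIN = 0
METER_MAX = 100

EVENT_TICK = "tick"
EVENT_LEVEL_UP = "level_up"
EVENT_FINISHED = "finished"
EVENT_TIMEOUT = "timeout"

#: Points added per attentive second, levels 0-4.
DEFAULT_GAINS = (18, 16, 14, 12, 10)
#: Points subtracted per inattentive second, levels 0-4.
DEFAULT_PENALTIES = (2, 3, 4, 5, 6)
#: Points required to clear each level (gain x perfect-play seconds).
DEFAULT_TARGETS = (90, 144, 196, 240, 700)


@dataclass(frozen=True)
class LevelParams:
    """Scoring schedule of one difficulty level.

    Parameters
    ----------
    gain
        Points added to the level score per attentive second (> 0).
    penalty
        Points subtracted per inattentive second, given as a positive
        magnitude (> 0).
    target
        Points required to clear the level (> 0).
    """

    gain: int
    penalty: int
    target: int

    def __post_init__(self) -> None:
        for name in ("gain", "penalty", "target"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"LevelParams.{name} must be an integer, got {v!r}")
            if v <= 0:
                raise ValueError(f"LevelParams.{name} must be positive, got {v}")


@dataclass(frozen=True)
class GameConfig:
    """Full game configuration: level schedule, threshold and session cap."""

    levels: tuple[LevelParams, ...]
    attentive_threshold: int = 50
    tick_seconds: int = 1
    max_session_seconds: int = 300

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("GameConfig needs at least one level")
        object.__setattr__(self, "levels", tuple(self.levels))
        if not (METER_MIN <= self.attentive_threshold <= METER_MAX):
            raise ValueError(
                f"attentive_threshold must lie in the meter range "
                f"[{METER_MIN}, {METER_MAX}], got {self.attentive_threshold}"
            )
        if self.tick_seconds < 1:
            raise ValueError("tick_seconds must be >= 1")
        minimal = sum(math.ceil(lp.target / lp.gain) for lp in self.levels)
        if self.max_session_seconds < minimal:
            raise ValueError(
                f"max_session_seconds={self.max_session_seconds} is shorter than "
                f"the minimal completion time {minimal} s of this level schedule"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def default_config() -> GameConfig:
    """The reference five-level configuration (threshold 50, 300 s cap)."""
    levels = tuple(
        LevelParams(gain=g, penalty=p, target=t)
        for g, p, t in zip(DEFAULT_GAINS, DEFAULT_PENALTIES, DEFAULT_TARGETS)
    )
    return GameConfig(levels=levels)


@dataclass(frozen=True)
class GameState:
    """Immutable snapshot of a running session."""

    level: int = 0
    level_score: int = 0
    elapsed_seconds: int = 0
    finished: bool = False
    entry_times: tuple[int, ...] = (0,)  # second at which each level was entered


def classify_attentive(attention: int, threshold: int = 50) -> bool:
    """True iff the meter value counts as attentive (``attention >= threshold``).

    The meter value 50 itself is attentive under the default threshold; the
    meter splits into an attentive upper half (50-100) and an inattentive
    lower half (0-49).
    """
    if not (METER_MIN <= attention <= METER_MAX):
        raise ValueError(
            f"attention meter value must lie in [{METER_MIN}, {METER_MAX}], "
            f"got {attention}"
        )
    return attention >= threshold


def step(state: GameState, attention: int, config: GameConfig) -> GameState:
    """Advance the session by one tick given one attention sample.

    The current level's score moves by +gain (attentive) or -penalty
    (inattentive), floored at zero.  Reaching the level target clears the
    level: the score resets to zero and the level index advances, or the
    session finishes if it was the last level.  Reaching the session cap
    without finishing leaves the state unfinished (a timeout).
    """
    if state.finished:
        raise RuntimeError("cannot step a finished session")
    if state.elapsed_seconds >= config.max_session_seconds:
        raise RuntimeError("cannot step a session past its time cap")
    classify_attentive(attention, config.attentive_threshold)  # range check
    lp = config.levels[state.level]
    attentive = attention >= config.attentive_threshold
    raw = state.level_score + (lp.gain if attentive else -lp.penalty)
    new_score = max(0, raw)
    elapsed = state.elapsed_seconds + 1
    if new_score >= lp.target:
        if state.level == config.n_levels - 1:
            return replace(
                state,
                level_score=lp.target,
                elapsed_seconds=elapsed,
                finished=True,
            )
        return GameState(
            level=state.level + 1,
            level_score=0,
            elapsed_seconds=elapsed,
            finished=False,
            entry_times=state.entry_times + (elapsed,),
        )
    return replace(state, level_score=new_score, elapsed_seconds=elapsed)


@dataclass
class SessionLog:
    """Columnar per-second trace of one play-through.

    One record per consumed tick: the 0-based second, the attention sample,
    the level being played during that tick, the level score after the tick
    (clamped at the level target on the clearing tick) and an event label
    (``tick``, ``level_up``, ``finished`` or ``timeout``).  The final record
    carries ``finished`` exactly when the session cleared the last level;
    otherwise it carries ``timeout``.
    """

    second: np.ndarray
    attention: np.ndarray
    level: np.ndarray
    level_score: np.ndarray
    event: np.ndarray
    meditation: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.second)

    @property
    def completed(self) -> bool:
        return len(self) > 0 and self.event[-1] == EVENT_FINISHED

    @property
    def duration_seconds(self) -> int:
        return int(self.second[-1]) + 1

    def level_up_seconds(self) -> np.ndarray:
        """Seconds (0-based record index) at which a level was cleared,
        including the final clearing of the last level."""
        mask = (self.event == EVENT_LEVEL_UP) | (self.event == EVENT_FINISHED)
        if self.event[-1] == EVENT_FINISHED:
            return self.second[mask]
        return self.second[(self.event == EVENT_LEVEL_UP)]

    def level_durations(self) -> dict[int, int]:
        """Seconds spent in each level actually entered."""
        levels, counts = np.unique(self.level, return_counts=True)
        return {int(l): int(c) for l, c in zip(levels, counts)}

    def to_frame(self):
        """Session log as a pandas DataFrame in the CSV column order."""
        import pandas as pd

        med = (
            self.meditation
            if self.meditation is not None
            else np.full(len(self), np.nan)
        )
        return pd.DataFrame(
            {
                "second": self.second,
                "attention": self.attention,
                "meditation": med,
                "level": self.level,
                "level_score": self.level_score,
                "event": self.event,
            }
        )

    def validate(self) -> None:
        """Check internal invariants; raise ValueError on violation."""
        n = len(self)
        if n == 0:
            raise ValueError("empty session log")
        if np.any(np.diff(self.second) != 1):
            raise ValueError("seconds must increase by one tick per record")
        if np.any(np.diff(self.level) < 0):
            raise ValueError("level must be non-decreasing")
        if np.any((self.attention < METER_MIN) | (self.attention > METER_MAX)):
            raise ValueError("attention values out of meter range")
        terminal = np.isin(self.event, (EVENT_FINISHED, EVENT_TIMEOUT))
        if terminal.sum() != 1 or not terminal[-1]:
            raise ValueError("log must end with exactly one finished/timeout event")


def run_session(
    stream: Sequence[int] | Iterable[int],
    config: GameConfig,
    meditation: Sequence[int] | None = None,
) -> SessionLog:
    """Play a full session from an ordered attention stream.

    Consumes one sample per tick until the last level is cleared or the
    session cap is reached; surplus samples are ignored.  A stream that
    runs out before the session finishes ends the session as a timeout.

    The implementation is vectorised per level: within a level the score
    follows a Lindley recursion (a random walk reflected at zero), so the
    clearing tick is the first crossing of the level target by
    ``cumsum(deltas) - min(0, running_min(cumsum(deltas)))``.  It is
    tick-for-tick identical to iterating :func:`step`.
    """
    att = np.asarray(list(stream) if not isinstance(stream, np.ndarray) else stream)
    if att.size == 0:
        raise ValueError("attention stream is empty")
    if not np.issubdtype(att.dtype, np.number):
        raise TypeError("attention stream must be numeric")
    if np.any((att < METER_MIN) | (att > METER_MAX)):
        raise ValueError(f"attention values must lie in [{METER_MIN}, {METER_MAX}]")
    att = att.astype(np.int64)

    n = min(att.size, config.max_session_seconds)
    attentive = att[:n] >= config.attentive_threshold

    level_col = np.empty(n, dtype=np.int64)
    score_col = np.empty(n, dtype=np.int64)
    event_col = np.full(n, EVENT_TICK, dtype=object)

    pos = 0
    finished = False
    for li, lp in enumerate(config.levels):
        if pos >= n:
            break
        delta = np.where(attentive[pos:n], lp.gain, -lp.penalty)
        cum = np.cumsum(delta)
        running = cum - np.minimum(np.minimum.accumulate(cum), 0)
        crossing = np.nonzero(running >= lp.target)[0]
        if crossing.size == 0:  # level never cleared: rest of session here
            level_col[pos:n] = li
            score_col[pos:n] = running
            pos = n
            break
        k = int(crossing[0])
        level_col[pos : pos + k + 1] = li
        score_col[pos : pos + k] = running[:k]
        score_col[pos + k] = lp.target
        if li == config.n_levels - 1:
            event_col[pos + k] = EVENT_FINISHED
            finished = True
            pos = pos + k + 1
            break
        event_col[pos + k] = EVENT_LEVEL_UP
        pos = pos + k + 1

    n_used = pos
    level_col = level_col[:n_used]
    score_col = score_col[:n_used]
    event_col = event_col[:n_used]
    if not finished:
        # session ended by cap or stream exhaustion without clearing the game
        event_col[-1] = EVENT_TIMEOUT

    med_col = None
    if meditation is not None:
        med = np.asarray(meditation, dtype=float)
        med_col = med[:n_used]

    return SessionLog(
        second=np.arange(n_used, dtype=np.int64),
        attention=att[:n_used],
        level=level_col,
        level_score=score_col,
        event=event_col,
        meditation=med_col,
    )


def perfect_play_times(config: GameConfig) -> list[int]:
    """Seconds per level for a constantly-attentive player.

    For each level this is the smallest tick count ``t`` with
    ``t * gain >= target``; it agrees exactly with :func:`run_session` on a
    constant maximal-attention stream.
    """
    return [math.ceil(lp.target / lp.gain) for lp in config.levels]


def per_level_mean_attention(log: SessionLog) -> dict[int, float]:
    """Arithmetic mean of the attention samples recorded in each level.

    Only levels actually entered appear as keys; a level never reached is
    absent, never reported as zero.
    """
    if len(log) == 0:
        raise ValueError("empty session log")
    levels = log.level
    sums = np.bincount(levels, weights=log.attention)
    counts = np.bincount(levels)
    return {
        int(l): float(sums[l] / counts[l]) for l in np.nonzero(counts)[0]
    }
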