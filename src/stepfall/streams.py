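"""Step-event streams, walking-bout segmentation and trimming.

The upstream contract of this package is a placement-agnostic step detector:
all that reaches us per participant is an ordered sequence of step-event
timestamps (seconds from recording start). Steps are grouped into *walking
bouts* wherever consecutive events are separated by less than a gap
threshold (default 2 s); only bouts longer than a minimum raw step count
(default 200, i.e. roughly two minutes of continuous walking) are analysed,
and the first and last 5 steps of each kept bout are discarded to remove
gait initiation and termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StepEventSeries",
    "WalkingBout",
    "OutcomeRecord",
    "Bouts",
    "StepStreamError",
    "UndefinedWindowError",
    "load_step_events",
    "load_outcomes",
    "segment_bouts",
    "extract_middle200",
]


class StepStreamError(ValueError):
    """Malformed or invalid step-event data."""


class UndefinedWindowError(ValueError):
    """Requested analysis window is undefined for this bout."""


@dataclass(frozen=True)
class StepEventSeries:
    """One participant's ordered step-event timestamps (seconds).

    Timestamps must be strictly increasing and non-negative; an empty
    series is valid (the participant simply contributes no bouts).
    """

    participant_id: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1:
            raise StepStreamError(f"{self.participant_id}: timestamps must be 1-D")
        if ts.size and ts[0] < 0:
            raise StepStreamError(f"{self.participant_id}: negative timestamp {ts[0]}")
        if ts.size > 1:
            diffs = np.diff(ts)
            bad = np.flatnonzero(diffs <= 0)
            if bad.size:
                i = bad[0]
                kind = "duplicate" if diffs[i] == 0 else "non-monotone"
                raise StepStreamError(
                    f"{self.participant_id}: {kind} timestamp at t={ts[i + 1]:g} s"
                )

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass(frozen=True)
class WalkingBout:
    """A gap-delimited run of steps, trimmed at both ends.

    ``raw_steps`` holds every timestamp in the run; ``retained_steps``
    drops ``trim`` steps at each end. Step intervals are successive
    differences of the retained steps; stride intervals span two steps
    (non-overlapping by default, since an unlabeled step detector cannot
    assign feet).
    """

    raw_steps: np.ndarray
    trim: int = 5

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_steps, dtype=float)
        object.__setattr__(self, "raw_steps", raw)
        if raw.size <= 2 * self.trim:
            raise StepStreamError(
                f"bout of {raw.size} steps cannot be trimmed by {self.trim} per end"
            )

    @property
    def retained_steps(self) -> np.ndarray:
        return self.raw_steps[self.trim : self.raw_steps.size - self.trim]

    @property
    def n_retained(self) -> int:
        return self.raw_steps.size - 2 * self.trim

    @property
    def start(self) -> float:
        return float(self.raw_steps[0])

    @property
    def duration(self) -> float:
        return float(self.raw_steps[-1] - self.raw_steps[0])

    @property
    def step_intervals(self) -> np.ndarray:
        return np.diff(self.retained_steps)

    def stride_intervals(self, overlapping: bool = False) -> np.ndarray:
        """Two-step spans of the retained steps.

        Non-overlapping (default): ``t[2k+2] - t[2k]`` starting at the first
        retained step, dropping a trailing unpaired step interval.
        Overlapping: ``t[k+2] - t[k]`` for every k.
        """
        t = self.retained_steps
        if overlapping:
            return t[2:] - t[:-2]
        n_pairs = (t.size - 1) // 2
        idx = 2 * np.arange(n_pairs)
        return t[idx + 2] - t[idx]

    @property
    def complexity_defined(self) -> bool:
        return self.n_retained >= 200

    @property
    def middle200_steps(self) -> np.ndarray:
        return extract_middle200(self)


@dataclass(frozen=True)
class OutcomeRecord:
    """Prospective 12-month fall outcome for one participant."""

    participant_id: str
    group: int
    fall_count: int

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise StepStreamError(
                f"{self.participant_id}: group must be 0 or 1, got {self.group}"
            )
        if self.fall_count < 0:
            raise StepStreamError(
                f"{self.participant_id}: negative fall count {self.fall_count}"
            )

    @property
    def faller(self) -> bool:
        return self.fall_count >= 1


@dataclass
class Bouts(Sequence):
    """Ordered kept bouts of one participant plus the discard tally."""

    participant_id: str
    bouts: list[WalkingBout] = field(default_factory=list)
    n_discarded_runs: int = 0
    n_discarded_steps: int = 0

    def __len__(self) -> int:
        return len(self.bouts)

    def __getitem__(self, i):
        return self.bouts[i]

    def __iter__(self) -> Iterator[WalkingBout]:
        return iter(self.bouts)


def load_step_events(path, dialect: dict | None = None) -> list[StepEventSeries]:
    """Read a step-event table (CSV with header ``participant_id,time_s``).

    One file may hold many participants. Timestamps are sorted per
    participant before validation; duplicates raise with the participant
    and offending time named.
    """
    dialect = dialect or {}
    id_col = dialect.get("id_col", "participant_id")
    time_col = dialect.get("time_col", "time_s")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise StepStreamError(f"{path}: malformed event table: {exc}") from exc
    for col in (id_col, time_col):
        if col not in df.columns:
            raise StepStreamError(f"{path}: missing required column {col!r}")
    if df[time_col].isna().any():
        row = int(df.index[df[time_col].isna()][0]) + 2  # 1-based + header
        raise StepStreamError(f"{path}: non-numeric or empty time at line {row}")
    out = []
    for pid, grp in df.groupby(id_col, sort=True):
        ts = np.sort(grp[time_col].to_numpy(dtype=float))
        out.append(StepEventSeries(str(pid), ts))
    return out


def load_outcomes(path) -> list[OutcomeRecord]:
    """Read an outcome table (CSV with header ``participant_id,group,fall_count``)."""
    df = pd.read_csv(path)
    for col in ("participant_id", "group", "fall_count"):
        if col not in df.columns:
            raise StepStreamError(f"{path}: missing required column {col!r}")
    dup = df["participant_id"].duplicated()
    if dup.any():
        raise StepStreamError(
            f"{path}: duplicate outcome rows for {df.loc[dup, 'participant_id'].iloc[0]}"
        )
    return [
        OutcomeRecord(str(r.participant_id), int(r.group), int(r.fall_count))
        for r in df.itertuples(index=False)
    ]


def _runs(timestamps: np.ndarray, gap_s: float) -> list[np.ndarray]:
    """Split timestamps into maximal runs with all internal gaps < gap_s."""
    if timestamps.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(timestamps) >= gap_s) + 1
    return np.split(timestamps, cuts)


def segment_bouts(
    series: StepEventSeries,
    gap_s: float = 2.0,
    min_steps: int = 200,
    trim: int = 5,
) -> Bouts:
    """Partition a step stream into kept walking bouts.

    A bout is a maximal run of steps in which every consecutive gap is
    strictly below ``gap_s`` (a gap of exactly ``gap_s`` splits). Runs with
    raw step count strictly greater than ``min_steps`` are kept and trimmed
    by ``trim`` steps at each end; shorter runs are discarded and tallied.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    if min_steps <= 2 * trim:
        raise ValueError("min_steps must exceed twice the trim")
    result = Bouts(series.participant_id)
    for run in _runs(series.timestamps, gap_s):
        if run.size > min_steps:
            result.bouts.append(WalkingBout(run, trim=trim))
        else:
            result.n_discarded_runs += 1
            result.n_discarded_steps += int(run.size)
    return result


def extract_middle200(bout: WalkingBout, window: int = 200) -> np.ndarray:
    """Central contiguous block of ``window`` retained steps (left-biased).

    Complexity measures are length-dependent, so every bout contributes a
    constant-length window; bouts with fewer retained steps than the window
    are ineligible.
    """
    t = bout.retained_steps
    if t.size < window:
        raise UndefinedWindowError(
            f"middle-{window} window undefined for {t.size} retained steps"
        )
    off = (t.size - window) // 2
    return t[off : off + window]
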