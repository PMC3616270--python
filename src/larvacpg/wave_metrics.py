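"""Extraction and quantification of peristaltic waves from trajectories.

A segmental "contraction" is suprathreshold excitatory activity: the
interval during which E_i exceeds the contraction threshold theta_C.
From the per-segment contraction intervals this module computes the wave
statistics used throughout: normalized contraction durations,
intersegmental phase lags, wave duration, validity classification, wave
counts under sustained drive, onset delay, and left/right synchrony for
the two-sided model.

Direction conventions: a *forward* wave is initiated at the posterior
segment A8 (= segment ``n``) and terminates at A1 (= segment 1); a
*backward* wave is the reverse.  The wave duration is the terminal
segment's contraction offset minus the initiating segment's onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .integrator import Trajectory
from .model_core import DriveProtocol

__all__ = [
    "Interval",
    "ContractionTable",
    "WaveMetrics",
    "SyncResult",
    "contraction_intervals",
    "normalized_durations",
    "intersegmental_phase_lags",
    "classify_wave",
    "count_waves",
    "wave_onset_delay",
    "left_right_sync",
    "wave_metrics",
]

Direction = Literal["forward", "backward"]
Rule = Literal["strict", "endpoint_relaxed"]

#: Default contraction threshold; 0.2 is used in high-inhibition two-sided
#: regimes where activity stays below 0.3.
DEFAULT_THRESHOLD = 0.3


@dataclass(frozen=True)
class Interval:
    """One suprathreshold excursion; boundary flags mark truncation at the
    trajectory edges (the activity was already / still above threshold)."""

    onset: float
    offset: float
    clipped_start: bool = False
    clipped_end: bool = False

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("interval requires onset < offset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class ContractionTable:
    """Per-segment contraction intervals at one threshold.

    ``intervals[i]`` belongs to segment ``i + 1`` (A1 first); within a
    segment intervals are disjoint and time-ordered.
    """

    threshold: float
    intervals: tuple[tuple[Interval, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals", tuple(tuple(seg) for seg in self.intervals)
        )
        for seg in self.intervals:
            for a, b in zip(seg, seg[1:]):
                if not a.offset <= b.onset:
                    raise ValueError("intervals within a segment must be disjoint and ordered")

    @property
    def n_segments(self) -> int:
        return len(self.intervals)

    def single_intervals(self) -> tuple[Interval, ...]:
        """The unique interval of each segment; error if any segment has
        zero or several (use count_waves to split multi-wave runs)."""
        out = []
        for i, seg in enumerate(self.intervals):
            if len(seg) != 1:
                raise ValueError(
                    f"segment {i + 1} has {len(seg)} contraction intervals; "
                    "expected exactly 1 — use count_waves for multi-wave runs"
                )
            out.append(seg[0])
        return tuple(out)


@dataclass(frozen=True)
class WaveMetrics:
    """Statistics of a single propagating wave."""

    direction: Direction
    wave_duration: float
    normalized_durations: tuple[float, ...]  # A1..An order
    phase_lags: tuple[float, ...]  # consecutive pairs from the initiating end
    valid: bool
    reason: str = ""

    @property
    def mean_normalized_duration(self) -> float:
        return float(np.mean(self.normalized_durations))

    @property
    def mean_phase_lag(self) -> float:
        return float(np.mean(self.phase_lags))


@dataclass(frozen=True)
class SyncResult:
    """Left/right coordination summary of a two-sided run."""

    mean_onset_difference: float
    classification: Literal["synchronous", "asynchronous", "alternating", "no_wave"]
    n_matched: int = 0
    discarded: bool = False


def _crossings(t: np.ndarray, x: np.ndarray, threshold: float) -> list[Interval]:
    """Suprathreshold intervals of one series, crossings refined by linear
    interpolation; a sample exactly at threshold counts as suprathreshold."""
    above = x >= threshold
    intervals: list[Interval] = []
    if not above.any():
        return intervals
    # indices where the state changes
    change = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts: list[tuple[float, bool]] = []
    if above[0]:
        starts.append((t[0], True))
    for k in change:
        # crossing between samples k and k+1
        tk = t[k] + (threshold - x[k]) * (t[k + 1] - t[k]) / (x[k + 1] - x[k])
        if above[k + 1] and not above[k]:
            starts.append((tk, False))
        else:
            onset, clipped = starts.pop()
            intervals.append(Interval(onset, tk, clipped_start=clipped))
    if starts:
        onset, clipped = starts.pop()
        intervals.append(Interval(onset, t[-1], clipped_start=clipped, clipped_end=True))
    return intervals


def contraction_intervals(
    trajectory: Trajectory, threshold: float, side: str | None = None
) -> ContractionTable:
    """Locate each segment's suprathreshold E intervals at ``threshold``.

    ``side`` selects ``"left"`` or ``"right"`` in two-sided runs.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if trajectory.times.size < 2:
        raise ValueError("trajectory too short for crossing analysis")
    if trajectory.spec.two_sided and side is None:
        raise ValueError("two-sided trajectory: specify side='left' or 'right'")
    E = trajectory.excitatory(side)
    t = trajectory.times
    segs = tuple(tuple(_crossings(t, E[:, i], threshold)) for i in range(E.shape[1]))
    return ContractionTable(threshold, segs)


def _wave_order(n: int, direction: Direction) -> np.ndarray:
    """Segment array indices from the initiating to the terminal segment."""
    order = np.arange(n)
    return order[::-1] if direction == "forward" else order


def _wave_duration(ivals: tuple[Interval, ...], direction: Direction) -> float:
    order = _wave_order(len(ivals), direction)
    return ivals[order[-1]].offset - ivals[order[0]].onset


def normalized_durations(
    table: ContractionTable, direction: Direction = "forward"
) -> tuple[tuple[float, ...], float]:
    """Per-segment contraction duration / wave duration, plus the wave duration.

    Returned durations are in A1..An order regardless of direction.
    """
    ivals = table.single_intervals()
    wd = _wave_duration(ivals, direction)
    if wd <= 0:
        raise ValueError("non-positive wave duration; not a propagating wave")
    return tuple(iv.duration / wd for iv in ivals), wd


def intersegmental_phase_lags(
    table: ContractionTable, direction: Direction = "forward"
) -> tuple[float, ...]:
    """Consecutive-pair onset differences / wave duration, ordered from the
    initiating end (A8->A7, ... for forward; A1->A2, ... for backward)."""
    ivals = table.single_intervals()
    wd = _wave_duration(ivals, direction)
    order = _wave_order(len(ivals), direction)
    onsets = np.array([ivals[i].onset for i in order])
    return tuple(np.diff(onsets) / wd)


def classify_wave(
    table: ContractionTable,
    direction: Direction = "forward",
    rule: Rule = "strict",
) -> tuple[bool, str]:
    """Propagation-validity check of a single wave.

    strict: contraction onsets *and* offsets must both follow the
    initiating-to-terminal segment order.  endpoint_relaxed: additionally
    accepts the terminal segment deactivating before its neighbour (the
    terminal segment receives no onward excitation, so without sensory
    feedback it routinely switches off early).
    """
    for i, seg in enumerate(table.intervals):
        if len(seg) == 0:
            return False, f"segment {i + 1} never crossed threshold"
        if len(seg) > 1:
            return False, f"segment {i + 1} has {len(seg)} excursions (not a single wave)"
    ivals = tuple(seg[0] for seg in table.intervals)
    order = _wave_order(len(ivals), direction)
    onsets = [ivals[i].onset for i in order]
    offsets = [ivals[i].offset for i in order]
    if np.any(np.diff(onsets) <= 0):
        return False, "onset order violated"
    off_diffs = np.diff(offsets)
    if np.all(off_diffs > 0):
        return True, ""
    if rule == "endpoint_relaxed" and np.all(off_diffs[:-1] > 0):
        return True, "terminal segment deactivated early (accepted by relaxed rule)"
    return False, "offset order violated"


def count_waves(
    trajectory: Trajectory,
    threshold: float,
    direction: Direction = "forward",
    side: str | None = None,
) -> tuple[int, list[ContractionTable]]:
    """Count complete propagating waves in a (possibly multi-wave) run.

    One wave is counted per suprathreshold excursion of the initiating
    segment that is followed by ordered threshold onsets of all remaining
    segments before the initiating segment's next excursion; excursions
    with incomplete or disordered propagation contribute nothing.  Under
    very strong sustained drive the initiating segment stays continuously
    active; that excursion still counts (at most) one wave, with the
    prolonged interval visible in the returned table.
    """
    table = contraction_intervals(trajectory, threshold, side=side)
    n = table.n_segments
    order = _wave_order(n, direction)
    init_idx, rest = order[0], order[1:]
    init_excursions = table.intervals[init_idx]
    tables: list[ContractionTable] = []
    for k, exc in enumerate(init_excursions):
        t_lo = exc.onset
        t_hi = (
            init_excursions[k + 1].onset
            if k + 1 < len(init_excursions)
            else np.inf
        )
        picked: list[Interval | None] = [None] * n
        picked[init_idx] = exc
        last_onset = exc.onset
        ok = True
        for i in rest:
            nxt = next(
                (iv for iv in table.intervals[i] if t_lo <= iv.onset < t_hi), None
            )
            if nxt is None or nxt.onset <= last_onset:
                ok = False
                break
            picked[i] = nxt
            last_onset = nxt.onset
        if ok:
            tables.append(
                ContractionTable(threshold, tuple((iv,) for iv in picked))  # type: ignore[arg-type]
            )
    return len(tables), tables


def wave_onset_delay(
    trajectory: Trajectory,
    protocol: DriveProtocol,
    threshold: float,
    side: str | None = None,
) -> float | None:
    """Delay between pulse onset and the driven segment's first threshold
    crossing; None if the driven segment never crosses (no wave)."""
    if len(protocol.pulses) != 1:
        raise ValueError("onset delay is defined for single-pulse protocols")
    pulse = protocol.pulses[0]
    table = contraction_intervals(trajectory, threshold, side=side)
    seg = table.intervals[pulse.segment_index - 1]
    if not seg:
        return None
    return seg[0].onset - pulse.onset_time


def _excursion_onsets(table: ContractionTable, i: int, t_min: float) -> list[Interval]:
    return [iv for iv in table.intervals[i] if iv.onset >= t_min]


def _interleaved(a: list[Interval], b: list[Interval]) -> bool:
    """True when each side's excursions fall inside the other's
    subthreshold gaps (no temporal overlap between any pair)."""
    if not a or not b:
        return False
    for ia in a:
        for ib in b:
            if ia.onset < ib.offset and ib.onset < ia.offset:
                return False
    return True


def left_right_sync(
    trajectory: Trajectory,
    threshold: float,
    transient_cut: float,
    sync_tolerance: float = 0.1,
    discard_above: float = 1.0,
) -> SyncResult:
    """Left/right onset-timing comparison for a two-sided run.

    Activity before ``transient_cut`` is ignored.  The k-th post-transient
    excursion of each segment on one side is paired with the k-th on the
    other; the statistic is the mean absolute onset difference across all
    matched pairs.  Classification: ``synchronous`` when the mean is at
    most ``sync_tolerance``; ``alternating`` when the two sides' excursions
    strictly interleave; otherwise ``asynchronous``.  Means above
    ``discard_above`` are flagged ``discarded`` (treated as unanalyzable).
    """
    if not trajectory.spec.two_sided:
        raise ValueError("left_right_sync requires a two-sided trajectory")
    if transient_cut >= trajectory.times[-1]:
        raise ValueError("transient_cut must fall inside the trajectory span")
    left = contraction_intervals(trajectory, threshold, side="left")
    right = contraction_intervals(trajectory, threshold, side="right")
    n = left.n_segments
    diffs: list[float] = []
    any_left = any_right = False
    unmatched = False
    interleave_all = True
    for i in range(n):
        li = _excursion_onsets(left, i, transient_cut)
        ri = _excursion_onsets(right, i, transient_cut)
        any_left |= bool(li)
        any_right |= bool(ri)
        if len(li) != len(ri):
            unmatched = True
        for a, b in zip(li, ri):
            diffs.append(abs(a.onset - b.onset))
        if not _interleaved(li, ri):
            interleave_all = False
    if not (any_left and any_right):
        return SyncResult(np.inf, "no_wave")
    if not diffs:
        # sides active but no pairable excursions: fully interleaved or offset
        cls = "alternating" if interleave_all else "asynchronous"
        return SyncResult(np.inf, cls, 0, True)
    mean_diff = float(np.mean(diffs))
    if interleave_all:
        cls = "alternating"
    elif mean_diff <= sync_tolerance and not unmatched:
        cls = "synchronous"
    else:
        cls = "asynchronous"
    return SyncResult(mean_diff, cls, len(diffs), mean_diff > discard_above)


def wave_metrics(
    table: ContractionTable, direction: Direction = "forward", rule: Rule = "strict"
) -> WaveMetrics:
    """Bundle validity, durations and lags of one single-wave table."""
    valid, reason = classify_wave(table, direction, rule)
    try:
        durs, wd = normalized_durations(table, direction)
        lags = intersegmental_phase_lags(table, direction)
    except ValueError as err:
        return WaveMetrics(direction, np.nan, (), (), False, str(err))
    return WaveMetrics(direction, wd, durs, lags, valid, reason)
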