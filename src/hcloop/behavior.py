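"""Scoring of freely-moving behavior: object exploration and Barnes maze.

Exploration of an object is defined as frames in which the head is within a
maximum distance (default 2 cm) of the object and directed at it; novelty
and discrimination indices are computed from per-object exploration times.
Barnes-maze trials are scored from event logs as error counts (hole visits
without entry, escape hole included) and latency to enter the escape box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrackingSession",
    "ObjectSpec",
    "ExplorationBout",
    "BarnesLog",
    "BarnesScore",
    "detect_exploration",
    "exploration_time",
    "novelty_index",
    "discrimination_index",
    "score_barnes",
]

ARENA_CM = (37.0, 29.0)  # length x width of the open-field arena


@dataclass
class TrackingSession:
    """Head-tracking record of one trial.

    ``t`` (s), ``x``/``y`` (cm) and ``heading`` (degrees, 0 = +x,
    counter-clockwise) are parallel per-frame arrays at ``frame_rate`` Hz.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    frame_rate: float = 20.0
    arena: tuple[float, float] = ARENA_CM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.heading.size == n):
            raise ValueError("t, x, y, heading must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def duration(self) -> float:
        if self.t.size < 2:
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1.0 / self.frame_rate


@dataclass(frozen=True)
class ObjectSpec:
    """A circular object (or object location) inside the arena."""

    id: str
    x: float
    y: float
    radius: float
    status: str = "familiar"  # familiar | novel

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("object radius must be > 0")
        if self.status not in ("familiar", "novel"):
            raise ValueError(f"unknown object status {self.status!r}")

    def inside_arena(self, arena: tuple[float, float]) -> bool:
        return (
            self.radius <= self.x <= arena[0] - self.radius
            and self.radius <= self.y <= arena[1] - self.radius
        )


@dataclass(frozen=True)
class ExplorationBout:
    object_id: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def _wrap_angle_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def exploring_mask(
    session: TrackingSession,
    obj: ObjectSpec,
    max_dist: float = 2.0,
    heading_tol: float = 45.0,
    edge_distance: bool = True,
) -> np.ndarray:
    """Boolean per-frame mask of the exploration criterion for one object.

    A frame explores the object iff the head is within ``max_dist`` cm of
    the object boundary (``edge_distance=False`` measures to the center) and
    the heading points at the object center within ``heading_tol`` degrees.
    Frames with the head inside the object footprint count as exploring.
    """
    dx = obj.x - session.x
    dy = obj.y - session.y
    d_center = np.hypot(dx, dy)
    d = d_center - obj.radius if edge_distance else d_center
    near = d <= max_dist
    bearing = np.degrees(np.arctan2(dy, dx))
    facing = np.abs(_wrap_angle_deg(bearing - session.heading)) <= heading_tol
    inside = d_center <= obj.radius
    return near & (facing | inside)


def _mask_to_bouts(
    mask: np.ndarray,
    t: np.ndarray,
    frame_rate: float,
    obj_id: str,
    min_bout: float,
    merge_gap: float,
) -> list[ExplorationBout]:
    if mask.size == 0 or not mask.any():
        return []
    dt = 1.0 / frame_rate
    idx = np.flatnonzero(mask)
    # split into consecutive runs, then merge runs separated by short gaps
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = [(r[0], r[-1]) for r in np.split(idx, breaks + 1)]
    merged = [runs[0]]
    for a, b in runs[1:]:
        last_a, last_b = merged[-1]
        if (t[a] - t[last_b]) - dt <= merge_gap + 1e-12:
            merged[-1] = (last_a, b)
        else:
            merged.append((a, b))
    bouts = []
    for a, b in merged:
        start, end = float(t[a]), float(t[b]) + dt
        if end - start >= min_bout - 1e-12:
            bouts.append(ExplorationBout(object_id=obj_id, start=start, end=end))
    return bouts


def detect_exploration(
    session: TrackingSession,
    objects: list[ObjectSpec],
    max_dist: float = 2.0,
    heading_tol: float = 45.0,
    min_bout: float = 0.2,
    merge_gap: float = 0.25,
    edge_distance: bool = True,
) -> list[ExplorationBout]:
    """Segment per-object exploration bouts from a tracking session.

    Consecutive exploring frames form bouts; bouts separated by gaps of at
    most ``merge_gap`` s are merged and bouts shorter than ``min_bout`` s
    are dropped.  An empty session yields an empty list.
    """
    for obj in objects:
        if not obj.inside_arena(session.arena):
            raise ValueError(f"object {obj.id!r} does not fit inside the arena")
    bouts: list[ExplorationBout] = []
    for obj in objects:
        mask = exploring_mask(
            session, obj, max_dist=max_dist, heading_tol=heading_tol,
            edge_distance=edge_distance,
        )
        bouts.extend(
            _mask_to_bouts(mask, session.t, session.frame_rate, obj.id,
                           min_bout, merge_gap)
        )
    return bouts


def exploration_time(bouts: list[ExplorationBout], object_id: str | None = None) -> float:
    """Total bout duration, optionally restricted to one object."""
    return sum(b.duration for b in bouts
               if object_id is None or b.object_id == object_id)


def novelty_index(novel_time: float, familiar_time: float) -> float:
    """Novelty (recognition/location) index: novel / (novel + familiar)."""
    total = novel_time + familiar_time
    if total <= 0:
        raise ValueError("novelty index undefined: zero total exploration time")
    return novel_time / total


def discrimination_index(novel_time: float, familiar_time: float) -> float:
    """Discrimination index: (novel - familiar) / (novel + familiar)."""
    total = novel_time + familiar_time
    if total <= 0:
        raise ValueError("discrimination index undefined: zero total exploration")
    return (novel_time - familiar_time) / total


@dataclass
class BarnesLog:
    """Event log of one Barnes-maze trial.

    ``events`` is an ordered list of ``(time_s, hole_id, entered)``;
    at most one event may have ``entered=True`` (entry into the escape box
    ends the trial).  ``trial_cap`` is the exploration limit (180 s during
    training).
    """

    events: list[tuple[float, int, bool]]
    escape_hole: int
    trial_cap: float = 180.0
    n_holes: int = 20

    def __post_init__(self) -> None:
        times = [e[0] for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if sum(1 for e in self.events if e[2]) > 1:
            raise ValueError("log contains more than one escape-box entry")


@dataclass(frozen=True)
class BarnesScore:
    errors: int
    latency: float
    entered: bool


def score_barnes(log: BarnesLog) -> BarnesScore:
    """Errors and latency for one trial.

    Errors are hole-visit events without entry (visits to the escape hole
    included; repeated visits count separately).  Latency is the time of the
    entry event; if the animal never enters, latency is the trial cap and
    the score is flagged.
    """
    errors = sum(1 for _, _, entered in log.events if not entered)
    entry = [t for t, _, entered in log.events if entered]
    if entry:
        return BarnesScore(errors=errors, latency=float(entry[0]), entered=True)
    return BarnesScore(errors=errors, latency=float(log.trial_cap), entered=False)
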