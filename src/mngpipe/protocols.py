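"""Task protocols for isotonic (grasp-pressure) and isokinetic (finger-flexion) sessions.

An isotonic repetition asks the subject to reach and hold a target pressure
(1/2/4/6 kPa) on a sensor for 11 s; an isokinetic repetition is a finger
flexion at a target angular velocity (17/26/47 deg/s) whose duration depends
on the speed. Consecutive repetitions are separated by 2 s of rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

ISOTONIC = "isotonic"
ISOKINETIC = "isokinetic"

ISOTONIC_REP_S = 11.0
REST_S = 2.0
#: fixed flexion path length (degrees) shared by all speeds
FLEXION_RANGE_DEG = 160.0
ISOKINETIC_REP_BOUNDS_S = (4.0, 10.0)


@dataclass
class ProtocolTimeline:
    """Cue schedule of one recording session.

    ``cue_times`` holds one (start, stop) pair per repetition, in seconds from
    session start; ``rep_levels`` the commanded level (kPa or deg/s) of each
    repetition. Intervals are half-open [start, stop). Each repetition is
    preceded by ``rest_duration`` seconds of rest, so a 12-repetition
    isotonic session spans 12 x (2 + 11) = 156 s.
    """

    task: str
    levels: list[float]
    rep_levels: list[float]
    cue_times: list[tuple[float, float]]
    rest_duration: float = REST_S

    @property
    def n_reps(self) -> int:
        return len(self.cue_times)

    @property
    def total_duration(self) -> float:
        """Span of the session (rests + repetitions)."""
        if not self.cue_times:
            return 0.0
        return self.cue_times[-1][1]

    def rest_intervals(self) -> list[tuple[float, float]]:
        """Half-open rest intervals (before each repetition)."""
        return [(start - self.rest_duration, start)
                for start, _ in self.cue_times]

    def rep_duration(self, i: int) -> float:
        start, stop = self.cue_times[i]
        return stop - start

    def validate(self) -> None:
        for i, (a, b) in enumerate(self.cue_times):
            if b <= a:
                raise ValueError(f"repetition {i} has non-positive duration")
            if i and a < self.cue_times[i - 1][1]:
                raise ValueError(f"repetitions {i-1} and {i} overlap")
        if self.task == ISOTONIC:
            for a, b in self.cue_times:
                if abs((b - a) - ISOTONIC_REP_S) > 1e-9:
                    raise ValueError("isotonic repetitions must last 11 s")
        elif self.task == ISOKINETIC:
            lo, hi = ISOKINETIC_REP_BOUNDS_S
            for a, b in self.cue_times:
                if not (lo - 1e-9 <= b - a <= hi + 1e-9):
                    raise ValueError("isokinetic repetitions must last 4-10 s")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolTimeline":
        d = dict(d)
        d["cue_times"] = [tuple(c) for c in d["cue_times"]]
        return cls(**d)


def isokinetic_rep_duration(velocity_deg_s: float) -> float:
    """Repetition duration for one flexion: path length over speed, clipped
    to the protocol's 4-10 s range."""
    lo, hi = ISOKINETIC_REP_BOUNDS_S
    return float(np.clip(FLEXION_RANGE_DEG / velocity_deg_s, lo, hi))


def make_protocol(
    task: str,
    levels: list[float],
    reps_per_level: int,
    order: str = "blocked",
    seed: int | None = None,
) -> ProtocolTimeline:
    """Build a cue timeline with ``reps_per_level`` repetitions per level.

    ``order`` is "blocked" (ascending levels, the default) or "randomized"
    (uses ``seed``).
    """
    if task not in (ISOTONIC, ISOKINETIC):
        raise ValueError(f"unknown task {task!r}")
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(lv <= 0 for lv in levels):
        raise ValueError("levels must be positive")
    if reps_per_level < 1:
        raise ValueError("reps_per_level must be >= 1")

    rep_levels = [lv for lv in sorted(levels) for _ in range(reps_per_level)]
    if order == "randomized":
        rng = np.random.default_rng(seed)
        rep_levels = list(rng.permutation(rep_levels))
    elif order != "blocked":
        raise ValueError(f"unknown order {order!r}")

    cue_times = []
    t = 0.0
    for lv in rep_levels:
        dur = ISOTONIC_REP_S if task == ISOTONIC else isokinetic_rep_duration(lv)
        cue_times.append((t + REST_S, t + REST_S + dur))
        t += REST_S + dur
    tl = ProtocolTimeline(task=task, levels=sorted(set(levels)),
                          rep_levels=[float(v) for v in rep_levels],
                          cue_times=cue_times)
    tl.validate()
    return tl
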