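"""Drying/tempering schedules, intermittency, and drying-time accounting."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .exceptions import ConfigurationError, DomainError, TargetNotReachedError
from .physics import AmbientState

DRYING = "drying"
TEMPERING = "tempering"


@dataclass(frozen=True)
class Phase:
    """One schedule phase: active drying or tempering rest."""

    kind: str
    duration: float  # s
    ambient: AmbientState

    def __post_init__(self):
        if self.kind not in (DRYING, TEMPERING):
            raise ConfigurationError(f"unknown phase kind {self.kind!r}")
        if self.duration <= 0.0:
            raise ConfigurationError("phase duration must be positive")


@dataclass(frozen=True)
class Schedule:
    """Ordered list of phases; periodic schedules carry their cycle definition."""

    phases: Tuple[Phase, ...]
    t_D: Optional[float] = None  # drying duration per cycle when periodic, s
    t_T: Optional[float] = None  # tempering duration per cycle when periodic, s

    def __post_init__(self):
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))

    @property
    def alpha(self) -> float:
        """Intermittency of the periodic cycle definition (1 if continuous)."""
        if self.t_D is None:
            raise ConfigurationError("schedule has no periodic cycle definition")
        return intermittency(self.t_D, 0.0 if self.t_T is None else self.t_T)

    def spans(self) -> List[Tuple[str, float, float]]:
        """Per-phase ``(kind, t_start, t_end)`` wall-clock spans."""
        out, t = [], 0.0
        for p in self.phases:
            out.append((p.kind, t, t + p.duration))
            t += p.duration
        return out

    def operating_time_until(self, t: float) -> float:
        """Cumulative drying-phase (dryer-on) time in ``[0, t]``."""
        acc = 0.0
        for kind, t0, t1 in self.spans():
            if t0 >= t:
                break
            if kind == DRYING:
                acc += min(t, t1) - t0
        return acc


def intermittency(t_D: float, t_T: float) -> float:
    """Intermittency alpha = t_D / (t_D + t_T) of one drying/tempering cycle.

    ``t_T = 0`` is the continuous-drying limit (alpha = 1).
    """
    if t_D <= 0.0:
        raise DomainError("drying duration t_D must be positive")
    if t_T < 0.0:
        raise DomainError("tempering duration t_T must be non-negative")
    return t_D / (t_D + t_T)


def build_periodic_schedule(
    t_D: float,
    t_T: float,
    drying_ambient: AmbientState,
    tempering_ambient: Optional[AmbientState],
    max_total: float,
) -> Schedule:
    """Alternating drying/tempering schedule, starting with drying.

    The phase list is truncated so the total duration does not exceed
    ``max_total`` (a trailing partial phase is shortened to fit).
    ``t_T = 0`` yields a single continuous drying phase of ``max_total``.
    """
    if t_D <= 0.0:
        raise ConfigurationError("t_D must be positive")
    if t_T < 0.0:
        raise ConfigurationError("t_T must be non-negative")
    if max_total < t_D:
        raise ConfigurationError(
            f"max_total = {max_total} s is shorter than one drying phase ({t_D} s)"
        )
    if t_T == 0.0:
        return Schedule(
            phases=(Phase(DRYING, max_total, drying_ambient),), t_D=t_D, t_T=0.0
        )
    if tempering_ambient is None:
        raise ConfigurationError("tempering ambient required when t_T > 0")
    phases: List[Phase] = []
    t = 0.0
    while t < max_total:
        kind = DRYING if len(phases) % 2 == 0 else TEMPERING
        dur = t_D if kind == DRYING else t_T
        dur = min(dur, max_total - t)
        if dur <= 0.0:
            break
        amb = drying_ambient if kind == DRYING else tempering_ambient
        phases.append(Phase(kind, dur, amb))
        t += dur
    return Schedule(phases=tuple(phases), t_D=t_D, t_T=t_T)


def time_accounting(curve, X_target: float) -> Tuple[float, float]:
    """Total elapsed time and cumulative dryer-on time to reach ``X_target``.

    The crossing instant is located by linear interpolation of X between the
    two output samples bracketing the first crossing, so reported times are
    not quantized to the output grid.  ``operating`` counts only drying-phase
    time up to that instant.

    Raises
    ------
    TargetNotReachedError
        If the curve never drops to ``X_target``; carries the closest
        (final) moisture and time.
    """
    t = np.asarray(curve.t, dtype=float)
    X = np.asarray(curve.X, dtype=float)
    below = np.nonzero(X <= X_target)[0]
    if below.size == 0:
        raise TargetNotReachedError(
            f"moisture target {X_target} kg/kg never reached; final "
            f"X = {X[-1]:.5f} kg/kg at t = {t[-1]:.0f} s",
            final_X=float(X[-1]),
            final_t=float(t[-1]),
        )
    i = int(below[0])
    if i == 0:
        t_cross = float(t[0])
    else:
        x0, x1 = X[i - 1], X[i]
        frac = (x0 - X_target) / (x0 - x1) if x1 != x0 else 1.0
        t_cross = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    spans = curve.phase_spans
    operating = 0.0
    for kind, t0, t1 in spans:
        if t0 >= t_cross:
            break
        if kind == DRYING:
            operating += min(t_cross, t1) - t0
    return t_cross, operating
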