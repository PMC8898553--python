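"""Decomposition of trajectories into waiting and dash phases, and gamma
modelling of the resulting motion parameters.

Aquarium fish alternate between hovering near one spot and sudden
relocations ("dashes").  The segmentation here formalises that
observation: a *waiting phase* is a maximal run of samples that stays
within ``radius_px`` of the position where the run started, provided it
lasts at least ``min_wait_s``; everything between committed waits is a
*movement phase*.  Wait durations, dash distances and dash velocities
are then each modelled with a two-parameter gamma law fitted by maximum
likelihood.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import DegenerateSampleError, InsufficientDataError, InvalidInputError
from .trajectory import Trajectory

__all__ = [
    "PhaseKind",
    "Phase",
    "GammaFit",
    "MotionModel",
    "PhaseSummaries",
    "segment_trajectory",
    "summarize_phases",
    "fit_gamma_mle",
    "fit_motion_model",
    "write_phases_csv",
]


class PhaseKind(enum.Enum):
    WAIT = "WAIT"
    MOVE = "MOVE"


@dataclass
class Phase:
    """One waiting or movement segment of a trajectory.

    ``anchor`` and ``max_excursion`` are set for WAIT phases only;
    ``distance`` (path length, px), ``mean_velocity`` (px/s) and
    ``direction`` (atan2 of net displacement, radians) for MOVE phases
    only.  Phases of one trajectory tile its time span.
    """

    kind: PhaseKind
    t_start: float
    t_end: float
    anchor: tuple[float, float] | None = None
    max_excursion: float | None = None
    distance: float | None = None
    mean_velocity: float | None = None
    direction: float | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class GammaFit:
    """Maximum-likelihood gamma fit: shape ``k``, scale ``theta``."""

    k: float
    theta: float
    n: int
    loglik: float

    @property
    def mean(self) -> float:
        return self.k * self.theta

    def logpdf(self, x) -> np.ndarray:
        return stats.gamma.logpdf(x, a=self.k, scale=self.theta)


@dataclass
class MotionModel:
    """Fitted wait/dash motion law for fish-like movement.

    Three gamma distributions (wait duration in s, dash distance in px,
    dash velocity in px/s), the positional jitter radius during waits,
    and the dash-direction rule (uniform on [0, 2pi)).
    """

    wait_duration: GammaFit
    dash_distance: GammaFit
    dash_velocity: GammaFit
    jitter_radius: float = 10.0
    direction_rule: str = "uniform"

    def __post_init__(self) -> None:
        for fit in (self.wait_duration, self.dash_distance, self.dash_velocity):
            if fit.k <= 0 or fit.theta <= 0:
                raise InvalidInputError("gamma parameters must be positive")
        if self.jitter_radius < 0:
            raise InvalidInputError("jitter_radius must be non-negative")


@dataclass
class PhaseSummaries:
    """Pooled per-kind phase statistics ready for gamma fitting."""

    wait_durations: np.ndarray
    dash_distances: np.ndarray
    dash_velocities: np.ndarray
    dash_directions: np.ndarray
    time_fraction_wait: float
    time_fraction_move: float


def _run_end(xy: np.ndarray, start: int, radius: float) -> int:
    """Last index of the maximal run from ``start`` whose samples all stay
    within ``radius`` of ``xy[start]``.  Scans in blocks to stay vectorised."""
    n = len(xy)
    anchor = xy[start]
    j = start
    block = 256
    while j + 1 < n:
        hi = min(j + 1 + block, n)
        d2 = np.sum((xy[j + 1 : hi] - anchor) ** 2, axis=1)
        bad = np.nonzero(d2 > radius * radius)[0]
        if bad.size:
            return j + int(bad[0])
        j = hi - 1
    return j


def segment_trajectory(
    traj: Trajectory, radius_px: float = 60.0, min_wait_s: float = 0.2
) -> list[Phase]:
    """Greedy left-to-right decomposition into WAIT and MOVE phases.

    A candidate wait opens at the current sample (that sample is the
    anchor) and extends while every sample stays within ``radius_px`` of
    the anchor.  It is committed iff it lasts at least ``min_wait_s``;
    otherwise the scan keeps moving and the stretch is absorbed into the
    enclosing MOVE phase.  Committed phases share boundary samples, so
    their durations tile the trajectory exactly.
    """
    if radius_px <= 0:
        raise InvalidInputError("radius_px must be positive")
    if min_wait_s < 0:
        raise InvalidInputError("min_wait_s must be non-negative")
    xy = traj.xy
    t = traj.t
    n = len(traj)
    phases: list[Phase] = []
    i = 0
    while i < n - 1:
        j = _run_end(xy, i, radius_px)
        if t[j] - t[i] >= min_wait_s:
            d = np.sqrt(np.sum((xy[i : j + 1] - xy[i]) ** 2, axis=1))
            phases.append(
                Phase(
                    PhaseKind.WAIT,
                    t_start=float(t[i]),
                    t_end=float(t[j]),
                    anchor=(float(xy[i, 0]), float(xy[i, 1])),
                    max_excursion=float(d.max()),
                )
            )
            i = j
        else:
            # advance until a committable wait opens (or the end)
            k = i + 1
            while k < n - 1:
                j2 = _run_end(xy, k, radius_px)
                if t[j2] - t[k] >= min_wait_s:
                    break
                k += 1
            steps = np.sqrt(np.sum(np.diff(xy[i : k + 1], axis=0) ** 2, axis=1))
            dist = float(steps.sum())
            dur = float(t[k] - t[i])
            net = xy[k] - xy[i]
            phases.append(
                Phase(
                    PhaseKind.MOVE,
                    t_start=float(t[i]),
                    t_end=float(t[k]),
                    distance=dist,
                    mean_velocity=dist / dur,
                    direction=float(math.atan2(net[1], net[0])),
                )
            )
            i = k
    return phases


def summarize_phases(phases: list[Phase]) -> PhaseSummaries:
    """Pool phase statistics and compute the wait/move time split."""
    if not phases:
        raise InvalidInputError("phase list is empty")
    waits = [p for p in phases if p.kind is PhaseKind.WAIT]
    moves = [p for p in phases if p.kind is PhaseKind.MOVE]
    t_wait = sum(p.duration for p in waits)
    t_move = sum(p.duration for p in moves)
    total = t_wait + t_move
    if total <= 0:
        raise InvalidInputError("phases have zero total duration")
    return PhaseSummaries(
        wait_durations=np.array([p.duration for p in waits]),
        dash_distances=np.array([p.distance for p in moves]),
        dash_velocities=np.array([p.mean_velocity for p in moves]),
        dash_directions=np.array([p.direction for p in moves]),
        time_fraction_wait=t_wait / total,
        time_fraction_move=t_move / total,
    )


def fit_gamma_mle(samples) -> GammaFit:
    """Two-parameter gamma maximum-likelihood fit (location fixed at 0).

    The profiled shape equation ``log k - psi(k) = log(mean) - mean(log)``
    is solved by safeguarded Newton iteration on the digamma function;
    the scale then follows as ``theta = mean / k``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise InvalidInputError("need at least 3 samples")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise InvalidInputError("samples must be positive and finite")
    mean = float(np.mean(x))
    s = math.log(mean) - float(np.mean(np.log(x)))
    if s <= 1e-12:
        raise DegenerateSampleError("samples have (near-)zero variance")

    # Minka's closed-form initialiser, then Newton with a bisection bracket.
    k = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    lo, hi = 1e-9, 1e9
    for _ in range(100):
        f = math.log(k) - special.digamma(k) - s
        if abs(f) < 1e-12:
            break
        if f > 0:
            lo = max(lo, k)
        else:
            hi = min(hi, k)
        fprime = 1.0 / k - special.polygamma(1, k)
        step = k - f / fprime
        k = step if lo < step < hi else 0.5 * (lo + hi)
    theta = mean / k
    loglik = float(np.sum(stats.gamma.logpdf(x, a=k, scale=theta)))
    return GammaFit(k=k, theta=theta, n=len(x), loglik=loglik)


def fit_motion_model(
    trajs: list[Trajectory],
    radius_px: float = 60.0,
    min_wait_s: float = 0.2,
) -> MotionModel:
    """Segment all trajectories, pool the phases, fit the three gamma laws.

    The jitter radius is taken as the median maximal excursion observed
    within waiting phases (never exceeding the segmentation radius).
    """
    all_phases: list[Phase] = []
    for traj in trajs:
        all_phases.extend(segment_trajectory(traj, radius_px, min_wait_s))
    waits = [p for p in all_phases if p.kind is PhaseKind.WAIT]
    moves = [p for p in all_phases if p.kind is PhaseKind.MOVE]
    if len(waits) < 3 or len(moves) < 3:
        raise InsufficientDataError(
            f"need >= 3 phases of each kind, got {len(waits)} WAIT / {len(moves)} MOVE"
        )
    summ = summarize_phases(all_phases)
    jitter = float(np.median([p.max_excursion for p in waits]))
    return MotionModel(
        wait_duration=fit_gamma_mle(summ.wait_durations),
        dash_distance=fit_gamma_mle(summ.dash_distances),
        dash_velocity=fit_gamma_mle(summ.dash_velocities),
        jitter_radius=min(jitter, radius_px),
    )


def write_phases_csv(phases_by_object: dict[str, list[Phase]], path) -> None:
    """Export phases as object_id,kind,t_start,t_end,distance,mean_velocity,direction."""
    rows = []
    for oid, phases in phases_by_object.items():
        for p in phases:
            rows.append(
                {
                    "object_id": oid,
                    "kind": p.kind.value,
                    "t_start": p.t_start,
                    "t_end": p.t_end,
                    "distance": p.distance,
                    "mean_velocity": p.mean_velocity,
                    "direction": p.direction,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
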