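"""Empirical path-time events: exits, direct transition paths, KS comparisons.

An exit-path time is the first-passage time from an interior start to either
interval boundary.  A transition-path time spans from the *last* crossing of
one boundary to the first subsequent crossing of the other with no
intermediate return — trajectories that come back to the starting boundary
are not transitions and are not counted.  Crossing times are linearly
interpolated between samples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import kolmogorov

from .errors import EstimationError, InvalidParameterError
from .simulate import Trajectory

__all__ = [
    "IntervalSpec",
    "PathTimeSample",
    "KSResult",
    "detect_exits",
    "detect_transition_paths",
    "summarize",
    "ks_two_sample",
    "scan_interval",
]


@dataclass(frozen=True)
class IntervalSpec:
    x_left: float
    x_right: float

    def __post_init__(self) -> None:
        if not self.x_left < self.x_right:
            raise InvalidParameterError("interval requires x_left < x_right")


@dataclass(frozen=True)
class PathTimeSample:
    direction: str  # "to_left" | "to_right" | "L_to_R" | "R_to_L"
    tau: float
    t_start: float
    traj_id: int = 0


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int

    def band_halfwidth(self, significance: float) -> float:
        """Critical KS distance at the given significance for the two-sample
        comparison: c(s)·sqrt((n1+n2)/(n1·n2)) with c(s) = sqrt(-ln(s/2)/2)."""
        if not 0 < significance < 1:
            raise InvalidParameterError("significance must be in (0, 1)")
        c = np.sqrt(-np.log(significance / 2.0) / 2.0)
        return float(c * np.sqrt((self.n1 + self.n2) / (self.n1 * self.n2)))


def _cross_time(t0, x0, t1, x1, b):
    """Linear-interpolated time at which the segment (t0,x0)->(t1,x1) crosses b."""
    return t0 + (b - x0) / (x1 - x0) * (t1 - t0)


def detect_exits(
    traj: Trajectory, interval: IntervalSpec, t_start: float = 0.0
) -> PathTimeSample | None:
    """First boundary reached after ``t_start``; None if censored (trajectory
    ends inside the interval)."""
    t, x = traj.t, traj.x
    i0 = int(np.searchsorted(t, t_start, side="left"))
    if i0 >= t.size:
        raise InvalidParameterError("t_start beyond the end of the trajectory")
    if not interval.x_left < x[i0] < interval.x_right:
        raise InvalidParameterError("trajectory must start strictly inside the interval")
    xs = x[i0:]
    out = (xs <= interval.x_left) | (xs >= interval.x_right)
    hits = np.flatnonzero(out)
    if hits.size == 0:
        return None
    j = i0 + hits[0]
    if x[j] <= interval.x_left:
        tc = _cross_time(t[j - 1], x[j - 1], t[j], x[j], interval.x_left)
        direction = "to_left"
    else:
        tc = _cross_time(t[j - 1], x[j - 1], t[j], x[j], interval.x_right)
        direction = "to_right"
    return PathTimeSample(direction=direction, tau=float(tc - t_start), t_start=float(t_start))


def detect_transition_paths(
    traj: Trajectory, interval: IntervalSpec, traj_id: int = 0
) -> list[PathTimeSample]:
    """All direct boundary-to-boundary transition events, in time order.

    An L→R event spans from the last up-crossing of x_left before the first
    subsequent crossing of x_right with no intermediate return to x_left
    (standard last-crossing convention); symmetric for R→L.
    """
    t, x = traj.t, traj.x
    xl, xr = interval.x_left, interval.x_right
    region = np.zeros(x.size, dtype=np.int8)
    region[x <= xl] = -1
    region[x >= xr] = 1
    nz = np.flatnonzero(region)
    if nz.size < 2:
        return []
    s = region[nz]
    flips = np.flatnonzero(s[:-1] != s[1:])
    samples: list[PathTimeSample] = []
    for k in flips:
        i, j = nz[k], nz[k + 1]  # last sample in origin region, first in target
        if s[k] == -1:  # L -> R
            t_startc = _cross_time(t[i], x[i], t[i + 1], x[i + 1], xl)
            t_end = _cross_time(t[j - 1], x[j - 1], t[j], x[j], xr)
            direction = "L_to_R"
        else:  # R -> L
            t_startc = _cross_time(t[i], x[i], t[i + 1], x[i + 1], xr)
            t_end = _cross_time(t[j - 1], x[j - 1], t[j], x[j], xl)
            direction = "R_to_L"
        samples.append(
            PathTimeSample(
                direction=direction,
                tau=float(t_end - t_startc),
                t_start=float(t_startc),
                traj_id=traj_id,
            )
        )
    return samples


def summarize(samples) -> tuple[float, float, int]:
    """(mean, SEM, n) of the path times; SEM is nan for a single sample."""
    taus = np.asarray(
        [s.tau if isinstance(s, PathTimeSample) else float(s) for s in samples], dtype=float
    )
    if taus.size < 1:
        raise EstimationError("no samples to summarize")
    mean = float(np.mean(taus))
    sem = float(np.std(taus, ddof=1) / np.sqrt(taus.size)) if taus.size >= 2 else float("nan")
    return mean, sem, int(taus.size)


def ks_two_sample(a, b) -> KSResult:
    """Two-sided two-sample Kolmogorov–Smirnov comparison.

    The statistic is the exact ECDF sup-gap; the p-value uses the asymptotic
    Kolmogorov distribution at effective size n1·n2/(n1+n2), adequate for the
    10²–10³ event counts this package produces.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise EstimationError("KS comparison requires non-empty samples")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    ne = a.size * b.size / (a.size + b.size)
    p = float(kolmogorov(np.sqrt(ne) * d))
    return KSResult(statistic=d, p_value=min(1.0, p), n1=int(a.size), n2=int(b.size))


def scan_interval(
    trajs, window: float, step: float, x_range: tuple[float, float]
) -> "pd.DataFrame":
    """Sliding-interval scan: transition probabilities and mean path times in
    both directions for a window of fixed width moved along x.

    The transition probability in a direction is the number of successful
    direct crossings divided by the number of entries into the window interior
    from that side (each boundary up-crossing is an attempt; only the last one
    before reaching the far boundary succeeds).
    """
    import pandas as pd

    if window <= 0 or step <= 0:
        raise InvalidParameterError("window and step must be positive")
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    lo, hi = x_range
    if lo + window > hi:
        import warnings

        warnings.warn("window wider than the scan range; empty scan table")
        return pd.DataFrame(
            columns=[
                "x_center", "p_LR", "p_RL", "tau_LR_mean", "tau_LR_sem",
                "tau_RL_mean", "tau_RL_sem", "n_LR", "n_RL",
            ]
        )
    centers = np.arange(lo + window / 2.0, hi - window / 2.0 + 1e-12, step)
    rows = []
    for xc in centers:
        itv = IntervalSpec(xc - window / 2.0, xc + window / 2.0)
        taus_lr, taus_rl = [], []
        att_lr = att_rl = 0
        for tid, traj in enumerate(trajs):
            x = traj.x
            # attempts: entries into the interior from each boundary region
            left = x <= itv.x_left
            right = x >= itv.x_right
            inside = ~left & ~right
            att_lr += int(np.count_nonzero(left[:-1] & inside[1:]))
            att_rl += int(np.count_nonzero(right[:-1] & inside[1:]))
            # direct both-boundary jumps in one step also count as attempts
            att_lr += int(np.count_nonzero(left[:-1] & right[1:]))
            att_rl += int(np.count_nonzero(right[:-1] & left[1:]))
            for s in detect_transition_paths(traj, itv, traj_id=tid):
                (taus_lr if s.direction == "L_to_R" else taus_rl).append(s.tau)
        def _ms(taus):
            if not taus:
                return float("nan"), float("nan")
            m, sem, _ = summarize(taus)
            return m, sem
        m_lr, s_lr = _ms(taus_lr)
        m_rl, s_rl = _ms(taus_rl)
        rows.append(
            dict(
                x_center=float(xc),
                p_LR=len(taus_lr) / att_lr if att_lr else float("nan"),
                p_RL=len(taus_rl) / att_rl if att_rl else float("nan"),
                tau_LR_mean=m_lr, tau_LR_sem=s_lr,
                tau_RL_mean=m_rl, tau_RL_sem=s_rl,
                n_LR=len(taus_lr), n_RL=len(taus_rl),
            )
        )
    return pd.DataFrame(rows)
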