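"""Force/diffusion/potential inference from trajectory ensembles.

Single-step displacements Δx collected in spatial bins (by their starting
position, consistent with the Itô drift) are Gaussian with mean Δt·f/γ and
variance 2DΔt.  Moment matching per bin — equivalent to maximum likelihood
for the Gaussian step model — gives D̂ = var/(2Δt) and, eliminating the
friction γ through Einstein–Stokes D = kBT/γ, f̂ = mean·kBT/(D̂·Δt).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimationError, InvalidParameterError
from .model import DEFAULT_UNITS, Units, potential_from_force
from .simulate import Trajectory

__all__ = [
    "DriftDiffusionEstimate",
    "fit_drift_diffusion",
    "force_from_exit_counts",
    "reconstruct_potential",
    "pooled_estimate",
]

MIN_STEPS_PER_BIN = 50


@dataclass
class DriftDiffusionEstimate:
    """Per-bin drift/diffusion estimates; bins with too few steps carry NaN."""

    x: np.ndarray       # bin centers, µm
    f: np.ndarray       # fN
    f_se: np.ndarray
    D: np.ndarray       # µm²/s
    D_se: np.ndarray
    n: np.ndarray       # steps per bin
    dt: float
    kBT: float

    @property
    def valid(self) -> np.ndarray:
        return self.n >= MIN_STEPS_PER_BIN


def fit_drift_diffusion(
    trajs,
    bin_edges,
    dt: float | None = None,
    units: Units = DEFAULT_UNITS,
) -> DriftDiffusionEstimate:
    """Per-bin Gaussian (moment-matching) fit of single-step displacements."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise InvalidParameterError("bin_edges must be increasing with >= 2 entries")
    starts, steps = [], []
    for traj in trajs:
        if dt is None:
            dt = traj.dt
        elif not np.isclose(traj.dt, dt, rtol=1e-6):
            raise InvalidParameterError(
                f"trajectory sampling interval {traj.dt} != requested dt {dt}"
            )
        starts.append(traj.x[:-1])
        steps.append(np.diff(traj.x))
    x0 = np.concatenate(starts)
    dx = np.concatenate(steps)
    nb = edges.size - 1
    idx = np.digitize(x0, edges) - 1
    ok = (idx >= 0) & (idx < nb)
    idx, dx = idx[ok], dx[ok]
    centers = 0.5 * (edges[:-1] + edges[1:])
    f = np.full(nb, np.nan)
    f_se = np.full(nb, np.nan)
    Dh = np.full(nb, np.nan)
    D_se = np.full(nb, np.nan)
    counts = np.bincount(idx, minlength=nb)
    for b in range(nb):
        if counts[b] < MIN_STEPS_PER_BIN:
            continue  # flagged: too few steps for a meaningful estimate
        d = dx[idx == b]
        m = d.mean()
        v = d.var(ddof=1)
        Dh[b] = v / (2.0 * dt)
        D_se[b] = Dh[b] * np.sqrt(2.0 / (d.size - 1))
        f[b] = m * units.kBT / (Dh[b] * dt)
        f_se[b] = (np.sqrt(v / d.size)) * units.kBT / (Dh[b] * dt)
    return DriftDiffusionEstimate(
        x=centers, f=f, f_se=f_se, D=Dh, D_se=D_se, n=counts, dt=float(dt),
        kBT=units.kBT,
    )


def pooled_estimate(est: DriftDiffusionEstimate) -> tuple[float, float]:
    """Count-weighted (f, D) over valid bins — the global estimate for a
    spatially uniform landscape segment."""
    m = est.valid
    if not np.any(m):
        raise EstimationError("no bin has enough steps for a pooled estimate")
    w = est.n[m] / est.n[m].sum()
    return float(np.sum(w * est.f[m])), float(np.sum(w * est.D[m]))


def force_from_exit_counts(
    n_left: int,
    n_right: int,
    L: float,
    units: Units = DEFAULT_UNITS,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Force from the left/right exit split of a centred interval of length L.

    Inverts P_right = (1 + e^{−fL/(2 kBT)})⁻¹, i.e. f̂ = (2kBT/L)·
    ln(n_right/n_left), positive when the majority exit is rightward.  The
    Wilson score interval on the exit fraction is propagated through the
    (monotone) logit transform; with a zero count the estimate is infinite and
    the interval one-sided.
    """
    n = n_left + n_right
    if n < 20:
        raise EstimationError("need at least 20 exits to infer a force")
    if L <= 0:
        raise InvalidParameterError("interval length must be positive")
    scale = 2.0 * units.kBT / L

    def _f_of_p(p: float) -> float:
        if p <= 0.0:
            return -np.inf
        if p >= 1.0:
            return np.inf
        return scale * np.log(p / (1.0 - p))

    p_hat = n_right / n
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    denom = 1.0 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = z / denom * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2))
    lo, hi = center - half, center + half
    return _f_of_p(p_hat), (_f_of_p(lo), _f_of_p(hi))


def reconstruct_potential(est: DriftDiffusionEstimate):
    """Potential U(x) in kBT over the contiguous valid bins by trapezoidal
    integration of -f̂ from the left end; returns (x, U, U_se)."""
    m = est.valid
    if not np.any(m):
        raise EstimationError("no valid bins to integrate")
    idx = np.flatnonzero(m)
    if np.any(np.diff(idx) != 1):
        raise EstimationError("valid bins are not contiguous; cannot integrate")
    x = est.x[idx]
    f = est.f[idx]
    fse = est.f_se[idx]
    units = Units(est.kBT)
    U = potential_from_force(x, f, units)
    # SE accumulates in quadrature along the trapezoid sum
    dxs = np.diff(x)
    var_inc = (dxs / 2.0) ** 2 * (fse[:-1] ** 2 + fse[1:] ** 2) / est.kBT**2
    U_se = np.sqrt(np.concatenate([[0.0], np.cumsum(var_inc)]))
    return x, U, U_se
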