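"""Synthetic-data generator: overdamped Langevin dynamics and experiment protocols.

Integrates γ dx/dt = f_ext(t) − dU/dx + sqrt(2 kBT γ) ξ(t) by Euler–Maruyama,
with γ = kBT/D(x) (Einstein–Stokes) and the kinetic-convention spurious drift
+dD/dx for spatially varying diffusion, so that the simulator and the
Fokker–Planck module agree on the stationary state.  This module is the
package's stand-in for the optical-tweezers experiments it emulates: colloids
in a 4 µm microchannel under fN-scale forces, a bistable landscape under a
randomly sign-switching force, and a hairpin-like extension coordinate under
two-level force feedback.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import DomainError, InvalidParameterError
from .model import (
    DEFAULT_UNITS,
    ConstantD,
    DiffusionProfile,
    PotentialSpec,
    Quartic,
    TelegraphSpec,
    Units,
    as_diffusion,
    quartic_from_barrier,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "ProtocolResult",
    "simulate_overdamped",
    "run_exit_protocol",
    "hairpin_preset",
]

_N_TAB = 4097  # drift/noise table resolution; interpolation error O(h²) ≪ kBT


@dataclass(frozen=True)
class SimConfig:
    """Integrator configuration.

    dt default 1e-3 s is well below the fastest well-relaxation time at the
    parameter scales of the systems emulated here (γ/U'' ≳ 0.04 s).
    """

    dt: float = 1e-3
    t_max: float = 10.0
    x0: float = 0.0
    record_stride: int = 1
    reflecting_bounds: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if self.t_max < self.dt:
            raise InvalidParameterError("t_max must be >= dt")
        if self.record_stride < 1:
            raise InvalidParameterError("record_stride must be >= 1")
        if self.reflecting_bounds is not None:
            lo, hi = self.reflecting_bounds
            if not lo < hi:
                raise InvalidParameterError("reflecting_bounds must be ordered (lo, hi)")


@dataclass
class Trajectory:
    """Uniformly sampled time series of position (and optional telegraph force)."""

    t: np.ndarray
    x: np.ndarray
    fext: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.shape != self.x.shape or self.t.ndim != 1:
            raise InvalidParameterError("t and x must be 1D arrays of equal length")
        if self.t.size >= 2:
            dts = np.diff(self.t)
            if np.any(dts <= 0):
                raise InvalidParameterError("t must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise InvalidParameterError("t must be uniformly spaced")
        if self.fext is not None:
            self.fext = np.asarray(self.fext, dtype=float)
            if self.fext.shape != self.t.shape:
                raise InvalidParameterError("fext must match t in length")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size

    def reversed(self) -> "Trajectory":
        """Time-reversed copy (same time grid, reversed path)."""
        fx = None if self.fext is None else self.fext[::-1].copy()
        return Trajectory(self.t.copy(), self.x[::-1].copy(), fx)


@dataclass(frozen=True)
class ProtocolResult:
    """Outcome of one exit-protocol repeat."""

    side: str  # "left" | "right" | "censored"
    tau: float  # s; nan when censored
    trajectory: Trajectory | None = None


def _child_seed(seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _tables(
    potential: PotentialSpec,
    D: DiffusionProfile,
    domain: tuple[float, float],
    units: Units,
):
    lo, hi = domain
    xg = np.linspace(lo, hi, _N_TAB)
    Dv = np.asarray(D.value(xg), dtype=float)
    dDdx = np.asarray(D.grad(xg), dtype=float)
    # drift = -dU/dx · D/kBT + dD/dx  (µm/s); mobility D/kBT couples f_ext
    grad = np.asarray(potential.grad(xg, units.kBT), dtype=float)
    drift = -grad * Dv + dDdx
    sig = np.sqrt(2.0 * Dv)
    mob = Dv / units.kBT
    inv_h = (_N_TAB - 1) / (hi - lo)
    return xg[0], inv_h, drift, sig, mob


def _auto_domain(
    potential: PotentialSpec,
    D: DiffusionProfile,
    cfg: SimConfig,
    units: Units,
) -> tuple[float, float]:
    if cfg.reflecting_bounds is not None:
        lo, hi = cfg.reflecting_bounds
    elif D.domain is not None:
        lo, hi = D.domain
    elif hasattr(potential, "x"):  # tabulated potential
        lo, hi = potential.x[0], potential.x[-1]
    elif isinstance(potential, Quartic):
        # confine to where U exceeds its minimum by 50 kBT — never reached
        span = (200.0 / potential.a) ** 0.25 + (abs(potential.b) / potential.a) ** 0.5 + 2.0
        lo, hi = cfg.x0 - span, cfg.x0 + span
    else:
        # non-confining potential: cover the drift + 6σ diffusion envelope
        v = float(np.max(np.abs(potential.grad(np.array([cfg.x0]), units.kBT)))) * _max_D(D)
        span = v * cfg.t_max + 6.0 * np.sqrt(2.0 * _max_D(D) * cfg.t_max) + 1.0
        lo, hi = cfg.x0 - span, cfg.x0 + span
    if not (lo < cfg.x0 < hi):
        raise InvalidParameterError(f"x0={cfg.x0} outside simulation domain ({lo}, {hi})")
    return float(lo), float(hi)


def _max_D(D: DiffusionProfile) -> float:
    if isinstance(D, ConstantD):
        return D.D
    return float(np.max(D.D))


def simulate_overdamped(
    potential: PotentialSpec,
    D: DiffusionProfile | float,
    telegraph: TelegraphSpec | None,
    cfg: SimConfig,
    units: Units = DEFAULT_UNITS,
) -> Trajectory:
    """Euler–Maruyama trajectory; reproducible under a fixed cfg.seed."""
    D = as_diffusion(D)
    domain = _auto_domain(potential, D, cfg, units)
    tab_lo, inv_h, drift, sig, mob = _tables(potential, D, domain, units)
    n_steps = int(round(cfg.t_max / cfg.dt))
    if telegraph is not None and telegraph.f0 > 0:
        f0 = telegraph.f0
        rate = telegraph.alpha / 2.0
        rng = np.random.default_rng(_child_seed(cfg.seed, 1))
        if telegraph.initial_level == "random":
            level0 = int(rng.choice([-1, 1]))
        else:
            level0 = int(telegraph.initial_level)
    else:
        f0, rate, level0 = 0.0, 0.0, 1
    reflect = cfg.reflecting_bounds is not None
    x_rec, lv_rec, status = _kernels.em_run(
        float(cfg.x0),
        n_steps,
        float(cfg.dt),
        int(cfg.record_stride),
        tab_lo,
        inv_h,
        drift,
        sig,
        mob,
        float(f0),
        float(rate),
        level0,
        domain[0],
        domain[1],
        reflect,
        _child_seed(cfg.seed, 0),
    )
    if status != 0:
        raise DomainError(
            f"trajectory left the simulation domain {domain} with no reflecting bounds"
        )
    t = np.arange(x_rec.size) * (cfg.dt * cfg.record_stride)
    fext = lv_rec.astype(float) * f0 if telegraph is not None else None
    return Trajectory(t=t, x=x_rec, fext=fext)


def run_exit_protocol(
    potential: PotentialSpec,
    D: DiffusionProfile | float,
    interval: tuple[float, float],
    cfg: SimConfig,
    n_repeats: int,
    units: Units = DEFAULT_UNITS,
) -> list[ProtocolResult]:
    """Automated drag-and-drop emulation: initialize at cfg.x0, integrate until
    the first crossing of either interval boundary (crossing time linearly
    interpolated within the step) or t_max (censored)."""
    if n_repeats < 1:
        raise InvalidParameterError("n_repeats must be >= 1")
    xl, xr = interval
    if not xl < cfg.x0 < xr:
        raise InvalidParameterError("x0 must lie strictly inside the interval")
    D = as_diffusion(D)
    # pad the table past the absorbing boundaries to cover the overshoot step
    pad = 0.25 * (xr - xl)
    tab_lo_, inv_h, drift, sig, _ = _tables(potential, D, (xl - pad, xr + pad), units)
    max_steps = int(round(cfg.t_max / cfg.dt))
    seeds = np.array(
        [_child_seed(cfg.seed, 2, r) for r in range(n_repeats)], dtype=np.uint32
    )
    sides, taus = _kernels.em_exit_batch(
        float(cfg.x0), float(xl), float(xr), max_steps, float(cfg.dt),
        tab_lo_, inv_h, drift, sig, seeds,
    )
    out = []
    for s, tau in zip(sides, taus):
        if s == 0:
            out.append(ProtocolResult(side="censored", tau=float("nan")))
        else:
            out.append(ProtocolResult(side="left" if s < 0 else "right", tau=float(tau)))
    return out


def hairpin_preset(
    force_levels: tuple[float, float] = (-14.0, 14.0),
    alpha: float = 0.2,
    barrier: float = 4.0,
    asymmetry: float = 1.0,
    extension_span: float = 1.0,
    units: Units = DEFAULT_UNITS,
    seed: int = 0,
) -> tuple[PotentialSpec, TelegraphSpec, SimConfig]:
    """Hairpin-like bistable extension coordinate under two-level force feedback.

    An asymmetric quartic in the extension coordinate (folded F near -span/2,
    unfolded U near +span/2; the F well deeper by ``asymmetry`` kBT, as for a
    hairpin held below its coexistence force) is tilted by a telegraph force
    switching between the two given levels.  Defaults are chosen so that
    (i) the tilt at each level dominates the well asymmetry (±14 fN over a
    1 µm span shifts the wells by ±1.7 kBT), so all four (extension × force)
    states F±, U± are visited, (ii) the mean dwell per force level, 2/α =
    10 s, exceeds the downhill relaxation time of a few seconds, producing
    four metastable occupancy lobes, and (iii) the well asymmetry makes the
    intermediate dwells path-dependent, which is what renders the
    corner-to-corner path times directionally asymmetric.  With equal force
    levels the preset degenerates to an equilibrium two-state system.
    """
    f_lo, f_hi = force_levels
    if barrier <= 0 or extension_span <= 0:
        raise InvalidParameterError("barrier and extension_span must be positive")
    base = quartic_from_barrier(barrier, asymmetry, extension_span)
    f_mean = 0.5 * (f_lo + f_hi)
    f0 = 0.5 * abs(f_hi - f_lo)
    # constant (mean) part of the force enters the landscape as a linear tilt
    potential = Quartic(a=base.a, b=base.b, c=base.c - f_mean / units.kBT)
    telegraph = TelegraphSpec(f0=f0, alpha=alpha, initial_level="random", seed=seed)
    half = 1.5 * extension_span
    cfg = SimConfig(
        dt=1e-3,
        t_max=4000.0,
        x0=-extension_span / 2.0,
        record_stride=5,
        reflecting_bounds=(-half, half),
        seed=seed,
    )
    return potential, telegraph, cfg
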