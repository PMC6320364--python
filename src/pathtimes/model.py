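"""Energy landscapes, diffusion profiles, units, and the telegraph force process.

Internal unit system: length in µm, time in s, force in fN, energy in kBT.
1 fN·µm = 1e-21 J, so thermal energy at ~298 K is kBT ≈ 4.11 fN·µm; all
quantities of the systems studied here are then O(1).  Energies are stored in
kBT and forces in fN; every conversion between the two goes through
:class:`Units` to avoid silent unit bugs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DomainError, EstimationError, InvalidParameterError

__all__ = [
    "Units",
    "Quartic",
    "Linear",
    "TrapMixture",
    "Tabulated",
    "PotentialSpec",
    "DiffusionProfile",
    "ConstantD",
    "TabulatedD",
    "TelegraphSpec",
    "quartic_from_barrier",
    "quartic_minima",
    "potential_eval",
    "potential_grad",
    "force_eval",
    "potential_from_force",
    "sample_telegraph",
    "fit_decorrelation_rate",
]


@dataclass(frozen=True)
class Units:
    """Unit system anchor: thermal energy in fN·µm (default ≈ 298 K)."""

    kBT: float = 4.11

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise InvalidParameterError(f"kBT must be positive, got {self.kBT}")


DEFAULT_UNITS = Units()


# ---------------------------------------------------------------------------
# Potentials.  Each variant exposes energy(x, kBT) in kBT and grad(x, kBT) in
# kBT/µm; the force in fN is -grad * kBT (see force_eval).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Quartic:
    """Bistable asymmetric quartic U(x) = a/4 x⁴ + b/2 x² + c x (kBT, x in µm).

    a > 0 gives confinement; b < 0 a double well; c tilts the landscape and
    controls the asymmetry around x = 0.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidParameterError(f"quartic requires a > 0, got a={self.a}")

    def energy(self, x, kBT: float = DEFAULT_UNITS.kBT):
        x = np.asarray(x, dtype=float)
        return self.a / 4.0 * x**4 + self.b / 2.0 * x**2 + self.c * x

    def grad(self, x, kBT: float = DEFAULT_UNITS.kBT):
        x = np.asarray(x, dtype=float)
        return self.a * x**3 + self.b * x + self.c


@dataclass(frozen=True)
class Linear:
    """Constant-force tilt: U(x) = -(f/kBT)·x with f in fN (positive → rightward)."""

    f: float

    def energy(self, x, kBT: float = DEFAULT_UNITS.kBT):
        x = np.asarray(x, dtype=float)
        return -(self.f / kBT) * x

    def grad(self, x, kBT: float = DEFAULT_UNITS.kBT):
        x = np.asarray(x, dtype=float)
        return np.broadcast_to(-(self.f / kBT), x.shape).copy() if x.shape else -(self.f / kBT)


@dataclass(frozen=True)
class TrapMixture:
    """Sum of Gaussian optical wells: U(x) = -Σ dᵢ exp(-(x-cᵢ)²/(2wᵢ²)).

    Each trap is (center µm, depth kBT, width µm).  Gaussian wells are the
    package's model for point/line optical traps; the functional form of a
    real trap is instrument-specific.
    """

    traps: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        traps = tuple(tuple(float(v) for v in t) for t in self.traps)
        for (_, _, w) in traps:
            if w <= 0:
                raise InvalidParameterError(f"trap width must be > 0, got {w}")
        object.__setattr__(self, "traps", traps)

    def energy(self, x, kBT: float = DEFAULT_UNITS.kBT):
        x = np.asarray(x, dtype=float)
        u = np.zeros_like(x)
        for c, d, w in self.traps:
            u -= d * np.exp(-((x - c) ** 2) / (2 * w**2))
        return u

    def grad(self, x, kBT: float = DEFAULT_UNITS.kBT):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for c, d, w in self.traps:
            g += d * (x - c) / w**2 * np.exp(-((x - c) ** 2) / (2 * w**2))
        return g


@dataclass(frozen=True)
class Tabulated:
    """Tabulated U(x) with cubic-spline interpolation; extrapolation forbidden."""

    x: tuple[float, ...]
    U: tuple[float, ...]
    _spline: CubicSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        U = np.asarray(self.U, dtype=float)
        if x.ndim != 1 or x.size < 4:
            raise InvalidParameterError("tabulated potential needs >= 4 grid points")
        if x.size != U.size:
            raise InvalidParameterError("x grid and U values must have equal length")
        if not np.all(np.diff(x) > 0):
            raise InvalidParameterError("tabulated x grid must be strictly increasing")
        object.__setattr__(self, "x", tuple(x))
        object.__setattr__(self, "U", tuple(U))
        object.__setattr__(self, "_spline", CubicSpline(x, U))

    def _check_domain(self, xq: np.ndarray) -> None:
        if np.any(xq < self.x[0]) or np.any(xq > self.x[-1]):
            raise DomainError(
                f"x outside tabulated domain [{self.x[0]}, {self.x[-1]}]"
            )

    def energy(self, x, kBT: float = DEFAULT_UNITS.kBT):
        xq = np.asarray(x, dtype=float)
        self._check_domain(xq)
        return self._spline(xq)

    def grad(self, x, kBT: float = DEFAULT_UNITS.kBT):
        xq = np.asarray(x, dtype=float)
        self._check_domain(xq)
        return self._spline(xq, 1)


PotentialSpec = Quartic | Linear | TrapMixture | Tabulated


def quartic_from_barrier(dU1: float, dU2: float, L: float) -> Quartic:
    """Quartic coefficients from barrier height ΔU1 (kBT), asymmetry ΔU2 (kBT)
    and well separation L (µm): a = 64ΔU1/L⁴, b = -aL²/4, c = 2ΔU2/L.

    For ΔU2 = 0 the minima sit at ±L/2, each ΔU1 below U(0).
    """
    if dU1 <= 0 or L <= 0:
        raise InvalidParameterError(
            f"barrier dU1 and separation L must be positive (got {dU1}, {L})"
        )
    a = 64.0 * dU1 / L**4
    return Quartic(a=a, b=-a * L**2 / 4.0, c=2.0 * dU2 / L)


def quartic_minima(spec: Quartic) -> tuple[float, float]:
    """Positions of the two local minima of a bistable quartic (left, right)."""
    roots = np.roots([spec.a, 0.0, spec.b, spec.c])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    if real.size != 3:
        raise InvalidParameterError("quartic is not bistable at these coefficients")
    return float(real[0]), float(real[2])


def potential_eval(spec: PotentialSpec, x, units: Units = DEFAULT_UNITS):
    """U(x) in kBT."""
    return spec.energy(x, units.kBT)


def potential_grad(spec: PotentialSpec, x, units: Units = DEFAULT_UNITS):
    """dU/dx in kBT/µm."""
    return spec.grad(x, units.kBT)


def force_eval(spec: PotentialSpec, x, units: Units = DEFAULT_UNITS):
    """Mechanical force -dU/dx in fN."""
    return -np.asarray(spec.grad(x, units.kBT)) * units.kBT


def potential_from_force(x_grid, f, units: Units = DEFAULT_UNITS) -> np.ndarray:
    """Potential in kBT from a force profile in fN by trapezoidal integration,
    U(x) = -∫ f dx' from the left end, anchored at U(x_grid[0]) = 0."""
    x = np.asarray(x_grid, dtype=float)
    fv = np.asarray(f, dtype=float)
    if x.shape != fv.shape or x.ndim != 1:
        raise InvalidParameterError("x_grid and f must be 1D arrays of equal length")
    if not np.all(np.diff(x) > 0):
        raise InvalidParameterError("x_grid must be strictly increasing")
    U = np.zeros_like(x)
    U[1:] = -np.cumsum(np.diff(x) / 2.0 * (fv[:-1] + fv[1:]))
    return U / units.kBT


# ---------------------------------------------------------------------------
# Diffusion profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantD:
    """Spatially uniform diffusion coefficient, µm²/s."""

    D: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise InvalidParameterError(f"D must be positive, got {self.D}")

    def value(self, x):
        x = np.asarray(x, dtype=float)
        return np.broadcast_to(self.D, x.shape).copy() if x.shape else self.D

    def grad(self, x):
        x = np.asarray(x, dtype=float)
        return np.zeros_like(x) if x.shape else 0.0

    @property
    def domain(self) -> tuple[float, float] | None:
        return None


@dataclass(frozen=True)
class TabulatedD:
    """Tabulated D(x) (µm²/s), cubic-spline interpolated; must stay positive."""

    x: tuple[float, ...]
    D: tuple[float, ...]
    _spline: CubicSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        D = np.asarray(self.D, dtype=float)
        if x.size != D.size or x.size < 4:
            raise InvalidParameterError("tabulated D needs >= 4 matching grid points")
        if not np.all(np.diff(x) > 0):
            raise InvalidParameterError("tabulated D grid must be strictly increasing")
        if np.any(D <= 0):
            raise InvalidParameterError("D(x) must be positive everywhere")
        object.__setattr__(self, "x", tuple(x))
        object.__setattr__(self, "D", tuple(D))
        object.__setattr__(self, "_spline", CubicSpline(x, D))

    def value(self, x):
        xq = np.asarray(x, dtype=float)
        if np.any(xq < self.x[0]) or np.any(xq > self.x[-1]):
            raise DomainError(f"x outside tabulated D domain [{self.x[0]}, {self.x[-1]}]")
        return self._spline(xq)

    def grad(self, x):
        xq = np.asarray(x, dtype=float)
        if np.any(xq < self.x[0]) or np.any(xq > self.x[-1]):
            raise DomainError(f"x outside tabulated D domain [{self.x[0]}, {self.x[-1]}]")
        return self._spline(xq, 1)

    @property
    def domain(self) -> tuple[float, float]:
        return (self.x[0], self.x[-1])


DiffusionProfile = ConstantD | TabulatedD


def as_diffusion(D: DiffusionProfile | float) -> DiffusionProfile:
    return ConstantD(float(D)) if isinstance(D, (int, float)) else D


# ---------------------------------------------------------------------------
# Telegraph (dichotomous) force process
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-level force switching between +f0 and -f0 (fN).

    ``alpha`` is the decorrelation rate of the process, defined through the
    autocovariance <f(t+Δt) f(t)> ∝ exp(-α Δt).  For a symmetric two-level
    process this means the per-direction switch rate is α/2 and the mean dwell
    time per level is 2/α.
    """

    f0: float
    alpha: float
    initial_level: int | str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 < 0:
            raise InvalidParameterError(f"telegraph amplitude f0 must be >= 0, got {self.f0}")
        if self.alpha <= 0:
            raise InvalidParameterError(f"decorrelation rate alpha must be > 0, got {self.alpha}")
        if self.initial_level not in (+1, -1, "random"):
            raise InvalidParameterError("initial_level must be +1, -1 or 'random'")


def _initial_level(spec: TelegraphSpec, rng: np.random.Generator) -> int:
    if spec.initial_level == "random":
        return int(rng.choice([-1, 1]))
    return int(spec.initial_level)


def sample_telegraph(spec: TelegraphSpec, t_grid) -> np.ndarray:
    """Telegraph levels in {+1, -1} on ``t_grid`` (piecewise constant).

    Switch times are a Poisson process of rate α/2 (exponential dwell times of
    mean 2/α), which yields the autocovariance decay e^{-αΔt}.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0 or not np.all(np.diff(t) > 0):
        raise InvalidParameterError("t_grid must be a non-empty increasing 1D array")
    rng = np.random.default_rng(spec.seed)
    level0 = _initial_level(spec, rng)
    span = t[-1] - t[0]
    rate = spec.alpha / 2.0
    # Draw dwell times in blocks until the grid is covered.
    switch_times: list[np.ndarray] = []
    total = 0.0
    n_guess = max(16, int(rate * span * 1.5) + 16)
    while total <= span:
        dwells = rng.exponential(1.0 / rate, size=n_guess)
        switch_times.append(dwells)
        total += dwells.sum()
    cum = t[0] + np.cumsum(np.concatenate(switch_times))
    n_switches_before = np.searchsorted(cum, t, side="right")
    levels = level0 * (-1) ** n_switches_before
    return levels.astype(np.int8)


def fit_decorrelation_rate(levels, t_grid, max_lag_fraction: float = 0.1):
    """Least-squares estimate of the decorrelation rate α from a level series.

    Fits log of the empirical autocovariance against lag over the range where
    the autocovariance stays above 20% of the variance (exponential decay is
    well resolved there).  Returns (alpha_hat, standard_error).
    """
    lv = np.asarray(levels, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if lv.size != t.size or lv.size < 10:
        raise EstimationError("need a level sample on the same grid with >= 10 points")
    n_switches = int(np.count_nonzero(np.diff(lv)))
    if n_switches < 2:
        raise EstimationError(
            f"only {n_switches} switches observed; cannot estimate a rate"
        )
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-12):
        raise EstimationError("t_grid must be uniform for the autocovariance fit")
    z = lv - lv.mean()
    var = float(np.mean(z * z))
    max_lag = max(2, int(round(max_lag_fraction * lv.size)))
    lags = np.arange(1, max_lag)
    acov = np.array([np.mean(z[: -k or None] * z[k:]) for k in lags])
    keep = acov > 0.2 * var
    # Stop at the first lag that drops below the floor to avoid log of noise.
    if not keep[0]:
        raise EstimationError("autocovariance decays below the fit floor at lag 1")
    n_keep = int(np.argmin(keep)) if not keep.all() else keep.size
    if n_keep < 3:
        raise EstimationError("fewer than 3 usable lags for the log-linear fit")
    tau = lags[:n_keep] * dt
    y = np.log(acov[:n_keep] / var)
    A = np.vstack([tau, np.ones_like(tau)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    alpha_hat = -float(coef[0])
    # Residual-based regression SEs are meaningless here (neighbouring-lag
    # autocovariances are strongly correlated); the information content of the
    # series is the number of observed switches, each dwell contributing one
    # exponential draw, so the relative error of a rate estimate is 1/sqrt(n).
    se = alpha_hat / np.sqrt(n_switches)
    return alpha_hat, se
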