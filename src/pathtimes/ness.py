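"""Non-equilibrium steady-state diagnostics.

A one-dimensional coordinate driven by telegraph noise lives in an effectively
two-dimensional phase space (position × force).  In that space a NESS shows
up as (i) a splitting of metastable states into doublets, (ii) non-zero
coarse-grained probability currents circulating between bins (broken detailed
balance), and (iii) direction-dependent transition-path times.  This module
measures all three from trajectories.

Circulation statistic: the net inter-bin fluxes J are lever-weighted around
the occupancy centroid, giving a signed "angular momentum" of the probability
current.  It is exactly antisymmetric under time reversal and has zero mean
under detailed balance, so a block-decomposition z-score against zero is an
assumption-free test; the non-negative ``circulation_score`` normalizes its
magnitude by the total number of inter-bin crossings.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import EstimationError, InvalidParameterError
from .events import IntervalSpec, detect_transition_paths, ks_two_sample, summarize
from .model import DEFAULT_UNITS, DiffusionProfile, PotentialSpec, TelegraphSpec, Units
from .simulate import SimConfig, Trajectory, simulate_overdamped

__all__ = [
    "OccupancyGrid",
    "CurrentField",
    "SweepResult",
    "HairpinStates",
    "occupancy_2d",
    "coarse_current_2d",
    "circulation_null_test",
    "asymmetry_sweep",
    "classify_hairpin_states",
    "doublet_transition_times",
]


def _total_force(traj: Trajectory, potential: PotentialSpec, units: Units) -> np.ndarray:
    """f_total = f_ext − dU/dx in fN at every sample."""
    if traj.fext is None:
        raise InvalidParameterError("trajectory must carry the external-force column")
    grad = np.asarray(potential.grad(traj.x, units.kBT), dtype=float)
    return traj.fext - grad * units.kBT


@dataclass
class OccupancyGrid:
    """Normalized 2D histogram over (position, total force)."""

    x_edges: np.ndarray
    f_edges: np.ndarray
    P: np.ndarray  # shape (n_x_bins, n_f_bins), sums to 1

    def __post_init__(self) -> None:
        if abs(float(self.P.sum()) - 1.0) > 1e-9 or np.any(self.P < 0):
            raise InvalidParameterError("occupancy must be a normalized histogram")


@dataclass
class CurrentField:
    """Coarse-grained net probability currents between adjacent bins.

    J_x[i, j]: net crossings/s from x-bin i to i+1 within force-bin j;
    J_f[i, j]: net crossings/s from force-bin j to j+1 within x-bin i.
    Both are antisymmetric under swapping the bin pair by construction
    (a reverse crossing counts as −1).  ``circulation`` is the signed
    lever-weighted sum; ``circulation_score`` = |circulation| / total
    crossings ≥ 0.
    """

    x_edges: np.ndarray
    f_edges: np.ndarray
    J_x: np.ndarray
    J_f: np.ndarray
    circulation: float
    circulation_score: float
    total_crossings: int


def occupancy_2d(
    traj: Trajectory,
    potential: PotentialSpec,
    bins: tuple[int, int] | tuple[np.ndarray, np.ndarray] = (40, 40),
    units: Units = DEFAULT_UNITS,
) -> OccupancyGrid:
    """Occupancy P_ij of the (position × total force) plane."""
    f_tot = _total_force(traj, potential, units)
    H, x_edges, f_edges = np.histogram2d(traj.x, f_tot, bins=bins)
    P = H / H.sum()
    return OccupancyGrid(x_edges=x_edges, f_edges=f_edges, P=P)


def _bin_series(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.clip(np.digitize(values, edges) - 1, 0, edges.size - 2)
    return idx


def _currents(xb, fb, xmb, fmb, n_x, n_f, T):
    """Net inter-bin crossing rates from bin-index series (length N).

    A crossing is attributed to the lane of the *midpoint* of the segment
    (xmb/fmb are the bin indices of segment midpoints): midpoints are
    invariant under time reversal, so reversing the trajectory negates every
    J exactly, and motion along a static curve f(x) generates no spurious
    lane asymmetry.
    """
    dxb = np.diff(xb)
    dfb = np.diff(fb)
    J_x = np.zeros((n_x - 1, n_f))
    J_f = np.zeros((n_x, n_f - 1))
    single = np.abs(dxb) == 1
    np.add.at(
        J_x,
        (np.minimum(xb[:-1], xb[1:])[single], fmb[single]),
        np.sign(dxb[single]).astype(float),
    )
    # rare multi-bin jumps cross every intermediate edge (keeps J consistent
    # with a continuous path)
    multi = np.flatnonzero(np.abs(dxb) > 1)
    for k in multi:
        i0, i1, j = xb[k], xb[k + 1], fmb[k]
        step = 1.0 if i1 > i0 else -1.0
        J_x[min(i0, i1):max(i0, i1), j] += step
    singlef = np.abs(dfb) == 1
    np.add.at(
        J_f,
        (xmb[singlef], np.minimum(fb[:-1], fb[1:])[singlef]),
        np.sign(dfb[singlef]).astype(float),
    )
    multif = np.flatnonzero(np.abs(dfb) > 1)
    for k in multif:
        j0, j1, i = fb[k], fb[k + 1], xmb[k]
        step = 1.0 if j1 > j0 else -1.0
        J_f[i, min(j0, j1):max(j0, j1)] += step
    total = int(np.count_nonzero(dxb) + np.count_nonzero(dfb))
    return J_x / T, J_f / T, total


def _signed_circulation(J_x, J_f, x_c, f_c, x_edges, f_edges, x_scale, f_scale):
    """Angular momentum of the current field about the centroid (x_c, f_c),
    with each axis normalized by its scale so the two contribute comparably."""
    xe = 0.5 * (x_edges[:-1] + x_edges[1:])  # x-bin centers
    fe = 0.5 * (f_edges[:-1] + f_edges[1:])
    circ = 0.0
    # x-edge currents: lever arm is the force coordinate of the lane
    for j in range(J_x.shape[1]):
        lever = (fe[j] - f_c) / f_scale
        circ -= float(J_x[:, j].sum()) * lever
    for i in range(J_f.shape[0]):
        lever = (xe[i] - x_c) / x_scale
        circ += float(J_f[i, :].sum()) * lever
    return circ


def coarse_current_2d(
    traj: Trajectory,
    potential: PotentialSpec,
    bins: tuple[int, int] = (24, 24),
    units: Units = DEFAULT_UNITS,
) -> CurrentField:
    """Coarse-grained currents in the (position × total force) plane."""
    f_tot = _total_force(traj, potential, units)
    x_edges = np.histogram_bin_edges(traj.x, bins=bins[0])
    f_edges = np.histogram_bin_edges(f_tot, bins=bins[1])
    T = float(traj.t[-1] - traj.t[0])
    xb = _bin_series(traj.x, x_edges)
    fb = _bin_series(f_tot, f_edges)
    xmb = _bin_series(0.5 * (traj.x[:-1] + traj.x[1:]), x_edges)
    fmb = _bin_series(0.5 * (f_tot[:-1] + f_tot[1:]), f_edges)
    J_x, J_f, total = _currents(xb, fb, xmb, fmb, x_edges.size - 1, f_edges.size - 1, T)
    x_c, f_c = float(traj.x.mean()), float(f_tot.mean())
    x_s, f_s = float(traj.x.std()) or 1.0, float(f_tot.std()) or 1.0
    circ = _signed_circulation(J_x, J_f, x_c, f_c, x_edges, f_edges, x_s, f_s)
    score = abs(circ) * T / total if total else 0.0
    return CurrentField(
        x_edges=x_edges, f_edges=f_edges, J_x=J_x, J_f=J_f,
        circulation=circ, circulation_score=score, total_crossings=total,
    )


def circulation_null_test(
    traj: Trajectory,
    potential: PotentialSpec,
    bins: tuple[int, int] = (24, 24),
    n_blocks: int = 10,
    units: Units = DEFAULT_UNITS,
) -> tuple[float, float]:
    """z-score of the signed circulation against the detailed-balance null.

    The trajectory is cut into ``n_blocks`` contiguous blocks; the signed
    circulation (computed with the global bin edges and centroid) is averaged
    over blocks and compared with zero via its SEM.  Under detailed balance
    the statistic has zero mean — the time-reversed trajectory gives exactly
    the negated circulation — so |z| > 3 flags broken detailed balance.
    Returns (circulation, z).
    """
    if n_blocks < 3:
        raise InvalidParameterError("need at least 3 blocks for a SEM")
    f_tot = _total_force(traj, potential, units)
    x_edges = np.histogram_bin_edges(traj.x, bins=bins[0])
    f_edges = np.histogram_bin_edges(f_tot, bins=bins[1])
    xb = _bin_series(traj.x, x_edges)
    fb = _bin_series(f_tot, f_edges)
    xmb = _bin_series(0.5 * (traj.x[:-1] + traj.x[1:]), x_edges)
    fmb = _bin_series(0.5 * (f_tot[:-1] + f_tot[1:]), f_edges)
    x_c, f_c = float(traj.x.mean()), float(f_tot.mean())
    x_s, f_s = float(traj.x.std()) or 1.0, float(f_tot.std()) or 1.0
    N = traj.x.size
    edges_idx = np.linspace(0, N, n_blocks + 1, dtype=int)
    vals = []
    for b in range(n_blocks):
        s = slice(edges_idx[b], min(edges_idx[b + 1] + 1, N))
        Tb = float(traj.t[s.stop - 1] - traj.t[s.start])
        sm = slice(s.start, s.stop - 1)
        J_x, J_f, _ = _currents(
            xb[s], fb[s], xmb[sm], fmb[sm], x_edges.size - 1, f_edges.size - 1, Tb
        )
        vals.append(
            _signed_circulation(J_x, J_f, x_c, f_c, x_edges, f_edges, x_s, f_s)
        )
    vals = np.asarray(vals)
    sem = vals.std(ddof=1) / np.sqrt(n_blocks)
    mean = float(vals.mean())
    z = mean / sem if sem > 0 else 0.0
    return mean, float(z)


# ---------------------------------------------------------------------------
# Path-time asymmetry vs telegraph decorrelation rate
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    alphas: np.ndarray
    mean_LR: np.ndarray
    sem_LR: np.ndarray
    mean_RL: np.ndarray
    sem_RL: np.ndarray
    n_LR: np.ndarray
    n_RL: np.ndarray
    ks_p: np.ndarray

    def asymmetry(self) -> np.ndarray:
        """|<τ_L→R> − <τ_R→L>| per decorrelation rate."""
        return np.abs(self.mean_LR - self.mean_RL)


def collect_transitions(
    potential: PotentialSpec,
    D: DiffusionProfile | float,
    telegraph: TelegraphSpec | None,
    interval: IntervalSpec,
    cfg: SimConfig,
    min_events: int,
    max_chunks: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate in chunks of cfg.t_max until ≥ min_events transitions have
    been observed in each direction; returns (τ_L→R, τ_R→L) arrays."""
    taus_lr: list[float] = []
    taus_rl: list[float] = []
    for chunk in range(max_chunks):
        c = replace(cfg, seed=cfg.seed + 7919 * chunk)
        traj = simulate_overdamped(potential, D, telegraph, c)
        for s in detect_transition_paths(traj, interval, traj_id=chunk):
            (taus_lr if s.direction == "L_to_R" else taus_rl).append(s.tau)
        if len(taus_lr) >= min_events and len(taus_rl) >= min_events:
            break
    else:
        raise EstimationError(
            f"could not collect {min_events} events per direction in "
            f"{max_chunks} chunks ({len(taus_lr)}/{len(taus_rl)} found)"
        )
    return np.asarray(taus_lr), np.asarray(taus_rl)


def asymmetry_sweep(
    alphas,
    potential: PotentialSpec,
    D: DiffusionProfile | float,
    f0: float,
    interval: IntervalSpec,
    cfg: SimConfig,
    min_events: int = 1000,
) -> SweepResult:
    """Directional transition-path-time statistics over telegraph rates α."""
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas <= 0):
        raise InvalidParameterError("all alphas must be positive")
    out = {k: [] for k in ("mlr", "slr", "mrl", "srl", "nlr", "nrl", "p")}
    for i, alpha in enumerate(alphas):
        tg = TelegraphSpec(f0=f0, alpha=float(alpha), seed=cfg.seed + i) if f0 > 0 else None
        lr, rl = collect_transitions(potential, D, tg, interval, cfg, min_events)
        m1, s1, n1 = summarize(lr)
        m2, s2, n2 = summarize(rl)
        ks = ks_two_sample(lr, rl)
        out["mlr"].append(m1); out["slr"].append(s1); out["nlr"].append(n1)
        out["mrl"].append(m2); out["srl"].append(s2); out["nrl"].append(n2)
        out["p"].append(ks.p_value)
    return SweepResult(
        alphas=alphas,
        mean_LR=np.asarray(out["mlr"]), sem_LR=np.asarray(out["slr"]),
        mean_RL=np.asarray(out["mrl"]), sem_RL=np.asarray(out["srl"]),
        n_LR=np.asarray(out["nlr"], dtype=int), n_RL=np.asarray(out["nrl"], dtype=int),
        ks_p=np.asarray(out["p"]),
    )


# ---------------------------------------------------------------------------
# Hairpin doublet analysis
# ---------------------------------------------------------------------------


@dataclass
class HairpinStates:
    """Per-sample labels over the (extension × force) doublet structure."""

    labels: np.ndarray  # strings in {F+, F-, U+, U-, transit}

    def fractions(self) -> dict[str, float]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {str(v): float(c) / self.labels.size for v, c in zip(vals, counts)}


def classify_hairpin_states(
    traj: Trajectory,
    x_threshold: float = 0.0,
    level_threshold: float = 0.0,
    buffer: float = 0.0,
) -> HairpinStates:
    """Label each sample F/U by extension against ``x_threshold`` (folded =
    small extension, below threshold) and +/− by the external force against
    ``level_threshold``; samples within ±buffer of the extension threshold are
    'transit'."""
    if traj.fext is None:
        raise InvalidParameterError("hairpin classification needs the force column")
    x = traj.x
    plus = traj.fext > level_threshold
    labels = np.empty(x.size, dtype=object)
    folded = x < x_threshold - buffer
    unfolded = x > x_threshold + buffer
    transit = ~(folded | unfolded)
    labels[folded & plus] = "F+"
    labels[folded & ~plus] = "F-"
    labels[unfolded & plus] = "U+"
    labels[unfolded & ~plus] = "U-"
    labels[transit] = "transit"
    return HairpinStates(labels=np.asarray(labels, dtype="U7"))


def doublet_transition_times(
    traj: Trajectory,
    x_unfolded: float,
    x_folded: float,
    level_hi: float = 0.0,
    level_lo: float = 0.0,
    min_visits: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Corner-to-corner path times between the U+ region (extension ≥
    x_unfolded at force ≥ level_hi) and the F− region (extension ≤ x_folded
    at force ≤ level_lo), including any dwells in the intermediate states
    (U−, F+) along the way.

    A U+→F− sample spans from the last exit of U+ to the first subsequent
    entry into F−, and symmetrically.  Returns (τ[U+→F−], τ[F−→U+]).
    """
    if traj.fext is None:
        raise InvalidParameterError("doublet analysis needs the force column")
    x, f, t = traj.x, traj.fext, traj.t
    in_a = (x >= x_unfolded) & (f >= level_hi)   # U+
    in_b = (x <= x_folded) & (f <= level_lo)     # F-
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a < min_visits or n_b < min_visits:
        raise EstimationError(
            f"corner states underpopulated (U+ {n_a}, F- {n_b} samples)"
        )
    region = np.zeros(x.size, dtype=np.int8)
    region[in_a] = 1
    region[in_b] = -1
    nz = np.flatnonzero(region)
    s = region[nz]
    flips = np.flatnonzero(s[:-1] != s[1:])
    a_to_b, b_to_a = [], []
    for k in flips:
        i, j = nz[k], nz[k + 1]
        tau = float(t[j] - t[i])
        (a_to_b if s[k] == 1 else b_to_a).append(tau)
    return np.asarray(a_to_b), np.asarray(b_to_a)
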