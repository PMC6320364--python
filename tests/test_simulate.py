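"""Langevin integrator and experiment protocols."""
import numpy as np
import pytest

from pathtimes import (
    Linear,
    SimConfig,
    TelegraphSpec,
    Trajectory,
    hairpin_preset,
    quartic_from_barrier,
    run_exit_protocol,
    simulate_overdamped,
)
from pathtimes.errors import InvalidParameterError
from pathtimes.model import TrapMixture
from scipy import stats


D_CHANNEL = 0.15  # µm²/s, microchannel value


class TestFreeDynamics:
    def test_msd_matches_2Dt(self):
        cfg = SimConfig(dt=1e-3, t_max=200.0, reflecting_bounds=(-100, 100), seed=1)
        traj = simulate_overdamped(Linear(0.0), D_CHANNEL, None, cfg)
        lag = 100  # 0.1 s
        dx = traj.x[lag:] - traj.x[:-lag]
        dx = dx[::lag]  # non-overlapping increments
        msd = np.mean(dx**2)
        sem = np.std(dx**2) / np.sqrt(dx.size)
        assert abs(msd - 2 * D_CHANNEL * 0.1) < 3 * sem

    def test_constant_force_drift(self):
        # ensemble of short runs: mean displacement = (f/γ) T = f D T / kBT
        f, T = 3.3, 5.0
        disp = []
        for s in range(40):
            cfg = SimConfig(dt=1e-3, t_max=T, reflecting_bounds=(-50, 50), seed=300 + s)
            tr = simulate_overdamped(Linear(f), D_CHANNEL, None, cfg)
            disp.append(tr.x[-1] - tr.x[0])
        disp = np.asarray(disp)
        expected = f * D_CHANNEL * T / 4.11
        assert abs(disp.mean() - expected) < 3 * disp.std() / np.sqrt(disp.size)

    def test_seeded_determinism(self):
        cfg = SimConfig(dt=1e-3, t_max=5.0, reflecting_bounds=(-5, 5), seed=7)
        a = simulate_overdamped(Linear(1.0), D_CHANNEL, None, cfg)
        b = simulate_overdamped(Linear(1.0), D_CHANNEL, None, cfg)
        assert np.array_equal(a.x, b.x)

    def test_record_stride(self):
        cfg = SimConfig(dt=1e-3, t_max=1.0, record_stride=10, reflecting_bounds=(-5, 5), seed=2)
        tr = simulate_overdamped(Linear(0.0), D_CHANNEL, None, cfg)
        assert tr.dt == pytest.approx(1e-2)
        assert len(tr) == 101


class TestStationarity:
    def test_boltzmann_histogram_not_rejected(self):
        """Equilibrium occupancy follows e^{-U/kBT} (χ² on 20 bins at 1%,
        samples spaced well beyond the relaxation time)."""
        q = quartic_from_barrier(1.0, 0.5, 1.0)
        cfg = SimConfig(
            dt=1e-3, t_max=2.0e5, x0=-0.5, record_stride=2000,
            reflecting_bounds=(-1.2, 1.2), seed=9,
        )
        x = simulate_overdamped(q, D_CHANNEL, None, cfg).x[5:]
        edges = np.linspace(-1.1, 1.1, 21)
        obs, _ = np.histogram(x, edges)
        fine = np.linspace(-1.1, 1.1, 4001)
        w = np.exp(-q.energy(fine))
        b = np.digitize(fine, edges) - 1
        expw = np.array([w[b == i].sum() for i in range(20)])
        expw /= expw.sum()
        chi2 = np.sum((obs - expw * obs.sum()) ** 2 / (expw * obs.sum()))
        assert stats.chi2.sf(chi2, df=19) > 0.01

    def test_telegraph_bistable_occupies_both_wells(self, paper_quartic):
        cfg = SimConfig(
            dt=1e-3, t_max=200.0, x0=-0.5, record_stride=10,
            reflecting_bounds=(-1.6, 1.6), seed=3,
        )
        tg = TelegraphSpec(f0=82.0, alpha=0.5, seed=3)
        tr = simulate_overdamped(paper_quartic, D_CHANNEL, tg, cfg)
        assert tr.fext is not None and set(np.unique(tr.fext)) == {-82.0, 82.0}
        frac_left = np.mean(tr.x < 0)
        assert 0.2 < frac_left < 0.8


class TestExitProtocol:
    def test_symmetric_exit_split(self, channel_interval):
        res = run_exit_protocol(
            Linear(0.0), D_CHANNEL, channel_interval,
            SimConfig(dt=1e-3, t_max=200.0, seed=11), 400,
        )
        n_r = sum(r.side == "right" for r in res)
        n = sum(r.side != "censored" for r in res)
        assert abs(n_r - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_uphill_fraction_matches_splitting_formula(self, channel_interval):
        # P_uphill = 1/(1+e^{fL/2kBT}) ≈ 0.185 at f=3.3 fN, L=3.7 µm
        res = run_exit_protocol(
            Linear(3.3), D_CHANNEL, channel_interval,
            SimConfig(dt=1e-3, t_max=400.0, seed=12), 600,
        )
        n_l = sum(r.side == "left" for r in res)
        n = sum(r.side != "censored" for r in res)
        p = 1.0 / (1.0 + np.exp(1.4854))
        assert abs(n_l - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_deep_trap_censors(self):
        trap = TrapMixture(traps=((0.0, 15.0, 0.1),))
        res = run_exit_protocol(
            trap, D_CHANNEL, (-1.0, 1.0), SimConfig(dt=1e-3, t_max=0.5, seed=1), 20
        )
        assert all(r.side == "censored" for r in res)
        assert all(np.isnan(r.tau) for r in res)

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            run_exit_protocol(Linear(0.0), D_CHANNEL, (-1, 1), SimConfig(seed=0), 0)
        with pytest.raises(InvalidParameterError):
            run_exit_protocol(
                Linear(0.0), D_CHANNEL, (0.5, 1.0), SimConfig(x0=0.0, seed=0), 5
            )


def test_weak_convergence_of_exit_times(channel_interval):
    """Halving dt moves the mean first-exit time by less than the combined
    3·SEM — the integrator converges weakly at the default step."""
    means = []
    sems = []
    for dt in (2e-3, 1e-3):
        res = run_exit_protocol(
            Linear(0.0), D_CHANNEL, channel_interval,
            SimConfig(dt=dt, t_max=300.0, seed=77), 800,
        )
        taus = np.array([r.tau for r in res if r.side != "censored"])
        means.append(taus.mean())
        sems.append(taus.std() / np.sqrt(taus.size))
    assert abs(means[0] - means[1]) < 3 * np.hypot(*sems)


class TestHairpinPreset:
    def test_four_lobes_occupied(self):
        pot, tg, cfg = hairpin_preset(seed=4)
        from dataclasses import replace

        tr = simulate_overdamped(pot, D_CHANNEL, tg, replace(cfg, t_max=3000.0))
        hi = tr.fext > 0
        for name, mask in {
            "F+": (tr.x < -0.1) & hi,
            "F-": (tr.x < -0.1) & ~hi,
            "U+": (tr.x > 0.1) & hi,
            "U-": (tr.x > 0.1) & ~hi,
        }.items():
            assert mask.mean() > 0.01, f"state {name} unoccupied"

    def test_equal_levels_constant_force(self):
        pot, tg, cfg = hairpin_preset(force_levels=(5.0, 5.0), seed=1)
        assert tg.f0 == 0.0
        from dataclasses import replace

        tr = simulate_overdamped(pot, D_CHANNEL, tg, replace(cfg, t_max=10.0))
        assert np.all(tr.fext == 0.0)  # mean force folded into the landscape

    def test_fast_switching_merges_doublets(self):
        """alpha far above the relaxation rates averages the telegraph force
        out: occupancy conditioned on force level becomes level-independent."""
        from dataclasses import replace

        pot, tg, cfg = hairpin_preset(alpha=200.0, seed=8)
        tr = simulate_overdamped(pot, D_CHANNEL, tg, replace(cfg, t_max=2000.0))
        hi = tr.fext > 0
        # fraction unfolded at high vs low force nearly equal
        fu_hi = np.mean(tr.x[hi] > 0)
        fu_lo = np.mean(tr.x[~hi] > 0)
        assert abs(fu_hi - fu_lo) < 0.05
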