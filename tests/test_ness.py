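"""NESS diagnostics: occupancy, currents, asymmetry, hairpin doublets."""
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from pathtimes import (
    IntervalSpec,
    SimConfig,
    TelegraphSpec,
    ks_two_sample,
    hairpin_preset,
    quartic_from_barrier,
    simulate_overdamped,
)
from pathtimes.errors import EstimationError, InvalidParameterError
from pathtimes.ness import (
    asymmetry_sweep,
    circulation_null_test,
    classify_hairpin_states,
    coarse_current_2d,
    collect_transitions,
    doublet_transition_times,
    occupancy_2d,
)

D0 = 0.15


@pytest.fixture(scope="module")
def telegraph_run(paper_quartic):
    cfg = SimConfig(
        dt=1e-3, t_max=1000.0, x0=-0.5, record_stride=1,
        reflecting_bounds=(-1.6, 1.6), seed=5,
    )
    tg = TelegraphSpec(f0=82.0, alpha=0.5, seed=5)
    return simulate_overdamped(paper_quartic, D0, tg, cfg)


@pytest.fixture(scope="module")
def equilibrium_run(paper_quartic):
    cfg = SimConfig(
        dt=1e-3, t_max=1000.0, x0=-0.5, record_stride=1,
        reflecting_bounds=(-1.6, 1.6), seed=6,
    )
    return simulate_overdamped(
        paper_quartic, D0, TelegraphSpec(f0=0.0, alpha=1.0), cfg
    )


class TestOccupancy:
    def test_normalized(self, telegraph_run, paper_quartic):
        occ = occupancy_2d(telegraph_run, paper_quartic)
        assert occ.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(occ.P >= 0)

    def test_four_lobes_in_telegraph_run(self, telegraph_run, paper_quartic):
        occ = occupancy_2d(telegraph_run, paper_quartic, bins=(2, 2))
        # quadrant masses of the (position × total force) plane all populated
        assert np.all(occ.P > 0.02)

    def test_equilibrium_x_marginal_is_boltzmann(self, mild_quartic):
        # decorrelated samples (10 s spacing, beyond the ~5-10 s deep-well
        # dwell of the 2 kBT-barrier landscape) from a long equilibrium run
        cfg = SimConfig(
            dt=1e-3, t_max=2.0e5, x0=-0.5, record_stride=10000,
            reflecting_bounds=(-1.0, 0.9), seed=31,
        )
        tr = simulate_overdamped(mild_quartic, D0, TelegraphSpec(f0=0.0, alpha=1.0), cfg)
        occ = occupancy_2d(tr, mild_quartic, bins=(12, 5))
        marg = occ.P.sum(axis=1)
        fine = np.linspace(occ.x_edges[0], occ.x_edges[-1], 4001)
        w = np.exp(-mild_quartic.energy(fine))
        b = np.clip(np.digitize(fine, occ.x_edges) - 1, 0, 11)
        expw = np.array([w[b == i].sum() for i in range(12)])
        expw /= expw.sum()
        n = len(tr)
        chi2 = np.sum((marg * n - expw * n) ** 2 / np.maximum(expw * n, 1e-9))
        assert stats.chi2.sf(chi2, df=11) > 0.01

    def test_missing_force_column_rejected(self, paper_quartic):
        cfg = SimConfig(dt=1e-3, t_max=1.0, reflecting_bounds=(-1, 1), seed=0)
        tr = simulate_overdamped(paper_quartic, D0, None, cfg)
        with pytest.raises(InvalidParameterError):
            occupancy_2d(tr, paper_quartic)


class TestCurrents:
    def test_antisymmetry_under_time_reversal(self, telegraph_run, paper_quartic):
        fwd = coarse_current_2d(telegraph_run, paper_quartic)
        rev = coarse_current_2d(telegraph_run.reversed(), paper_quartic)
        assert np.allclose(fwd.J_x, -rev.J_x)
        assert np.allclose(fwd.J_f, -rev.J_f)
        assert fwd.circulation == pytest.approx(-rev.circulation)
        assert fwd.circulation_score >= 0

    def test_telegraph_run_breaks_detailed_balance(self, telegraph_run, paper_quartic):
        _, z = circulation_null_test(telegraph_run, paper_quartic)
        assert abs(z) > 3

    def test_equilibrium_run_is_null_consistent(self, equilibrium_run, paper_quartic):
        _, z = circulation_null_test(equilibrium_run, paper_quartic)
        assert abs(z) < 3


class TestAsymmetrySweep:
    def test_asymmetry_decreases_with_alpha(self, paper_quartic):
        from pathtimes.model import quartic_minima

        xl, xr = quartic_minima(paper_quartic)
        cfg = SimConfig(
            dt=1e-3, t_max=2000.0, x0=xl, record_stride=1,
            reflecting_bounds=(-1.6, 1.6), seed=11,
        )
        res = asymmetry_sweep(
            [0.5, 50.0], paper_quartic, D0, 82.0,
            IntervalSpec(xl, xr), cfg, min_events=500,
        )
        asym = res.asymmetry()
        assert res.ks_p[0] < 0.05           # slow switching: broken symmetry
        assert asym[1] < asym[0]            # fast switching restores it
        assert np.all(res.n_LR >= 500) and np.all(res.n_RL >= 500)

    def test_zero_amplitude_symmetric(self, mild_quartic):
        from pathtimes.model import quartic_minima

        xl, xr = quartic_minima(mild_quartic)
        cfg = SimConfig(
            dt=1e-3, t_max=1000.0, x0=xl, record_stride=1,
            reflecting_bounds=(-1.6, 1.6), seed=13,
        )
        res = asymmetry_sweep(
            [1.0], mild_quartic, D0, 0.0, IntervalSpec(xl, xr), cfg, min_events=400
        )
        assert res.ks_p[0] > 0.05
        assert res.asymmetry()[0] < 3 * np.hypot(res.sem_LR[0], res.sem_RL[0])

    def test_sem_shrinks_with_events(self, mild_quartic):
        from pathtimes.model import quartic_minima

        xl, xr = quartic_minima(mild_quartic)
        cfg = SimConfig(
            dt=1e-3, t_max=1000.0, x0=xl, record_stride=1,
            reflecting_bounds=(-1.6, 1.6), seed=17,
        )
        sems = []
        for me in (200, 800):
            res = asymmetry_sweep(
                [1.0], mild_quartic, D0, 0.0, IntervalSpec(xl, xr), cfg, min_events=me
            )
            sems.append(res.sem_LR[0])
        assert sems[1] < sems[0] / 1.4  # ~1/sqrt(4) with sampling slack


@pytest.fixture(scope="module")
def hairpin_run():
    pot, tg, cfg = hairpin_preset(seed=42)
    traj = simulate_overdamped(pot, D0, tg, replace(cfg, t_max=24000.0))
    return pot, traj


class TestHairpin:
    def test_all_four_labels_occur(self, hairpin_run):
        _, traj = hairpin_run
        st = classify_hairpin_states(traj, 0.0, 0.0, buffer=0.1)
        fr = st.fractions()
        for lbl in ("F+", "F-", "U+", "U-"):
            assert fr.get(lbl, 0.0) > 0.01

    def test_constant_force_two_labels(self):
        pot, tg, cfg = hairpin_preset(force_levels=(6.0, 6.0), seed=2)
        tr = simulate_overdamped(pot, D0, tg, replace(cfg, t_max=50.0))
        st = classify_hairpin_states(tr, 0.0, 0.5, buffer=0.05)
        assert {l for l in st.labels if l != "transit"} <= {"F-", "U-"}

    def test_flip_force_sign_swaps_pm_labels(self, hairpin_run):
        _, traj = hairpin_run
        st = classify_hairpin_states(traj, 0.0, 0.0, buffer=0.1)
        tr2 = type(traj)(traj.t, traj.x, -traj.fext)
        st2 = classify_hairpin_states(tr2, 0.0, 0.0, buffer=0.1)
        swap = {"F+": "F-", "F-": "F+", "U+": "U-", "U-": "U+", "transit": "transit"}
        assert all(swap[a] == b for a, b in zip(st.labels[:5000], st2.labels[:5000]))

    def test_directional_doublet_asymmetry(self, hairpin_run):
        _, traj = hairpin_run
        a2b, b2a = doublet_transition_times(traj, 0.35, -0.35)
        assert a2b.size >= 300 and b2a.size >= 300
        assert ks_two_sample(a2b, b2a).p_value < 0.05

    def test_time_reversal_swaps_doublet_sets(self, hairpin_run):
        _, traj = hairpin_run
        a2b, b2a = doublet_transition_times(traj, 0.35, -0.35)
        r_a2b, r_b2a = doublet_transition_times(traj.reversed(), 0.35, -0.35)
        assert np.allclose(np.sort(a2b), np.sort(r_b2a))
        assert np.allclose(np.sort(b2a), np.sort(r_a2b))

    def test_degenerate_preset_symmetric(self):
        pot, tg, cfg = hairpin_preset(force_levels=(0.0, 0.0), seed=43)
        tr = simulate_overdamped(pot, D0, tg, replace(cfg, t_max=8000.0))
        a, b = doublet_transition_times(tr, 0.35, -0.35)
        assert ks_two_sample(a, b).p_value > 0.05

    def test_underpopulated_corners_rejected(self):
        pot, tg, cfg = hairpin_preset(seed=1)
        tr = simulate_overdamped(pot, D0, tg, replace(cfg, t_max=20.0))
        with pytest.raises(EstimationError):
            doublet_transition_times(tr, 0.35, -0.35)
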