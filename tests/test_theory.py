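"""First-passage-time theory: MFPT, exit and transition densities, splitting."""
import numpy as np
import pytest

from pathtimes import (
    FPGrid,
    Linear,
    Tabulated,
    exit_time_density,
    mean_transition_time,
    mfpt_profile,
    quartic_from_barrier,
    splitting_probability,
    transition_time_density,
)
from pathtimes.errors import InvalidParameterError
from pathtimes.model import ConstantD, TabulatedD, Quartic

D0 = 0.15
CHANNEL = (-1.85, 1.85)  # L = 3.7 µm


class TestMFPT:
    def test_free_diffusion_closed_form(self, channel_interval):
        prof = mfpt_profile(Linear(0.0), D0, channel_interval)
        L = channel_interval[1] - channel_interval[0]
        assert prof.at(0.0) == pytest.approx(L**2 / (8 * D0), rel=1e-4)
        # full parabola, not just the centre
        x = np.linspace(*channel_interval, 31)
        exact = (x - channel_interval[0]) * (channel_interval[1] - x) / (2 * D0)
        assert np.allclose([prof.at(v) for v in x], exact, rtol=1e-3, atol=1e-4)

    def test_absorbing_boundaries(self, paper_quartic):
        prof = mfpt_profile(paper_quartic, D0, (-0.5, 0.5))
        assert prof.tau[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.tau[-1] == pytest.approx(0.0, abs=1e-12)

    def test_force_sign_symmetry_from_centre(self, channel_interval):
        tp = mfpt_profile(Linear(3.3), D0, channel_interval).at(0.0)
        tm = mfpt_profile(Linear(-3.3), D0, channel_interval).at(0.0)
        assert tp == pytest.approx(tm, rel=1e-6)

    def test_nonpositive_D_rejected(self):
        with pytest.raises(InvalidParameterError):
            mfpt_profile(Linear(0.0), -0.1, (0, 1))


class TestSplitting:
    def test_free_diffusion_linear(self):
        s = splitting_probability(Linear(0.0), D0, 0.25, (0.0, 1.0))
        assert s.P_right == pytest.approx(0.25, abs=1e-6)

    def test_printed_uphill_value(self, channel_interval):
        s = splitting_probability(Linear(3.3), D0, 0.0, channel_interval)
        assert s.P_left == pytest.approx(1 / (1 + np.exp(1.4854)), rel=1e-3)
        assert s.P_left + s.P_right == pytest.approx(1.0, abs=1e-12)

    def test_downhill_majority_for_positive_force(self, channel_interval):
        s = splitting_probability(Linear(2.0), D0, 0.0, channel_interval)
        assert s.P_right > 0.5

    def test_one_over_D_weight_matters(self):
        # spatially varying D shifts the splitting even for U = 0: the slow
        # (small-D) region on the left carries more 1/D resistance, so the
        # centre start is effectively closer to the right boundary
        x = np.linspace(0, 1, 64)
        Dv = TabulatedD(x=tuple(x), D=tuple(0.1 + 0.2 * x))
        s = splitting_probability(Linear(0.0), Dv, 0.5, (0.0, 1.0))
        assert s.P_right > 0.5
        chain = _chain_splitting(x, np.zeros_like(x), 0.1 + 0.2 * x)
        assert s.P_right == pytest.approx(chain, rel=1e-2)


def _chain_splitting(x, U, Dv):
    """Independent oracle: absorbing birth–death chain on the grid with
    detailed-balance rates; returns P(absorb right | start mid-node)."""
    h = x[1] - x[0]
    n = x.size
    Dh = 0.5 * (Dv[:-1] + Dv[1:])
    up = Dh / h**2 * np.exp(-(U[1:] - U[:-1]) / 2)
    dn = Dh / h**2 * np.exp(+(U[1:] - U[:-1]) / 2)
    # P_i = probability to reach n-1 before 0 from i
    P = np.zeros(n)
    P[-1] = 1.0
    # solve tridiagonal harmonic equation by forward substitution
    import numpy.linalg as la

    A = np.zeros((n - 2, n - 2))
    b = np.zeros(n - 2)
    for i in range(1, n - 1):
        r = i - 1
        A[r, r] = -(up[i] + dn[i - 1])
        if r > 0:
            A[r, r - 1] = dn[i - 1]
        if r < n - 3:
            A[r, r + 1] = up[i]
        if i == n - 2:
            b[r] = -up[i]
    P[1:-1] = la.solve(A, b)
    return float(np.interp(0.5, x, P))


class TestMeanTransitionTime:
    def test_free_diffusion_L2_over_6D(self):
        assert mean_transition_time(Linear(0.0), D0, (0.0, 1.0)) == pytest.approx(
            1.0 / (6 * D0), rel=1e-4
        )

    def test_invariant_under_constant_energy_shift(self, paper_quartic):
        base = mean_transition_time(paper_quartic, D0, (-0.5, 0.5))
        shifted = Quartic(paper_quartic.a, paper_quartic.b, paper_quartic.c)
        x = np.linspace(-0.6, 0.6, 201)
        tab = Tabulated(x=tuple(x), U=tuple(paper_quartic.energy(x) + 12.3))
        assert mean_transition_time(tab, D0, (-0.5, 0.5)) == pytest.approx(base, rel=1e-3)

    def test_force_sign_invariance(self):
        tp = mean_transition_time(Linear(4.0), D0, (0.0, 1.0))
        tm = mean_transition_time(Linear(-4.0), D0, (0.0, 1.0))
        assert tp == pytest.approx(tm, rel=1e-9)


class TestExitTimeDensity:
    def test_densities_normalized_and_symmetric_at_zero_force(self):
        left, right, s = exit_time_density(Linear(0.0), D0, 0.5, (0.0, 1.0))
        assert left.mass == pytest.approx(1.0, abs=1e-3)
        assert right.mass == pytest.approx(1.0, abs=1e-3)
        assert s.P_left == pytest.approx(0.5, abs=1e-3)
        assert np.max(np.abs(left.density - right.density)) < 1e-6 * left.density.max()

    def test_uphill_downhill_pointwise_identical(self, channel_interval):
        """The central equilibrium result: conditioned exit densities to the
        uphill and downhill boundaries coincide for constant force."""
        left, right, _ = exit_time_density(Linear(3.3), D0, 0.0, channel_interval)
        assert (
            np.max(np.abs(left.density - right.density)) < 1e-3 * left.density.max()
        )

    def test_moments_recover_mfpt(self, channel_interval):
        left, right, s = exit_time_density(Linear(2.0), D0, 0.0, channel_interval)
        mixed = s.P_left * left.mean() + s.P_right * right.mean()
        assert mixed == pytest.approx(
            mfpt_profile(Linear(2.0), D0, channel_interval).at(0.0), rel=1e-2
        )

    def test_free_exit_density_matches_images_series(self):
        """Sup-norm check against the method-of-images series solution."""
        L, x0 = 1.0, 0.5
        left, right, _ = exit_time_density(Linear(0.0), D0, x0, (0.0, L))
        t = left.t[1:]
        flux = np.zeros_like(t)
        for n in range(-60, 61):
            # first-passage flux to the left boundary of Brownian motion with
            # two absorbing walls: D·∂xρ(0,t) = Σ_n a_n/sqrt(4πDt³)·e^{-a_n²/4Dt}
            # with a_n = x0 + 2nL (both image families collapse onto one sum)
            a = x0 + 2 * n * L
            flux += a / np.sqrt(4 * np.pi * D0 * t**3) * np.exp(-a**2 / (4 * D0 * t))
        dens = flux / 0.5  # P_left = 1/2
        assert np.max(np.abs(dens - left.density[1:])) < 1e-3 * dens.max()

    def test_boundary_start_rejected(self):
        with pytest.raises(InvalidParameterError):
            exit_time_density(Linear(0.0), D0, 0.0, (0.0, 1.0))


class TestTransitionTimeDensity:
    def test_free_diffusion_first_moment(self):
        d = transition_time_density(Linear(0.0), D0, (0.0, 1.0))
        assert d.mass == pytest.approx(1.0, abs=1e-3)
        assert d.mean() == pytest.approx(1.0 / (6 * D0), rel=1e-2)

    def test_direction_symmetry_on_the_quartic(self, paper_quartic):
        dlr = transition_time_density(paper_quartic, D0, (-0.5, 0.5), "L_to_R")
        drl = transition_time_density(paper_quartic, D0, (-0.5, 0.5), "R_to_L")
        n = min(dlr.t.size, drl.t.size)
        assert np.max(np.abs(dlr.density[:n] - drl.density[:n])) < 1e-2 * dlr.density.max()
        assert dlr.mean() == pytest.approx(drl.mean(), rel=1e-3)

    def test_first_moment_matches_quadrature(self, paper_quartic):
        d = transition_time_density(paper_quartic, D0, (-0.5, 0.5))
        assert d.mean() == pytest.approx(
            mean_transition_time(paper_quartic, D0, (-0.5, 0.5)), rel=1e-2
        )

    def test_bad_direction(self):
        with pytest.raises(InvalidParameterError):
            transition_time_density(Linear(0.0), D0, (0, 1), "up")


def test_fpgrid_validation():
    with pytest.raises(InvalidParameterError):
        FPGrid(n_x=32)
    with pytest.raises(InvalidParameterError):
        FPGrid(dt=-1.0)
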