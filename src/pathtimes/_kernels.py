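"""Numba inner loops for the Euler–Maruyama integrator.

The drift field (including the spurious-drift correction dD/dx for spatially
varying diffusion), noise amplitude sqrt(2D) and mobility D/kBT are passed as
dense tables on a uniform grid and linearly interpolated — one code path for
all potential variants.  Telegraph switching is generated inside the loop from
exponential dwell draws at rate alpha/2 per direction.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _interp(tab, lo, inv_h, n, x):
    """Clamped linear interpolation on a uniform table."""
    u = (x - lo) * inv_h
    if u <= 0.0:
        return tab[0]
    if u >= n - 1:
        return tab[n - 1]
    i = int(u)
    w = u - i
    return tab[i] * (1.0 - w) + tab[i + 1] * w


@njit(cache=True)
def em_run(
    x0,
    n_steps,
    dt,
    stride,
    tab_lo,
    inv_h,
    drift_tab,
    sig_tab,
    mob_tab,
    f0,
    switch_rate,
    level0,
    lo,
    hi,
    reflect,
    seed,
):
    """Integrate with recording every ``stride`` steps.

    Returns (x_rec, level_rec, status): status 0 = completed, 1 = left the
    table domain while reflection is disabled (position at failure recorded
    last).
    """
    np.random.seed(seed)
    n_tab = drift_tab.shape[0]
    n_rec = n_steps // stride + 1
    x_rec = np.empty(n_rec, dtype=np.float64)
    lv_rec = np.empty(n_rec, dtype=np.int8)
    x = x0
    level = level0
    t_switch = np.random.exponential(1.0 / switch_rate) if switch_rate > 0.0 else 1.0e300
    sqdt = np.sqrt(dt)
    x_rec[0] = x
    lv_rec[0] = level
    k_rec = 1
    t = 0.0
    for k in range(1, n_steps + 1):
        drift = _interp(drift_tab, tab_lo, inv_h, n_tab, x)
        if f0 > 0.0:
            drift += level * f0 * _interp(mob_tab, tab_lo, inv_h, n_tab, x)
        sig = _interp(sig_tab, tab_lo, inv_h, n_tab, x)
        x = x + drift * dt + sig * sqdt * np.random.standard_normal()
        t += dt
        while t >= t_switch:
            level = -level
            t_switch += np.random.exponential(1.0 / switch_rate)
        if x < lo:
            if reflect:
                x = 2.0 * lo - x
            else:
                x_rec[k_rec] = x
                lv_rec[k_rec] = level
                return x_rec[: k_rec + 1], lv_rec[: k_rec + 1], 1
        elif x > hi:
            if reflect:
                x = 2.0 * hi - x
            else:
                x_rec[k_rec] = x
                lv_rec[k_rec] = level
                return x_rec[: k_rec + 1], lv_rec[: k_rec + 1], 1
        if k % stride == 0:
            x_rec[k_rec] = x
            lv_rec[k_rec] = level
            k_rec += 1
    return x_rec, lv_rec, 0


@njit(cache=True)
def em_exit_batch(
    x0,
    xl,
    xr,
    max_steps,
    dt,
    tab_lo,
    inv_h,
    drift_tab,
    sig_tab,
    seeds,
):
    """First-exit protocol without telegraph forcing, batched over repeats.

    For each seed: start at x0, integrate until x crosses xl or xr, return the
    side (-1 left, +1 right, 0 censored) and the linearly interpolated
    crossing time.
    """
    n = seeds.shape[0]
    n_tab = drift_tab.shape[0]
    sides = np.zeros(n, dtype=np.int8)
    taus = np.full(n, np.nan, dtype=np.float64)
    sqdt = np.sqrt(dt)
    for r in range(n):
        np.random.seed(seeds[r])
        x = x0
        for k in range(1, max_steps + 1):
            drift = _interp(drift_tab, tab_lo, inv_h, n_tab, x)
            sig = _interp(sig_tab, tab_lo, inv_h, n_tab, x)
            x_new = x + drift * dt + sig * sqdt * np.random.standard_normal()
            if x_new <= xl:
                frac = (x - xl) / (x - x_new)
                sides[r] = -1
                taus[r] = (k - 1 + frac) * dt
                break
            if x_new >= xr:
                frac = (xr - x) / (x_new - x)
                sides[r] = 1
                taus[r] = (k - 1 + frac) * dt
                break
            x = x_new
    return sides, taus
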