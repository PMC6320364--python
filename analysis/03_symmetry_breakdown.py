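#!/usr/bin/env python
"""Breakdown of transition-path-time symmetry under telegraph forcing.

The bistable asymmetric quartic (barrier 5 kBT, asymmetry 2 kBT, wells 1 µm
apart, D = 0.15 µm²/s) is driven by a ±82 fN telegraph force.  At slow
switching (decorrelation time 2 s) the directional transition-time
distributions split; towards fast switching the symmetry is restored.  The
coarse-grained currents in the (position × total force) plane show the
circulating probability flux — broken detailed balance — behind the effect.

Writes results/asymmetry_vs_alpha.tsv and results/circulation.tsv.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from pathtimes import (
    IntervalSpec,
    SimConfig,
    TelegraphSpec,
    quartic_from_barrier,
    quartic_minima,
    simulate_overdamped,
)
from pathtimes.ness import asymmetry_sweep, circulation_null_test, occupancy_2d

D0 = 0.15
out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

q = quartic_from_barrier(5.0, 2.0, 1.0)
xl, xr = quartic_minima(q)
itv = IntervalSpec(xl, xr)
cfg = SimConfig(
    dt=1e-3, t_max=2000.0, x0=xl, record_stride=1,
    reflecting_bounds=(-1.6, 1.6), seed=37,
)

alphas = [0.2, 0.5, 2.0, 10.0, 50.0]
res = asymmetry_sweep(alphas, q, D0, 82.0, itv, cfg, min_events=600)
tab = pd.DataFrame(
    dict(
        alpha_per_s=res.alphas,
        mean_LR_s=res.mean_LR, sem_LR_s=res.sem_LR,
        mean_RL_s=res.mean_RL, sem_RL_s=res.sem_RL,
        n_LR=res.n_LR, n_RL=res.n_RL, ks_p=res.ks_p,
        asymmetry_s=res.asymmetry(),
    )
)
tab.to_csv(out_dir / "asymmetry_vs_alpha.tsv", sep="\t", index=False)
for _, r in tab.iterrows():
    print(
        f"alpha={r.alpha_per_s:5.1f}/s: <tau> {r.mean_LR_s:.3f}/{r.mean_RL_s:.3f} s, "
        f"asymmetry {r.asymmetry_s:.3f} s, KS p={r.ks_p:.2e}"
    )

# broken detailed balance at the slowest rate vs equilibrium control
rows = []
for label, tg in (
    ("telegraph", TelegraphSpec(f0=82.0, alpha=0.5, seed=41)),
    ("equilibrium", TelegraphSpec(f0=0.0, alpha=1.0)),
):
    traj = simulate_overdamped(q, D0, tg, cfg)
    circ, z = circulation_null_test(traj, q)
    occ = occupancy_2d(traj, q, bins=(2, 2))
    rows.append(dict(run=label, circulation=circ, z=z,
                     occupied_quadrants=int((occ.P > 0.02).sum())))
    print(f"{label}: circulation z = {z:+.1f}, quadrants occupied: {rows[-1]['occupied_quadrants']}")
pd.DataFrame(rows).to_csv(out_dir / "circulation.tsv", sep="\t", index=False)
print(
    "\nSlowly decorrelating telegraph forces split the transition pathways in "
    "the (position × force) plane, break detailed balance there, and make "
    "directional transition-path times measurably different; fast switching "
    "averages the force out and restores the symmetry."
)
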