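#!/usr/bin/env python
"""Hairpin-like folding under two-level force feedback: doublet states and
directional path-time asymmetry.

The preset simulates a bistable extension coordinate (folded F / unfolded U)
whose landscape is tilted by a telegraph force switching between ±14 fN.
Each conformational state splits into a high/low-force doublet (F±, U±); the
corner-to-corner transition times U+→F− (folding) and F−→U+ (unfolding),
which include the dwells in the intermediate states, become directionally
asymmetric.  Equal force levels restore the equilibrium symmetry.

Writes results/hairpin_states.tsv and results/hairpin_path_times.tsv.
"""
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from pathtimes import hairpin_preset, ks_two_sample, simulate_overdamped
from pathtimes.ness import classify_hairpin_states, doublet_transition_times

D0 = 0.15
out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

rows = []
for label, levels, T in (
    ("telegraph", (-14.0, 14.0), 20000.0),
    ("degenerate", (0.0, 0.0), 8000.0),
):
    pot, tg, cfg = hairpin_preset(force_levels=levels, seed=42)
    traj = simulate_overdamped(pot, D0, tg, replace(cfg, t_max=T))
    states = classify_hairpin_states(traj, 0.0, 0.0, buffer=0.1)
    fracs = states.fractions()
    fold, unfold = doublet_transition_times(traj, 0.35, -0.35)
    ks = ks_two_sample(fold, unfold)
    rows.append(
        dict(
            run=label,
            **{f"frac_{k}": fracs.get(k, 0.0) for k in ("F+", "F-", "U+", "U-")},
            n_fold=fold.size, n_unfold=unfold.size,
            mean_fold_s=fold.mean(), mean_unfold_s=unfold.mean(),
            ks_p=ks.p_value,
        )
    )
    print(
        f"{label}: state fractions "
        + ", ".join(f"{k}={fracs.get(k, 0.0):.3f}" for k in ("F+", "F-", "U+", "U-"))
    )
    print(
        f"  U+→F− n={fold.size} <tau>={fold.mean():.2f} s; "
        f"F−→U+ n={unfold.size} <tau>={unfold.mean():.2f} s; KS p={ks.p_value:.2e}"
    )

pd.DataFrame(rows).to_csv(out_dir / "hairpin_path_times.tsv", sep="\t", index=False)
# per-state occupancy of the telegraph run for the phase-plane picture
pot, tg, cfg = hairpin_preset(seed=42)
traj = simulate_overdamped(pot, D0, tg, replace(cfg, t_max=4000.0))
states = classify_hairpin_states(traj, 0.0, 0.0, buffer=0.1)
pd.Series(states.fractions()).rename("fraction").to_csv(
    out_dir / "hairpin_states.tsv", sep="\t"
)
print(
    "\nThe switching force splits both conformations into doublets and routes "
    "folding and unfolding through different intermediates, so their "
    "corner-to-corner path times differ; with equal levels the distributions "
    "coincide again."
)
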