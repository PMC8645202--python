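#!/usr/bin/env python
"""Caste-determination equilibrium under fixed hybridization.

Evaluates the closed-form equilibrium omega*(eta, e) on a grid together
with the complete worker-loss threshold eta = 1/(1+2e), and cross-checks
the closed form against the invasion engine's gradient root at a few
points.  Writes results/equilibrium_grid.tsv and
results/worker_loss_threshold.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from castecoevo.colony import ModelParams, plasticity_equilibrium, worker_loss_threshold
from castecoevo.invasion import omega_root_at_eta

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    rows = []
    for e in np.round(np.arange(0.0, 2.01, 0.05), 3):
        for eta in np.round(np.arange(0.0, 0.991, 0.01), 3):
            eq = plasticity_equilibrium(eta, e)
            rows.append((e, eta, eq.unclipped, eq.clipped))
    grid = pd.DataFrame(rows, columns=["e", "eta", "omega_star_unclipped", "omega_star"])
    grid.to_csv(OUT / "equilibrium_grid.tsv", sep="\t", index=False, float_format="%.6g")

    thr = pd.DataFrame(
        {"e": np.round(np.arange(0.05, 2.01, 0.05), 3)}
    ).assign(worker_loss_eta=lambda d: d.e.map(worker_loss_threshold))
    thr.to_csv(OUT / "worker_loss_threshold.tsv", sep="\t", index=False, float_format="%.6g")

    print("closed form vs invasion-engine gradient root (m infinite, c=0):")
    for e, eta in [(1.0, 0.0), (1.0, 0.2), (0.5, 0.1), (2.0, 0.1)]:
        closed = plasticity_equilibrium(eta, e).clipped
        root = omega_root_at_eta(ModelParams(m=None, e=e), eta)
        print(f"  e={e:.1f} eta={eta:.1f}: closed={closed:.6f} gradient-root={root:.6f}")
    print(f"worker-loss threshold at e=1: eta >= {worker_loss_threshold(1.0):.4f}")
    print(f"wrote {OUT / 'equilibrium_grid.tsv'} ({len(grid)} rows)")


if __name__ == "__main__":
    main()
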