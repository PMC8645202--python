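#!/usr/bin/env python
"""Thelytokous parthenogenesis and the evolution of worker loss.

Classifies (c, e) grids under monandry and m = 2, traces the hybridization
level selected at worker loss as a function of parthenogenesis (checking
the complete-hybridization condition c >= (m-1)/(3m-1) for m > 1), and
integrates the monandrous scenario (m=1, c=0.4, e=0.9) from (1/2, 0),
which ends at worker loss with complete hybridization (0, 1).  Writes
results/region_map_c_e_m{1,2}.tsv, results/eta_hat_vs_c.tsv and
results/parthenogenesis_trajectory.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from castecoevo.colony import ModelParams, TraitPair
from castecoevo.invasion import classify_region, integrate_trajectory, worker_loss_stable

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    e_grid = np.round(np.arange(0.1, 2.01, 0.1), 3)
    c_grid = np.round(np.arange(0.0, 0.91, 0.05), 3)
    for m in (1, 2):
        rm = classify_region(("c", c_grid), ("e", e_grid), ModelParams(m=m, e=1.0))
        df = rm.to_frame()
        df.to_csv(OUT / f"region_map_c_e_m{m}.tsv", sep="\t", index=False, float_format="%.6g")
        n_wl = (df.outcome == "worker-loss-always").sum()
        print(f"m={m}: {n_wl}/{len(df)} cells are worker-loss-always")

    rows = []
    for m in (1, 2, 3, 5):
        c_star = 0.0 if m == 1 else (m - 1) / (3 * m - 1)
        for c in np.round(np.arange(0.0, 0.81, 0.04), 3):
            wl = worker_loss_stable(ModelParams(m=m, e=1.0, c=float(c)))
            rows.append((m, c, c_star, wl.eta_hat, wl.stable, wl.viable))
    hat = pd.DataFrame(
        rows, columns=["m", "c", "c_full_hybridization", "eta_hat", "stable", "viable"]
    )
    hat.to_csv(OUT / "eta_hat_vs_c.tsv", sep="\t", index=False, float_format="%.6g")
    print("\nhybridization selected at worker loss (eta_hat = 1 marks complete"
          " loss of intraspecific mating):")
    for m in (1, 2, 3, 5):
        sub = hat[(hat.m == m) & hat.viable]
        full = sub.loc[sub.eta_hat >= 1.0 - 1e-9, "c"]
        onset = full.min() if len(full) else None
        pred = 0.0 if m == 1 else (m - 1) / (3 * m - 1)
        print(f"  m={m}: eta_hat=1 from c={onset} (condition c >= {pred:.3f})")

    tr = integrate_trajectory(TraitPair(0.5, 0.0), ModelParams(m=1, e=0.9, c=0.4))
    tr.to_frame().to_csv(
        OUT / "parthenogenesis_trajectory.tsv", sep="\t", index=False, float_format="%.6g"
    )
    print(
        f"\nm=1, c=0.4, e=0.9 from (0.5, 0): endpoint "
        f"({tr.endpoint.omega:.4f}, {tr.endpoint.eta:.4f}) [{tr.termination}]"
    )


if __name__ == "__main__":
    main()
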