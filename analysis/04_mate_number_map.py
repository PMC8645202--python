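#!/usr/bin/env python
"""Selection outcome as a function of mate number and hybrid-worker efficiency.

Classifies each (m, e) cell into plasticity-maintained / bistable /
worker-loss-always / internal-attractor using the worker-loss stability
condition, the instability of eta = 0, and interior singular-point search.
Also reports, under monandry, the efficiency range where the interior
attractor exists and whether it is invadable (evolutionary branching).
Writes results/region_map_m_e.tsv and results/monandry_attractor.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from castecoevo.colony import ModelParams
from castecoevo.invasion import classify_region, find_singular_points, mutant_hessian

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    e_grid = np.round(np.arange(0.1, 2.01, 0.1), 3)
    rm = classify_region(
        ("m", [1, 2, 3, 4, 5, 6, 8]), ("e", e_grid), ModelParams(m=2, e=1.0)
    )
    df = rm.to_frame()
    df.to_csv(OUT / "region_map_m_e.tsv", sep="\t", index=False, float_format="%.6g")
    summary = df.groupby("m").outcome.value_counts().unstack(fill_value=0)
    print("outcome counts per mate number (e in [0.1, 2]):")
    print(summary.to_string())
    with_attractor = sorted(df.loc[df.outcome == "internal-attractor", "m"].unique())
    print(f"\nmate numbers with an internal attractor: {with_attractor}")

    rows = []
    for e in np.round(np.arange(0.9, 2.01, 0.05), 3):
        pts = [
            s
            for s in find_singular_points(
                ModelParams(m=1, e=float(e)), n_starts=4, include_boundary=False
            )
            if s.convergence_stable
        ]
        if not pts:
            rows.append((e, np.nan, np.nan, False, np.nan))
            continue
        s = pts[0]
        H = mutant_hessian(s.location, ModelParams(m=1, e=float(e)))
        lead = float(np.linalg.eigvalsh(H).max())
        rows.append((e, s.location.omega, s.location.eta, lead > 1e-6, lead))
    mono = pd.DataFrame(
        rows, columns=["e", "omega_star", "eta_star", "invadable", "leading_hessian_eig"]
    )
    mono.to_csv(OUT / "monandry_attractor.tsv", sep="\t", index=False, float_format="%.6g")
    print("\nmonandry interior attractor across e (invadable => branching):")
    print(mono.to_string(index=False))


if __name__ == "__main__":
    main()
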