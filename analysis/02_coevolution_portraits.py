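#!/usr/bin/env python
"""Coevolutionary phase portraits of caste determination and hybridization.

For three hybrid-worker efficiencies spanning the qualitative regimes
(e = 0.1 avoidance-only, e = 0.4 bistable, e = 0.7 worker-loss-always,
with queens mating with effectively infinitely many males) this computes
the selection-gradient field on a grid, the singular points with their
classification, and representative trajectories.  Writes per-regime tables
under results/.
"""

import pathlib

import numpy as np
import pandas as pd

from castecoevo.colony import ModelParams, TraitPair
from castecoevo.invasion import (
    ResidentInviableError,
    find_singular_points,
    integrate_trajectory,
    selection_gradient,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

REGIMES = {
    0.1: [(0.5, 0.5), (0.1, 0.8)],
    0.4: [(0.45, 0.1), (0.1, 0.9)],
    0.7: [(1 / 3, 1e-3), (0.8, 0.2)],
}


def main():
    field_rows, sp_rows, traj_frames = [], [], []
    for e, inits in REGIMES.items():
        params = ModelParams(m=None, e=e)
        for o in np.linspace(0.02, 0.98, 17):
            for t in np.linspace(0.02, 0.98, 17):
                try:
                    g = selection_gradient(TraitPair(o, t), params)
                    field_rows.append((e, o, t, g.g_omega, g.g_eta))
                except ResidentInviableError:
                    field_rows.append((e, o, t, np.nan, np.nan))
        for s in find_singular_points(params):
            sp_rows.append(
                (e, s.location.omega, s.location.eta, s.convergence_stable, s.ess, s.label)
            )
        for i, (o0, t0) in enumerate(inits):
            tr = integrate_trajectory(TraitPair(o0, t0), params)
            df = tr.to_frame()
            df.insert(0, "e", e)
            df.insert(1, "trajectory", i)
            traj_frames.append(df)
            print(
                f"e={e}: start ({o0:.3f}, {t0:.3f}) -> end "
                f"({tr.endpoint.omega:.4f}, {tr.endpoint.eta:.4f}) [{tr.termination}]"
            )

    pd.DataFrame(
        field_rows, columns=["e", "omega", "eta", "g_omega", "g_eta"]
    ).to_csv(OUT / "gradient_fields.tsv", sep="\t", index=False, float_format="%.6g")
    sp = pd.DataFrame(
        sp_rows, columns=["e", "omega", "eta", "convergence_stable", "ess", "label"]
    )
    sp.to_csv(OUT / "singular_points.tsv", sep="\t", index=False, float_format="%.6g")
    pd.concat(traj_frames).to_csv(
        OUT / "coevolution_trajectories.tsv", sep="\t", index=False, float_format="%.6g"
    )
    print("\nsingular points:")
    print(sp.to_string(index=False))


if __name__ == "__main__":
    main()
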