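#!/usr/bin/env python
"""Sweep the osteological range of motion of every synthetic joint.

Classifies all 75,295 poses of the 5° grid (270° flexion-extension, 180°
abduction-adduction and inversion-eversion) for each fixture from step 01,
writes the per-joint viability tables, and — for the ball-and-socket
joints — measures agreement with the analytic clearance predicate.
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from graspmorph.rig import generate_pose_grid, sweep
from graspmorph.synthetic import (
    BallSocketSpec,
    SaddleSpec,
    make_ball_and_socket,
    make_saddle_joint,
    swing_angle_deg,
)

sys.path.insert(0, str(Path(__file__).resolve().parent))
defs = __import__("01_simulate_fixtures")

RESULTS = defs.RESULTS
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "sweeps"


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    grid = generate_pose_grid()
    rows = []

    for name, opening in defs.BALL_SOCKETS.items():
        model, predicate, params = make_ball_and_socket(
            BallSocketSpec(opening_half_angle=opening,
                           mesh_resolution=defs.MESH_RESOLUTION, seed=defs.SEED))
        table = sweep(model, grid)
        table.to_csv(SCRATCH / f"{name}_viability.csv")
        codes = table.df["code"].to_numpy()
        analytic = np.array([predicate(p) for p in grid.poses], dtype=int)
        agree = float((codes == analytic).mean())
        disagree = codes != analytic
        dev = (np.abs(swing_angle_deg(grid.poses[disagree])
                      - params["swing_limit_deg"]).max()
               if disagree.any() else 0.0)
        rows.append({"joint": name, "kind": "ball_socket", "n_poses": len(grid),
                     "n_viable": table.n_viable, "oracle_agreement": agree,
                     "max_boundary_deviation_deg": float(dev)})
        print(f"{name}: {table.n_viable} viable poses, "
              f"oracle agreement {100 * agree:.2f}%, "
              f"boundary deviation <= {dev:.2f} deg")

    for name, (fe, ab) in defs.SADDLES.items():
        model = make_saddle_joint(SaddleSpec(fe_clearance=fe, abad_clearance=ab,
                                             mesh_resolution=defs.MESH_RESOLUTION,
                                             seed=defs.SEED))
        table = sweep(model, grid)
        table.to_csv(SCRATCH / f"{name}_viability.csv")
        rows.append({"joint": name, "kind": "saddle", "n_poses": len(grid),
                     "n_viable": table.n_viable, "oracle_agreement": np.nan,
                     "max_boundary_deviation_deg": np.nan})
        print(f"{name}: {table.n_viable} viable poses")

    pd.DataFrame(rows).to_csv(RESULTS / "rom_sweeps.csv", index=False)
    print(f"wrote {RESULTS / 'rom_sweeps.csv'}")


if __name__ == "__main__":
    main()
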