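#!/usr/bin/env python
"""Cosine-corrected pose-space volumetrics of the swept joints.

For every viability table from step 02: cosine-correct the viable poses,
pick the alpha radius (floor 50°, or the critical alpha when larger),
build the 3D alpha shape and report its volume in cubed degrees plus the
per-axis excursions. Confirms the saddle-joint anisotropy (FE excursion
exceeds ABAD when its clearance is larger) and the monotone growth of the
pose-space volume with either clearance.
"""
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from graspmorph.posespace import cosine_correct, excursion_summary, pose_space_shape
from graspmorph.rig import PoseViabilityTable

sys.path.insert(0, str(Path(__file__).resolve().parent))
defs = __import__("01_simulate_fixtures")

RESULTS = defs.RESULTS
SWEEPS = Path(__file__).resolve().parents[1] / "scratch" / "sweeps"


def main():
    rows = []
    for path in sorted(SWEEPS.glob("*_viability.csv")):
        name = path.name.replace("_viability.csv", "")
        table = PoseViabilityTable.from_csv(path)
        cloud = cosine_correct(table.viable[["z_deg", "y_deg", "x_deg"]].to_numpy())
        shape = pose_space_shape(cloud, floor=50.0)
        exc = excursion_summary(cloud)
        rows.append({"joint": name, "n_viable": len(cloud),
                     "alpha_radius": shape.alpha_radius,
                     "critical_alpha": shape.critical_alpha,
                     "volume_deg3": shape.volume, **exc.as_dict()})
        print(f"{name}: alpha {shape.alpha_radius:.0f} deg, "
              f"volume {shape.volume:,.0f} deg^3, "
              f"ccFE [{exc.fe_min:.0f}, {exc.fe_max:.0f}], "
              f"ccABAD [{exc.abad_min:.0f}, {exc.abad_max:.0f}]")

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "pose_space.csv", index=False)

    sad = df[df.joint.str.startswith("SAD")].set_index("joint")
    if len(sad) == 3:
        base = sad.loc["SAD4020"]
        fe_span = base.cc_fe_max - base.cc_fe_min
        ab_span = base.cc_abad_max - base.cc_abad_min
        print(f"\nanisotropy check (SAD4020): FE span {fe_span:.0f} deg "
              f"vs ABAD span {ab_span:.0f} deg -> "
              f"{'FE-dominated' if fe_span > ab_span else 'ABAD-dominated'}")
        print("volume monotonicity: "
              f"FE clearance 40->60 deg: {base.volume_deg3:,.0f} -> "
              f"{sad.loc['SAD6020'].volume_deg3:,.0f} deg^3; "
              f"ABAD 20->35 deg: {base.volume_deg3:,.0f} -> "
              f"{sad.loc['SAD4035'].volume_deg3:,.0f} deg^3")
    print(f"wrote {RESULTS / 'pose_space.csv'}")


if __name__ == "__main__":
    main()
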