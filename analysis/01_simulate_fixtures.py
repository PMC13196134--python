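#!/usr/bin/env python
"""Generate the synthetic study sample.

Builds a specimen metadata table (body masses, storage history, clade
conventions) and a panel of synthetic joints with known ground truth:
ball-and-socket joints across three opening angles and anisotropic
"saddle-like" joints across FE/ABAD clearance combinations. Meshes and
ground-truth parameters go to scratch/fixtures (regenerable from seeds);
the metadata table goes to results/.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from graspmorph import io as gio
from graspmorph.synthetic import (
    BallSocketSpec,
    SaddleSpec,
    make_ball_and_socket,
    make_saddle_joint,
    make_specimen_table,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "fixtures"

BALL_SOCKETS = {f"BS{int(a):02d}": a for a in (20.0, 30.0, 45.0)}
SADDLES = {
    "SAD4020": (40.0, 20.0),
    "SAD6020": (60.0, 20.0),
    "SAD4035": (40.0, 35.0),
}
SEED = 7
MESH_RESOLUTION = 1500


def main():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    table = make_specimen_table(12, seed=SEED)
    table.to_csv(RESULTS / "specimen_metadata.csv", index=False)
    print(f"specimen metadata: {len(table)} specimens, "
          f"masses {table.body_mass_g.min():.1f}-{table.body_mass_g.max():.1f} g")

    for name, opening in BALL_SOCKETS.items():
        model, _, params = make_ball_and_socket(
            BallSocketSpec(opening_half_angle=opening,
                           mesh_resolution=MESH_RESOLUTION, seed=SEED))
        d = SCRATCH / name
        d.mkdir(exist_ok=True)
        gio.save_mesh(model.proximal, d / "proximal.ply")
        gio.save_mesh(model.distal, d / "distal.ply")
        (d / "ground_truth.json").write_text(json.dumps(
            {"kind": "ball_socket", "seed": SEED, **params}, indent=2))
        print(f"{name}: ball-and-socket, swing limit {params['swing_limit_deg']:.1f} deg")

    for name, (fe, ab) in SADDLES.items():
        model = make_saddle_joint(SaddleSpec(fe_clearance=fe, abad_clearance=ab,
                                             mesh_resolution=MESH_RESOLUTION, seed=SEED))
        d = SCRATCH / name
        d.mkdir(exist_ok=True)
        gio.save_mesh(model.proximal, d / "proximal.ply")
        gio.save_mesh(model.distal, d / "distal.ply")
        (d / "ground_truth.json").write_text(json.dumps(
            {"kind": "saddle", "fe_clearance_deg": fe, "abad_clearance_deg": ab,
             "seed": SEED}, indent=2))
        print(f"{name}: saddle-like joint, FE {fe:.0f} deg / ABAD {ab:.0f} deg clearance")


if __name__ == "__main__":
    main()
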