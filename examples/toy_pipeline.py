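"""Full pipeline on a generated dataset: simulate, analyze, inspect.

Writes the scripted toy system for a 2-temperature x 3-pressure grid, runs
every analysis stage, and prints the pressure-response classification
table, which can be compared directly against the dataset's ground-truth
JSON.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

import piezotraj as pt
from piezotraj.pipeline import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    data = pt.write_toy_dataset(
        pt.GeneratorConfig(seed=1, temperatures=(293.0, 308.0),
                           pressures=(1.0, 1000.0, 2500.0)),
        Path(tmp) / "toy", n_frames=60,
    )
    out = Path(tmp) / "out"
    traj_paths = {
        p.stem.removeprefix("traj_").replace("K_", ",").removesuffix("bar"): str(p)
        for p in sorted(data.glob("traj_*.npz"))
    }
    manifest = run_pipeline(RunConfig(
        topology_path=str(data / "toy.pdb"),
        annotation_path=str(data / "annotation.tsv"),
        trajectory_paths=traj_paths,
        methyl_table=str(data / "methyl_axes.tsv"),
        output_dir=str(out),
    ))
    print("tables written:", ", ".join(sorted(manifest["tables"])))
    response = pd.read_csv(out / "pressure_response.csv")
    print(response[["label", "verdict", "n_positive", "n_negative"]]
          .to_string(index=False))
    truth = json.loads((data / "ground_truth.json").read_text())
    print("ground-truth occupancy of the scripted Arg-Gly bond at "
          f"2500 bar: {truth['direct_occupancy']['308,2500']['R1-G4']}")
# the scripted Arg-Gly occupancy rises with pressure (verdict 'enhanced');
# the hydrophobic pair distance compresses (verdict 'destabilized' for the
# distance observable means it decreases as pressure grows).
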