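"""Back-calculate an H-bond scalar coupling from donor-acceptor geometry.

Builds a synthetic per-frame (r_HO, theta) series for one backbone H-bond,
averages the coupling surface over it with ten-block standard errors, and
compares against a small mock experimental table.
"""

import numpy as np

import piezotraj as pt

cfg = pt.GeneratorConfig(seed=42, n_frames=10_000)
r, theta = pt.gen_hbond_geometry(cfg, pressure=1.0)
series = pt.HBondGeometrySeries(r, theta, frame_interval=100.0,
                                bond_label="K6-L67")
result = pt.ensemble_coupling(series, n_blocks=10)

print(f"bond {series.bond_label}: J = {result.J_mean:.3f} "
      f"+/- {result.block_se:.3f} Hz over {result.n_frames} frames")
# J is negative by convention; |J| grows as the H...O distance shrinks.

exp = {"K6-L67": result.J_mean + 0.04, "I3-L15": -0.63, "R42-V70": -0.30}
calc = {"K6-L67": result.J_mean, "I3-L15": -0.60, "R42-V70": -0.45}
table, summary = pt.delta_couplings(calc, exp)
print(table.to_string(index=False))
print(f"mean |dJ| = {summary['mean_abs_delta']:.3f} Hz, "
      f"{summary['n_flagged']} bond(s) beyond the 0.1 Hz threshold")
# flagged bonds deviate systematically from experiment; a mean |dJ| well
# under 0.1 Hz indicates the simulated ensemble reproduces the couplings.
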