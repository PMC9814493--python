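# piezotraj

Pressure-response analysis of protein molecular-dynamics trajectories.

High-pressure NMR can follow how individual hydrogen bonds and side-chain
motions in a folded protein respond as hydrostatic pressure rises toward the
denaturation regime, and MD simulations run across a temperature × pressure
grid can be validated against — and then extend — those measurements.
`piezotraj` implements the trajectory-analysis side of that workflow for
structural biologists and force-field developers:

- **H-bond scalar couplings.** The through-space coupling across a backbone
  N–H···O=C hydrogen bond is back-calculated per frame as
  `h3J_NC' = ⟨(−357 Hz) · exp(−3.2 r_HO) · cos²θ⟩`, with `r_HO` the
  hydrogen–acceptor-oxygen distance in Å and `θ` the H···O=C angle.
  Agreement with experiment is reported as per-bond ΔJ (flagged beyond
  ±0.1 Hz), Pearson r, RMSD and the NMR Q factor, with ten-block standard
  errors.
- **Methyl order parameters.** `S² = (3/2) tr⟨Φ⟩² − (1/2)(tr⟨Φ⟩)²` from the
  frame-averaged orientation tensor `Φ_ij = r_i r_j / r²` of each side-chain
  methyl C–C axis (1 = rigid, 0 = isotropic).
- **H-bond occupancy and lifetimes.** Per-frame detection with
  `r_HO ≤ 2.4 Å` and `θ ≥ 100°`; contacts through chemically equivalent
  hydrogens/oxygens (Lys NH₃⁺, Arg guanidinium, Asn/Gln amide, Asp/Glu
  carboxylate, chain termini) are merged into one interaction before
  occupancy ("effective occupancy") and dwell-event statistics are taken.
  Water-bridged H-bonds (one water simultaneously bonded to both residues)
  and hydrophobic mass-center contacts (cutoff 3.5 Å, no angle criterion)
  use the same event machinery.
- **Structural fluctuation.** Kabsch superposition, heavy-atom RMSD time
  series against a crystal reference, per-residue RMSF split by atom class
  and secondary-structure domain, hydrophobic-core pair distances.
- **Pressure-response regression.** Any per-condition observable is
  correlated with pressure within each temperature group (Pearson ρ, OLS
  with R²); sign consistency across groups classifies each H-bond as
  enhanced (ρ > 0), destabilized (ρ < 0) or unclear.

A fully scripted synthetic-trajectory module generates all of the above
with known ground truth, so every stage is testable without microsecond MD
data.

## Worked example

Occupancy and lifetimes of a breathing H-bond
(`examples/hbond_occupancy_lifetimes.py`):

```
effective occupancy = 0.8770 (stationary value 0.875)
1245 events, mean lifetime 7.04 ns (generator tau_on = 7 ns)
lifetime bins (0,6] / (6,100] / (100,inf) ns: (732, 513, 0)
```

The generator breathes with mean bound/unbound lifetimes of 7 ns / 1 ns, so
the stationary occupancy is 7/8; the event extractor recovers both numbers
from the boolean frame series alone, and the bin counts separate breathing
events from constantly formed bonds.

Pressure response over a 4-temperature × 6-pressure grid
(`examples/pressure_response_grid.py`):

```
278 K: rho(|J|, p) = +0.993
293 K: rho(|J|, p) = +0.994
308 K: rho(|J|, p) = +0.993
323 K: rho(|J|, p) = +0.993
classification: enhanced, fully positive
```

A −10⁻⁴ Å/bar compression of the mean H···O distance strengthens the
coupling; the per-temperature correlations recover the sign in every group
and the classifier reports the bond as pressure-enhanced.

The other examples cover coupling back-calculation with ΔJ flagging,
order-parameter recovery from cone diffusion, and the end-to-end pipeline
on a generated dataset. A thin CLI wraps the same pipeline:

```sh
piezotraj simulate --seed 1 --out dataset/
piezotraj analyze --data dataset/ --out results/
```

## Layout

- `src/piezotraj/model_io.py` — topology/trajectory model, PDB and table I/O
- `src/piezotraj/synthetic.py` — ground-truth generators and the toy system
- `src/piezotraj/jcoupling.py` — coupling surface and validation metrics
- `src/piezotraj/methyl.py` — order parameters
- `src/piezotraj/hbonds.py` — detection, merging, events, bridges, contacts
- `src/piezotraj/fluct.py` — superposition, RMSD, RMSF, core distances
- `src/piezotraj/pressure.py` — condition-grid regression and classification
- `src/piezotraj/pipeline.py`, `cli.py` — orchestration and the CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
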