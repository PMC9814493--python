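# Methods

## Scope and data model

`piezotraj` analyses coordinate trajectories of a folded protein recorded at
a fixed saving interval across a grid of (temperature, pressure) conditions
and converts them into NMR-comparable observables plus their pressure
regressions. The in-memory model is minimal: a flat atom list (0-based
internal indices; author PDB numbering retained for every reported label,
so outputs read like "K27-D52"), per-residue secondary-structure labels
taken from an annotation table rather than a DSSP run (the domain split is
treated as fixed for a stable fold), and donor/acceptor *groups* encoding
chemical equivalence. PDB reading and writing go through gemmi; a light
validation pass adds line-numbered parse errors and duplicate-atom
detection. Trajectories are plain `(frames, atoms, 3)` float arrays in Å
with a `.npz` container for persistence; adapters for binary MD formats are
deliberately out of scope because every analysis here is format-agnostic.

The analysis window drops an equilibration prefix by snapshot time: frame
`f` is taken to have been saved at `(f+1)·interval`, so discarding the
first 0.2 μs of a 1.2 μs run saved every 100 ps leaves exactly 10,000
frames.

## H-bond couplings

The through-space coupling across N–H···O=C is evaluated per frame as
`(−357 Hz)·exp(−3.2 r_HO)·cos²θ` and ensemble-averaged. `θ` is measured at
the acceptor oxygen, between the O→H and O→C directions; the same angle
convention is reused by the detection criterion below, since both describe
the same geometry. The two surface constants are exposed as arguments but
not refit. Standard errors come from ten contiguous equal blocks (the
100-ns-block convention for a 1-μs window): block SE = SD of block means /
√(n_blocks). Remainder frames after block partitioning are dropped from the
block statistics but kept in the grand mean. Agreement metrics against an
experimental table are Pearson r, RMSD and `Q = RMSD / rms(exp)` (the
standard NMR Q factor), computed over the shared bond labels only; per-bond
ΔJ values beyond ±0.1 Hz are flagged as systematic deviations.

## Methyl order parameters

`S² = (3/2) tr⟨Φ⟩² − (1/2)(tr⟨Φ⟩)²` with `Φ_ij = r_i r_j/r²` built from the
unit vector along each annotated methyl C–C axis (attached carbon → methyl
carbon) and averaged over the whole analysis window in one pass — no
internal time-windowing, so the value is the plateau ("model-free") order
parameter of the axis. `Φ` is even in the vector, so S² is invariant to
per-frame sign flips and to any global rotation. Block standard errors use
the same ten-block scheme as the couplings for uniformity. For uniform
diffusion in a cone of semiangle β the closed form
`S² = [cos β (1+cos β)/2]²` serves as the generator ground truth.

## H-bond detection, merging and events

A (hydrogen, oxygen) pair is bonded in a frame iff `r_HO ≤ 2.4 Å` and
`θ ≥ 100°` (both boundaries inclusive). Candidates are all donor-group ×
acceptor-group pairs with sequence separation ≥ 1; salt bridges are
candidates whose donor side chain is basic (Lys/Arg/His⁺ or an N-terminus)
and whose acceptor side chain is acidic (Asp/Glu or a C-terminus).

Symmetry-equivalent hydrogens (Asn HD21/HD22, Gln HE21/HE22, Lys HZ1–3,
Arg HE/HH11/HH12/HH21/HH22, N-terminal HT1–3) and oxygens (Asp OD1/OD2,
Glu OE1/OE2, C-terminal OT1/OT2) belong to one group: the merged per-frame
indicator is the logical OR over all member pairs, so interchanging
contacts within a group count as a single continuous interaction. Note the
Arg group spans hydrogens bonded to three different heavy atoms; the group
stores a primary heavy atom but does not require all hydrogens to be bonded
to it (no bond topology is parsed).

Events are maximal runs of bonded frames; a run of `n` frames has lifetime
`n·interval` (each saved frame represents one saving interval) and a single
unbonded frame terminates an event by default — a `gap_tolerance` parameter
can bridge short gaps, with bridged frames not counted toward occupancy.
Effective occupancy is the bonded-frame fraction, identically equal to
Σ lifetimes / window duration. Lifetime bins are right-closed, (0,6],
(6,100] and (100,∞) ns for direct bonds; water-bridged statistics default
to a (0,4] ns short bin because bridge events are dominated by fast water
exchange.

**Water bridges.** A frame counts for a residue pair when one water
simultaneously satisfies the criterion with both residues. Each leg may run
in either direction: residue-donor → water oxygen, with the angle evaluated
at the water oxygen using each water hydrogen in turn as the antecedent
(any orientation qualifies), or water-hydrogen → residue acceptor with the
residue's own O=C antecedent. The symmetric 2.4 Å/100° rule on both legs is
an interpretation and is isolated in a single predicate
(`_water_link_indicator`) so it can be swapped. The bridging water's
identity may change between frames without breaking an event: occupancy is
defined per residue pair, not per water molecule.

**Hydrophobic contacts.** Contact iff the distance between side-chain
mass-weighted centers is ≤ 3.5 Å, with no direction criterion; a
water-bridged contact requires a water oxygen within the same cutoff of
both centers.

## Superposition, RMSD, RMSF

Superposition is the weighted least-squares rigid fit (Kabsch): both sets
are centred at their weighted centroids, the optimal proper rotation comes
from `scipy.spatial.transform.Rotation.align_vectors`, and the residual is
recomputed explicitly after applying the fit (the library's own residual
loses ~1e-8 Å to cancellation near zero, which matters for identity
checks). Weights default to uniform; mass weighting is a caller choice.
Fewer than three atoms or a collinear set raises.

RMSD time series superpose each frame on the reference over the configured
selection (for a ubiquitin-like system with a dangling C-terminal tail, the
convention is heavy atoms of the structured residues only, e.g. 1–71) and
report the trajectory mean with the SD of block means as the error bar.
RMSF uses the mean structure as reference with one refit pass: frames are
fitted to the initial reference, the mean structure is computed, frames are
refitted to that mean, and the per-residue RMSF is the RMS displacement
over frames and selected atoms from their mean positions. Crystal-reference
RMSF is available through the `reference` argument. Domain averages group
residues by secondary structure for each atom class (all/backbone/side
chain heavy), optionally excluding listed residues (the tail) from the
averages; a residue with no atoms in a class is reported absent, not zero.

## Pressure-response layer

Observables live in a condition table keyed by (temperature, pressure);
duplicated conditions are rejected and the sparse experimental grid simply
leaves cells absent. Correlations are computed strictly within one
temperature group, never pooling temperatures; groups with fewer than
three pressure points, or an observable with zero variance, yield a
missing value (NaN) rather than zero. Classification counts the signs of
the defined per-temperature ρ: "enhanced" with ρ > 0 in ≥ 3 groups,
"destabilized" with ρ < 0 in ≥ 3, otherwise "unclear"; fully consistent
signs are additionally flagged, and |ρ| < 0.5 in every group marks a weak
response. The 0.5 threshold is a convention, not a derived quantity, and is
configurable and surfaced in every report. Linear fits are ordinary least
squares of the observable on pressure in bar with R² reported; no
nonlinear pressure models are offered because the condition grids of
interest (6–10 pressures per temperature) cannot constrain them. Couplings
can be correlated either signed or as |J| (default signed); distance-
pressure matrices report the per-pair ρ symmetrically with residue labels
for heat-map rendering.

## Synthetic generators

The generators emulate the statistical structure of the data, not the
physics: pressure enters only through a prescribed linear compression of
the mean H···O distance (and of the scripted contact distances) and through
scripted occupancy schedules. Random streams are split per observable
(seed + stream-name hash), so adding one generator call never shifts
another's sequence, and everything is bitwise reproducible under a fixed
seed.

Defaults are fixed to the study conditions: 100 ps saving interval, a
10,000-frame window, mean `r_HO` 2.0 Å with 0.1 Å spread (a typical strong
backbone H-bond), compression slope −10⁻⁴ Å/bar (≈0.25 Å over 2500 bar,
the magnitude needed for a clearly resolvable coupling response),
bound/unbound lifetimes 7 ns/1 ns (stationary occupancy 0.875, resolvable
at the saving interval), a 30° methyl cone (S² ≈ 0.65, mid-range for side
chains), and a 4-temperature (278–323 K) × 6-pressure (1–2500 bar) grid
matching the experimentally backed subset of conditions.

- `gen_hbond_geometry`: r from a truncated normal (r > 0), θ from a normal
  clipped to [0°, 180°].
- `gen_two_state_series`: two-state Markov chain with per-frame switch
  probabilities `interval/tau_off` (off→on) and `interval/tau_on` (on→off);
  warns when the interval exceeds a mean lifetime. Start state defaults to
  a stationary draw.
- `gen_cone_vectors`: uniform over the spherical cap (cos θ uniform on
  [cos β, 1], azimuth uniform).
- `gen_toy_system`: nine residues in three clusters ≥ 25 Å apart so no
  unintended contacts arise. A Lys–Asp salt bridge alternates its bonded
  hydrogen every frame (merged occupancy exactly 1, members 0.5); an
  Arg–Gly bond follows a scripted occupancy rising linearly with pressure,
  with a water bridging the same pair in 2 of every 3 frames; a Leu–Val
  pair sits in mass-center contact for half the frames at a
  pressure-compressed distance, with a water bridging it in the separated
  half; Val's CB–CG1 axis diffuses on the configured cone. The written
  dataset (PDB + annotation + trajectories + ground-truth JSON) feeds the
  full pipeline. The toy default of 600 frames per condition (divisible by
  2, 3 and 10) keeps every scripted fraction exact.

**What passing tests do and do not show.** The generators validate the
estimators — occupancy, lifetimes, S², couplings, regressions — against
known ground truth, including their convergence at 10⁵ frames. They do not
exercise force-field physics, solvent structure, correlated protein motion,
or the detection criterion's behaviour on borderline real geometries;
agreement on synthetic data says the analysis is correct, not that a given
simulation reproduces experiment.

## Numerical and design choices

- For equivalent acceptor oxygens, the per-frame coupling geometry uses the
  member pair with minimum `r_HO` that frame, consistent with the merging
  rule (the choice only matters in the rare frames where two members are
  simultaneously close).
- Per-block validation metrics recompute r/RMSD/Q from block-wise
  calculated means against the fixed experimental vector.
- Degenerate geometry (hydrogen or antecedent coincident with the oxygen)
  raises instead of returning an arbitrary angle.
- The pipeline consolidates stage selection into one `analyze --stages`
  flag rather than one subcommand per stage; intermediate tables are plain
  long-format CSV so stages can be rerun and joined externally. A failed
  stage removes the partial outputs of that run and names the stage.
- End-to-end determinism: rerunning the pipeline on the same dataset
  produces byte-identical tables.

## Known limitations

- No gap-tolerant event definition by default; H-bond kinetics via
  intermittent autocorrelation (Luzar–Chandler) are out of scope.
- Water-donor bridge geometry uses the water-hydrogen-as-antecedent
  convention described above; alternative conventions would change bridge
  occupancies near the angular cutoff.
- The RMSF reference (mean structure, one refit pass) differs from a
  crystal-reference RMSF by design; both are exposed.
- Superposition weights are uniform by default; mass-weighted fits change
  RMSD in the third decimal for typical proteins.
- No B-factor comparison, solvent-accessible surface area, cavity/tunnel
  analysis, or MD-engine invocation.
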