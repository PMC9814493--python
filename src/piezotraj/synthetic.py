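"""Synthetic trajectories and geometry series with known ground truth.

Every analysis stage in this package is testable without MD data: the
generators here emulate the *statistical structure* of pressure-series
protein trajectories — Gaussian donor–acceptor geometry whose mean distance
compresses linearly with pressure, two-state (bound/unbound) H-bond dynamics
with tunable mean lifetimes, methyl axes diffusing uniformly in a cone with
a closed-form order parameter, and a small scripted peptide-like system in
which H-bond indicator series, water bridges and mass-center distances are
realised exactly by construction.  No physics is simulated: pressure enters
only through the prescribed linear compression and scripted occupancies.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .methyl import cone_order_parameter
from .model_io import (
    AtomRecord,
    ConditionLabel,
    Residue,
    Topology,
    Trajectory,
    save_trajectory,
    write_pdb,
)

__all__ = [
    "GeneratorConfig",
    "gen_hbond_geometry",
    "gen_two_state_series",
    "gen_cone_vectors",
    "gen_toy_system",
    "write_toy_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generators.

    Defaults follow the study conditions: 100 ps saving interval and a
    10,000-frame analysis window; a 2.0 Å mean H...O distance with 0.1 Å
    spread compressing at -1e-4 Å/bar; bound/unbound mean lifetimes of
    7 ns / 1 ns (stationary occupancy 0.875); a 30 degree methyl cone; and a
    grid of four temperatures by six pressures spanning 1–2500 bar.
    """

    seed: int = 0
    n_frames: int = 10_000
    frame_interval: float = 100.0          # ps
    r_mean_at_1bar: float = 2.0            # Å
    r_sigma: float = 0.1                   # Å
    compression_slope: float = -1e-4       # Å/bar (<= 0 compresses)
    theta_mean: float = 160.0              # degrees
    theta_sigma: float = 10.0              # degrees
    tau_on: float = 7000.0                 # ps
    tau_off: float = 1000.0                # ps
    cone_semiangle: float = 30.0           # degrees
    pressures: tuple[float, ...] = (1.0, 500.0, 1000.0, 1500.0, 2000.0, 2500.0)
    temperatures: tuple[float, ...] = (278.0, 293.0, 308.0, 323.0)

    def __post_init__(self) -> None:
        if self.r_sigma < 0:
            raise ValueError("r_sigma must be non-negative")
        if not 0 < self.cone_semiangle <= 90:
            raise ValueError("cone_semiangle must lie in (0, 90] degrees")
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("tau_on and tau_off must be positive")
        if self.n_frames < 1 or self.frame_interval <= 0:
            raise ValueError("need n_frames >= 1 and a positive frame_interval")


def _rng(seed: int, stream: str, *extra: float) -> np.random.Generator:
    """Independent stream per observable: adding one generator call does not
    shift another's sequence."""
    key = [seed, zlib.crc32(stream.encode())]
    key += [int(round(x * 1000)) % (2**31) for x in extra]
    return np.random.default_rng(np.random.SeedSequence(key))


def gen_hbond_geometry(
    config: GeneratorConfig, pressure: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (r_HO, theta) series at one pressure.

    r ~ Normal(r_mean_at_1bar + compression_slope * (p - 1), r_sigma)
    truncated at r > 0; theta ~ Normal(theta_mean, theta_sigma) clipped to
    [0, 180] degrees.
    """
    rng = _rng(config.seed, "hbond_geometry", pressure)
    mean = config.r_mean_at_1bar + config.compression_slope * (pressure - 1.0)
    if config.r_sigma == 0:
        r = np.full(config.n_frames, mean)
    else:
        a = (0.0 - mean) / config.r_sigma   # truncate at r > 0
        r = stats.truncnorm.rvs(
            a, np.inf, loc=mean, scale=config.r_sigma,
            size=config.n_frames, random_state=rng,
        )
    theta = np.clip(
        rng.normal(config.theta_mean, config.theta_sigma, config.n_frames),
        0.0, 180.0,
    )
    return r, theta


def gen_two_state_series(
    config: GeneratorConfig,
    n_frames: int | None = None,
    start: str = "stationary",
) -> np.ndarray:
    """Boolean bound/unbound series from a two-state Markov chain.

    Per-frame switch probabilities are interval/tau_off (unbound -> bound)
    and interval/tau_on (bound -> unbound), so the stationary occupancy is
    tau_on / (tau_on + tau_off) and the mean bound dwell is tau_on.
    ``start`` is "on", "off" or "stationary" (drawn from the stationary
    distribution).
    """
    n = config.n_frames if n_frames is None else n_frames
    dt = config.frame_interval
    if dt > min(config.tau_on, config.tau_off):
        warnings.warn(
            "frame interval exceeds a mean lifetime: dwell times unresolvable",
            stacklevel=2,
        )
    p_on_off = min(dt / config.tau_on, 1.0)
    p_off_on = min(dt / config.tau_off, 1.0)
    rng = _rng(config.seed, "two_state")
    occ = config.tau_on / (config.tau_on + config.tau_off)
    if start == "stationary":
        state = bool(rng.random() < occ)
    elif start in ("on", "off"):
        state = start == "on"
    else:
        raise ValueError("start must be 'on', 'off' or 'stationary'")
    u = rng.random(n)
    out = np.empty(n, dtype=bool)
    for i in range(n):
        out[i] = state
        if state:
            if u[i] < p_on_off:
                state = False
        elif u[i] < p_off_on:
            state = True
    return out


def gen_cone_vectors(
    config: GeneratorConfig,
    n_frames: int | None = None,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
) -> np.ndarray:
    """Unit vectors uniform over the spherical cap of the configured
    semiangle about ``axis``; ground-truth S^2 is
    :func:`piezotraj.methyl.cone_order_parameter`."""
    n = config.n_frames if n_frames is None else n_frames
    rng = _rng(config.seed, "cone")
    cos_beta = np.cos(np.deg2rad(config.cone_semiangle))
    cos_t = rng.uniform(cos_beta, 1.0, n)         # uniform in solid angle
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    local = np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t]
    )
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    if np.allclose(a, [0, 0, 1]):
        return local
    # rotate +z onto the requested axis
    v = np.cross([0.0, 0.0, 1.0], a)
    s = np.linalg.norm(v)
    c = float(a[2])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return local @ R.T


# ---------------------------------------------------------------------------
# Scripted toy system
# ---------------------------------------------------------------------------

# toy residue layout: three well-separated clusters (>= 25 Å apart) so no
# unintended contacts arise between scripted interactions
_OA = np.array([0.0, 0.0, 0.0])      # Lys2 / Asp3 salt bridge
_OB = np.array([40.0, 0.0, 0.0])     # Arg1 / Gly4 bond + water bridge
_OC = np.array([0.0, 40.0, 0.0])     # Leu5 / Val6 hydrophobic pair + water

_TOY_RESIDUES = [
    ("ARG", 1), ("LYS", 2), ("ASP", 3), ("GLY", 4),
    ("LEU", 5), ("VAL", 6), ("HOH", 7), ("HOH", 8), ("HOH", 9),
]

# static atoms: name -> (element, position); dynamic atoms get positions per
# frame in _toy_frame
_TOY_ATOMS: dict[int, list[tuple[str, str, np.ndarray | None]]] = {
    1: [  # Arg-like: guanidinium donor group of 5 equivalent hydrogens
        ("N", "N", _OB + (-4.0, -4.0, 0.0)),
        ("CA", "C", _OB + (-3.0, -4.5, 0.0)),
        ("C", "C", _OB + (-2.0, -5.0, 0.5)),
        ("O", "O", _OB + (-1.5, -6.0, 0.2)),
        ("NE", "N", _OB + (-3.4, 0.0, 0.0)),
        ("HE", "H", None),
        ("HH11", "H", None),
        ("HH12", "H", _OB + (-8.0, 1.0, 0.0)),
        ("HH21", "H", _OB + (-8.0, -1.0, 0.0)),
        ("HH22", "H", _OB + (-8.0, 0.0, -1.0)),
    ],
    2: [  # Lys-like: ammonium donor group, alternating hydrogens
        ("N", "N", _OA + (-3.0, -4.0, 0.0)),
        ("CA", "C", _OA + (-2.0, -4.5, 0.0)),
        ("C", "C", _OA + (-1.0, -5.0, 0.5)),
        ("O", "O", _OA + (-0.5, -6.0, 0.2)),
        ("NZ", "N", _OA + (-3.0, 0.0, 0.0)),
        ("HZ1", "H", None),
        ("HZ2", "H", None),
        ("HZ3", "H", _OA + (-6.0, -0.5, 0.0)),
    ],
    3: [  # Asp-like: carboxylate acceptor pair
        ("N", "N", _OA + (5.0, -3.0, 0.0)),
        ("CA", "C", _OA + (4.0, -2.5, 0.0)),
        ("C", "C", _OA + (4.5, -4.0, 0.5)),
        ("O", "O", _OA + (5.5, -4.5, 0.5)),
        ("CG", "C", _OA + (1.25, 0.0, 0.0)),
        ("OD1", "O", _OA + (0.0, 0.0, 0.0)),
        ("OD2", "O", _OA + (2.0, 1.0, 0.0)),
    ],
    4: [  # Gly-like: backbone carbonyl acceptor
        ("N", "N", _OB + (2.5, 1.5, 0.0)),
        ("CA", "C", _OB + (3.5, 0.8, 0.0)),
        ("C", "C", _OB + (1.23, 0.0, 0.0)),
        ("O", "O", _OB + (0.0, 0.0, 0.0)),
    ],
    5: [  # Leu-like hydrophobic side chain
        ("N", "N", _OC + (-1.0, -4.0, 0.0)),
        ("CA", "C", _OC + (0.0, -4.5, 0.0)),
        ("C", "C", _OC + (1.0, -5.0, 0.5)),
        ("O", "O", _OC + (1.5, -6.0, 0.2)),
        ("CB", "C", None),
        ("CG", "C", None),
        ("CD1", "C", None),
        ("CD2", "C", None),
    ],
    6: [  # Val-like hydrophobic side chain; CB->CG1 is the methyl axis
        ("N", "N", _OC + (6.0, -4.0, 0.0)),
        ("CA", "C", _OC + (7.0, -4.5, 0.0)),
        ("C", "C", _OC + (8.0, -5.0, 0.5)),
        ("O", "O", _OC + (8.5, -6.0, 0.2)),
        ("CB", "C", None),
        ("CG1", "C", None),
        ("CG2", "C", None),
    ],
    7: [("O", "O", None), ("H1", "H", None), ("H2", "H", None)],
    8: [("O", "O", None), ("H1", "H", None), ("H2", "H", None)],
    9: [
        ("O", "O", np.array([40.0, 40.0, 0.0])),
        ("H1", "H", np.array([40.6, 40.6, 0.0])),
        ("H2", "H", np.array([40.6, 39.4, 0.0])),
    ],
}

_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "H": 1.008}

# Leu side-chain shape, equal carbon masses -> local mass center (1.525, 0, 0)
_LEU_LOCAL = {
    "CB": np.array([0.0, 0.0, 0.0]),
    "CG": np.array([1.5, 0.0, 0.0]),
    "CD1": np.array([2.3, 1.2, 0.0]),
    "CD2": np.array([2.3, -1.2, 0.0]),
}
_LEU_CENTER = np.mean(list(_LEU_LOCAL.values()), axis=0)

ANNOTATION_TSV = """\
record\tresidue\tspec\tkind
donor\t1\tNE:HE,HH11,HH12,HH21,HH22\tsidechain
donor\t2\tNZ:HZ1,HZ2,HZ3\tsidechain
acceptor\t3\tOD1@CG,OD2@CG\tsidechain
acceptor\t4\tO@C\tbackbone
core\t5\tCB,CG,CD1,CD2\t
core\t6\tCB,CG1,CG2\t
ss\t1-2\thelix\t
ss\t3-4\tsheet\t
ss\t5-9\tloop\t
"""

METHYL_TSV = """\
residue\tmethyl\tattached
6\tCG1\tCB
"""


def _toy_topology() -> Topology:
    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    for name, number in _TOY_RESIDUES:
        res_idx = len(residues)
        residues.append(
            Residue(name=name, author_number=number, chain="A",
                    is_solvent=name == "HOH")
        )
        for atom_name, element, _ in _TOY_ATOMS[number]:
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    name=atom_name,
                    element=element,
                    mass=_MASS[element],
                    residue_index=res_idx,
                    residue_name=name,
                    chain="A",
                )
            )
    return Topology(atoms=atoms, residues=residues)


def _direct_occupancy(pressure: float) -> float:
    """Scripted Arg1-Gly4 occupancy: rises linearly with pressure."""
    return min(0.5 + 8e-5 * (pressure - 1.0), 0.95)


def _toy_frame(
    f: int,
    n_frames: int,
    pressure: float,
    compression_slope: float,
    cone_vec: np.ndarray,
    positions: dict[tuple[int, str], np.ndarray],
) -> None:
    """Fill the dynamic atom positions of frame ``f`` in-place."""
    # --- cluster A: Lys2 HZ1 (even frames) / HZ2 (odd frames) to Asp3 OD1
    if f % 2 == 0:
        positions[(2, "HZ1")] = _OA + (-2.0, 0.0, 0.0)
        positions[(2, "HZ2")] = _OA + (-6.0, 0.05, 0.0)
    else:
        positions[(2, "HZ1")] = _OA + (-6.0, 0.0, 0.0)
        positions[(2, "HZ2")] = _OA + (-2.0, 0.05, 0.0)

    # --- cluster B: Arg1 HE to Gly4 O for the first occ*F frames
    bonded = f < round(_direct_occupancy(pressure) * n_frames)
    positions[(1, "HE")] = _OB + ((-2.0, 0.0, 0.0) if bonded else (-6.0, 0.0, 0.0))

    # water bridge Arg1--w7--Gly4 in frames with f % 3 != 1
    if f % 3 != 1:
        w_o = _OB + (-2.33, 0.0, 2.83)
        u = (w_o - _OB) / np.linalg.norm(w_o - _OB)     # Gly O -> water O
        positions[(7, "O")] = w_o
        positions[(7, "H1")] = _OB + 2.0 * u            # donates to Gly4 O
        positions[(7, "H2")] = w_o + (0.0, 0.96, 0.0)
        positions[(1, "HH11")] = w_o + 2.0 * u          # accepts Arg1 H
    else:
        positions[(7, "O")] = _OB + (0.0, 12.0, 0.0)
        positions[(7, "H1")] = _OB + (0.6, 12.6, 0.0)
        positions[(7, "H2")] = _OB + (-0.6, 12.6, 0.0)
        positions[(1, "HH11")] = _OB + (-8.0, 0.0, 1.0)

    # --- cluster C: hydrophobic pair at d(p) for the first half, 5 Å after
    slope_term = compression_slope * (pressure - 1.0)
    close = f < n_frames // 2
    d = (3.4 if close else 5.0) + slope_term
    center_a = _OC
    center_b = _OC + (d, 0.0, 0.0)
    for name, local in _LEU_LOCAL.items():
        positions[(5, name)] = center_a + (local - _LEU_CENTER)
    # Val6: CB at origin of its local frame, CG1 on the cone, CG2 fixed;
    # translate so the three-carbon mass center lands exactly on center_b
    cb = np.zeros(3)
    cg1 = 1.54 * cone_vec
    cg2 = np.array([-1.0, -1.0, -0.5])
    local_center = (cb + cg1 + cg2) / 3.0
    shift = center_b - local_center
    positions[(6, "CB")] = cb + shift
    positions[(6, "CG1")] = cg1 + shift
    positions[(6, "CG2")] = cg2 + shift

    # water8 bridges the hydrophobic pair only while the pair is separated
    if not close:
        mid = (center_a + center_b) / 2.0
        positions[(8, "O")] = mid
        positions[(8, "H1")] = mid + (0.6, 0.6, 0.0)
        positions[(8, "H2")] = mid + (-0.6, 0.6, 0.0)
    else:
        positions[(8, "O")] = _OC + (0.0, 12.0, 0.0)
        positions[(8, "H1")] = _OC + (0.6, 12.6, 0.0)
        positions[(8, "H2")] = _OC + (-0.6, 12.6, 0.0)


def gen_toy_system(
    config: GeneratorConfig,
    n_frames: int | None = None,
) -> tuple[Topology, dict[ConditionLabel, Trajectory], dict]:
    """Scripted peptide-like system realising known analysis results exactly.

    Nine residues in three isolated clusters: a Lys-Asp salt bridge whose
    equivalent hydrogens alternate every frame (merged occupancy 1.0, each
    member 0.5); an Arg-Gly H-bond with pressure-dependent scripted
    occupancy plus a water bridging the same pair in 2 of every 3 frames;
    and a Leu-Val hydrophobic pair in mass-center contact for half the
    frames (contact distance compressing linearly with pressure) with a
    water bridging the pair in the separated half.  Val's CB-CG1 axis
    diffuses on the configured cone.  Returns (topology, trajectory per
    condition, ground-truth dict).
    """
    n = n_frames if n_frames is not None else config.n_frames
    topo = _toy_topology()
    name_to_idx = {
        (topo.residues[a.residue_index].author_number, a.name): a.index
        for a in topo.atoms
    }
    static = {
        (number, atom_name): pos
        for number, entries in _TOY_ATOMS.items()
        for atom_name, _, pos in entries
        if pos is not None
    }
    cone = gen_cone_vectors(config, n_frames=n)

    trajectories: dict[ConditionLabel, Trajectory] = {}
    for t in config.temperatures:
        for p in config.pressures:
            coords = np.empty((n, topo.n_atoms, 3))
            positions: dict[tuple[int, str], np.ndarray] = dict(static)
            for f in range(n):
                _toy_frame(f, n, p, config.compression_slope, cone[f], positions)
                for key, idx in name_to_idx.items():
                    coords[f, idx] = positions[key]
            cond = ConditionLabel(temperature=t, pressure=p)
            trajectories[cond] = Trajectory(
                topology=topo,
                coords=coords,
                frame_interval=config.frame_interval,
                condition=cond,
            )

    bridge_frames = sum(1 for f in range(n) if f % 3 != 1)
    ground_truth = {
        "n_frames": n,
        "direct_occupancy": {
            f"{t:g},{p:g}": {
                "R1-G4": round(_direct_occupancy(p) * n) / n,
                "K2-D3": 1.0,
            }
            for t in config.temperatures
            for p in config.pressures
        },
        "member_occupancy_K2_D3": [
            (n - n // 2) / n,   # HZ1, even frames
            (n // 2) / n,       # HZ2, odd frames
            0.0,                # HZ3 parked
        ],
        "bridge_occupancy_R1_G4": bridge_frames / n,
        "contact_occupancy_L5_V6": (n // 2) / n,
        "bridged_contact_occupancy_L5_V6": (n - n // 2) / n,
        "s2_cone": cone_order_parameter(config.cone_semiangle),
        "compression_slope": config.compression_slope,
        "contact_distance_close": 3.4,
        "contact_distance_far": 5.0,
    }
    return topo, trajectories, ground_truth


def write_toy_dataset(
    config: GeneratorConfig,
    outdir: str | Path,
    n_frames: int | None = None,
    force: bool = False,
) -> Path:
    """Write the toy system to disk as PDB + annotation table + per-condition
    trajectory containers + ground-truth JSON, loadable by the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    topo, trajs, truth = gen_toy_system(config, n_frames=n_frames)
    first = next(iter(trajs.values()))
    write_pdb(topo, first.coords[0], outdir / "toy.pdb")
    (outdir / "annotation.tsv").write_text(ANNOTATION_TSV)
    (outdir / "methyl_axes.tsv").write_text(METHYL_TSV)
    for cond, traj in trajs.items():
        save_trajectory(traj, outdir / f"traj_{cond}.npz")
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2))
    return outdir
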