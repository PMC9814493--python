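"""Topology and trajectory data model, PDB and table I/O, analysis-window selection.

The in-memory model is deliberately small: a flat atom list with 0-based
internal indices, a residue list that keeps the author (PDB) numbering for
reporting, and donor/acceptor *groups* that encode the chemical equivalence
of symmetry-related hydrogens and oxygens (Lys NH3+, Arg guanidinium,
Asn/Gln amide, Asp/Glu carboxylate, chain termini).  Coordinates are plain
``(n_frames, n_atoms, 3)`` float arrays in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Residue",
    "DonorGroup",
    "AcceptorGroup",
    "Topology",
    "ConditionLabel",
    "Trajectory",
    "PDBParseError",
    "AnnotationError",
    "read_pdb",
    "write_pdb",
    "annotate_topology",
    "select_analysis_window",
    "read_reference_table",
    "save_trajectory",
    "load_trajectory",
]

#: residue names recognised as solvent water (configurable per call)
WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SOL"})

SS_LABELS = ("helix", "sheet", "loop")


class PDBParseError(ValueError):
    """Raised for malformed PDB records; message names the offending line."""


class AnnotationError(ValueError):
    """Raised when an annotation row cannot be resolved against the topology."""


@dataclass(frozen=True)
class AtomRecord:
    index: int                # 0-based internal index
    name: str                 # PDB atom name, e.g. "HZ1", "OD2"
    element: str
    mass: float               # amu
    residue_index: int        # 0-based internal residue index
    residue_name: str
    chain: str


@dataclass
class Residue:
    name: str
    author_number: int        # PDB numbering, used in all reported labels
    chain: str
    secondary_structure: str = "loop"   # helix | sheet | loop
    is_solvent: bool = False


@dataclass(frozen=True)
class DonorGroup:
    """Equivalence group of donor hydrogens sharing one interaction identity."""

    residue_index: int
    heavy_atom: int                 # primary heavy atom (backbone/sidechain N)
    hydrogens: tuple[int, ...]      # treated as chemically equivalent
    kind: str = "sidechain"         # backbone | sidechain | terminal

    def __post_init__(self) -> None:
        if not self.hydrogens:
            raise ValueError("donor group needs at least one hydrogen")


@dataclass(frozen=True)
class AcceptorGroup:
    """Equivalence group of acceptor oxygens, each with its antecedent carbon."""

    residue_index: int
    oxygens: tuple[int, ...]
    antecedent_carbons: Mapping[int, int]   # oxygen index -> bonded C index
    kind: str = "sidechain"

    def __post_init__(self) -> None:
        if not self.oxygens:
            raise ValueError("acceptor group needs at least one oxygen")
        missing = [o for o in self.oxygens if o not in self.antecedent_carbons]
        if missing:
            raise ValueError(f"oxygens without antecedent carbon: {missing}")


@dataclass
class Topology:
    atoms: list[AtomRecord]
    residues: list[Residue]
    donor_groups: list[DonorGroup] = field(default_factory=list)
    acceptor_groups: list[AcceptorGroup] = field(default_factory=list)
    # residue_index -> side-chain heavy-atom indices of the hydrophobic core
    hydrophobic_core: dict[int, tuple[int, ...]] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atoms_of_residue(self, residue_index: int) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue_index == residue_index]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == atom_name:
                return a.index
        res = self.residues[residue_index]
        raise AnnotationError(
            f"atom {atom_name!r} not found in residue "
            f"{res.name}{res.author_number} (chain {res.chain})"
        )

    def residue_by_author_number(self, number: int, chain: str | None = None) -> int:
        for i, r in enumerate(self.residues):
            if r.author_number == number and (chain is None or r.chain == chain):
                return i
        raise AnnotationError(f"no residue with author number {number}")

    def water_residues(self) -> list[int]:
        return [i for i, r in enumerate(self.residues) if r.is_solvent]

    def residue_label(self, residue_index: int) -> str:
        r = self.residues[residue_index]
        return f"{_one_letter(r.name)}{r.author_number}"

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ConditionLabel:
    temperature: float    # K
    pressure: float       # bar

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if self.pressure < 1:
            raise ValueError("pressure must be >= 1 bar")

    def __str__(self) -> str:
        return f"{self.temperature:g}K_{self.pressure:g}bar"


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (Å) at a fixed saving interval (ps)."""

    topology: Topology
    coords: np.ndarray            # (n_frames, n_atoms, 3), Å
    frame_interval: float         # ps
    condition: ConditionLabel | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ps)")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Snapshot times in ps; frame f was saved at (f+1)*interval."""
        return (np.arange(self.n_frames) + 1) * self.frame_interval

    @property
    def span(self) -> float:
        """Total simulated span covered by the saved frames, ps."""
        return self.n_frames * self.frame_interval


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "HSD": "H",
    "ILE": "I", "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F",
    "PRO": "P", "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y",
    "VAL": "V",
}


def _one_letter(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.upper(), resname.capitalize())


# ---------------------------------------------------------------------------
# PDB I/O (backed by gemmi; a validation pass supplies line-numbered errors)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> None:
    seen: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated {rec} record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed {rec} record ({exc})")
            key = (line[21], int(line[22:26]), line[26], line[12:16].strip())
            if key in seen:
                raise PDBParseError(
                    f"line {lineno}: duplicate atom {line[12:16].strip()!r} "
                    f"in residue {int(line[22:26])} chain {line[21]!r}"
                )
            seen.add(key)


def read_pdb(
    path: str | Path,
    water_resnames: Iterable[str] = WATER_RESNAMES,
) -> tuple[Topology, np.ndarray]:
    """Read ATOM/HETATM records into a topology skeleton and one coordinate frame.

    The returned topology has no donor/acceptor groups yet (see
    :func:`annotate_topology`).  Waters are flagged as solvent by residue name.
    """
    path = Path(path)
    _validate_pdb_lines(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    waters = {w.upper() for w in water_resnames}

    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    xyz: list[tuple[float, float, float]] = []
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    model = st[0]
    for chain in model:
        for res in chain:
            res_idx = len(residues)
            residues.append(
                Residue(
                    name=res.name,
                    author_number=res.seqid.num,
                    chain=chain.name,
                    is_solvent=res.name.upper() in waters,
                )
            )
            for atom in res:
                el = atom.element
                atoms.append(
                    AtomRecord(
                        index=len(atoms),
                        name=atom.name,
                        element=el.name,
                        mass=float(el.weight) if el.weight > 0 else 1.0,
                        residue_index=res_idx,
                        residue_name=res.name,
                        chain=chain.name,
                    )
                )
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return Topology(atoms=atoms, residues=residues), np.asarray(xyz, dtype=float)


def write_pdb(topology: Topology, coords: np.ndarray, path: str | Path) -> None:
    """Write a single coordinate frame as a PDB file (ATOM/HETATM only)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coords must have shape (n_atoms, 3)")
    st = gemmi.Structure()
    st.name = "piezotraj"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res_idx, res in enumerate(topology.residues):
        ch = chains.get(res.chain)
        if ch is None:
            ch = gemmi.Chain(res.chain)
            chains[res.chain] = ch
            model.add_chain(ch)
            ch = model[len(model) - 1]
            chains[res.chain] = ch
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.author_number, " ")
        gres.het_flag = "H" if res.is_solvent else "A"
        for a in topology.atoms_of_residue(res_idx):
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            x, y, z = coords[a.index]
            ga.pos = gemmi.Position(float(x), float(y), float(z))
            gres.add_atom(ga)
        ch.add_residue(gres)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

def _parse_residue_field(value: str) -> tuple[int, int]:
    s = str(value).strip()
    if "-" in s[1:]:
        head, tail = s[1:].split("-", 1)
        return int(s[0] + head), int(tail)
    return int(s), int(s)


def annotate_topology(
    topology: Topology,
    table: str | Path | pd.DataFrame,
) -> Topology:
    """Resolve an annotation table into donor/acceptor groups, secondary
    structure labels and hydrophobic-core selections.

    The table is tab-delimited text with columns ``record``, ``residue``,
    ``spec`` and ``kind``.  Record types:

    ``donor``
        ``spec`` is ``HEAVY:H1,H2,...`` — a heavy atom and its equivalent
        hydrogens (e.g. ``NZ:HZ1,HZ2,HZ3`` for Lys).
    ``acceptor``
        ``spec`` is ``O1@C1,O2@C2`` — equivalent oxygens with the antecedent
        carbon defining each O=C axis (``OD1@CG,OD2@CG`` for Asp).
    ``ss``
        ``residue`` may be a range ``23-34``; ``spec`` is helix/sheet/loop.
    ``core``
        ``spec`` lists the side-chain heavy atoms of a hydrophobic-core
        residue.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t", comment="#", dtype=str)
    required = {"record", "residue", "spec"}
    if not required.issubset(table.columns):
        raise AnnotationError(f"annotation table must have columns {sorted(required)}")

    topo = replace_topology(topology)
    for _, row in table.iterrows():
        record = str(row["record"]).strip().lower()
        kind = str(row.get("kind", "") or "sidechain").strip().lower()
        spec = str(row["spec"]).strip()
        if record == "ss":
            lo, hi = _parse_residue_field(row["residue"])
            label = spec.lower()
            if label not in SS_LABELS:
                raise AnnotationError(f"unknown secondary-structure label {spec!r}")
            hit = False
            for r in topo.residues:
                if lo <= r.author_number <= hi and not r.is_solvent:
                    r.secondary_structure = label
                    hit = True
            if not hit:
                raise AnnotationError(f"ss range {lo}-{hi} matches no residue")
            continue

        res_idx = topo.residue_by_author_number(int(row["residue"]))
        if record == "donor":
            heavy_name, _, h_part = spec.partition(":")
            if not h_part:
                raise AnnotationError(f"donor spec {spec!r} must be 'HEAVY:H1,H2,...'")
            heavy = topo.atom_index(res_idx, heavy_name.strip())
            hydrogens = tuple(
                topo.atom_index(res_idx, h.strip()) for h in h_part.split(",")
            )
            topo.donor_groups.append(
                DonorGroup(res_idx, heavy, hydrogens, kind=kind)
            )
        elif record == "acceptor":
            oxygens: list[int] = []
            antecedents: dict[int, int] = {}
            for pair in spec.split(","):
                o_name, _, c_name = pair.partition("@")
                if not c_name:
                    raise AnnotationError(
                        f"acceptor spec {spec!r} must be 'O1@C1,O2@C2,...'"
                    )
                o = topo.atom_index(res_idx, o_name.strip())
                oxygens.append(o)
                antecedents[o] = topo.atom_index(res_idx, c_name.strip())
            topo.acceptor_groups.append(
                AcceptorGroup(res_idx, tuple(oxygens), antecedents, kind=kind)
            )
        elif record == "core":
            sel = tuple(topo.atom_index(res_idx, n.strip()) for n in spec.split(","))
            for i in sel:
                if topo.atoms[i].element.upper() == "H":
                    raise AnnotationError(
                        f"hydrophobic-core selection contains hydrogen "
                        f"{topo.atoms[i].name!r} in residue {row['residue']}"
                    )
            topo.hydrophobic_core[res_idx] = sel
        else:
            raise AnnotationError(f"unknown annotation record {record!r}")
    _check_group_partition(topo)
    return topo


def replace_topology(topology: Topology) -> Topology:
    """Shallow-rebuild a topology so annotation never mutates the input."""
    return Topology(
        atoms=list(topology.atoms),
        residues=[replace(r) for r in topology.residues],
        donor_groups=list(topology.donor_groups),
        acceptor_groups=list(topology.acceptor_groups),
        hydrophobic_core=dict(topology.hydrophobic_core),
    )


def _check_group_partition(topo: Topology) -> None:
    seen_h: set[int] = set()
    for g in topo.donor_groups:
        for h in g.hydrogens:
            if h in seen_h:
                raise AnnotationError(
                    f"hydrogen {topo.atoms[h].name!r} appears in two donor groups"
                )
            seen_h.add(h)
    seen_o: set[int] = set()
    for g in topo.acceptor_groups:
        for o in g.oxygens:
            if o in seen_o:
                raise AnnotationError(
                    f"oxygen {topo.atoms[o].name!r} appears in two acceptor groups"
                )
            seen_o.add(o)


# ---------------------------------------------------------------------------
# Analysis window and tables
# ---------------------------------------------------------------------------

def select_analysis_window(trajectory: Trajectory, discard_time: float) -> Trajectory:
    """Drop the equilibration prefix: frames saved at time <= discard_time (ps).

    A 1.2 us trajectory saved every 100 ps reduces to exactly 10,000 frames
    when the first 0.2 us is discarded.
    """
    if discard_time < 0:
        raise ValueError("discard_time must be non-negative")
    if discard_time >= trajectory.span:
        raise ValueError(
            f"discard_time {discard_time} ps >= trajectory span "
            f"{trajectory.span} ps: empty analysis window"
        )
    keep = trajectory.times > discard_time
    return Trajectory(
        topology=trajectory.topology,
        coords=trajectory.coords[keep],
        frame_interval=trajectory.frame_interval,
        condition=trajectory.condition,
    )


def read_reference_table(path: str | Path) -> dict[str, float]:
    """Read a two-column delimited table of (label, value) experimental data."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     header=None, names=["label", "value"], skipinitialspace=True)
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        out[str(row["label"]).strip()] = float(row["value"])
    if not out:
        raise ValueError(f"{path}: empty reference table")
    return out


def save_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Persist frames + metadata as a compressed array container (.npz)."""
    cond = trajectory.condition
    np.savez_compressed(
        path,
        coords=trajectory.coords,
        frame_interval=np.array([trajectory.frame_interval]),
        condition=np.array(
            [cond.temperature if cond else np.nan, cond.pressure if cond else np.nan]
        ),
    )


def load_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    with np.load(path) as data:
        coords = data["coords"]
        interval = float(data["frame_interval"][0])
        t, p = data["condition"]
    cond = None if np.isnan(t) else ConditionLabel(float(t), float(p))
    return Trajectory(topology, coords, interval, cond)
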