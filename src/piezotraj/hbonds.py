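"""Per-frame H-bond detection, equivalence merging, occupancy, lifetimes,
water bridges and hydrophobic contacts.

Detection criterion: r_HO <= 2.4 Å and H...O=C angle >= 100 degrees.  For a
residue with symmetry-equivalent donor hydrogens or acceptor oxygens
(Lys NH3+, Arg guanidinium, Asn/Gln amide, Asp/Glu carboxylate, chain
termini), contacts through any equivalent member count as the *same*
interaction: the merged per-frame indicator is the logical OR over all
member pairs, and occupancy/lifetimes are computed on the merged series
("effective occupancy").

Hydrophobic contacts use only the distance between side-chain mass centers
(cutoff 3.5 Å, no direction criterion).  A water-bridged H-bond requires a
single water simultaneously H-bonded to both residues of a pair; a
water-bridged hydrophobic contact requires a water oxygen within the
mass-center cutoff of both side-chain centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model_io import (
    AcceptorGroup,
    DonorGroup,
    Topology,
    Trajectory,
)
from .jcoupling import HBondGeometrySeries

__all__ = [
    "R_CUT_ANGSTROM",
    "THETA_MIN_DEGREES",
    "CONTACT_CUT_ANGSTROM",
    "DIRECT_LIFETIME_BINS_NS",
    "WATER_LIFETIME_BINS_NS",
    "HBondCandidate",
    "BondedSeries",
    "Event",
    "OccupancyRecord",
    "hbond_geometry",
    "frame_hbond",
    "enumerate_candidates",
    "merged_series",
    "geometry_series",
    "extract_events",
    "lifetime_histogram",
    "water_bridge_series",
    "hydrophobic_contact_series",
    "water_bridged_contact_series",
]

R_CUT_ANGSTROM = 2.4
THETA_MIN_DEGREES = 100.0
CONTACT_CUT_ANGSTROM = 3.5

#: lifetime bins (ns) for direct H-bonds: short, long, constant
DIRECT_LIFETIME_BINS_NS = ((0.0, 6.0), (6.0, 100.0), (100.0, np.inf))
#: water-bridged events are mostly transient; the short bin is < 4 ns
WATER_LIFETIME_BINS_NS = ((0.0, 4.0), (4.0, 100.0), (100.0, np.inf))

_BASIC = {"LYS", "ARG", "HIS", "HSP"}
_ACIDIC = {"ASP", "GLU"}


@dataclass(frozen=True)
class HBondCandidate:
    donor: DonorGroup
    acceptor: AcceptorGroup
    label: str                 # "DonorRes-AcceptorRes" in author numbering
    category: str              # backbone-backbone | backbone-sidechain |
                               # sidechain-sidechain | salt-bridge


@dataclass
class BondedSeries:
    """Boolean per-frame indicator (after degeneracy merging)."""

    indicator: np.ndarray
    frame_interval: float      # ps
    label: str = ""

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.ndim != 1:
            raise ValueError("indicator must be one-dimensional")

    def __len__(self) -> int:
        return self.indicator.size

    @property
    def occupancy(self) -> float:
        return float(self.indicator.mean()) if len(self) else 0.0


@dataclass(frozen=True)
class Event:
    start_frame: int
    end_frame: int             # inclusive
    lifetime: float            # ns; (end - start + 1) * interval


@dataclass
class OccupancyRecord:
    label: str
    effective_occupancy: float
    n_events: int
    lifetime_bin_counts: tuple[int, ...]
    bins_ns: tuple[tuple[float, float], ...] = DIRECT_LIFETIME_BINS_NS


# ---------------------------------------------------------------------------
# Geometry and per-frame criterion
# ---------------------------------------------------------------------------

def hbond_geometry(
    donor_h: np.ndarray, acceptor_o: np.ndarray, antecedent_c: np.ndarray
) -> tuple[float, float]:
    """(r_HO in Å, H...O=C angle in degrees) for one frame.

    The angle is measured at the oxygen vertex, between the O->H and O->C
    directions.
    """
    h = np.asarray(donor_h, float)
    o = np.asarray(acceptor_o, float)
    c = np.asarray(antecedent_c, float)
    u = h - o
    w = c - o
    r = float(np.linalg.norm(u))
    if r == 0:
        raise ValueError("degenerate geometry: hydrogen coincident with oxygen")
    wn = float(np.linalg.norm(w))
    if wn == 0:
        raise ValueError("degenerate geometry: antecedent carbon coincident with oxygen")
    cos_t = float(np.clip(u @ w / (r * wn), -1.0, 1.0))
    return r, float(np.degrees(np.arccos(cos_t)))


def frame_hbond(
    donor_h: np.ndarray,
    acceptor_o: np.ndarray,
    antecedent_c: np.ndarray,
    r_cut: float = R_CUT_ANGSTROM,
    theta_min: float = THETA_MIN_DEGREES,
) -> tuple[bool, float, float]:
    """Apply the distance + angle criterion to one H/O/C triple.

    Returns (bonded, r_HO, theta); geometry is returned whether or not the
    criterion is met.
    """
    r, theta = hbond_geometry(donor_h, acceptor_o, antecedent_c)
    return (r <= r_cut and theta >= theta_min), r, theta


# ---------------------------------------------------------------------------
# Candidate enumeration and merged detection
# ---------------------------------------------------------------------------

def _category(topo: Topology, donor: DonorGroup, acceptor: AcceptorGroup) -> str:
    d_res = topo.residues[donor.residue_index].name.upper()
    a_res = topo.residues[acceptor.residue_index].name.upper()
    basic = donor.kind == "terminal" or (
        donor.kind == "sidechain" and d_res in _BASIC
    )
    acidic = acceptor.kind == "terminal" or (
        acceptor.kind == "sidechain" and a_res in _ACIDIC
    )
    if basic and acidic:
        return "salt-bridge"
    if donor.kind == "backbone" and acceptor.kind == "backbone":
        return "backbone-backbone"
    if donor.kind == "backbone" or acceptor.kind == "backbone":
        return "backbone-sidechain"
    return "sidechain-sidechain"


def candidate_label(topo: Topology, donor: DonorGroup, acceptor: AcceptorGroup) -> str:
    return f"{topo.residue_label(donor.residue_index)}-" \
           f"{topo.residue_label(acceptor.residue_index)}"


def enumerate_candidates(
    topology: Topology, min_seq_separation: int = 1
) -> list[HBondCandidate]:
    """All donor-group x acceptor-group pairs with residues separated by at
    least ``min_seq_separation`` in author numbering (intra-residue excluded).
    """
    out: list[HBondCandidate] = []
    for d in topology.donor_groups:
        for a in topology.acceptor_groups:
            sep = abs(
                topology.residues[d.residue_index].author_number
                - topology.residues[a.residue_index].author_number
            )
            if sep < max(min_seq_separation, 1):
                continue
            out.append(
                HBondCandidate(
                    donor=d,
                    acceptor=a,
                    label=candidate_label(topology, d, a),
                    category=_category(topology, d, a),
                )
            )
    return out


def _pair_geometry(
    coords: np.ndarray,
    hydrogens: Sequence[int],
    oxygens: Sequence[int],
    antecedents: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised r/theta over frames x hydrogens x oxygens.

    Returns arrays of shape (n_frames, n_h, n_o).
    """
    h = coords[:, list(hydrogens), None, :]            # (F, H, 1, 3)
    o = coords[:, None, list(oxygens), :]              # (F, 1, O, 3)
    c = coords[:, None, list(antecedents), :]          # (F, 1, O, 3)
    u = h - o
    w = c - o
    r = np.linalg.norm(u, axis=-1)
    wn = np.linalg.norm(w, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.einsum("fhox,fhox->fho", u, w) / (r * wn)
    theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    return r, theta


def _member_indicators(
    trajectory: Trajectory,
    candidate: HBondCandidate,
    r_cut: float,
    theta_min: float,
) -> np.ndarray:
    """(n_frames, n_h, n_o) boolean array of the criterion per member pair."""
    acc = candidate.acceptor
    ants = [acc.antecedent_carbons[o] for o in acc.oxygens]
    r, theta = _pair_geometry(
        trajectory.coords, candidate.donor.hydrogens, acc.oxygens, ants
    )
    return (r <= r_cut) & (theta >= theta_min)


def merged_series(
    trajectory: Trajectory,
    candidate: HBondCandidate,
    r_cut: float = R_CUT_ANGSTROM,
    theta_min: float = THETA_MIN_DEGREES,
) -> BondedSeries:
    """Degeneracy-merged indicator: OR of the criterion over all equivalent
    (hydrogen, oxygen) member pairs per frame."""
    bonded = _member_indicators(trajectory, candidate, r_cut, theta_min)
    return BondedSeries(
        indicator=bonded.any(axis=(1, 2)),
        frame_interval=trajectory.frame_interval,
        label=candidate.label,
    )


def member_occupancies(
    trajectory: Trajectory,
    candidate: HBondCandidate,
    r_cut: float = R_CUT_ANGSTROM,
    theta_min: float = THETA_MIN_DEGREES,
) -> np.ndarray:
    """Per-(hydrogen, oxygen) occupancies before merging, shape (n_h, n_o)."""
    bonded = _member_indicators(trajectory, candidate, r_cut, theta_min)
    return bonded.mean(axis=0)


def geometry_series(
    trajectory: Trajectory, candidate: HBondCandidate
) -> HBondGeometrySeries:
    """Per-frame (r_HO, theta) for coupling back-calculation.

    For groups with equivalent members the (hydrogen, oxygen) pair with the
    minimum r_HO is taken each frame, consistent with degeneracy merging.
    """
    acc = candidate.acceptor
    ants = [acc.antecedent_carbons[o] for o in acc.oxygens]
    r, theta = _pair_geometry(
        trajectory.coords, candidate.donor.hydrogens, acc.oxygens, ants
    )
    flat_r = r.reshape(r.shape[0], -1)
    flat_t = theta.reshape(theta.shape[0], -1)
    best = np.argmin(flat_r, axis=1)
    rows = np.arange(flat_r.shape[0])
    return HBondGeometrySeries(
        r_ho=flat_r[rows, best],
        theta=flat_t[rows, best],
        frame_interval=trajectory.frame_interval,
        bond_label=candidate.label,
    )


# ---------------------------------------------------------------------------
# Events, occupancy, lifetimes
# ---------------------------------------------------------------------------

def extract_events(
    series: BondedSeries,
    gap_tolerance: int = 0,
    bins_ns: tuple[tuple[float, float], ...] = DIRECT_LIFETIME_BINS_NS,
) -> tuple[list[Event], OccupancyRecord]:
    """Maximal runs of bonded frames as dwell events, plus the occupancy record.

    Lifetime of a run of ``n`` frames is ``n * frame_interval`` (each bonded
    frame contributes one saving interval).  With the default
    ``gap_tolerance = 0`` a single unbonded frame terminates an event; a
    positive tolerance bridges gaps up to that many frames (the bridged
    frames do not count toward occupancy).
    """
    ind = series.indicator
    if ind.size == 0:
        raise ValueError("empty indicator series")
    padded = np.concatenate(([False], ind, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1

    runs: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if runs and s - runs[-1][1] - 1 <= gap_tolerance:
            runs[-1] = (runs[-1][0], e)
        else:
            runs.append((s, e))

    interval_ns = series.frame_interval / 1000.0
    events = [
        Event(s, e, lifetime=float((e - s + 1) * interval_ns)) for s, e in runs
    ]
    occupancy = float(ind.mean())
    counts = lifetime_histogram(events, bins_ns)
    record = OccupancyRecord(
        label=series.label,
        effective_occupancy=occupancy,
        n_events=len(events),
        lifetime_bin_counts=counts,
        bins_ns=bins_ns,
    )
    return events, record


def lifetime_histogram(
    events: Sequence[Event],
    bins_ns: tuple[tuple[float, float], ...] = DIRECT_LIFETIME_BINS_NS,
) -> tuple[int, ...]:
    """Event counts per lifetime bin; bins are half-open (lo, hi] in ns."""
    for (lo1, hi1), (lo2, _) in zip(bins_ns, bins_ns[1:]):
        if hi1 > lo2:
            raise ValueError("lifetime bins overlap")
    counts = [0] * len(bins_ns)
    for ev in events:
        for i, (lo, hi) in enumerate(bins_ns):
            if lo < ev.lifetime <= hi:
                counts[i] += 1
                break
    return tuple(counts)


# ---------------------------------------------------------------------------
# Water bridges
# ---------------------------------------------------------------------------

def _water_atoms(topo: Topology, water_index: int) -> tuple[int, list[int]]:
    oxygen = None
    hydrogens: list[int] = []
    for a in topo.atoms_of_residue(water_index):
        if a.element.upper() == "O":
            oxygen = a.index
        elif a.element.upper() == "H":
            hydrogens.append(a.index)
    if oxygen is None or not hydrogens:
        raise ValueError(
            f"water residue {topo.residues[water_index].author_number} lacks O or H"
        )
    return oxygen, hydrogens


def _water_link_indicator(
    trajectory: Trajectory,
    residue_index: int,
    water_index: int,
    r_cut: float,
    theta_min: float,
) -> np.ndarray:
    """Per-frame: water H-bonded to the residue through either leg direction.

    Residue-donor leg: residue H -> water O, angle at the water oxygen with
    each water hydrogen serving as the antecedent (any orientation of the
    water counts).  Water-donor leg: water H -> residue acceptor O with the
    residue's own O=C antecedent.  Equivalent residue hydrogens/oxygens are
    merged by OR, as for direct bonds.
    """
    topo = trajectory.topology
    w_o, w_hs = _water_atoms(topo, water_index)
    n_frames = trajectory.n_frames
    linked = np.zeros(n_frames, dtype=bool)

    for donor in topo.donor_groups:
        if donor.residue_index != residue_index:
            continue
        # water O as acceptor; each water H tried as the angle antecedent
        for ant in w_hs:
            r, theta = _pair_geometry(
                trajectory.coords, donor.hydrogens, [w_o], [ant]
            )
            linked |= ((r <= r_cut) & (theta >= theta_min)).any(axis=(1, 2))

    for acc in topo.acceptor_groups:
        if acc.residue_index != residue_index:
            continue
        ants = [acc.antecedent_carbons[o] for o in acc.oxygens]
        r, theta = _pair_geometry(trajectory.coords, w_hs, acc.oxygens, ants)
        linked |= ((r <= r_cut) & (theta >= theta_min)).any(axis=(1, 2))

    return linked


def water_bridge_series(
    trajectory: Trajectory,
    residue_pair: tuple[int, int],
    r_cut: float = R_CUT_ANGSTROM,
    theta_min: float = THETA_MIN_DEGREES,
) -> BondedSeries:
    """Per-frame indicator that *some* water bridges the two residues.

    A frame counts when a single water satisfies the H-bond criterion with
    both residues simultaneously; the bridging water's identity may change
    between frames without breaking an event (occupancy is defined per
    residue pair, not per water).
    """
    topo = trajectory.topology
    waters = topo.water_residues()
    if not waters:
        raise ValueError("topology contains no water residues")
    res_a, res_b = residue_pair
    bridged = np.zeros(trajectory.n_frames, dtype=bool)
    for w in waters:
        link_a = _water_link_indicator(trajectory, res_a, w, r_cut, theta_min)
        if not link_a.any():
            continue
        link_b = _water_link_indicator(trajectory, res_b, w, r_cut, theta_min)
        bridged |= link_a & link_b
    label = f"{topo.residue_label(res_a)}-{topo.residue_label(res_b)}(w)"
    return BondedSeries(bridged, trajectory.frame_interval, label=label)


# ---------------------------------------------------------------------------
# Hydrophobic contacts
# ---------------------------------------------------------------------------

def _mass_center_series(trajectory: Trajectory, atom_indices: Sequence[int]) -> np.ndarray:
    if not atom_indices:
        raise ValueError("empty side-chain selection")
    masses = trajectory.topology.masses()[list(atom_indices)]
    pos = trajectory.coords[:, list(atom_indices), :]
    return (pos * masses[None, :, None]).sum(axis=1) / masses.sum()


def hydrophobic_contact_series(
    trajectory: Trajectory,
    sidechain_pair: tuple[int, int],
    cutoff: float = CONTACT_CUT_ANGSTROM,
) -> tuple[BondedSeries, np.ndarray]:
    """Mass-center contact between two hydrophobic side chains.

    Contact in a frame iff the distance between the side-chain mass centers
    is <= ``cutoff`` (3.5 Å); no direction criterion.  Returns the indicator
    series and the per-frame distance series (Å).
    """
    topo = trajectory.topology
    res_a, res_b = sidechain_pair
    try:
        sel_a = topo.hydrophobic_core[res_a]
        sel_b = topo.hydrophobic_core[res_b]
    except KeyError as exc:
        raise ValueError(f"residue {exc} has no hydrophobic-core selection")
    ca = _mass_center_series(trajectory, sel_a)
    cb = _mass_center_series(trajectory, sel_b)
    dist = np.linalg.norm(ca - cb, axis=1)
    label = f"{topo.residue_label(res_a)}-{topo.residue_label(res_b)}"
    return (
        BondedSeries(dist <= cutoff, trajectory.frame_interval, label=label),
        dist,
    )


def water_bridged_contact_series(
    trajectory: Trajectory,
    sidechain_pair: tuple[int, int],
    cutoff: float = CONTACT_CUT_ANGSTROM,
) -> BondedSeries:
    """Frame counts when a water oxygen is within ``cutoff`` of both
    side-chain mass centers (any water)."""
    topo = trajectory.topology
    waters = topo.water_residues()
    if not waters:
        raise ValueError("topology contains no water residues")
    res_a, res_b = sidechain_pair
    ca = _mass_center_series(trajectory, topo.hydrophobic_core[res_a])
    cb = _mass_center_series(trajectory, topo.hydrophobic_core[res_b])
    bridged = np.zeros(trajectory.n_frames, dtype=bool)
    for w in waters:
        w_o, _ = _water_atoms(topo, w)
        pos = trajectory.coords[:, w_o, :]
        near_a = np.linalg.norm(pos - ca, axis=1) <= cutoff
        near_b = np.linalg.norm(pos - cb, axis=1) <= cutoff
        bridged |= near_a & near_b
    label = f"{topo.residue_label(res_a)}-{topo.residue_label(res_b)}(w)"
    return BondedSeries(bridged, trajectory.frame_interval, label=label)
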