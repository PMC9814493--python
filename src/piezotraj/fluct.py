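"""Rigid-body superposition (Kabsch), RMSD time series, per-residue RMSF with
secondary-structure domain averages, and hydrophobic-core pair distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model_io import Topology, Trajectory
from .jcoupling import block_means

__all__ = [
    "SelectionSpec",
    "FluctuationTable",
    "superpose",
    "rmsd_timeseries",
    "rmsf_per_residue",
    "core_pair_distances",
]

BACKBONE_HEAVY = frozenset({"N", "CA", "C", "O", "OT1", "OT2", "OXT"})
ATOM_CLASSES = ("all-heavy", "backbone-heavy", "sidechain-heavy")


@dataclass(frozen=True)
class SelectionSpec:
    """Residue range (author numbering, inclusive) plus an atom class."""

    first_residue: int
    last_residue: int
    atom_class: str = "all-heavy"

    def __post_init__(self) -> None:
        if self.atom_class not in ATOM_CLASSES:
            raise ValueError(f"atom_class must be one of {ATOM_CLASSES}")

    def resolve(self, topology: Topology) -> np.ndarray:
        """0-based atom indices covered by this selection (solvent excluded)."""
        idx = []
        for a in topology.atoms:
            res = topology.residues[a.residue_index]
            if res.is_solvent:
                continue
            if not (self.first_residue <= res.author_number <= self.last_residue):
                continue
            if a.element.upper() == "H":
                continue
            is_backbone = a.name in BACKBONE_HEAVY
            if self.atom_class == "backbone-heavy" and not is_backbone:
                continue
            if self.atom_class == "sidechain-heavy" and is_backbone:
                continue
            idx.append(a.index)
        if not idx:
            raise ValueError("selection resolves to no atoms")
        return np.array(idx, dtype=int)


@dataclass
class FluctuationTable:
    """Per-residue RMSF (Å) and secondary-structure domain averages."""

    per_residue: pd.DataFrame      # residue, author_number, ss, rmsf
    domain_averages: pd.DataFrame  # ss -> mean rmsf
    atom_class: str


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation 3x3 with det +1, translation, rmsd in Å): after
    ``x @ R.T + t`` the mobile set optimally overlays the reference.
    """
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    mob_c = (w[:, None] * mob).sum(0) / wsum
    ref_c = (w[:, None] * ref).sum(0) / wsum
    mob0 = mob - mob_c
    ref0 = ref - ref_c
    if np.linalg.matrix_rank(mob0, tol=1e-9) < 2:
        raise ValueError("collinear or degenerate atom set")
    rot, _ = Rotation.align_vectors(ref0, mob0, weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    # recompute the residual directly: the rssd reported by align_vectors
    # loses ~1e-8 absolute precision to cancellation near zero
    resid = ref0 - mob0 @ R.T
    rmsd = float(np.sqrt((w * np.sum(resid**2, axis=1)).sum() / wsum))
    return R, t, rmsd


def rmsd_timeseries(
    trajectory: Trajectory,
    reference: np.ndarray,
    selection: SelectionSpec,
    n_blocks: int = 10,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-frame RMSD (Å) of the selection vs a reference frame, after
    per-frame superposition; returns (series, mean, block SD).

    The block SD (standard deviation of contiguous block means) is the error
    bar convention for trajectory-average RMSD.
    """
    idx = selection.resolve(trajectory.topology)
    ref = np.asarray(reference, float)[idx]
    series = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        _, _, series[f] = superpose(trajectory.coords[f, idx], ref, weights)
    blocks = block_means(series, min(n_blocks, trajectory.n_frames))
    block_sd = float(np.std(blocks, ddof=1)) if blocks.size > 1 else 0.0
    return series, float(series.mean()), block_sd


def _fit_frames(coords: np.ndarray, ref: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``ref`` using the ``idx`` atoms for the fit;
    the transform is applied to all atoms."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R, t, _ = superpose(coords[f, idx], ref[idx])
        out[f] = coords[f] @ R.T + t
    return out


def rmsf_per_residue(
    trajectory: Trajectory,
    atom_class: str = "all-heavy",
    exclude_from_domains: Sequence[int] = (),
    reference: np.ndarray | None = None,
) -> FluctuationTable:
    """Per-residue RMSF about the mean structure after superposition.

    Frames are first fitted to the reference (default: frame 0), the mean
    structure is computed, and frames are refitted to that mean (one pass).
    RMSF of a residue is the RMS displacement over frames and its selected
    atoms from their mean positions.  Domain averages group residues by
    secondary structure, excluding ``exclude_from_domains`` (author numbers,
    e.g. a dangling C-terminal tail).
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    topo = trajectory.topology
    numbers = [r.author_number for r in topo.residues if not r.is_solvent]
    sel = SelectionSpec(min(numbers), max(numbers), atom_class)
    try:
        idx = sel.resolve(topo)
    except ValueError:
        raise ValueError(f"no atoms in class {atom_class!r}")

    ref = trajectory.coords[0] if reference is None else np.asarray(reference, float)
    fitted = _fit_frames(trajectory.coords, ref, idx)
    mean_structure = fitted.mean(axis=0)
    fitted = _fit_frames(fitted, mean_structure, idx)
    mean_structure = fitted.mean(axis=0)
    sq_disp = ((fitted - mean_structure) ** 2).sum(axis=2)   # (F, N)

    rows = []
    idx_set = set(idx.tolist())
    for res_i, res in enumerate(topo.residues):
        if res.is_solvent:
            continue
        atom_ids = [a.index for a in topo.atoms_of_residue(res_i) if a.index in idx_set]
        if not atom_ids:
            continue   # residue absent in this atom class, not zero
        rmsf = float(np.sqrt(sq_disp[:, atom_ids].mean()))
        rows.append(
            {
                "residue": topo.residue_label(res_i),
                "author_number": res.author_number,
                "ss": res.secondary_structure,
                "rmsf": rmsf,
            }
        )
    per_residue = pd.DataFrame(rows)
    excluded = set(exclude_from_domains)
    dom = (
        per_residue[~per_residue["author_number"].isin(excluded)]
        .groupby("ss")["rmsf"]
        .mean()
        .rename("mean_rmsf")
        .reset_index()
    )
    return FluctuationTable(per_residue, dom, atom_class)


def core_pair_distances(
    trajectory: Trajectory,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-frame mass-center distances (Å) for hydrophobic-core residue pairs.

    Columns are labelled "ResA-ResB"; by default all unordered pairs of the
    topology's hydrophobic core are measured.
    """
    from .hbonds import _mass_center_series   # shared mass-center helper

    topo = trajectory.topology
    core = sorted(topo.hydrophobic_core)
    if pairs is None:
        if len(core) < 2:
            raise ValueError("hydrophobic core needs at least 2 residues")
        pairs = [(a, b) for i, a in enumerate(core) for b in core[i + 1 :]]
    centers = {r: _mass_center_series(trajectory, topo.hydrophobic_core[r]) for r in core}
    data = {}
    for a, b in pairs:
        label = f"{topo.residue_label(a)}-{topo.residue_label(b)}"
        data[label] = np.linalg.norm(centers[a] - centers[b], axis=1)
    return pd.DataFrame(data)
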