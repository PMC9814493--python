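"""Methyl-axis order parameters from trajectory unit-vector series.

S^2 for a side-chain methyl C-C axis is computed from the frame-averaged
orientation tensor Phi_ij = r_i r_j / r^2:

    S^2 = (3/2) tr(<Phi>^2) - (1/2) (tr <Phi>)^2

S^2 = 1 for a rigid axis and 0 for isotropic reorientation.  For diffusion
restricted to a cone of semiangle beta the closed form is
S^2 = [cos(beta) (1 + cos(beta)) / 2]^2, which the synthetic cone generator
uses as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .jcoupling import _block_se
from .model_io import Trajectory

__all__ = [
    "AxisVectorSeries",
    "OrderParameterResult",
    "frame_projector",
    "order_parameter",
    "methyl_axes",
    "cone_order_parameter",
]


@dataclass
class AxisVectorSeries:
    """Per-frame unit vectors along one methyl C-C axis."""

    vectors: np.ndarray           # (n_frames, 3)
    axis_label: str               # e.g. "I3g2" (residue + methyl carbon)
    frame_interval: float         # ps

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must have shape (n_frames, 3)")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero vector in axis series")
        if np.any(np.abs(norms - 1.0) > 1e-6):
            warnings.warn("non-unit axis vectors normalised", stacklevel=2)
            self.vectors = self.vectors / norms[:, None]

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class OrderParameterResult:
    S2: float
    block_values: np.ndarray
    block_se: float
    n_frames: int
    axis_label: str = ""


def frame_projector(v: np.ndarray) -> np.ndarray:
    """Orientation tensor Phi_ij = v_i v_j / |v|^2 of a single vector.

    Symmetric, unit trace and idempotent for any non-zero v.
    """
    v = np.asarray(v, dtype=float)
    n2 = float(v @ v)
    if n2 == 0:
        raise ValueError("zero vector has no orientation")
    return np.outer(v, v) / n2


def _s2_from_mean_tensor(phi_mean: np.ndarray) -> float:
    return float(1.5 * np.trace(phi_mean @ phi_mean) - 0.5 * np.trace(phi_mean) ** 2)


def order_parameter(series: AxisVectorSeries, n_blocks: int = 10) -> OrderParameterResult:
    """Order parameter of an axis-vector series with block standard error.

    <Phi> is the average orientation tensor over all frames; block values
    recompute S^2 on contiguous equal blocks.
    """
    v = series.vectors
    if len(series) < 2:
        raise ValueError("order parameter needs at least 2 frames")
    # per-frame outer products, averaged: <Phi>_ij = mean_f v_i v_j
    phi = np.einsum("fi,fj->fij", v, v)
    s2 = _s2_from_mean_tensor(phi.mean(axis=0))

    n_blocks = min(n_blocks, len(series))
    block_len = len(series) // n_blocks
    blocks = np.array(
        [
            _s2_from_mean_tensor(phi[b * block_len : (b + 1) * block_len].mean(axis=0))
            for b in range(n_blocks)
        ]
    )
    return OrderParameterResult(
        S2=s2,
        block_values=blocks,
        block_se=_block_se(blocks),
        n_frames=len(series),
        axis_label=series.axis_label,
    )


def cone_order_parameter(beta_degrees: float) -> float:
    """Closed-form S^2 for uniform diffusion in a cone of semiangle beta."""
    c = np.cos(np.deg2rad(beta_degrees))
    return float((c * (1 + c) / 2) ** 2)


_GREEK = {"G": "g", "G1": "g1", "G2": "g2", "D": "d", "D1": "d1", "D2": "d2",
          "E": "e", "B": "b", "Z": "z"}


def _axis_label(residue_label: str, methyl_name: str) -> str:
    # "CG2" -> "g2" suffix in the NMR axis-naming convention
    suffix = methyl_name[1:] if methyl_name.startswith("C") else methyl_name
    return residue_label + _GREEK.get(suffix, suffix.lower())


def methyl_axes(
    trajectory: Trajectory,
    methyl_table: str | Path | pd.DataFrame,
) -> list[AxisVectorSeries]:
    """Per-frame unit vectors from attached carbon to methyl carbon.

    ``methyl_table`` is delimited text (or a DataFrame) with columns
    ``residue`` (author number), ``methyl`` and ``attached`` (atom names).
    """
    if isinstance(methyl_table, (str, Path)):
        methyl_table = pd.read_csv(methyl_table, sep="\t", comment="#", dtype=str)
    topo = trajectory.topology
    out: list[AxisVectorSeries] = []
    for _, row in methyl_table.iterrows():
        res_idx = topo.residue_by_author_number(int(row["residue"]))
        i_methyl = topo.atom_index(res_idx, str(row["methyl"]).strip())
        i_attached = topo.atom_index(res_idx, str(row["attached"]).strip())
        vec = trajectory.coords[:, i_methyl] - trajectory.coords[:, i_attached]
        norms = np.linalg.norm(vec, axis=1)
        if np.any(norms == 0):
            raise ValueError(
                f"coincident methyl/attached carbons in residue {row['residue']}"
            )
        out.append(
            AxisVectorSeries(
                vectors=vec / norms[:, None],
                axis_label=_axis_label(
                    topo.residue_label(res_idx), str(row["methyl"]).strip()
                ),
                frame_interval=trajectory.frame_interval,
            )
        )
    return out
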