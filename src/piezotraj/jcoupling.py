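"""Through-H-bond scalar couplings and agreement metrics against NMR data.

The coupling across a backbone N-H...O=C hydrogen bond is modelled as

    h3J_NC' = < (-357 Hz) * exp(-3.2 * r_HO) * cos^2(theta) >

with r_HO the hydrogen-to-acceptor-oxygen distance in Å and theta the
H...O=C angle measured at the oxygen.  The ensemble average runs over
trajectory frames; standard errors come from contiguous block averaging
(ten blocks by default, the 100-ns-block convention for a 1-us window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COUPLING_PREFACTOR_HZ",
    "COUPLING_DECAY_PER_ANGSTROM",
    "HBondGeometrySeries",
    "CouplingResult",
    "ValidationMetrics",
    "frame_coupling",
    "ensemble_coupling",
    "block_means",
    "delta_couplings",
    "validation_metrics",
]

COUPLING_PREFACTOR_HZ = -357.0
COUPLING_DECAY_PER_ANGSTROM = 3.2

#: flag threshold for systematic calc-vs-experiment discrepancy, Hz
DELTA_FLAG_THRESHOLD_HZ = 0.1


@dataclass
class HBondGeometrySeries:
    """Per-frame H-bond geometry: r_HO (Å) and the H...O=C angle (degrees)."""

    r_ho: np.ndarray
    theta: np.ndarray
    frame_interval: float          # ps
    bond_label: str = ""

    def __post_init__(self) -> None:
        self.r_ho = np.asarray(self.r_ho, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.r_ho.shape != self.theta.shape:
            raise ValueError("r_ho and theta must have the same length")
        if np.any(self.r_ho <= 0):
            raise ValueError("r_ho must be positive")
        if np.any((self.theta < 0) | (self.theta > 180)):
            raise ValueError("theta must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return self.r_ho.size


@dataclass
class CouplingResult:
    J_mean: float                  # Hz
    block_means: np.ndarray        # Hz, one per contiguous block
    block_se: float                # Hz
    n_frames: int
    bond_label: str = ""


@dataclass
class ValidationMetrics:
    """Agreement between calculated and experimental couplings.

    ``q_factor`` is the RMS deviation normalised by the RMS of the
    experimental values, the standard NMR Q factor.
    """

    pearson_r: float
    rmsd: float                    # Hz
    q_factor: float
    n_bonds: int
    block_pearson: np.ndarray = field(default_factory=lambda: np.array([]))
    block_rmsd: np.ndarray = field(default_factory=lambda: np.array([]))
    block_q: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def pearson_se(self) -> float:
        return _block_se(self.block_pearson)

    @property
    def rmsd_se(self) -> float:
        return _block_se(self.block_rmsd)

    @property
    def q_se(self) -> float:
        return _block_se(self.block_q)


def _block_se(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def frame_coupling(
    r_ho: float | np.ndarray,
    theta: float | np.ndarray,
    prefactor: float = COUPLING_PREFACTOR_HZ,
    decay: float = COUPLING_DECAY_PER_ANGSTROM,
) -> float | np.ndarray:
    """Single-frame coupling (Hz) from r_HO (Å) and the H...O=C angle (deg).

    Vectorised: array inputs broadcast.  Negative distances are rejected.
    """
    r = np.asarray(r_ho, dtype=float)
    if np.any(r < 0):
        raise ValueError("r_ho must be non-negative")
    th = np.deg2rad(np.asarray(theta, dtype=float))
    out = prefactor * np.exp(-decay * r) * np.cos(th) ** 2
    if np.isscalar(r_ho) and np.isscalar(theta):
        return float(out)
    return out


def block_means(values: Sequence[float], n_blocks: int) -> np.ndarray:
    """Means of ``n_blocks`` contiguous equal blocks; remainder frames dropped."""
    values = np.asarray(values, dtype=float)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if values.size < n_blocks:
        raise ValueError(
            f"{values.size} frames cannot be partitioned into {n_blocks} blocks"
        )
    block_len = values.size // n_blocks
    trimmed = values[: block_len * n_blocks]
    return trimmed.reshape(n_blocks, block_len).mean(axis=1)


def ensemble_coupling(
    series: HBondGeometrySeries, n_blocks: int = 10
) -> CouplingResult:
    """Trajectory-averaged coupling with a block-averaged standard error.

    The grand mean uses every frame; block statistics drop the remainder
    after partitioning into ``n_blocks`` contiguous equal blocks.
    """
    j = frame_coupling(series.r_ho, series.theta)
    blocks = block_means(j, n_blocks)
    return CouplingResult(
        J_mean=float(np.mean(j)),
        block_means=blocks,
        block_se=_block_se(blocks),
        n_frames=len(series),
        bond_label=series.bond_label,
    )


def delta_couplings(
    calc: Mapping[str, float],
    exp: Mapping[str, float],
    flag_threshold: float = DELTA_FLAG_THRESHOLD_HZ,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-bond discrepancy dJ = J_calc - J_exp over the shared bond labels.

    Returns a table (label, J_calc, J_exp, delta, flagged) and a summary with
    the mean absolute discrepancy and the mean relative discrepancy
    |dJ| / |J_exp|.  Bonds with |dJ| above ``flag_threshold`` (0.1 Hz by
    default) are flagged as systematically deviating.
    """
    shared = sorted(set(calc) & set(exp))
    if not shared:
        raise ValueError("no bond labels shared between calculated and experimental")
    rows = []
    for label in shared:
        d = calc[label] - exp[label]
        rows.append(
            {
                "label": label,
                "J_calc": calc[label],
                "J_exp": exp[label],
                "delta": d,
                "flagged": abs(d) > flag_threshold,
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "mean_abs_delta": float(table["delta"].abs().mean()),
        "mean_rel_delta": float(
            (table["delta"].abs() / table["J_exp"].abs()).mean()
        ),
        "n_shared": len(shared),
        "n_flagged": int(table["flagged"].sum()),
    }
    return table, summary


def validation_metrics(
    calc: Mapping[str, float],
    exp: Mapping[str, float],
    calc_blocks: Mapping[str, Sequence[float]] | None = None,
) -> ValidationMetrics:
    """Pearson r, RMSD and Q factor between calculated and experimental couplings.

    When per-bond block means are supplied the three metrics are also computed
    per block (using the block-wise calculated values against the fixed
    experimental vector), giving block standard errors.
    """
    shared = sorted(set(calc) & set(exp))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared bonds for validation metrics")
    c = np.array([calc[k] for k in shared])
    e = np.array([exp[k] for k in shared])
    if np.ptp(c) == 0 or np.ptp(e) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")

    def _metrics(cv: np.ndarray) -> tuple[float, float, float]:
        r = float(stats.pearsonr(cv, e).statistic)
        rmsd = float(np.sqrt(np.mean((cv - e) ** 2)))
        q = rmsd / float(np.sqrt(np.mean(e**2)))
        return r, rmsd, q

    r, rmsd, q = _metrics(c)
    bp, br, bq = [], [], []
    if calc_blocks is not None:
        blocks = np.array([np.asarray(calc_blocks[k], dtype=float) for k in shared])
        for b in range(blocks.shape[1]):
            rb, rmsdb, qb = _metrics(blocks[:, b])
            bp.append(rb); br.append(rmsdb); bq.append(qb)
    return ValidationMetrics(
        pearson_r=r,
        rmsd=rmsd,
        q_factor=q,
        n_bonds=len(shared),
        block_pearson=np.array(bp),
        block_rmsd=np.array(br),
        block_q=np.array(bq),
    )
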