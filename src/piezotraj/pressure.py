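"""Pressure-response statistics over a (temperature, pressure) condition grid.

Any per-condition observable (coupling, effective occupancy, pair distance,
domain-average RMSF) can be regressed against pressure *within* a
temperature group: Pearson correlation, OLS with R^2, and a three-way
response classification — enhanced (rho > 0), destabilized (rho < 0) or
unclear — based on sign consistency across temperature groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WEAK_RHO_THRESHOLD",
    "ConditionTable",
    "ResponseClassification",
    "pearson_vs_pressure",
    "classify_response",
    "linear_fit_vs_pressure",
    "distance_pressure_matrix",
]

#: |rho| below this is flagged as a weak correlation (configurable)
WEAK_RHO_THRESHOLD = 0.5

#: minimum pressure points per temperature group for a correlation
MIN_PRESSURES = 3


class ConditionTable:
    """Observables indexed by (temperature K, pressure bar) conditions.

    Thin wrapper over a DataFrame with ``temperature`` and ``pressure``
    columns plus one column per observable label.  Duplicated conditions are
    rejected; missing cells (the sparse study grid) are simply absent rows
    or NaN values.
    """

    def __init__(self, frame: pd.DataFrame):
        if not {"temperature", "pressure"}.issubset(frame.columns):
            raise ValueError("need 'temperature' and 'pressure' columns")
        if frame.duplicated(subset=["temperature", "pressure"]).any():
            raise ValueError("duplicated (temperature, pressure) condition")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(
        cls, records: Mapping[tuple[float, float], Mapping[str, float]]
    ) -> "ConditionTable":
        rows = []
        for (t, p), obs in records.items():
            rows.append({"temperature": t, "pressure": p, **obs})
        return cls(pd.DataFrame(rows))

    @property
    def temperatures(self) -> list[float]:
        return sorted(self.frame["temperature"].unique())

    @property
    def observables(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("temperature", "pressure")]

    def group(self, temperature: float) -> pd.DataFrame:
        g = self.frame[self.frame["temperature"] == temperature]
        if g.empty:
            raise ValueError(f"no conditions at {temperature} K")
        return g.sort_values("pressure")


@dataclass
class ResponseClassification:
    label: str
    rho_by_temperature: dict[float, float]
    n_positive: int
    n_negative: int
    verdict: str                       # enhanced | destabilized | unclear
    fully_positive: bool = False
    fully_negative: bool = False
    weak: bool = False                 # all defined |rho| < threshold
    notes: list[str] = field(default_factory=list)


def _group_values(
    table: ConditionTable, label: str, temperature: float
) -> tuple[np.ndarray, np.ndarray]:
    g = table.group(temperature).dropna(subset=[label])
    return g["pressure"].to_numpy(float), g[label].to_numpy(float)


def pearson_vs_pressure(
    table: ConditionTable, label: str, temperature: float
) -> float:
    """Pearson rho of one observable against pressure within one temperature.

    Returns NaN (missing, not zero) when the observable has no variance or
    fewer than three pressure points are available.
    """
    p, y = _group_values(table, label, temperature)
    if p.size < MIN_PRESSURES:
        return float("nan")
    if np.ptp(y) == 0 or np.ptp(p) == 0:
        return float("nan")
    return float(stats.pearsonr(y, p).statistic)


def classify_response(
    rho_by_temperature: Mapping[float, float],
    strong_threshold: float = WEAK_RHO_THRESHOLD,
    min_consistent: int = 3,
    label: str = "",
) -> ResponseClassification:
    """Sign-consistency classification of a pressure response.

    ``enhanced`` when rho > 0 in at least ``min_consistent`` temperature
    groups, ``destabilized`` when rho < 0 in at least that many, otherwise
    ``unclear``.  Fully consistent signs are additionally flagged, and the
    response is marked ``weak`` when every defined |rho| is below the
    threshold (default 0.5).
    """
    defined = {t: r for t, r in rho_by_temperature.items() if np.isfinite(r)}
    if not defined:
        raise ValueError("no defined correlation in any temperature group")
    n_pos = sum(1 for r in defined.values() if r > 0)
    n_neg = sum(1 for r in defined.values() if r < 0)
    n_groups = len(defined)
    if n_pos >= min(min_consistent, n_groups) and n_pos > n_neg:
        verdict = "enhanced"
    elif n_neg >= min(min_consistent, n_groups) and n_neg > n_pos:
        verdict = "destabilized"
    else:
        verdict = "unclear"
    notes = []
    if len(defined) < len(rho_by_temperature):
        notes.append("undefined correlation in some temperature groups")
    return ResponseClassification(
        label=label,
        rho_by_temperature=dict(rho_by_temperature),
        n_positive=n_pos,
        n_negative=n_neg,
        verdict=verdict,
        fully_positive=n_pos == n_groups,
        fully_negative=n_neg == n_groups,
        weak=all(abs(r) < strong_threshold for r in defined.values()),
        notes=notes,
    )


def linear_fit_vs_pressure(
    table: ConditionTable, label: str, temperature: float
) -> tuple[float, float, float]:
    """OLS of the observable on pressure: (slope per bar, intercept, R^2)."""
    p, y = _group_values(table, label, temperature)
    if p.size < MIN_PRESSURES:
        raise ValueError(f"need >= {MIN_PRESSURES} pressure points")
    if np.ptp(p) == 0:
        raise ValueError("all pressures identical: rank-deficient fit")
    fit = stats.linregress(p, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def distance_pressure_matrix(
    table: ConditionTable, temperature: float, labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric residue-pair matrix of distance-pressure Pearson rho.

    Observable labels must be "ResA-ResB" pair-distance columns; the result
    is a square DataFrame over the residues involved, NaN where a pair's
    distance had no variance, suitable for heat-map rendering.
    """
    labels = list(labels) if labels is not None else table.observables
    group = table.group(temperature)
    missing = [
        lab for lab in labels if group[lab].isna().any()
    ] if set(labels).issubset(group.columns) else []
    absent = [lab for lab in labels if lab not in group.columns]
    if absent:
        raise ValueError(f"pair distances missing from table: {absent}")
    if missing:
        raise ValueError(
            "missing condition rows for pairs "
            f"{missing} at pressures "
            f"{sorted(group.loc[group[missing].isna().any(axis=1), 'pressure'])}"
        )
    residues: list[str] = []
    for lab in labels:
        for r in lab.split("-"):
            if r not in residues:
                residues.append(r)
    mat = pd.DataFrame(np.nan, index=residues, columns=residues, dtype=float)
    for lab in labels:
        a, b = lab.split("-")
        rho = pearson_vs_pressure(table, lab, temperature)
        mat.loc[a, b] = rho
        mat.loc[b, a] = rho
    return mat
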