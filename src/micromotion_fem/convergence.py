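"""Mesh-sensitivity protocol.

Maximum strain at four fixed monitoring points (two near the probe-tip
interface, two near the top interface) is tracked across a ladder of mesh
densities at 1 um displacement. Convergence is judged at the monitoring
points, where the field is smooth, not at the global maximum: the global
max sits next to re-entrant probe corners and is not mesh-convergent in
linear elasticity (the table records its trend anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cases import CaseConfig
from .model import MicromotionModel

__all__ = ["SensitivityTable", "run_sensitivity", "converged_at"]


@dataclass
class SensitivityTable:
    """Rows of (element count, monitor strains 1–4, global max strain)."""

    element_counts: list[int] = field(default_factory=list)
    monitor_strains: list[np.ndarray] = field(default_factory=list)
    global_max: list[float] = field(default_factory=list)
    error: str | None = None

    def __post_init__(self) -> None:
        counts = self.element_counts
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValueError("element counts must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return len(self.element_counts)

    def plot(self, ax=None):
        """Monitor-point strain versus element count. Returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = np.asarray(self.monitor_strains)
        for i in range(4):
            ax.plot(self.element_counts, m[:, i], marker="o",
                    label=f"monitor {i + 1}")
        ax.set_xlabel("elements")
        ax.set_ylabel("Von Mises strain")
        ax.legend()
        return ax

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"n_elements": self.element_counts})
        m = np.asarray(self.monitor_strains)
        for i in range(4):
            df[f"monitor_{i + 1}"] = m[:, i] if len(m) else []
        df["global_max"] = self.global_max
        return df


def run_sensitivity(case: CaseConfig, density_ladder) -> SensitivityTable:
    """Solve ``case`` at 1 um displacement across a ladder of mesh
    refinement factors (1 = the case's own mesh params; < 1 finer).

    On solver failure the partial table is returned with ``error`` set.
    Rows come back sorted by element count.
    """
    factors = list(density_ladder)
    if not factors:
        raise ValueError("density ladder must be non-empty")
    table = SensitivityTable()
    rows = []
    for f in factors:
        cfg = case.replace(displacement=1.0, mesh=case.mesh.refined(float(f)))
        try:
            res = MicromotionModel(cfg).fit()
        except Exception as exc:  # noqa: BLE001 - partial table contract
            table.error = f"refinement {f}: {type(exc).__name__}: {exc}"
            break
        rows.append((res.n_elements, res.monitor_strains,
                     res.max_tissue_strain))
    rows.sort(key=lambda r: r[0])
    for n, m, g in rows:
        table.element_counts.append(n)
        table.monitor_strains.append(m)
        table.global_max.append(g)
    return table


def converged_at(table: SensitivityTable, tol_fraction: float = 0.05) -> int | None:
    """Smallest element count (below the finest) whose monitor-point strains
    all lie within ``tol_fraction`` (relative) of the finest mesh's;
    ``None`` if no coarser mesh qualifies."""
    if table.n_rows < 2:
        raise ValueError("need at least 2 sensitivity rows")
    ref = np.asarray(table.monitor_strains[-1])
    scale = np.where(ref != 0, np.abs(ref), 1.0)
    for n, m in zip(table.element_counts[:-1], table.monitor_strains[:-1]):
        if np.all(np.abs(np.asarray(m) - ref) / scale <= tol_fraction):
            return n
    return None
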