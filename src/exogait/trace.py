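"""Uniformly sampled signal containers shared across the pipeline.

A :class:`ForceTrace` holds one channel sampled either over a normalized
gait cycle (``domain="phase"``, grid in [0, 1)) or over wall time
(``domain="time"``, grid in seconds).  Phase convention throughout the
package: 0 = touchdown, stance first, then swing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ForceTrace:
    """A labeled, uniformly sampled 1-D signal.

    Parameters
    ----------
    values : ndarray
        Sample values.
    grid : ndarray
        Sample locations; phase fractions in [0, 1) or seconds.
    domain : {"phase", "time"}
        Interpretation of ``grid``.
    units : str
        Physical units of ``values`` (e.g. "N"; sEMG envelopes are "a.u.").
    """

    values: np.ndarray
    grid: np.ndarray
    domain: str = "phase"
    units: str = "N"
    label: str = field(default="")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.domain not in ("phase", "time"):
            raise ValueError(f"unknown domain {self.domain!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        """Grid spacing (assumed uniform)."""
        if len(self.grid) < 2:
            raise ValueError("trace has fewer than 2 samples")
        return float(self.grid[1] - self.grid[0])

    def copy_with(self, values: np.ndarray, label: str | None = None) -> "ForceTrace":
        return ForceTrace(
            values=np.asarray(values, dtype=float),
            grid=self.grid.copy(),
            domain=self.domain,
            units=self.units,
            label=self.label if label is None else label,
        )


def phase_grid(n: int) -> np.ndarray:
    """Uniform phase grid with ``n`` points on [0, 1), endpoint excluded."""
    if n < 2:
        raise ValueError("need at least 2 phase points")
    return np.arange(n) / n
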