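"""Forward-solution container shared by all solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ForwardSolution:
    """Scalp potentials at a set of evaluation points.

    points: (n, 3) evaluation coordinates [m] (scalp element centroids for
    the BEM, scalp mesh nodes for FEM/hybrid); potentials: (n,) volts;
    referencing: "raw" or "average"; meta: solver provenance.
    """

    points: np.ndarray
    potentials: np.ndarray
    referencing: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        self.potentials = np.asarray(self.potentials, float)
        if self.points.shape[0] != self.potentials.shape[0]:
            raise ValueError("one potential per evaluation point required")

    def average_referenced(self) -> "ForwardSolution":
        if self.referencing == "average":
            return self
        return ForwardSolution(
            points=self.points,
            potentials=self.potentials - self.potentials.mean(),
            referencing="average",
            meta=self.meta,
        )
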