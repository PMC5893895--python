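"""Monotone staircase curves shared by the consonance and circle-map modules."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StaircaseCurve"]


@dataclass
class StaircaseCurve:
    """An ordered, non-decreasing map from a control axis to a response.

    Used both for the empirical cumulative-recurrence curve (x = interval
    ratio, y = cumulative recurrence in [0, 1]) and for the circle-map
    staircase (x = bare winding number, y = dressed winding number).
    """

    x: np.ndarray
    y: np.ndarray
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if len(self.x) < 2:
            raise ValueError("a staircase needs at least two points")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("x must be non-decreasing")

    def __len__(self) -> int:
        return len(self.x)

    def normalized(self) -> "StaircaseCurve":
        """Min-max rescale both axes to the unit square."""
        x_span = self.x[-1] - self.x[0]
        y_span = self.y.max() - self.y.min()
        if x_span == 0 or y_span == 0:
            raise ValueError("degenerate curve cannot be normalized")
        return StaircaseCurve(
            (self.x - self.x[0]) / x_span,
            (self.y - self.y.min()) / y_span,
            self.x_label,
            self.y_label,
        )

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of y onto ``grid`` (clamped at the ends)."""
        return np.interp(grid, self.x, self.y)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({self.x_label: self.x, self.y_label: self.y}).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
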