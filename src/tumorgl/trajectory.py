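"""Longitudinal tumor-size series.

The package's single in-memory container for measured or simulated
tumor sizes: strictly increasing observation times (days) paired with
positive sizes (cells, mm^3, or mm -- the unit is carried as an opaque
label and never interpreted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TumorTrajectory"]


@dataclass(frozen=True)
class TumorTrajectory:
    """Time-stamped tumor sizes for one subject.

    Parameters
    ----------
    times : array-like
        Observation times in days, strictly increasing.
    sizes : array-like
        Tumor sizes, strictly positive, same length as ``times``.
    subject_id : str
        Subject identifier (free text).
    arm : str
        Study-arm label (free text).
    unit_label : str
        Size unit carried alongside the data (e.g. ``"mm^3"``, ``"mm"``,
        ``"cells"``); never interpreted numerically.
    """

    times: np.ndarray
    sizes: np.ndarray
    subject_id: str = "subject"
    arm: str = ""
    unit_label: str = "mm^3"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.sizes, dtype=float)
        if t.ndim != 1 or s.ndim != 1 or t.shape != s.shape:
            raise ValueError("times and sizes must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("trajectory must contain at least one observation")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(s)):
            raise ValueError("times and sizes must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"times must be strictly increasing (subject {self.subject_id!r})"
            )
        if np.any(s <= 0):
            raise ValueError(f"sizes must be positive (subject {self.subject_id!r})")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sizes", s)

    def __len__(self) -> int:
        return self.times.size

    @property
    def log_sizes(self) -> np.ndarray:
        """Natural log of the sizes (the scale all dynamics live on)."""
        return np.log(self.sizes)

    def restrict(self, t_min: float = -np.inf, t_max: float = np.inf) -> "TumorTrajectory":
        """Sub-trajectory with times in the closed interval [t_min, t_max]."""
        mask = (self.times >= t_min) & (self.times <= t_max)
        if not mask.any():
            raise ValueError("restriction leaves no observations")
        return TumorTrajectory(
            self.times[mask], self.sizes[mask], self.subject_id, self.arm, self.unit_label
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with the package's CSV schema columns."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "arm": self.arm,
                "time_days": self.times,
                "size": self.sizes,
                "unit": self.unit_label,
            }
        )
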