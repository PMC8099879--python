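"""Point-pattern containers for localization data.

A :class:`LocalizationField` is the in-memory unit that every spatial
statistic in this package consumes: the (x, y) coordinates (nm) of the
localizations of one color channel inside one rectangular region of
interest, plus the per-localization precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangular region of interest in nm."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("ROI must have positive area")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area_nm2(self) -> float:
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= self.x_min)
            & (xy[:, 0] <= self.x_max)
            & (xy[:, 1] >= self.y_min)
            & (xy[:, 1] <= self.y_max)
        )

    def erode(self, margin: float) -> "ROI":
        """Shrink the ROI by ``margin`` nm on every side."""
        return ROI(
            self.x_min + margin,
            self.y_min + margin,
            self.x_max - margin,
            self.y_max - margin,
        )

    @classmethod
    def square(cls, side: float, center: tuple[float, float] = (0.0, 0.0)) -> "ROI":
        cx, cy = center
        h = side / 2.0
        return cls(cx - h, cy - h, cx + h, cy + h)


@dataclass
class LocalizationField:
    """Localizations of one channel inside one ROI.

    Parameters
    ----------
    xy
        (n, 2) coordinates in nm.
    roi
        ROI bounds in nm; every point must lie inside.
    channel
        Channel identifier.
    precision
        Per-point localization precision (sigma, nm); optional.
    """

    xy: np.ndarray
    roi: ROI
    channel: int = 0
    precision: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.precision is not None:
            self.precision = np.asarray(self.precision, dtype=float).ravel()
            if self.precision.shape[0] != self.xy.shape[0]:
                raise ValueError("precision length must match point count")
        if self.xy.shape[0] and not self.roi.contains(self.xy).all():
            raise ValueError("all points must lie inside the ROI")

    def __len__(self) -> int:
        return self.xy.shape[0]

    @property
    def n(self) -> int:
        return self.xy.shape[0]

    @property
    def density_um2(self) -> float:
        """Global density <rho> in points per µm²."""
        return self.n / self.roi.area_um2
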