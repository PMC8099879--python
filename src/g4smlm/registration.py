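"""Bead-calibrated polynomial channel registration.

Multi-color SMLM channels suffer chromatic aberration; a 2nd-degree
polynomial warp fitted to fiducial-bead localizations maps each target
channel onto the reference channel.  Bead correspondence is established
by mutual nearest-neighbor pairing within a capture radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .fields import LocalizationField

__all__ = ["ChannelMapping", "fit_channel_map", "apply_channel_map"]

#: Monomial exponents of the degree-2 basis {1, x, y, x², xy, y²}.
_EXPONENTS = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]


@dataclass
class ChannelMapping:
    """Degree-2 polynomial warp of one target channel onto the reference.

    ``coef_x`` and ``coef_y`` each hold 6 coefficients over the
    monomials {1, x, y, x², xy, y²} evaluated on centered/scaled
    coordinates (``center`` nm, ``scale`` nm); outputs are in nm.
    """

    coef_x: np.ndarray
    coef_y: np.ndarray
    center: tuple[float, float]
    scale: float
    rms_residual_nm: float
    n_beads: int

    def __post_init__(self) -> None:
        self.coef_x = np.asarray(self.coef_x, dtype=float).ravel()
        self.coef_y = np.asarray(self.coef_y, dtype=float).ravel()
        if self.coef_x.shape != (6,) or self.coef_y.shape != (6,):
            raise ValueError("expected 6 coefficients per output coordinate")
        if self.rms_residual_nm < 0:
            raise ValueError("RMS residual must be non-negative")

    def transform(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        basis = _design_matrix(xy, self.center, self.scale)
        return np.column_stack([basis @ self.coef_x, basis @ self.coef_y])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coef_x": self.coef_x.tolist(),
            "coef_y": self.coef_y.tolist(),
            "center": list(self.center),
            "scale": self.scale,
            "rms_residual_nm": self.rms_residual_nm,
            "n_beads": self.n_beads,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChannelMapping":
        d = json.loads(Path(path).read_text())
        return cls(
            coef_x=np.array(d["coef_x"]),
            coef_y=np.array(d["coef_y"]),
            center=tuple(d["center"]),
            scale=float(d["scale"]),
            rms_residual_nm=float(d["rms_residual_nm"]),
            n_beads=int(d["n_beads"]),
        )


def _design_matrix(xy: np.ndarray, center: tuple[float, float], scale: float) -> np.ndarray:
    u = (xy[:, 0] - center[0]) / scale
    v = (xy[:, 1] - center[1]) / scale
    return np.column_stack([u**p * v**q for p, q in _EXPONENTS])


def pair_beads(
    reference: np.ndarray, target: np.ndarray, capture_radius_nm: float = 500.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual nearest-neighbor bead pairing within a capture radius.

    A reference bead and a target bead are paired only when each is the
    other's nearest neighbor and their separation is below the radius;
    ambiguous beads are dropped.
    """
    if len(reference) == 0 or len(target) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    tree_t = cKDTree(target)
    tree_r = cKDTree(reference)
    d_rt, nn_rt = tree_t.query(reference)
    _, nn_tr = tree_r.query(target)
    idx_r = np.arange(len(reference))
    mutual = (nn_tr[nn_rt] == idx_r) & (d_rt <= capture_radius_nm)
    return idx_r[mutual], nn_rt[mutual]


def fit_channel_map(
    reference_beads: LocalizationField,
    target_beads: LocalizationField,
    capture_radius_nm: float = 500.0,
) -> ChannelMapping:
    """Least-squares degree-2 polynomial map, target → reference.

    Coordinates are centered and scaled before the solve for
    conditioning.  Raises on fewer than 6 bead pairs (underdetermined)
    or a rank-deficient (e.g. collinear) bead layout.
    """
    i_ref, i_tgt = pair_beads(reference_beads.xy, target_beads.xy, capture_radius_nm)
    if i_ref.size < 6:
        raise ValueError(f"need at least 6 paired beads, got {i_ref.size}")
    ref = reference_beads.xy[i_ref]
    tgt = target_beads.xy[i_tgt]
    center = (float(tgt[:, 0].mean()), float(tgt[:, 1].mean()))
    scale = float(np.abs(tgt - np.asarray(center)).max())
    if scale == 0:
        raise ValueError("degenerate bead layout (zero spatial extent)")
    basis = _design_matrix(tgt, center, scale)
    rank = np.linalg.matrix_rank(basis)
    if rank < 6:
        raise ValueError(f"rank-deficient bead layout (rank {rank} < 6); beads may be collinear")
    coef_x, *_ = np.linalg.lstsq(basis, ref[:, 0], rcond=None)
    coef_y, *_ = np.linalg.lstsq(basis, ref[:, 1], rcond=None)
    pred = np.column_stack([basis @ coef_x, basis @ coef_y])
    rms = float(np.sqrt(np.mean(np.sum((pred - ref) ** 2, axis=1))))
    return ChannelMapping(
        coef_x=coef_x,
        coef_y=coef_y,
        center=center,
        scale=scale,
        rms_residual_nm=rms,
        n_beads=int(i_ref.size),
    )


def apply_channel_map(mapping: ChannelMapping, field: LocalizationField) -> LocalizationField:
    """Warp a localization field into the reference frame.

    Precision values are carried through unchanged.  The ROI is mapped
    along with the points (bounding box of the warped ROI corners and
    the warped points), so the result can be re-cropped to a common
    analysis ROI afterwards.
    """
    from .fields import ROI

    if mapping is None:
        raise ValueError("channel has no fitted mapping")
    new_xy = mapping.transform(field.xy)
    roi = field.roi
    corners = np.array(
        [
            [roi.x_min, roi.y_min],
            [roi.x_min, roi.y_max],
            [roi.x_max, roi.y_min],
            [roi.x_max, roi.y_max],
        ]
    )
    warped = mapping.transform(corners)
    pts = np.vstack([warped, new_xy]) if new_xy.size else warped
    new_roi = ROI(
        float(pts[:, 0].min()),
        float(pts[:, 1].min()),
        float(pts[:, 0].max()),
        float(pts[:, 1].max()),
    )
    return LocalizationField(
        xy=new_xy, roi=new_roi, channel=field.channel, precision=field.precision
    )
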