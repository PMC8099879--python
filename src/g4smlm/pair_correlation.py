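"""Pair-correlation statistics of SMLM localization fields.

The auto-correlation g(r) of one channel is the density-normalized
pair-distance histogram,

    g(r) = <rho(R) rho(R + r)>_R / <rho>^2 ,

estimated by direct pair counting with reference points restricted to
the ROI eroded by r_max (unbiased annulus areas without analytic edge
corrections); complete spatial randomness gives g = 1.  The profile is
fitted by the two-Gaussian focus model

    g(r) = 1/(4 pi sigma^2 <rho>) exp(-r^2 / 4 sigma^2)
         + A exp(-r^2 / (4 (sigma^2 + r_app^2))) + 1 ,

whose first term is the stochastic-resampling peak set by the
localization precision sigma and whose second term is the
auto-correlation of Gaussian-shaped foci of apparent radius r_app; the
mean molecular content per focus is <N> = 2 pi <rho> A r_app^2.

The cross-correlation c(r) between two registered channels is the
inter-channel analog (baseline 1 under independence) and is compared
with a randomized baseline for colocalization testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree

from .fields import ROI, LocalizationField

__all__ = [
    "CorrelationProfile",
    "ACFitResult",
    "crop_roi",
    "auto_correlation",
    "fit_ac_model",
    "cross_correlation",
]


@dataclass
class CorrelationProfile:
    """Binned correlation profile g(r) or c(r)."""

    r_nm: np.ndarray
    value: np.ndarray
    pairs: np.ndarray
    bin_width_nm: float

    def __post_init__(self) -> None:
        self.r_nm = np.asarray(self.r_nm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=float)
        if np.any(np.diff(self.r_nm) <= 0):
            raise ValueError("r bins must be strictly increasing")
        if np.any(self.pairs < 0):
            raise ValueError("pair counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.r_nm, "value": self.value, "pairs": self.pairs})


@dataclass(frozen=True)
class ACFitResult:
    """Two-Gaussian auto-correlation fit.

    sigma_nm : localization precision; rho_um2 : global density
    (points/µm², fixed during the fit); amplitude : A; r_app_nm :
    apparent focus sigma radius; n_per_focus : <N> = 2π<rho>A r_app².
    """

    sigma_nm: float
    rho_um2: float
    amplitude: float
    r_app_nm: float
    n_per_focus: float
    covariance: np.ndarray
    amplitude_clipped: bool = False


def molecular_content(rho_um2: float, amplitude: float, r_app_nm: float) -> float:
    """<N> = 2 pi <rho> A r_app^2 (rho converted to nm^-2)."""
    return 2.0 * np.pi * (rho_um2 / 1e6) * amplitude * r_app_nm**2


def crop_roi(
    table: pd.DataFrame | LocalizationField,
    side_nm: float = 6000.0,
    center: tuple[float, float] | None = None,
    channel: int | None = None,
) -> LocalizationField:
    """Crop localizations to a centered square ROI.

    Accepts a localization table (DataFrame with x_nm/y_nm columns) or
    an existing field.  ``center`` defaults to the coordinate median.
    An empty result is allowed (the field simply has zero points).
    """
    if side_nm <= 0:
        raise ValueError("side must be positive")
    if isinstance(table, LocalizationField):
        xy = table.xy
        prec = table.precision
        ch = table.channel
    else:
        df = table
        if channel is not None:
            df = df[df["channel"] == channel]
        xy = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
        prec = df["precision_nm"].to_numpy(dtype=float) if "precision_nm" in df else None
        ch = channel if channel is not None else (int(df["channel"].iloc[0]) if len(df) else 0)
    if center is None:
        center = (
            (float(np.median(xy[:, 0])), float(np.median(xy[:, 1]))) if len(xy) else (0.0, 0.0)
        )
    roi = ROI.square(side_nm, center)
    keep = roi.contains(xy) if len(xy) else np.zeros(0, dtype=bool)
    return LocalizationField(
        xy=xy[keep] if len(xy) else np.empty((0, 2)),
        roi=roi,
        channel=ch,
        precision=prec[keep] if prec is not None and len(xy) else None,
    )


def _pair_counts(
    ref_xy: np.ndarray,
    all_xy: np.ndarray,
    edges: np.ndarray,
    subtract_self: bool,
) -> np.ndarray:
    """Per-annulus pair counts between reference and full point sets."""
    tree_ref = cKDTree(ref_xy)
    tree_all = cKDTree(all_xy)
    cum = tree_ref.count_neighbors(tree_all, edges)
    counts = np.diff(cum).astype(float)
    if subtract_self:
        # cum[0] (distance <= 0) holds one self-pair per reference point
        # plus any genuinely coincident pairs; keep the latter.
        counts[0] += cum[0] - len(ref_xy)
    else:
        counts[0] += cum[0]
    return counts


def _correlation(
    ref_field: LocalizationField,
    all_field: LocalizationField,
    bin_width_nm: float,
    r_max_nm: float,
    auto: bool,
) -> CorrelationProfile:
    roi = ref_field.roi
    if r_max_nm >= min(roi.width, roi.height) / 2:
        raise ValueError("r_max must be below half the ROI side")
    inner = roi.erode(r_max_nm)
    keep = inner.contains(ref_field.xy)
    ref_xy = ref_field.xy[keep]
    n_ref = len(ref_xy)
    if n_ref < 1 or all_field.n < 2:
        raise ValueError("too few points for correlation analysis")
    edges = np.arange(0.0, r_max_nm + bin_width_nm / 2, bin_width_nm)
    counts = _pair_counts(ref_xy, all_field.xy, edges, subtract_self=auto)
    areas = np.pi * np.diff(edges**2)
    rho_nm2 = all_field.n / all_field.roi.area_nm2
    value = counts / (n_ref * rho_nm2 * areas)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CorrelationProfile(r_nm=centers, value=value, pairs=counts, bin_width_nm=bin_width_nm)


def auto_correlation(
    field: LocalizationField,
    bin_width_nm: float = 10.0,
    r_max_nm: float = 500.0,
) -> CorrelationProfile:
    """Auto-correlation g(r) by direct pair counting.

    Reference points are restricted to the ROI eroded by ``r_max_nm``
    so that every annulus lies fully inside the ROI; the density
    normalizer uses the full field.  One self-pair per reference point
    is excluded.
    """
    if field.n < 2:
        raise ValueError("need at least 2 points")
    return _correlation(field, field, bin_width_nm, r_max_nm, auto=True)


def _ac_model(r, sigma, amplitude, r_app, rho_nm2):
    term1 = np.exp(-(r**2) / (4 * sigma**2)) / (4 * np.pi * sigma**2 * rho_nm2)
    term2 = amplitude * np.exp(-(r**2) / (4 * (sigma**2 + r_app**2)))
    return term1 + term2 + 1.0


def fit_ac_model(
    profile: CorrelationProfile,
    rho_um2: float,
    skip_first_bin: bool = True,
) -> ACFitResult:
    """Weighted least-squares fit of the two-Gaussian focus model.

    <rho> is fixed to the observed global density (the first-term
    amplitude is otherwise degenerate with A).  Bin weights are
    1/sqrt(pairs + 1); the first bin (self/merge artifacts) is excluded
    by default.  A is bounded below by 0; a fit pinned at 0 is flagged
    ``amplitude_clipped``.
    """
    if len(profile.r_nm) < 10:
        raise ValueError("need at least 10 bins")
    if rho_um2 <= 0:
        raise ValueError("rho must be positive")
    rho_nm2 = rho_um2 / 1e6
    sl = slice(1, None) if skip_first_bin else slice(None)
    r = profile.r_nm[sl]
    g = profile.value[sl]
    w_sigma = 1.0 / np.sqrt(profile.pairs[sl] + 1.0)

    def model(rr, sigma, amplitude, r_app):
        return _ac_model(rr, sigma, amplitude, r_app, rho_nm2)

    a0 = max(float(np.max(g) - 1.0), 0.01)
    p0 = [10.0, a0, 50.0]
    bounds = ([0.5, 0.0, 1.0], [200.0, np.inf, max(500.0, r[-1])])
    try:
        popt, pcov = optimize.curve_fit(
            model, r, g, p0=p0, sigma=w_sigma, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise ValueError(f"two-Gaussian correlation fit did not converge: {exc}") from exc
    sigma, amplitude, r_app = popt
    clipped = amplitude < 1e-10
    amplitude = max(amplitude, 0.0)
    return ACFitResult(
        sigma_nm=float(sigma),
        rho_um2=float(rho_um2),
        amplitude=float(amplitude),
        r_app_nm=float(r_app),
        n_per_focus=molecular_content(rho_um2, float(amplitude), float(r_app)),
        covariance=pcov,
        amplitude_clipped=bool(clipped),
    )


def toroidal_shift(field: LocalizationField, shift: tuple[float, float] | None = None) -> LocalizationField:
    """Shift a field by half the ROI with wrap-around (null construction)."""
    roi = field.roi
    if shift is None:
        shift = (roi.width / 2.0, roi.height / 2.0)
    xy = field.xy.copy()
    xy[:, 0] = roi.x_min + np.mod(xy[:, 0] - roi.x_min + shift[0], roi.width)
    xy[:, 1] = roi.y_min + np.mod(xy[:, 1] - roi.y_min + shift[1], roi.height)
    return LocalizationField(xy=xy, roi=roi, channel=field.channel, precision=field.precision)


def cross_correlation(
    field_a: LocalizationField,
    field_b: LocalizationField,
    bin_width_nm: float = 10.0,
    r_max_nm: float = 500.0,
    null_field: LocalizationField | None = None,
) -> tuple[CorrelationProfile, CorrelationProfile]:
    """Cross-correlation c(r) between two channels plus a null profile.

    Both fields must share one (registered) ROI.  The null profile is
    computed against ``null_field`` (e.g. the same species from a
    different scene) when given, otherwise against a toroidally shifted
    copy of field B.
    """
    if field_a.roi != field_b.roi:
        raise ValueError("fields must share one registered ROI")
    observed = _correlation(field_a, field_b, bin_width_nm, r_max_nm, auto=False)
    if null_field is None:
        null_b = toroidal_shift(field_b)
    else:
        if null_field.roi != field_a.roi:
            raise ValueError("null field must share the analysis ROI")
        null_b = null_field
    null = _correlation(field_a, null_b, bin_width_nm, r_max_nm, auto=False)
    return observed, null
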