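"""Triple-correlation (TC) analysis of three-channel localization fields.

The TC function quantifies recurrent three-species spatial patterns
(e.g. helicase / nascent-DNA / G4 arrangements within replisomes):

    f(r1, r2) = <d_rho1(R) d_rho2(R + r1) d_rho3(R + r2)>_R
                / (<rho1> <rho2> <rho3>)

where d_rho_i = rho_i - <rho_i> is the local density fluctuation of
channel i.  Because SMLM data are coordinates rather than pixel
intensities, the function is computed directly by visiting each
channel-1 coordinate and estimating d_rho2 and d_rho3 in sector-annulus
bins at displacements r1 = (r1, theta) and r2 = (r2, theta + dtheta).
Since triplets are randomly oriented, f is averaged along
theta in [-pi, pi) and collapsed onto the rotation-invariant geometry
grid (r1, r2, r3) with r3^2 = r1^2 + r2^2 + 2 r1 r2 cos(dtheta).

Significance is assessed against randomized null maps in which the
probe channel (channel 3) is resampled as CSR at matched density;
above-threshold connected regions of the z-map become TC triplets.
The conditional local density

    C3(r1, r2) = <d_rho1 d_rho2 d_rho3> / <d_rho1 d_rho2>

estimates the local density of the third species at its triplet vertex
given a channel-1/2 pair correlating at r1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .fields import LocalizationField
from .synthetic import generate_point_field

__all__ = [
    "TCMap",
    "TCTriplet",
    "TripletFrequencyResult",
    "compute_tc_map",
    "tc_null_maps",
    "find_tc_triplets",
    "conditional_density",
    "brute_force_triplets",
    "triplet_frequency",
]


@dataclass
class TCMap:
    """TC amplitudes on the (r1, r2, dtheta) grid and its (r1, r2, r3) collapse.

    ``f_theta[i, j, d]`` is the normalized TC amplitude for radial bins
    i (channel 2) and j (channel 3) at angular offset bin d;
    ``f3[i, j, k]`` is its average over the angular-offset cells whose
    printed transform lands in r3 bin k (NaN where no cell maps).
    ``num23`` keeps the unnormalized fluctuation product (nm^-4) and
    ``mean_d2`` the visit-averaged channel-2 fluctuation (nm^-2) used
    by the conditional-density estimator.
    """

    bin_width_nm: float
    n_theta: int
    r_centers_nm: np.ndarray
    r3_centers_nm: np.ndarray
    f_theta: np.ndarray
    f3: np.ndarray
    n3: np.ndarray  # contributing (visit x angular-cell) counts per f3 cell
    num23: np.ndarray
    mean_d2: np.ndarray
    rho_um2: tuple[float, float, float]
    n_visits: int
    channels: tuple[int, int, int] = (1, 2, 3)

    @property
    def grid_signature(self) -> tuple:
        return (float(self.bin_width_nm), len(self.r_centers_nm), self.n_theta)


@dataclass(frozen=True)
class TCTriplet:
    """A significant recurrent three-species geometry."""

    r1_nm: float
    r2_nm: float
    r3_nm: float
    f: float
    z: float
    index: tuple[int, int, int]
    channels: tuple[int, int, int] = (1, 2, 3)
    c3_um2: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.z):
            raise ValueError("z-score must be finite")
        # geometry comes from bin centers, so the triangle inequality is
        # enforced only up to one bin of rounding slack
        r1, r2, r3 = self.r1_nm, self.r2_nm, self.r3_nm
        slack = 0.5 * (r1 + r2 + r3) / 3 + 1e-6
        if r3 > r1 + r2 + slack or r3 < abs(r1 - r2) - slack:
            raise ValueError("triplet geometry violates the triangle inequality")


@dataclass(frozen=True)
class TripletFrequencyResult:
    """Pattern frequency relative to a reference pattern count."""

    frequency: float
    instance_count: int
    reference_count: int


def r3_transform(r1: np.ndarray, r2: np.ndarray, dtheta: np.ndarray) -> np.ndarray:
    """Third side of the rotation-collapsed triplet geometry.

    r3^2 = r1^2 + r2^2 + 2 r1 r2 cos(dtheta); dtheta is the angular
    offset between the two displacement vectors, so dtheta = pi gives
    the collinear opposite case r3 = |r1 - r2| and dtheta = 0 gives
    r3 = r1 + r2.
    """
    return np.sqrt(np.maximum(r1**2 + r2**2 + 2 * r1 * r2 * np.cos(dtheta), 0.0))


def _shift_angles(n_theta: int) -> np.ndarray:
    """Angular offset of each circular-shift index, wrapped to (-pi, pi]."""
    dth = 2 * np.pi / n_theta
    ang = np.arange(n_theta) * dth
    return np.where(ang > np.pi, ang - 2 * np.pi, ang)


def _polar_counts(
    ref_xy: np.ndarray,
    tree: cKDTree,
    xy: np.ndarray,
    r_max: float,
    nr: int,
    n_theta: int,
) -> list[np.ndarray]:
    """Sector-annulus counts (nr, n_theta) around each reference point."""
    dr = r_max / nr
    dth = 2 * np.pi / n_theta
    out = []
    neighbor_lists = tree.query_ball_point(ref_xy, r_max)
    for i, nbrs in enumerate(neighbor_lists):
        counts = np.zeros((nr, n_theta))
        if nbrs:
            d = xy[nbrs] - ref_xy[i]
            r = np.hypot(d[:, 0], d[:, 1])
            mask = r > 0
            ir = np.minimum((r[mask] / dr).astype(int), nr - 1)
            th = np.arctan2(d[mask, 1], d[mask, 0])
            it = np.minimum(((th + np.pi) / dth).astype(int), n_theta - 1)
            np.add.at(counts, (ir, it), 1.0)
        out.append(counts)
    return out


def compute_tc_map(
    field1: LocalizationField,
    field2: LocalizationField,
    field3: LocalizationField,
    r_max_nm: float = 300.0,
    bin_width_nm: float = 20.0,
    n_theta: int = 18,
    min_points: int = 10,
) -> TCMap:
    """Direct coordinate-visiting computation of the TC function.

    Visits every channel-1 point inside the ROI eroded by ``r_max_nm``;
    estimates the channel-2 and channel-3 density fluctuations in
    sector-annulus bins (area r dr dtheta), forms their product at every
    (r1, r2, dtheta) cell, averages over visits and theta, normalizes
    per the TC definition, and collapses onto (r1, r2, r3).
    """
    roi = field1.roi
    for f in (field2, field3):
        if f.roi != roi:
            raise ValueError("fields must be registered to one ROI")
    for f in (field1, field2, field3):
        if f.n < min_points:
            raise ValueError(f"channel {f.channel} has fewer than {min_points} points")
    if r_max_nm >= min(roi.width, roi.height) / 2:
        raise ValueError("r_max must be below half the ROI side")

    nr = int(round(r_max_nm / bin_width_nm))
    dr = r_max_nm / nr
    dth = 2 * np.pi / n_theta
    inner = roi.erode(r_max_nm)
    ref_xy = field1.xy[inner.contains(field1.xy)]
    n_vis = len(ref_xy)
    if n_vis == 0:
        raise ValueError("no channel-1 points left after ROI erosion")

    r_centers = (np.arange(nr) + 0.5) * dr
    # exact sector-annulus areas: (pi (r_hi^2 - r_lo^2)) / n_theta
    r_edges = np.arange(nr + 1) * dr
    areas = np.pi * np.diff(r_edges**2) / n_theta  # nm^2 per sector bin

    rho2 = field2.n / roi.area_nm2
    rho3 = field3.n / roi.area_nm2
    rho1 = field1.n / roi.area_nm2

    tree2 = cKDTree(field2.xy)
    tree3 = cKDTree(field3.xy)
    counts2 = _polar_counts(ref_xy, tree2, field2.xy, r_max_nm, nr, n_theta)
    counts3 = _polar_counts(ref_xy, tree3, field3.xy, r_max_nm, nr, n_theta)

    num23 = np.zeros((nr, nr, n_theta))
    sum_d2 = np.zeros(nr)
    shifts = np.arange(n_theta)
    for c2, c3 in zip(counts2, counts3):
        d2 = c2 / areas[:, None] - rho2
        d3 = c3 / areas[:, None] - rho3
        # circular correlation over theta for every (r1, r2) pair
        rolled = np.stack([np.roll(d3, -d, axis=1) for d in shifts])  # (ntheta, nr, ntheta)
        num23 += np.einsum("it,djt->ijd", d2, rolled)
        sum_d2 += d2.mean(axis=1)
    num23 /= n_vis * n_theta  # mean over visits and theta
    mean_d2 = sum_d2 / n_vis
    f_theta = num23 / (rho2 * rho3)

    # collapse (r1, r2, dtheta) -> (r1, r2, r3) by the printed transform;
    # shift index d corresponds to an exact angular offset of d * dth
    # (difference of sector-bin centers), wrapped to (-pi, pi]
    n3 = int(np.ceil(2 * r_max_nm / dr))
    r3_centers = (np.arange(n3) + 0.5) * dr
    dth_centers = _shift_angles(n_theta)
    R1 = r_centers[:, None, None]
    R2 = r_centers[None, :, None]
    # The printed transform's angular variable is the supplement of the
    # sampling-direction offset phi: with dtheta = pi - |phi| the + sign
    # yields r3 = |r2 - r1|, the physical channel-2/channel-3 distance
    # (an equilateral pattern, vertex angle 60 deg, lands at r3 = r1 = r2).
    DT = (np.pi - np.abs(dth_centers))[None, None, :]
    r3_vals = r3_transform(R1, R2, DT)
    k_idx = np.minimum((r3_vals / dr).astype(int), n3 - 1)
    f3 = np.full((nr, nr, n3), np.nan)
    cell_n = np.zeros((nr, nr, n3))
    sums = np.zeros((nr, nr, n3))
    for d in range(n_theta):
        np.add.at(sums, (np.arange(nr)[:, None].repeat(nr, 1), np.arange(nr)[None, :].repeat(nr, 0), k_idx[:, :, d]), f_theta[:, :, d])
        np.add.at(cell_n, (np.arange(nr)[:, None].repeat(nr, 1), np.arange(nr)[None, :].repeat(nr, 0), k_idx[:, :, d]), 1.0)
    valid = cell_n > 0
    f3[valid] = sums[valid] / cell_n[valid]

    return TCMap(
        bin_width_nm=dr,
        n_theta=n_theta,
        r_centers_nm=r_centers,
        r3_centers_nm=r3_centers,
        f_theta=f_theta,
        f3=f3,
        n3=cell_n * n_vis,
        num23=num23,
        mean_d2=mean_d2,
        rho_um2=(rho1 * 1e6, rho2 * 1e6, rho3 * 1e6),
        n_visits=n_vis,
        channels=(field1.channel, field2.channel, field3.channel),
    )


def tc_null_maps(
    field1: LocalizationField,
    field2: LocalizationField,
    field3: LocalizationField,
    n_rand: int = 20,
    seed: int = 0,
    r_max_nm: float = 300.0,
    bin_width_nm: float = 20.0,
    n_theta: int = 18,
) -> list[TCMap]:
    """Null TC maps with the probe channel resampled as CSR.

    Channel 3 is replaced by ``n_rand`` CSR realizations at matched
    density (channels 1-2 structure preserved), giving the per-cell
    null distribution of f under 'no recurrent third species'.
    """
    if n_rand < 2:
        raise ValueError("need at least 2 null realizations")
    rng = np.random.default_rng(seed)
    density = field3.density_um2
    maps = []
    for _ in range(n_rand):
        csr3 = generate_point_field(
            density, field3.roi, channel=field3.channel, seed=int(rng.integers(2**31))
        )
        if csr3.n < 10:  # pragma: no cover - sparse edge
            continue
        maps.append(
            compute_tc_map(
                field1, field2, csr3,
                r_max_nm=r_max_nm, bin_width_nm=bin_width_nm, n_theta=n_theta,
            )
        )
    return maps


def null_statistics(nulls: list[TCMap]) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean and sd of the null f3 maps."""
    stack = np.stack([m.f3 for m in nulls])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        return np.nanmean(stack, axis=0), np.nanstd(stack, axis=0, ddof=1)


def z_map(observed: TCMap, nulls: list[TCMap]) -> np.ndarray:
    """Per-cell z-score of the observed f3 against the null ensemble."""
    for m in nulls:
        if m.grid_signature != observed.grid_signature:
            raise ValueError("null map grid does not match the observed map")
    mean, sd = null_statistics(nulls)
    return _z_score(observed.f3, mean, sd)


def _z_score(f3: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Cell-wise z with a variance floor.

    Cells whose null sd is estimated near zero (few contributing
    angular cells, small ensembles) would otherwise produce unbounded
    z; the sd is floored at a quarter of the median positive cell sd.
    """
    finite = sd[np.isfinite(sd) & (sd > 0)]
    floor = 0.25 * np.median(finite) if finite.size else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (f3 - mean) / np.maximum(sd, floor)
    z[~np.isfinite(z)] = 0.0
    return z


def _scan_mask(shape: tuple[int, ...], skip_first_radial_bin: bool) -> np.ndarray:
    """Cells eligible for significance scanning.

    The innermost radial bin of r1/r2 has a near-zero sector area, so a
    single chance count there produces an enormous density fluctuation
    (the analog of the self/merge artifact bin excluded from g(r)
    fits); it is excluded from detection and calibration by default.
    """
    mask = np.ones(shape, dtype=bool)
    if skip_first_radial_bin and shape[0] > 1 and shape[1] > 1:
        mask[0, :, :] = False
        mask[:, 0, :] = False
    return mask


def null_max_z(nulls: list[TCMap], skip_first_radial_bin: bool = True) -> np.ndarray:
    """Maximum cell z of each null map against the rest of the ensemble.

    Leave-one-out z-scoring of every null realization yields the null
    distribution of the map-wide maximum statistic, which calibrates a
    family-wise detection threshold across the thousands of grid cells.
    """
    maxima = np.empty(len(nulls))
    scan = None
    for i, m in enumerate(nulls):
        rest = nulls[:i] + nulls[i + 1 :]
        mean, sd = null_statistics(rest)
        if scan is None:
            scan = _scan_mask(m.f3.shape, skip_first_radial_bin)
        maxima[i] = _z_score(m.f3, mean, sd)[scan].max()
    return maxima


def find_tc_triplets(
    observed: TCMap,
    nulls: list[TCMap],
    z_threshold: float = 3.0,
    fwer_alpha: float | None = 0.05,
) -> list[TCTriplet]:
    """Significant recurrent triplet geometries, ordered by z.

    Cells of the (r1, r2, r3) grid with z >= ``z_threshold`` are grouped
    into connected above-threshold regions; each region is reported as
    one triplet at its mode cell (largest z, ties broken by smaller
    r1 + r2 + r3).

    Because the grid holds thousands of cells, the per-cell threshold
    alone does not control the scene-level false-positive rate.  With
    ``fwer_alpha`` set (default 0.05) the effective threshold is raised
    to the (1 - alpha) quantile of the null ensemble's own maximum-z
    distribution (leave-one-out), a max-statistic family-wise
    calibration; pass ``fwer_alpha=None`` for the raw per-cell rule.
    """
    z = z_map(observed, nulls)
    threshold = z_threshold
    if fwer_alpha is not None:
        maxima = np.sort(null_max_z(nulls))
        # order statistic giving exact exceedance <= alpha for the observed
        # map among n+1 exchangeable realizations (k = ceil((1-a)(n+1)))
        k = min(len(maxima), int(np.ceil((1.0 - fwer_alpha) * (len(maxima) + 1))))
        threshold = max(z_threshold, float(maxima[k - 1]))
    mask = (z >= threshold) & _scan_mask(z.shape, skip_first_radial_bin=True)
    if not mask.any():
        return []
    labels, n_lab = ndimage.label(mask)
    triplets = []
    r1c = observed.r_centers_nm
    r3c = observed.r3_centers_nm
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)
        zs = z[tuple(idx.T)]
        best_z = zs.max()
        cand = idx[zs >= best_z - 1e-12]
        if len(cand) > 1:
            sums = r1c[cand[:, 0]] + r1c[cand[:, 1]] + r3c[cand[:, 2]]
            cand = cand[[int(np.argmin(sums))]]
        i, j, k = (int(v) for v in cand[0])
        triplets.append(
            TCTriplet(
                r1_nm=float(r1c[i]),
                r2_nm=float(r1c[j]),
                r3_nm=float(r3c[k]),
                f=float(observed.f3[i, j, k]),
                z=float(z[i, j, k]),
                index=(i, j, k),
                channels=observed.channels,
            )
        )
    triplets.sort(key=lambda t: -t.z)
    return triplets


def conditional_density(
    field1: LocalizationField,
    field2: LocalizationField,
    field3: LocalizationField,
    triplet: TCTriplet,
    tc_map: TCMap | None = None,
    **tc_kwargs,
) -> float:
    """Conditional local density C3 (points/µm²) at a triplet geometry.

    C3 = <d_rho1 d_rho2 d_rho3> / <d_rho1 d_rho2> evaluated at the
    triplet's cells: the fluctuation-product numerator is averaged over
    the angular-offset cells mapping into the triplet's r3 bin and
    divided by the visit-averaged channel-2 fluctuation at the r1 bin.
    Raises when the pair-correlation denominator is non-positive (no
    significant channel-1/2 pair support at r1).
    """
    m = tc_map if tc_map is not None else compute_tc_map(field1, field2, field3, **tc_kwargs)
    i, j, k = triplet.index
    dr = m.bin_width_nm
    r3_vals = r3_transform(
        m.r_centers_nm[i], m.r_centers_nm[j], np.pi - np.abs(_shift_angles(m.n_theta))
    )
    d_cells = np.flatnonzero(
        np.minimum((r3_vals / dr).astype(int), len(m.r3_centers_nm) - 1) == k
    )
    if d_cells.size == 0:
        raise ValueError("triplet geometry maps to no angular cell on this grid")
    numerator = float(m.num23[i, j, d_cells].mean())  # nm^-4
    denominator = float(m.mean_d2[i])  # nm^-2
    if denominator <= 0:
        raise ValueError("no significant channel-1/2 pair support at r1 (denominator <= 0)")
    return numerator / denominator * 1e6  # nm^-2 -> um^-2


def brute_force_triplets(
    field1: LocalizationField,
    field2: LocalizationField,
    field3: LocalizationField,
    geometry: tuple[float, float, float],
    tolerance_nm: float,
) -> int:
    """Exhaustive O(N1 N2 N3) count of triplets matching a geometry.

    Counts point triples (p1, p2, p3) whose pairwise distances satisfy
    |d12 - r1| <= tol, |d13 - r2| <= tol and |d23 - r3| <= tol, where
    (r1, r2, r3) follow the TC convention: r1 = channel-1/2 distance,
    r2 = channel-1/3 distance, r3 = channel-2/3 distance.
    """
    if tolerance_nm <= 0:
        raise ValueError("tolerance must be positive")
    r1, r2, r3 = geometry
    if field1.n == 0 or field2.n == 0 or field3.n == 0:
        return 0
    xy1, xy2, xy3 = field1.xy, field2.xy, field3.xy
    d23 = np.linalg.norm(xy2[:, None, :] - xy3[None, :, :], axis=-1)
    ok23 = np.abs(d23 - r3) <= tolerance_nm
    count = 0
    for p in xy1:
        m12 = np.abs(np.linalg.norm(xy2 - p, axis=1) - r1) <= tolerance_nm
        if not m12.any():
            continue
        m13 = np.abs(np.linalg.norm(xy3 - p, axis=1) - r2) <= tolerance_nm
        if not m13.any():
            continue
        count += int(ok23[np.ix_(m12, m13)].sum())
    return count


def triplet_frequency(
    fields: tuple[LocalizationField, LocalizationField, LocalizationField],
    triplets: list[TCTriplet],
    reference_pattern_count: int,
    tolerance_nm: float | None = None,
) -> TripletFrequencyResult:
    """Frequency of the top significant pattern per reference pattern.

    The instance count is the brute-force triplet count at the most
    significant geometry with tolerance one grid bin (or
    ``tolerance_nm``), normalized by the co-analyzed reference-pattern
    count.  With no significant triplet the frequency is 0.
    """
    if reference_pattern_count <= 0:
        raise ValueError("reference pattern count must be positive")
    if not triplets:
        return TripletFrequencyResult(0.0, 0, reference_pattern_count)
    top = triplets[0]
    tol = tolerance_nm if tolerance_nm is not None else 20.0
    n = brute_force_triplets(
        fields[0], fields[1], fields[2], (top.r1_nm, top.r2_nm, top.r3_nm), tol
    )
    return TripletFrequencyResult(n / reference_pattern_count, n, reference_pattern_count)
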