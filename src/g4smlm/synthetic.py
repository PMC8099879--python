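"""Synthetic data with known ground truth for the whole pipeline.

Generators for (i) sCMOS camera frames of point emitters under the
Poisson-shot-noise / Gaussian-read-noise model, (ii) CSR (complete
spatial randomness) localization fields, (iii) multi-channel nuclear
scenes with planted three-species triplet patterns at fixed geometry —
the synthetic analog of recurrent replisome/G4 arrangements — and
(iv) two-state smFRET trajectories from a continuous-time Markov chain.

Every generator is seeded and returns its ground truth so that
parameter-recovery tests can compare estimates against the planted
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import ROI, LocalizationField
from .localization import CameraCalibration, ImageStack, _psf_1d
from .smfret import FretTrajectory

__all__ = [
    "SceneSpec",
    "FretSimSpec",
    "make_calibration",
    "simulate_frames",
    "generate_point_field",
    "generate_cluster_field",
    "generate_triplet_scene",
    "simulate_fret_trajectories",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a planted three-channel triplet scene.

    ``triplet_geometry`` holds the pairwise distances (nm) between the
    channel-1/2, channel-1/3 and channel-2/3 sites of each planted
    triplet; it must satisfy the triangle inequality.
    """

    roi_size: float = 6000.0
    background_density: tuple[float, float, float] = (20.0, 20.0, 20.0)
    n_triplets: int = 50
    triplet_geometry: tuple[float, float, float] = (100.0, 100.0, 100.0)
    molecules_per_site: tuple[float, float, float] = (8.0, 8.0, 8.0)
    site_sigma: float = 10.0
    detection_efficiency: tuple[float, float, float] = (0.8, 0.8, 0.8)
    localization_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.background_density):
            raise ValueError("background densities must be non-negative")
        r12, r13, r23 = self.triplet_geometry
        if not (r12 + r13 >= r23 and r12 + r23 >= r13 and r13 + r23 >= r12):
            raise ValueError("triplet geometry violates the triangle inequality")
        if not all(0 <= p <= 1 for p in self.detection_efficiency):
            raise ValueError("detection efficiencies must lie in [0, 1]")
        if self.n_triplets < 0 or self.roi_size <= 0:
            raise ValueError("n_triplets must be >= 0 and roi_size positive")


@dataclass(frozen=True)
class FretSimSpec:
    """Parameters of the two-state smFRET simulator.

    Rates are in s⁻¹ (folded→unfolded at ``k_unfold``, unfolded→folded
    at ``k_fold``); intensities in photons/frame; ``frame_time`` in
    seconds (30 ms default, matching 800-frame movies at ~33 Hz).
    """

    n_traj: int = 100
    n_frames: int = 800
    frame_time: float = 0.030
    k_unfold: float = 1.0
    k_fold: float = 1.0
    e_folded: float = 0.70
    e_unfolded: float = 0.25
    total_intensity: float = 1000.0
    noise_sigma: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_unfold < 0 or self.k_fold < 0:
            raise ValueError("rates must be non-negative")
        if not (0 < self.e_unfolded < 1 and 0 < self.e_folded < 1):
            raise ValueError("FRET efficiencies must lie in (0, 1)")
        if self.e_folded <= self.e_unfolded:
            raise ValueError("e_folded must exceed e_unfolded")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


# ---------------------------------------------------------------------------
# Camera frames


def make_calibration(
    shape: tuple[int, int],
    offset_adu: float = 100.0,
    offset_sd: float = 2.0,
    gain: float = 2.0,
    gain_sd: float = 0.05,
    read_noise_e: float = 1.5,
    seed: int = 0,
) -> CameraCalibration:
    """Draw per-pixel sCMOS calibration maps from normal distributions.

    Defaults are typical sCMOS values: offset 100 ± 2 ADU, gain
    2.0 ± 0.05 ADU/e⁻, read noise 1.5 e⁻ rms.
    """
    rng = np.random.default_rng(seed)
    offset = rng.normal(offset_adu, offset_sd, size=shape)
    gain_map = np.maximum(rng.normal(gain, gain_sd, size=shape), 0.1)
    read_var = (read_noise_e * gain_map) ** 2  # ADU²
    return CameraCalibration(offset=offset, gain=gain_map, read_var=read_var)


def expected_photoelectrons(
    emitters: list[tuple[float, float, float]],
    shape: tuple[int, int],
    psf_sigma_px: float,
    background: float,
) -> np.ndarray:
    """Noise-free expected photoelectron image (pixel-integrated PSF)."""
    h, w = shape
    mu = np.full((h, w), float(background))
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    for x, y, photons in emitters:
        ex, _ = _psf_1d(cols, x, psf_sigma_px)
        ey, _ = _psf_1d(rows, y, psf_sigma_px)
        mu += photons * np.outer(ey, ex)
    return mu


def simulate_frames(
    emitters: list[tuple[float, float, float]],
    calibration: CameraCalibration,
    psf_sigma_px: float = 1.1,
    background: float = 5.0,
    n_frames: int = 1,
    pixel_size_nm: float = 100.0,
    seed: int = 0,
) -> ImageStack:
    """Simulate raw camera frames of fixed emitters.

    Each pixel is ``offset + gain × Poisson(μ) + N(0, read-noise sd)``
    where μ is the background plus each emitter's photon flux
    integrated over the pixel under a 2D Gaussian PSF.  Emitter
    positions are in pixel units.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    h, w = calibration.shape
    for x, y, _ in emitters:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"emitter at ({x}, {y}) lies outside the {h}x{w} frame")
    rng = np.random.default_rng(seed)
    mu = expected_photoelectrons(emitters, (h, w), psf_sigma_px, background)
    frames = np.empty((n_frames, h, w))
    read_sd = np.sqrt(calibration.read_var)
    for f in range(n_frames):
        electrons = rng.poisson(mu)
        frames[f] = (
            calibration.offset
            + calibration.gain * electrons
            + rng.normal(0.0, 1.0, size=(h, w)) * read_sd
        )
    return ImageStack(frames=frames, calibration=calibration, pixel_size_nm=pixel_size_nm)


# ---------------------------------------------------------------------------
# Point fields and triplet scenes


def generate_point_field(
    density_um2: float,
    roi: ROI | float = 6000.0,
    channel: int = 0,
    seed: int = 0,
) -> LocalizationField:
    """Homogeneous Poisson (CSR) point field on the ROI."""
    if density_um2 < 0:
        raise ValueError("density must be non-negative")
    if not isinstance(roi, ROI):
        roi = ROI.square(float(roi))
    rng = np.random.default_rng(seed)
    n = rng.poisson(density_um2 * roi.area_um2)
    xy = np.column_stack(
        [
            rng.uniform(roi.x_min, roi.x_max, size=n),
            rng.uniform(roi.y_min, roi.y_max, size=n),
        ]
    )
    return LocalizationField(xy=xy, roi=roi, channel=channel)


def generate_cluster_field(
    n_clusters: int,
    molecules_per_cluster: float,
    cluster_sigma: float,
    roi: ROI | float = 6000.0,
    background_density_um2: float = 0.0,
    localization_sigma: float = 0.0,
    relocalizations: float = 1.0,
    channel: int = 0,
    seed: int = 0,
) -> tuple[LocalizationField, np.ndarray]:
    """Statistically homogeneous field of Gaussian clusters plus CSR background.

    Cluster centers are uniform on the full ROI and molecule
    coordinates wrap toroidally, so the global density matches the
    interior density (no boundary depletion).  Each cluster carries
    Poisson(``molecules_per_cluster``) molecules scattered with sd
    ``cluster_sigma``.  ``relocalizations`` is the mean number of
    localizations per molecule (1 + Poisson(relocalizations - 1)),
    each jittered independently by ``localization_sigma`` — the
    stochastic-resampling (blinking overcount) structure that the first
    term of the two-Gaussian correlation model describes.  Returns the
    field and the cluster-center ground truth.
    """
    if relocalizations < 1.0:
        raise ValueError("relocalizations must be >= 1")
    if not isinstance(roi, ROI):
        roi = ROI.square(float(roi))
    rng = np.random.default_rng(seed)
    centers = np.column_stack(
        [
            rng.uniform(roi.x_min, roi.x_max, size=n_clusters),
            rng.uniform(roi.y_min, roi.y_max, size=n_clusters),
        ]
    )
    molecules = []
    for cx, cy in centers:
        m = rng.poisson(molecules_per_cluster)
        if m == 0:
            continue
        molecules.append(
            np.column_stack(
                [rng.normal(cx, cluster_sigma, m), rng.normal(cy, cluster_sigma, m)]
            )
        )
    mol = np.vstack(molecules) if molecules else np.empty((0, 2))
    if mol.shape[0]:
        reps = 1 + rng.poisson(relocalizations - 1.0, size=mol.shape[0])
        xy = np.repeat(mol, reps, axis=0)
        if localization_sigma > 0:
            xy = xy + rng.normal(0.0, localization_sigma, size=xy.shape)
    else:
        xy = mol
    bg = generate_point_field(
        background_density_um2, roi, channel, seed=int(rng.integers(2**31))
    )
    xy = np.vstack([xy, bg.xy])
    # toroidal wrap keeps the point process homogeneous on the ROI
    xy[:, 0] = roi.x_min + np.mod(xy[:, 0] - roi.x_min, roi.width)
    xy[:, 1] = roi.y_min + np.mod(xy[:, 1] - roi.y_min, roi.height)
    return LocalizationField(xy=xy, roi=roi, channel=channel), centers


def _triplet_vertices(geometry: tuple[float, float, float]) -> np.ndarray:
    """Canonical triangle vertices (3, 2) with the given pairwise distances.

    Vertex 0 belongs to channel 1, vertex 1 to channel 2, vertex 2 to
    channel 3; d(0,1) = r12, d(0,2) = r13, d(1,2) = r23.
    """
    r12, r13, r23 = geometry
    x3 = (r12**2 + r13**2 - r23**2) / (2 * r12) if r12 > 0 else 0.0
    y3 = np.sqrt(max(r13**2 - x3**2, 0.0))
    v = np.array([[0.0, 0.0], [r12, 0.0], [x3, y3]])
    return v - v.mean(axis=0)


def generate_triplet_scene(
    spec: SceneSpec,
) -> tuple[tuple[LocalizationField, LocalizationField, LocalizationField], pd.DataFrame]:
    """Three-channel scene with planted triplet patterns and CSR background.

    ``n_triplets`` site triplets are placed uniformly (centroids in the
    ROI eroded by the largest vertex radius so no planted pattern
    straddles the boundary) with uniform orientation and random
    reflection.  Each vertex is dressed with Poisson molecules, thinned
    by the channel's detection efficiency and jittered by the
    localization error.  Ground truth lists every site coordinate.
    """
    rng = np.random.default_rng(spec.seed)
    roi = ROI.square(spec.roi_size)
    verts = _triplet_vertices(spec.triplet_geometry)
    radius = float(np.linalg.norm(verts, axis=1).max())
    margin = radius + 3.0 * spec.site_sigma + 3.0 * spec.localization_sigma
    inner = roi.erode(margin)

    truth_rows = []
    channel_pts: list[list[np.ndarray]] = [[], [], []]
    for t in range(spec.n_triplets):
        cx = rng.uniform(inner.x_min, inner.x_max)
        cy = rng.uniform(inner.y_min, inner.y_max)
        theta = rng.uniform(-np.pi, np.pi)
        flip = rng.integers(2) * 2 - 1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        v = verts.copy()
        v[:, 1] *= flip
        sites = v @ rot.T + np.array([cx, cy])
        for ch in range(3):
            sx, sy = sites[ch]
            truth_rows.append(
                {"triplet": t, "channel": ch + 1, "x_nm": sx, "y_nm": sy}
            )
            m = rng.poisson(spec.molecules_per_site[ch])
            if m == 0:
                continue
            mol = np.column_stack(
                [rng.normal(sx, spec.site_sigma, m), rng.normal(sy, spec.site_sigma, m)]
            ) if spec.site_sigma > 0 else np.tile([sx, sy], (m, 1))
            detected = mol[rng.uniform(size=m) < spec.detection_efficiency[ch]]
            channel_pts[ch].append(detected)

    fields = []
    for ch in range(3):
        xy = np.vstack(channel_pts[ch]) if channel_pts[ch] else np.empty((0, 2))
        if spec.localization_sigma > 0 and xy.shape[0]:
            xy = xy + rng.normal(0.0, spec.localization_sigma, size=xy.shape)
        bg = generate_point_field(
            spec.background_density[ch], roi, channel=ch + 1, seed=int(rng.integers(2**31))
        )
        xy = np.vstack([xy, bg.xy])
        keep = roi.contains(xy)
        fields.append(LocalizationField(xy=xy[keep], roi=roi, channel=ch + 1))
    truth = pd.DataFrame(truth_rows, columns=["triplet", "channel", "x_nm", "y_nm"])
    return (fields[0], fields[1], fields[2]), truth


# ---------------------------------------------------------------------------
# smFRET trajectories


def _sample_ctmc_path(
    rng: np.random.Generator,
    k_unfold: float,
    k_fold: float,
    n_frames: int,
    dt: float,
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Exact two-state CTMC sampled at frame starts.

    Returns the per-frame state (1 = folded, 0 = unfolded) and the list
    of continuous-time sojourns (state, duration) covering the movie.
    """
    total = k_unfold + k_fold
    p_folded = k_fold / total if total > 0 else 1.0
    state = 1 if rng.uniform() < p_folded else 0
    t_end = n_frames * dt
    t = 0.0
    path = np.empty(n_frames, dtype=np.int8)
    sojourns: list[tuple[int, float]] = []
    frame = 0
    while t < t_end:
        rate = k_unfold if state == 1 else k_fold
        dwell = rng.exponential(1.0 / rate) if rate > 0 else t_end - t + dt
        t_next = t + dwell
        while frame < n_frames and frame * dt < t_next:
            path[frame] = state
            frame += 1
        sojourns.append((state, min(dwell, t_end - t)))
        t = t_next
        state = 1 - state
    while frame < n_frames:  # pragma: no cover - numeric edge
        path[frame] = state
        frame += 1
    return path, sojourns


def simulate_fret_trajectories(
    spec: FretSimSpec,
) -> tuple[list[FretTrajectory], list[np.ndarray]]:
    """Simulate two-state smFRET movies with ground-truth state paths.

    The hidden state follows a continuous-time Markov chain
    (folded→unfolded at ``k_unfold``, unfolded→folded at ``k_fold``)
    sampled at the frame time.  Per frame, the acceptor mean is
    E_state × total_intensity and the donor mean the complement;
    independent Gaussian noise of sd ``noise_sigma`` is added to each
    channel.  The stationary unfolded occupancy is
    k_unfold / (k_unfold + k_fold).
    """
    rng = np.random.default_rng(spec.seed)
    trajs: list[FretTrajectory] = []
    paths: list[np.ndarray] = []
    e_by_state = np.array([spec.e_unfolded, spec.e_folded])
    for _ in range(spec.n_traj):
        path, _ = _sample_ctmc_path(
            rng, spec.k_unfold, spec.k_fold, spec.n_frames, spec.frame_time
        )
        e = e_by_state[path]
        acceptor = e * spec.total_intensity + rng.normal(0, spec.noise_sigma, spec.n_frames)
        donor = (1 - e) * spec.total_intensity + rng.normal(0, spec.noise_sigma, spec.n_frames)
        trajs.append(FretTrajectory(donor=donor, acceptor=acceptor, frame_time=spec.frame_time))
        paths.append(path)
    return trajs, paths
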