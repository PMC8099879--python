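"""Single-molecule localization from sCMOS camera stacks.

Pipeline: inverse-variance-weighted box filtering for background
estimation, local-maximum candidate detection, per-candidate maximum
likelihood fitting of a pixel-integrated 2D Gaussian PSF under the
per-pixel sCMOS noise model (Poisson shot noise convolved with Gaussian
read noise), Cramér–Rao lower bound (CRLB) precision estimates from the
Fisher information, merging of blinking events across consecutive
frames, and Gaussian-kernel rendering.

The sCMOS likelihood uses the standard variance-offset device: ADU
counts are converted to photoelectrons and the per-pixel read-noise
variance (in e⁻²) is added to both the data and the model expectation,
after which the compound noise is treated as Poisson.  The Fisher
information of that model yields the CRLB reported as the localization
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.special import erf

from .fields import ROI, LocalizationField

__all__ = [
    "CameraCalibration",
    "ImageStack",
    "PrecisionDistributionFit",
    "localize_stack",
    "fit_precision_distribution",
    "merge_blinking",
    "render_image",
]

#: Columns of a localization table (a pandas DataFrame).
TABLE_COLUMNS = [
    "channel",
    "x_nm",
    "y_nm",
    "frame",
    "photons",
    "background",
    "precision_nm",
    "crlb_x_nm2",
    "crlb_y_nm2",
    "multiplicity",
]


@dataclass(frozen=True)
class CameraCalibration:
    """Per-pixel sCMOS calibration maps.

    offset : ADU; gain : ADU per photoelectron; read_var : ADU².
    """

    offset: np.ndarray
    gain: np.ndarray
    read_var: np.ndarray

    def __post_init__(self) -> None:
        offset = np.asarray(self.offset, dtype=float)
        gain = np.asarray(self.gain, dtype=float)
        read_var = np.asarray(self.read_var, dtype=float)
        if not (offset.shape == gain.shape == read_var.shape):
            raise ValueError("calibration maps must share one shape")
        if np.any(gain <= 0):
            raise ValueError("gain must be positive everywhere")
        if np.any(read_var < 0):
            raise ValueError("read-noise variance must be non-negative")
        object.__setattr__(self, "offset", offset)
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "read_var", read_var)

    @property
    def shape(self) -> tuple[int, int]:
        return self.offset.shape

    @property
    def read_var_e2(self) -> np.ndarray:
        """Read-noise variance in photoelectrons² (var_ADU / gain²)."""
        return self.read_var / self.gain**2


@dataclass
class ImageStack:
    """Raw camera frames (frame, row, col) in ADU with calibration."""

    frames: np.ndarray
    calibration: CameraCalibration
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (frame, row, col) array")
        if self.frames.shape[1:] != self.calibration.shape:
            raise ValueError("frame shape does not match calibration maps")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class PrecisionDistributionFit:
    """Skew-Gaussian parameters of the precision distribution (QC)."""

    shape: float
    location: float
    scale: float


def empty_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in TABLE_COLUMNS})


# ---------------------------------------------------------------------------
# PSF model and MLE engine


def _psf_1d(centers: np.ndarray, mu: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-integrated 1D Gaussian and its derivative w.r.t. mu.

    Pixels are unit-width bins centred on integer ``centers``.
    """
    s2 = sigma * np.sqrt(2.0)
    hi = centers + 0.5 - mu
    lo = centers - 0.5 - mu
    val = 0.5 * (erf(hi / s2) - erf(lo / s2))
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    dval = norm * (np.exp(-(lo**2) / (2 * sigma**2)) - np.exp(-(hi**2) / (2 * sigma**2)))
    return val, dval


def _model_and_jac(theta, cols, rows, psf_sigma):
    x, y, n_ph, bg = theta
    ex, dex = _psf_1d(cols, x, psf_sigma)
    ey, dey = _psf_1d(rows, y, psf_sigma)
    psf = np.outer(ey, ex)
    mu = bg + n_ph * psf
    dmu = np.empty((4,) + mu.shape)
    dmu[0] = n_ph * np.outer(ey, dex)
    dmu[1] = n_ph * np.outer(dey, ex)
    dmu[2] = psf
    dmu[3] = 1.0
    return mu, dmu


def fit_emitter_window(
    window_e: np.ndarray,
    read_var_e2: np.ndarray,
    psf_sigma_px: float,
    x0: tuple[float, float, float, float] | None = None,
    max_iter: int = 400,
    tol: float = 1e-8,
) -> dict:
    """MLE fit of one emitter in a photoelectron-converted window.

    Parameters are (x, y) in pixel units relative to the window origin,
    total photons and uniform background (photons/pixel).  Returns the
    optimum, the CRLB variances of x and y (pixel²) from the inverse
    Fisher information, and a reduced chi-square-like residual used to
    flag crowded or misfit windows.
    """
    h, w = window_e.shape
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    q = window_e + read_var_e2  # variance-offset Poisson surrogate data
    q = np.maximum(q, 0.0)

    if x0 is None:
        bg0 = float(np.median(window_e))
        sig = np.clip(window_e - bg0, 0, None)
        tot = sig.sum()
        if tot <= 0:
            tot = 1.0
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        else:
            cx = float((sig * cols[None, :]).sum() / tot)
            cy = float((sig * rows[None, :]).sum() / tot)
        x0 = (cx, cy, max(tot, 10.0), max(bg0, 0.01))

    def nll_and_grad(theta):
        mu, dmu = _model_and_jac(theta, cols, rows, psf_sigma_px)
        mu_eff = mu + read_var_e2
        mu_eff = np.maximum(mu_eff, 1e-9)
        nll = float(np.sum(mu_eff - q * np.log(mu_eff)))
        w_res = 1.0 - q / mu_eff
        grad = np.array([float(np.sum(w_res * dmu[k])) for k in range(4)])
        return nll, grad

    bounds = [(-1.0, w), (-1.0, h), (1e-3, None), (0.0, None)]
    res = optimize.minimize(
        nll_and_grad,
        np.asarray(x0, dtype=float),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "maxfun": 4 * max_iter, "ftol": tol * 1e-4, "gtol": tol},
    )
    x, y, n_ph, bg = res.x
    mu, dmu = _model_and_jac(res.x, cols, rows, psf_sigma_px)
    mu_eff = np.maximum(mu + read_var_e2, 1e-9)
    fisher = np.einsum("aij,bij->ab", dmu / mu_eff[None], dmu)
    try:
        cov = np.linalg.inv(fisher)
        crlb_x, crlb_y = float(cov[0, 0]), float(cov[1, 1])
    except np.linalg.LinAlgError:
        crlb_x = crlb_y = np.nan
    chi2 = float(np.sum((q - mu_eff) ** 2 / mu_eff) / (q.size - 4))
    return {
        "x": float(x),
        "y": float(y),
        "photons": float(n_ph),
        "background": float(bg),
        "crlb_x_px2": crlb_x,
        "crlb_y_px2": crlb_y,
        "chi2": chi2,
        "converged": bool(res.success) or res.status == 1,
    }


def crlb_for_emitter(
    n_photons: float,
    background: float,
    psf_sigma_px: float,
    read_var_e2: float = 0.0,
    window: int = 7,
) -> tuple[float, float]:
    """CRLB variances of (x, y) in pixel² for a centred emitter.

    Independent closed-path evaluation of the Fisher information used
    by :func:`fit_emitter_window`; handy for efficiency checks.
    """
    c = (window - 1) / 2.0
    rows = cols = np.arange(window, dtype=float)
    mu, dmu = _model_and_jac((c, c, n_photons, background), cols, rows, psf_sigma_px)
    mu_eff = np.maximum(mu + read_var_e2, 1e-12)
    fisher = np.einsum("aij,bij->ab", dmu / mu_eff[None], dmu)
    cov = np.linalg.inv(fisher)
    return float(cov[0, 0]), float(cov[1, 1])


# ---------------------------------------------------------------------------
# Detection and stack processing


def _weighted_box_filter(img: np.ndarray, inv_var: np.ndarray, size: int) -> np.ndarray:
    num = ndimage.uniform_filter(img * inv_var, size=size, mode="nearest")
    den = ndimage.uniform_filter(inv_var, size=size, mode="nearest")
    return num / np.maximum(den, 1e-30)


def _find_candidates(diff: np.ndarray, threshold_sd: float, margin: int) -> np.ndarray:
    mad = np.median(np.abs(diff - np.median(diff)))
    noise_sd = 1.4826 * mad if mad > 0 else diff.std()
    if noise_sd == 0:
        return np.empty((0, 2), dtype=int)
    local_max = diff == ndimage.maximum_filter(diff, size=3, mode="nearest")
    mask = local_max & (diff > threshold_sd * noise_sd)
    mask[:margin] = mask[-margin:] = False
    mask[:, :margin] = mask[:, -margin:] = False
    return np.argwhere(mask)


def localize_stack(
    stack: ImageStack,
    psf_fwhm_px: float = 2.5,
    detection_threshold: float = 4.0,
    channel: int = 0,
    window: int = 7,
    photon_floor: float = 100.0,
    chi2_max: float = 3.0,
) -> pd.DataFrame:
    """Detect and fit emitters in every frame of a raw stack.

    Each frame is inverse-variance box-filtered (box = 4×FWHM) to
    estimate the low-frequency background; the low-pass image is
    subtracted from the raw frame and local maxima above
    ``detection_threshold`` robust noise sd become fit candidates.
    Every ``window``×``window`` region around a candidate is fitted by
    MLE under the per-pixel Poisson⊛Gaussian camera model with the PSF
    sd fixed from the FWHM.  Fits below ``photon_floor`` photons,
    non-converged fits and crowded windows (reduced residual above
    ``chi2_max``) are dropped.
    """
    if psf_fwhm_px <= 0:
        raise ValueError("psf_fwhm_px must be positive")
    cal = stack.calibration
    psf_sigma = psf_fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    box = int(round(4 * psf_fwhm_px)) | 1  # odd
    half = window // 2
    px = stack.pixel_size_nm

    # photoelectron conversion and per-pixel noise terms
    read_var_e2 = cal.read_var_e2
    inv_var = 1.0 / np.maximum(cal.read_var / cal.gain**2 + 1e-12, 1e-12)

    records: list[dict] = []
    for f in range(stack.n_frames):
        img_e = (stack.frames[f] - cal.offset) / cal.gain
        lowpass = _weighted_box_filter(img_e, inv_var, box)
        diff = img_e - lowpass
        for r, c in _find_candidates(diff, detection_threshold, half):
            win = img_e[r - half : r + half + 1, c - half : c + half + 1]
            win_var = read_var_e2[r - half : r + half + 1, c - half : c + half + 1]
            fit = fit_emitter_window(win, win_var, psf_sigma)
            if not fit["converged"] or fit["photons"] < photon_floor:
                continue
            if fit["chi2"] > chi2_max:
                continue
            if not (np.isfinite(fit["crlb_x_px2"]) and fit["crlb_x_px2"] > 0):
                continue
            crlb_x = fit["crlb_x_px2"] * px**2
            crlb_y = fit["crlb_y_px2"] * px**2
            records.append(
                {
                    "channel": channel,
                    "x_nm": (c - half + fit["x"]) * px,
                    "y_nm": (r - half + fit["y"]) * px,
                    "frame": f,
                    "photons": fit["photons"],
                    "background": fit["background"],
                    "precision_nm": np.sqrt(0.5 * (crlb_x + crlb_y)),
                    "crlb_x_nm2": crlb_x,
                    "crlb_y_nm2": crlb_y,
                    "multiplicity": 1,
                }
            )
    if not records:
        return empty_table()
    return pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Post-processing


def fit_precision_distribution(table: pd.DataFrame, min_records: int = 50) -> PrecisionDistributionFit:
    """Maximum-likelihood skew-Gaussian fit of the precision values."""
    prec = np.asarray(table["precision_nm"], dtype=float)
    prec = prec[np.isfinite(prec)]
    if prec.size < min_records:
        raise ValueError(f"need at least {min_records} records, got {prec.size}")
    if np.std(prec) == 0:
        raise ValueError("degenerate precision distribution (zero spread)")
    a, loc, scale = stats.skewnorm.fit(prec)
    return PrecisionDistributionFit(shape=float(a), location=float(loc), scale=float(scale))


def merge_blinking(table: pd.DataFrame, gate_sigma: float = 2.5) -> pd.DataFrame:
    """Collapse blinking events that reappear in consecutive frames.

    Localizations of one channel appearing in consecutive frames within
    ``gate_sigma`` times the candidate's own precision of the running
    inverse-variance-weighted mean position are chained and averaged
    into one record: position by inverse-CRLB-variance weighting,
    merged variance 1/Σ(1/varᵢ), photons summed, multiplicity = chain
    length.  Records with multiplicity > 1 are completed blinking
    events already: they pass through unchanged and neither extend nor
    join chains, which makes merging exactly idempotent.
    """
    if table.empty:
        return table.copy()
    out: list[dict] = []
    for _, sub in table.groupby("channel", sort=False):
        sub = sub.sort_values("frame", kind="stable")
        active: list[dict] = []
        closed: list[dict] = []
        for rec in sub.to_dict("records"):
            frame = int(rec["frame"])
            if int(rec.get("multiplicity", 1)) > 1:  # completed event
                wx0 = 1.0 / max(rec["crlb_x_nm2"], 1e-12)
                wy0 = 1.0 / max(rec["crlb_y_nm2"], 1e-12)
                closed.append(
                    {
                        "channel": rec["channel"], "start": frame, "end": frame,
                        "sx": wx0 * rec["x_nm"], "sy": wy0 * rec["y_nm"],
                        "wx": wx0, "wy": wy0, "photons": rec["photons"],
                        "background": rec["background"],
                        "mult": int(rec["multiplicity"]),
                    }
                )
                continue
            end = frame
            # retire chains ending before frame-1
            still = []
            for ch in active:
                (still if ch["end"] >= frame - 1 else closed).append(ch)
            active = still
            wx = 1.0 / max(rec["crlb_x_nm2"], 1e-12)
            wy = 1.0 / max(rec["crlb_y_nm2"], 1e-12)
            gate = gate_sigma * rec["precision_nm"]
            best, best_d = None, np.inf
            for ch in active:
                if ch["end"] != frame - 1:
                    continue
                d = np.hypot(ch["sx"] / ch["wx"] - rec["x_nm"], ch["sy"] / ch["wy"] - rec["y_nm"])
                if d <= gate and d < best_d:
                    best, best_d = ch, d
            if best is None:
                active.append(
                    {
                        "channel": rec["channel"],
                        "start": frame,
                        "end": end,
                        "sx": wx * rec["x_nm"],
                        "sy": wy * rec["y_nm"],
                        "wx": wx,
                        "wy": wy,
                        "photons": rec["photons"],
                        "background": rec["background"],
                        "mult": int(rec.get("multiplicity", 1)),
                    }
                )
            else:
                best["end"] = end
                best["sx"] += wx * rec["x_nm"]
                best["sy"] += wy * rec["y_nm"]
                best["wx"] += wx
                best["wy"] += wy
                best["photons"] += rec["photons"]
                best["mult"] += int(rec.get("multiplicity", 1))
        closed.extend(active)
        for ch in closed:
            var_x = 1.0 / ch["wx"]
            var_y = 1.0 / ch["wy"]
            out.append(
                {
                    "channel": ch["channel"],
                    "x_nm": ch["sx"] * var_x,
                    "y_nm": ch["sy"] * var_y,
                    "frame": ch["start"],
                    "photons": ch["photons"],
                    "background": ch["background"],
                    "precision_nm": np.sqrt(0.5 * (var_x + var_y)),
                    "crlb_x_nm2": var_x,
                    "crlb_y_nm2": var_y,
                    "multiplicity": ch["mult"],
                }
            )
    df = pd.DataFrame.from_records(out, columns=TABLE_COLUMNS)
    return df.sort_values(
        ["channel", "frame", "x_nm", "y_nm"], kind="stable"
    ).reset_index(drop=True)


def render_image(
    field: LocalizationField,
    pixel_size_nm: float = 10.0,
    kernel_sigma_nm: float = 10.0,
) -> np.ndarray:
    """Render localizations onto a canvas with a Gaussian kernel.

    A 2D histogram on a ``pixel_size_nm`` grid over the field's ROI is
    convolved with a Gaussian of sd ``kernel_sigma_nm``.  Total rendered
    mass equals the record count up to kernel truncation at the canvas
    boundary.
    """
    if pixel_size_nm <= 0 or kernel_sigma_nm <= 0:
        raise ValueError("pixel size and kernel sigma must be positive")
    roi = field.roi
    nx = max(int(np.ceil(roi.width / pixel_size_nm)), 1)
    ny = max(int(np.ceil(roi.height / pixel_size_nm)), 1)
    if field.n == 0:
        return np.zeros((ny, nx))
    hist, _, _ = np.histogram2d(
        field.xy[:, 1],
        field.xy[:, 0],
        bins=(ny, nx),
        range=[[roi.y_min, roi.y_min + ny * pixel_size_nm], [roi.x_min, roi.x_min + nx * pixel_size_nm]],
    )
    return ndimage.gaussian_filter(
        hist, sigma=kernel_sigma_nm / pixel_size_nm, mode="constant", truncate=6.0
    )
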