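"""Two-state smFRET trajectory analysis for G-quadruplex fold/unfold kinetics.

A surface-tethered DNA construct carries a donor/acceptor pair flanking
a G4-forming sequence: the folded structure gives high FRET efficiency,
the unfolded state low efficiency.  This module turns donor/acceptor
intensity time series into frame-wise efficiencies, decomposes the
pooled efficiency histogram into folded/unfolded Gaussian components,
idealizes each trajectory with a two-state Gaussian-emission hidden
Markov model (EM-trained, Viterbi paths), and fits single-exponential
dwell-time distributions to obtain the unfolding rate k_unfold (from
folded-state dwells) and the folding rate k_fold (from unfolded-state
dwells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "FretTrajectory",
    "FretHistogramFit",
    "RateFit",
    "fret_efficiency",
    "fit_fret_histogram",
    "idealize_two_state",
    "fit_rates",
    "extract_dwells",
]

#: Frames whose total intensity falls below this fraction of the median
#: total are masked as dark/bleached.
DARK_FRACTION = 0.10


@dataclass
class FretTrajectory:
    """Donor/acceptor intensity time series of one molecule.

    frame_time is in seconds (default 30 ms).
    """

    donor: np.ndarray
    acceptor: np.ndarray
    frame_time: float = 0.030

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float).ravel()
        self.acceptor = np.asarray(self.acceptor, dtype=float).ravel()
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor must have equal length")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")

    def __len__(self) -> int:
        return self.donor.shape[0]


@dataclass(frozen=True)
class FretHistogramFit:
    """Two-Gaussian decomposition of a pooled efficiency histogram.

    Component 0 is the low-efficiency (unfolded) population, component 1
    the high-efficiency (folded) one.  ``unfolded_fraction`` is the
    low-E area divided by the total area.
    """

    means: tuple[float, float]
    sds: tuple[float, float]
    areas: tuple[float, float]
    unfolded_fraction: float
    collapsed: bool = False

    @property
    def mean_unfolded(self) -> float:
        return self.means[0]

    @property
    def mean_folded(self) -> float:
        return self.means[1]


@dataclass(frozen=True)
class RateFit:
    """Exponential dwell-time fits for the two-state system (s⁻¹)."""

    k_unfold: float
    k_unfold_sd: float
    k_fold: float
    k_fold_sd: float
    n_dwells_folded: int
    n_dwells_unfolded: int


def fret_efficiency(traj: FretTrajectory) -> np.ma.MaskedArray:
    """Frame-wise FRET efficiency E = a / (a + d), clipped to [0, 1].

    Frames with non-positive total intensity, or total below
    ``DARK_FRACTION`` of the median total, are masked (dark/bleached).
    """
    total = traj.donor + traj.acceptor
    med = np.median(total[total > 0]) if np.any(total > 0) else 0.0
    bad = (total <= 0) | (total < DARK_FRACTION * med)
    if bad.all():
        warnings.warn("all frames dark; efficiency fully masked")
        return np.ma.masked_all(total.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, traj.acceptor / np.where(total > 0, total, 1.0), 0.0)
    e = np.clip(e, 0.0, 1.0)
    return np.ma.masked_array(e, mask=bad)


def pooled_efficiencies(trajs: list[FretTrajectory]) -> np.ndarray:
    """Unmasked frame-wise efficiencies pooled across trajectories."""
    return np.concatenate([fret_efficiency(t).compressed() for t in trajs])


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2)


def fit_fret_histogram(trajs: list[FretTrajectory], n_bins: int = 50) -> FretHistogramFit:
    """Fit two independent Gaussians to the pooled efficiency histogram.

    Initial component centers come from the two highest well-separated
    histogram peaks; component areas (amplitude × sd × √(2π)) give the
    unfolded fraction.  If the optimizer collapses onto one mode the fit
    is returned with ``collapsed=True``.
    """
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories")
    e = pooled_efficiencies(trajs)
    counts, edges = np.histogram(e, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # peak-seeded init: histogram maxima in the low and high halves
    lo_half = counts[: n_bins // 2]
    hi_half = counts[n_bins // 2 :]
    m1_0 = centers[np.argmax(lo_half)] if lo_half.any() else 0.25
    m2_0 = centers[n_bins // 2 + np.argmax(hi_half)] if hi_half.any() else 0.75
    p0 = [max(lo_half.max(), 1), m1_0, 0.08, max(hi_half.max(), 1), m2_0, 0.08]
    bounds = ([0, 0, 1e-3, 0, 0, 1e-3], [np.inf, 1, 0.5, np.inf, 1, 0.5])
    try:
        popt, _ = optimize.curve_fit(
            _two_gauss, centers, counts, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise ValueError(f"two-Gaussian histogram fit failed: {exc}") from exc
    a1, m1, s1, a2, m2, s2 = popt
    # order components low-E first
    if m1 > m2:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    area1 = a1 * s1 * np.sqrt(2 * np.pi)
    area2 = a2 * s2 * np.sqrt(2 * np.pi)
    total = area1 + area2
    collapsed = bool(abs(m2 - m1) < 2 * max(s1, s2) or min(area1, area2) < 1e-3 * total)
    return FretHistogramFit(
        means=(float(m1), float(m2)),
        sds=(float(s1), float(s2)),
        areas=(float(area1), float(area2)),
        unfolded_fraction=float(area1 / total) if total > 0 else np.nan,
        collapsed=collapsed,
    )


# ---------------------------------------------------------------------------
# Idealization


def idealize_two_state(
    efficiencies: list[np.ndarray] | np.ndarray,
    init_means: tuple[float, float] | None = None,
) -> list[np.ndarray]:
    """Assign each frame to the unfolded (0) or folded (1) state.

    A two-state Gaussian-emission hidden Markov model is EM-trained on
    the pooled efficiency sequences (means initialized from the
    histogram peaks unless ``init_means`` is given) and the most likely
    Viterbi path is returned per trajectory.  State 1 is the
    higher-mean (folded, high-FRET) state.  If EM degenerates, frames
    are thresholded at the midpoint of the initial means.
    """
    from hmmlearn.hmm import GaussianHMM

    if isinstance(efficiencies, np.ndarray):
        seqs = [np.asarray(efficiencies, dtype=float).ravel()]
    else:
        seqs = [np.asarray(e, dtype=float).ravel() for e in efficiencies]
    if min(len(s) for s in seqs) < 10:
        raise ValueError("each series must have at least 10 frames")
    pooled = np.concatenate(seqs)
    if np.ptp(pooled) < 1e-12:
        return [np.zeros(len(s), dtype=np.int8) for s in seqs]
    if init_means is None:
        counts, edges = np.histogram(pooled, bins=50, range=(0.0, 1.0))
        centers = 0.5 * (edges[:-1] + edges[1:])
        lo = centers[np.argmax(counts[:25])] if counts[:25].any() else 0.25
        hi = centers[25 + np.argmax(counts[25:])] if counts[25:].any() else 0.75
        if hi - lo < 0.05:  # single-mode data: split around the mean
            lo, hi = pooled.mean() - 0.1, pooled.mean() + 0.1
        init_means = (lo, hi)

    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=100,
        tol=1e-5,
        init_params="",
        params="stmc",
        random_state=0,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
    model.means_ = np.array(init_means, dtype=float).reshape(2, 1)
    var0 = max(pooled.std() / 2, 0.02) ** 2
    model.covars_ = np.full((2, 1), var0)
    X = pooled.reshape(-1, 1)
    lengths = [len(s) for s in seqs]
    degenerate = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, lengths)
        means = model.means_.ravel()
        degenerate = abs(means[1] - means[0]) < 1e-3
    except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
        degenerate = True
    if degenerate:
        warnings.warn("HMM collapsed; falling back to midpoint threshold")
        mid = float(np.mean(init_means))
        return [(s > mid).astype(np.int8) for s in seqs]
    # enforce state 1 = high-FRET folded
    order = np.argsort(model.means_.ravel())
    paths = []
    for s in seqs:
        raw = model.predict(s.reshape(-1, 1))
        paths.append(np.asarray(order.argsort()[raw], dtype=np.int8))
    return paths


# ---------------------------------------------------------------------------
# Dwell times and rates


def extract_dwells(
    paths: list[np.ndarray], frame_time: float, drop_censored: bool = True
) -> dict[int, np.ndarray]:
    """Dwell durations (seconds) per state from idealized paths.

    The first and last dwell of every trajectory are censored (their
    true duration extends beyond the observation window) and excluded
    by default.
    """
    dwells: dict[int, list[float]] = {0: [], 1: []}
    for path in paths:
        path = np.asarray(path)
        if path.size == 0:
            continue
        change = np.flatnonzero(np.diff(path)) + 1
        bounds = np.concatenate([[0], change, [path.size]])
        runs = list(zip(bounds[:-1], bounds[1:]))
        if drop_censored:
            runs = runs[1:-1]
        for a, b in runs:
            dwells[int(path[a])].append((b - a) * frame_time)
    return {s: np.asarray(v) for s, v in dwells.items()}


def _exp_mle(dwells: np.ndarray) -> tuple[float, float]:
    """Exponential-rate MLE and its sd (information matrix): k = 1/mean."""
    k = 1.0 / dwells.mean()
    return k, k / np.sqrt(dwells.size)


def fit_rates(
    paths: list[np.ndarray], frame_time: float, min_dwells: int = 10
) -> RateFit:
    """Exponential dwell-time fits: k_unfold from folded-state dwells,
    k_fold from unfolded-state dwells.

    Censored (first/last) dwells are excluded; rates are maximum
    likelihood on the dwell durations with sd k/√n from the Fisher
    information.  Degenerate dwell sets (all durations equal) raise.
    """
    dwells = extract_dwells(paths, frame_time)
    folded, unfolded = dwells[1], dwells[0]
    if folded.size < min_dwells:
        raise ValueError(f"too few complete folded-state dwells ({folded.size} < {min_dwells})")
    if unfolded.size < min_dwells:
        raise ValueError(f"too few complete unfolded-state dwells ({unfolded.size} < {min_dwells})")
    for name, d in (("folded", folded), ("unfolded", unfolded)):
        if np.ptp(d) == 0:
            raise ValueError(f"degenerate {name}-state dwell set (all durations equal)")
    k_unfold, k_unfold_sd = _exp_mle(folded)
    k_fold, k_fold_sd = _exp_mle(unfolded)
    return RateFit(
        k_unfold=k_unfold,
        k_unfold_sd=k_unfold_sd,
        k_fold=k_fold,
        k_fold_sd=k_fold_sd,
        n_dwells_folded=int(folded.size),
        n_dwells_unfolded=int(unfolded.size),
    )
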