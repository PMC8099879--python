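"""Condition summaries, figure-legend statistics, and table I/O.

Covers the dataset-level statistics used to compare experimental
conditions (mean ± s.e.m. summaries, percent change with first-order
error propagation, unpaired two-sample t-tests) and the CSV round-trip
for localization tables and smFRET trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .localization import TABLE_COLUMNS, empty_table
from .smfret import FretTrajectory

__all__ = [
    "GroupSummary",
    "percent_change",
    "two_sample_ttest",
    "read_localizations",
    "write_localizations",
    "read_fret_trajectories",
    "write_fret_trajectories",
]

REQUIRED_COLUMNS = ["channel", "x_nm", "y_nm", "frame", "photons", "precision_nm"]


@dataclass(frozen=True)
class GroupSummary:
    """Per-condition scene-level summary (mean ± sd, s.e.m. = sd/√n)."""

    label: str
    values: tuple[float, ...]
    mean: float
    sd: float
    sem: float
    n: int

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 1:
            raise ValueError("need at least one value")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(
            label=label,
            values=tuple(float(x) for x in v),
            mean=float(v.mean()),
            sd=sd,
            sem=sd / np.sqrt(v.size),
            n=int(v.size),
        )


def percent_change(reference: GroupSummary, treated: GroupSummary) -> tuple[float, float]:
    """Percent change of treated vs reference with propagated s.e.m.

    pct = 100 (m_t - m_r) / m_r; the uncertainty follows first-order
    propagation of the independent group means:
    s.e.m. = 100 (m_t / m_r) sqrt((s_r / m_r)^2 + (s_t / m_t)^2)
    with s the group s.e.m. values.
    """
    if reference.mean == 0:
        raise ValueError("reference mean is zero; percent change undefined")
    m_r, m_t = reference.mean, treated.mean
    s_r, s_t = reference.sem, treated.sem
    pct = 100.0 * (m_t - m_r) / m_r
    if m_t == 0:
        sem = 100.0 * s_t / abs(m_r)
    else:
        sem = 100.0 * abs(m_t / m_r) * np.sqrt((s_r / m_r) ** 2 + (s_t / m_t) ** 2)
    return float(pct), float(sem)


def two_sample_ttest(
    group_a, group_b, equal_var: bool = False, variance_floor: float = 1e-12
) -> tuple[float, float]:
    """Unpaired two-sample t-test (Welch by default).

    Zero-variance degenerate inputs are handled with a small variance
    floor so that groups with different means return a finite,
    very large |t| instead of infinity; identical groups give
    (t, p) = (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        se = np.sqrt(variance_floor / a.size + variance_floor / b.size)
        t = (a.mean() - b.mean()) / se
        df = a.size + b.size - 2
        p = 2 * stats.t.sf(abs(t), df)
        return float(t), float(p)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# CSV I/O


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization table, validating the required columns.

    Unknown extra columns are preserved; a missing required column or a
    non-numeric coordinate raises with the offending name or row.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    if df.empty:
        out = empty_table()
        for col in df.columns:
            if col not in out.columns:
                out[col] = pd.Series(dtype=df[col].dtype)
        return out
    for col in ("x_nm", "y_nm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric {col} at row {row}: {df[col].iloc[row]!r}")
        df[col] = coerced
    if "multiplicity" not in df.columns:
        df["multiplicity"] = 1
    return df


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.to_csv(path, index=False, columns=cols)


def write_fret_trajectories(trajs: list[FretTrajectory], path: str | Path) -> None:
    """Write trajectories as long-form CSV (trajectory, frame, donor, acceptor)."""
    rows = []
    for i, t in enumerate(trajs):
        rows.append(
            pd.DataFrame(
                {
                    "trajectory": i,
                    "frame": np.arange(len(t)),
                    "donor": t.donor,
                    "acceptor": t.acceptor,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_fret_trajectories(path: str | Path, frame_time: float = 0.030) -> list[FretTrajectory]:
    df = pd.read_csv(path)
    for col in ("trajectory", "frame", "donor", "acceptor"):
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    trajs = []
    for _, sub in df.groupby("trajectory", sort=True):
        sub = sub.sort_values("frame")
        trajs.append(
            FretTrajectory(
                donor=sub["donor"].to_numpy(float),
                acceptor=sub["acceptor"].to_numpy(float),
                frame_time=frame_time,
            )
        )
    return trajs
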