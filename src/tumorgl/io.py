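"""CSV interchange for trajectories and fit results.

One flat long-format schema serves every trajectory the package reads
or writes: columns ``subject_id, arm, time_days, size, unit`` (extra
columns are preserved on read but ignored).  Fit results serialize to a
flat table mirroring the effective-parameter summaries: phase label,
a_eff, a_err, k_eff, k_err, corr, rms_rel_err, n_points.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .trajectory import TumorTrajectory

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "fit_results_frame",
    "write_fit_results",
    "rates_frame",
]

REQUIRED_COLUMNS = ("subject_id", "arm", "time_days", "size", "unit")
_FLOAT_FMT = "%.10g"  # fixed format keeps identical runs byte-identical


def read_trajectories(path) -> list[TumorTrajectory]:
    """Read long-format trajectory CSV into per-subject trajectories.

    Rows are grouped by subject, sorted by time.  Errors carry the
    offending row number (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "arm": str, "unit": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    rows = df.index.to_numpy() + 2  # +2: header plus 1-based indexing
    for col in ("time_days", "size"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            r = rows[bad.to_numpy()][0]
            raise ValueError(f"{path}: non-numeric {col} at row {r}")
        df[col] = numeric
    nonpos = (df["size"] <= 0).to_numpy()
    if nonpos.any():
        r = rows[nonpos][0]
        raise ValueError(f"{path}: non-positive size at row {r}")

    out: list[TumorTrajectory] = []
    for subject, grp in df.groupby("subject_id", sort=True):
        dup = grp["time_days"].duplicated()
        if dup.any():
            r = int(grp.index[dup.to_numpy()][0]) + 2
            raise ValueError(
                f"{path}: duplicate time for subject {subject!r} at row {r}"
            )
        grp = grp.sort_values("time_days")
        out.append(
            TumorTrajectory(
                times=grp["time_days"].to_numpy(float),
                sizes=grp["size"].to_numpy(float),
                subject_id=str(subject),
                arm=str(grp["arm"].iloc[0]),
                unit_label=str(grp["unit"].iloc[0]),
            )
        )
    return out


def write_trajectories(trajectories: Iterable[TumorTrajectory], path) -> None:
    """Write trajectories to the long-format CSV schema (deterministic bytes)."""
    frames = [t.to_frame() for t in trajectories]
    if not frames:
        raise ValueError("no trajectories to write")
    df = pd.concat(frames, ignore_index=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def fit_results_frame(results: Sequence[FitResult],
                      subject_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Flat effective-parameter table, one row per fitted phase."""
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "subject_id": subject_ids[i] if subject_ids else "",
                "phase": r.phase_label,
                "a_eff": r.params.a_eff,
                "a_err": r.a_err,
                "k_eff": r.params.k_eff,
                "k_err": r.k_err,
                "a_linear_time": r.params.a_linear_time,
                "t0": r.params.t0,
                "n_t0": r.params.n_t0,
                "corr": r.correlation_coefficient,
                "rms_rel_err": r.rms_relative_error,
                "n_points": r.n_points,
                "regime": r.params.regime,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def write_fit_results(results: Sequence[FitResult], path,
                      subject_ids: Sequence[str] | None = None) -> None:
    df = fit_results_frame(results, subject_ids)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def rates_frame(series_by_subject: dict[str, "np.ndarray"]) -> pd.DataFrame:
    """Specific-rate table: subject_id, time_days, specific_rate."""
    rows = []
    for subject, series in series_by_subject.items():
        for t, r in zip(series.times, series.rates):
            rows.append({"subject_id": subject, "time_days": t, "specific_rate": r})
    return pd.DataFrame(rows)
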