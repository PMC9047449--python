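"""Sigmoidal fitting of feature time courses and transition-time selection.

Each feature series is analysed in sliding 13-point windows.  Within a
window the series is normalized to start at zero — relative change
``(x - x1) / x1`` for size-like features (optical volume, cell area, mean
central/peripheral phase), plain difference ``x - x1`` otherwise — and
fitted by the logistic

    f(t) = Amplitude / (1 + exp(Gain * (Cutoff - t)))

with the Cutoff fixed at the window's candidate time point.  ``Amplitude``
is the total (signed) change, ``Gain`` the rate in 1/h.  For fixed Gain
the optimal Amplitude is a closed-form least-squares solution, so the fit
reduces to a bounded 1-D search over Gain (coarse grid + Brent
refinement); the R^2 of the fit is evaluated on the normalized window.

The cell-level transition time ``T`` is the candidate cutoff at which the
largest number of features reach R^2 >= 0.7 (majority vote; earliest time
wins ties).  Each feature's final fit is then the one maximizing
``|Amplitude * Gain|`` among cutoffs within [T, T + 2 h], accommodating
features that change later than the bulk transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .synthetic import FEATURE_NAMES, RELATIVE_FEATURES, sigmoid

__all__ = [
    "SigmoidFit",
    "CellDynamicsRecord",
    "normalize_window",
    "fit_sigmoid_fixed_cutoff",
    "select_transition_time",
    "final_fit",
    "fit_cell",
    "fit_cohort",
]

WINDOW = 13
R2_THRESHOLD = 0.7
T_RANGE_H = 2.0
GAIN_BOUNDS = (-20.0, 20.0)

_GAIN_GRID = np.concatenate(
    [
        -np.geomspace(0.05, GAIN_BOUNDS[1], 24)[::-1],
        [0.0],
        np.geomspace(0.05, GAIN_BOUNDS[1], 24),
    ]
)


@dataclass(frozen=True)
class SigmoidFit:
    """One feature's fitted transition within one window."""

    feature: str
    amplitude: float
    gain: float  # 1/h
    cutoff: float  # h
    r2: float
    window_start: int
    kind: str  # "relative" or "additive"


@dataclass
class CellDynamicsRecord:
    """Per-cell summary: transition time, 11 final fits, sigmoidal count."""

    track_id: int
    transition_time: float | None
    fits: dict[str, SigmoidFit] = field(default_factory=dict)
    n_sigmoidal: int = 0
    class_label: str | None = None

    @property
    def transitioning(self) -> bool:
        return self.transition_time is not None


def feature_kind(feature: str) -> str:
    return "relative" if feature in RELATIVE_FEATURES else "additive"


def normalize_window(series: Sequence[float], kind: str) -> np.ndarray:
    """Normalize a window to start at zero (relative or additive)."""
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    if kind == "relative":
        if x[0] == 0:
            raise ValueError("relative normalization undefined: first value is 0")
        return (x - x[0]) / x[0]
    if kind == "additive":
        return x - x[0]
    raise ValueError(f"unknown normalization kind {kind!r}")


def _profiled_sse(y: np.ndarray, t: np.ndarray, cutoff: float, gains: np.ndarray):
    """SSE minimized over Amplitude, per candidate Gain (vectorized)."""
    x = np.clip(np.outer(gains, cutoff - t), -500.0, 500.0)
    s = 1.0 / (1.0 + np.exp(x))  # (G, T)
    ss = np.einsum("gt,gt->g", s, s)
    sy = s @ y
    amp = np.divide(sy, ss, out=np.zeros_like(sy), where=ss > 1e-12)
    sse = np.sum(y**2) - amp * sy
    return amp, np.maximum(sse, 0.0)


def fit_sigmoid_fixed_cutoff(
    series: Sequence[float],
    timepoints: Sequence[float],
    cutoff: float,
    gain_bounds: tuple[float, float] = GAIN_BOUNDS,
) -> tuple[float, float, float]:
    """Least-squares (Amplitude, Gain, R^2) at a fixed Cutoff.

    Amplitude is profiled out analytically per Gain; the Gain is located
    by a coarse signed log-grid over ``gain_bounds`` followed by bounded
    Brent refinement.  A constant series yields Amplitude 0 and, by
    convention, R^2 = 0 (a flat series must never count as a good
    sigmoidal fit).
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("series and timepoints must be 1-D and equally long")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(t)) and np.isfinite(cutoff)):
        raise ValueError("non-finite inputs")
    grid = _GAIN_GRID[(_GAIN_GRID >= gain_bounds[0]) & (_GAIN_GRID <= gain_bounds[1])]
    amps, sses = _profiled_sse(y, t, cutoff, grid)
    k = int(np.argmin(sses))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]

    def sse_of(g: float) -> float:
        return float(_profiled_sse(y, t, cutoff, np.array([g]))[1][0])

    gain = float(grid[k])
    best_sse = float(sses[k])
    if hi > lo:
        res = minimize_scalar(sse_of, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        if res.fun <= best_sse:
            gain, best_sse = float(res.x), float(res.fun)
    amp = float(_profiled_sse(y, t, cutoff, np.array([gain]))[0][0])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - best_sse / ss_tot
    return amp, gain, r2


def candidate_window_starts(n_points: int, window: int = WINDOW) -> np.ndarray:
    """Window start per candidate cutoff index (centred, clamped to bounds)."""
    if n_points < window:
        raise ValueError(f"need at least {window} points, got {n_points}")
    k = np.arange(n_points)
    return np.clip(k - window // 2, 0, n_points - window)


def fit_feature_all_cutoffs(
    series: Sequence[float],
    timepoints: Sequence[float],
    kind: str,
    window: int = WINDOW,
) -> pd.DataFrame:
    """Windowed fits of one feature at every candidate cutoff.

    Returns a frame indexed by the candidate's time index with columns
    (amplitude, gain, r2, cutoff, window_start).
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    starts = candidate_window_starts(len(y), window)
    rows = []
    for k, start in enumerate(starts):
        win = slice(start, start + window)
        if not np.all(np.isfinite(y[win])):
            # rejected masks inside the window: no fit at this cutoff
            rows.append(
                {"amplitude": 0.0, "gain": 0.0, "r2": 0.0, "cutoff": t[k],
                 "window_start": int(start)}
            )
            continue
        y_n = normalize_window(y[win], kind)
        amp, gain, r2 = fit_sigmoid_fixed_cutoff(y_n, t[win], t[k])
        rows.append(
            {"amplitude": amp, "gain": gain, "r2": r2, "cutoff": t[k],
             "window_start": int(start)}
        )
    return pd.DataFrame(rows)


def select_transition_time(
    r2_matrix: np.ndarray, timepoints: Sequence[float], threshold: float = R2_THRESHOLD
) -> tuple[float | None, np.ndarray]:
    """Majority-vote transition time from an (features x cutoffs) R^2 grid.

    ``count_k`` is the number of features with R^2 >= threshold at cutoff
    k; T is the earliest cutoff maximizing the count.  When no feature
    fits anywhere the cell is non-transitioning and T is ``None``.
    """
    r2 = np.asarray(r2_matrix, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if r2.ndim != 2 or r2.shape[1] != t.size:
        raise ValueError("R^2 matrix must be (n_features, n_cutoffs)")
    counts = np.sum(r2 >= threshold, axis=0)
    if counts.max() == 0:
        return None, counts
    return float(t[int(np.argmax(counts))]), counts


def final_fit(
    fits: pd.DataFrame,
    feature: str,
    kind: str,
    transition_time: float,
    t_range: float = T_RANGE_H,
) -> SigmoidFit:
    """Select the feature's final fit: max |Amplitude x Gain| in [T, T+2].

    ``fits`` is the per-cutoff table from :func:`fit_feature_all_cutoffs`.
    If no candidate falls in the range (short movie) the feature has no
    fit and is recorded with Amplitude 0 and R^2 0.
    """
    sel = fits[
        (fits["cutoff"] >= transition_time - 1e-9)
        & (fits["cutoff"] <= transition_time + t_range + 1e-9)
    ]
    if sel.empty:
        return SigmoidFit(feature, 0.0, 0.0, transition_time, 0.0, 0, kind)
    best = sel.loc[(sel["amplitude"] * sel["gain"]).abs().idxmax()]
    return SigmoidFit(
        feature,
        float(best["amplitude"]),
        float(best["gain"]),
        float(best["cutoff"]),
        float(best["r2"]),
        int(best["window_start"]),
        kind,
    )


def fit_cell(
    feature_table: pd.DataFrame,
    track_id: int | None = None,
    window: int = WINDOW,
    threshold: float = R2_THRESHOLD,
    t_range: float = T_RANGE_H,
) -> CellDynamicsRecord:
    """Full dynamics analysis of one cell's feature table.

    ``feature_table`` holds one row per frame with a ``t_hours`` column
    and the 11 feature columns.  Features with any non-finite value
    (degenerate masks) are excluded from the vote and recorded with an
    empty fit.  Requires at least ``window`` frames.
    """
    df = feature_table.sort_values("t_hours").reset_index(drop=True)
    t = df["t_hours"].to_numpy(dtype=float)
    if len(t) < window:
        raise ValueError(f"need at least {window} frames, got {len(t)}")
    if track_id is None:
        track_id = int(df["track_id"].iloc[0]) if "track_id" in df else 0
    per_feature: dict[str, pd.DataFrame] = {}
    r2_rows = []
    for feature in FEATURE_NAMES:
        series = df[feature].to_numpy(dtype=float)
        if not np.any(np.isfinite(series)):
            r2_rows.append(np.zeros(len(t)))
            continue
        fits = fit_feature_all_cutoffs(series, t, feature_kind(feature), window)
        per_feature[feature] = fits
        r2_rows.append(fits["r2"].to_numpy())
    r2_matrix = np.vstack(r2_rows)
    transition_time, counts = select_transition_time(r2_matrix, t, threshold)
    record = CellDynamicsRecord(track_id=track_id, transition_time=transition_time)
    if transition_time is None:
        for feature in FEATURE_NAMES:
            record.fits[feature] = SigmoidFit(
                feature, 0.0, 0.0, np.nan, 0.0, 0, feature_kind(feature)
            )
        record.n_sigmoidal = 0
        return record
    for feature in FEATURE_NAMES:
        kind = feature_kind(feature)
        if feature in per_feature:
            record.fits[feature] = final_fit(
                per_feature[feature], feature, kind, transition_time, t_range
            )
        else:
            record.fits[feature] = SigmoidFit(feature, 0.0, 0.0, np.nan, 0.0, 0, kind)
    record.n_sigmoidal = int(counts.max())
    return record


def fit_cohort(
    feature_table: pd.DataFrame,
    window: int = WINDOW,
    threshold: float = R2_THRESHOLD,
    t_range: float = T_RANGE_H,
) -> tuple[pd.DataFrame, list[CellDynamicsRecord]]:
    """Fit every track in a long-format feature table.

    Returns a tidy fits table (track_id, feature, amplitude, gain,
    cutoff, r2, window_start, kind, transition_time, n_sigmoidal) plus
    the per-cell records.
    """
    records = []
    rows = []
    for track_id, group in feature_table.groupby("track_id", sort=True):
        rec = fit_cell(group, int(track_id), window, threshold, t_range)
        records.append(rec)
        for feature, fit in rec.fits.items():
            rows.append(
                {
                    "track_id": rec.track_id,
                    "feature": feature,
                    "amplitude": fit.amplitude,
                    "gain": fit.gain,
                    "cutoff": fit.cutoff,
                    "r2": fit.r2,
                    "window_start": fit.window_start,
                    "kind": fit.kind,
                    "transition_time": rec.transition_time
                    if rec.transition_time is not None
                    else np.nan,
                    "n_sigmoidal": rec.n_sigmoidal,
                }
            )
    return pd.DataFrame(rows), records
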