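"""Trajectory QC, smoothing, instantaneous speed, standardisation, PCA.

The quality-control rules mirror a live-cell migration workflow: drop
debris and aggregates by size (cell area above the Tukey fence
Q3 + 1.5*IQR of all cell areas; nuclear area below 100 um^2), and drop
duplicated or merged nucleus/cell trajectories. Retained trajectories
are smoothed with a centred rolling mean (window 9) before computing the
instantaneous cell speed (ICS) per frame interval.

Quantile convention: Q1/Q3 use linear interpolation between order
statistics (numpy default). Window edges: the smoothing window shrinks
symmetrically to the largest odd size that fits (a "truncate" mode that
drops half-window frames at each end is available instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

__all__ = [
    "QCReport",
    "PCAResult",
    "qc_filter",
    "smooth_trajectory",
    "instantaneous_speed",
    "zscore",
    "pca",
]


@dataclass
class QCReport:
    """Counts of removed records per rule and the thresholds used."""

    n_input: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed": dict(self.removed),
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
        }


def _tukey_fence(values: np.ndarray, k: float) -> float:
    q3 = float(np.quantile(values, 0.75))  # linear interpolation
    q1 = float(np.quantile(values, 0.25))
    return q3 + k * (q3 - q1)


def qc_filter(
    table: pd.DataFrame,
    nucleus_min_area: float = 100.0,
    iqr_k: float = 1.5,
    cell_area_max: float | None = None,
    track_columns: tuple[str, ...] | None = None,
    centroid_columns: tuple[str, str] = ("nucleus_centroid_x", "nucleus_centroid_y"),
) -> tuple[pd.DataFrame, QCReport]:
    """Remove oversized cells, undersized nuclei and bad trajectories.

    Rules, in order: (a) records whose cell area exceeds
    ``cell_area_max`` (default: Q3 + iqr_k*IQR of all input cell areas);
    (b) records with nucleus area below ``nucleus_min_area`` (um^2);
    (c) duplicated trajectories — two tracks in the same group sharing
    at least 50% identical centroid records (the higher track id is
    dropped whole) — and merged trajectories, where two tracks occupy
    identical centroids at the same frame (both dropped whole). Rule (c)
    runs only when ``track_columns`` is given and the centroid columns
    exist.

    Passing the fitted ``cell_area_max`` back in (it is recorded in the
    report) makes the filter exactly idempotent.
    """
    for col in ("cell_area", "nucleus_area"):
        if col not in table.columns:
            raise KeyError(f"qc_filter requires column '{col}'")
    n_input = len(table)
    report = QCReport(n_input=n_input, n_retained=n_input)
    if n_input == 0:
        report.removed = {"oversized_cell": 0, "undersized_nucleus": 0,
                          "duplicated_trajectory": 0, "merged_trajectory": 0}
        return table.copy(), report

    if cell_area_max is None:
        cell_area_max = _tukey_fence(table["cell_area"].to_numpy(float), iqr_k)
    report.thresholds = {
        "cell_area_max": cell_area_max,
        "nucleus_min_area": nucleus_min_area,
        "iqr_k": iqr_k,
    }

    keep = table["cell_area"].to_numpy(float) <= cell_area_max
    report.removed["oversized_cell"] = int((~keep).sum())

    small = table["nucleus_area"].to_numpy(float) < nucleus_min_area
    report.removed["undersized_nucleus"] = int((keep & small).sum())
    keep &= ~small

    report.removed["duplicated_trajectory"] = 0
    report.removed["merged_trajectory"] = 0
    cx, cy = centroid_columns
    if track_columns and cx in table.columns and cy in table.columns:
        sub = table.loc[keep]
        drop_tracks: set[tuple] = set()
        group_cols = list(track_columns[:-1])
        tid_col = track_columns[-1]
        grouped = sub.groupby(group_cols, sort=False) if group_cols else [((), sub)]
        for gkey, grp in grouped:
            gkey = _as_tuple(gkey)
            tracks = {
                tid: set(zip(g["frame"], np.round(g[cx], 9), np.round(g[cy], 9)))
                for tid, g in grp.groupby(tid_col, sort=True)
            }
            tids = sorted(tracks)
            for i, a in enumerate(tids):
                for b in tids[i + 1:]:
                    shared = tracks[a] & tracks[b]
                    if not shared:
                        continue
                    frac = len(shared) / min(len(tracks[a]), len(tracks[b]))
                    if frac >= 0.5:  # duplicated: keep the lower track id
                        drop_tracks.add((gkey, b, "duplicated_trajectory"))
                    else:  # two tracks colliding on one record: merged
                        drop_tracks.add((gkey, a, "merged_trajectory"))
                        drop_tracks.add((gkey, b, "merged_trajectory"))
        if drop_tracks:
            full_key = list(
                map(tuple, table[group_cols + [tid_col]].itertuples(index=False))
            )
            for key, tid, rule in sorted(
                drop_tracks, key=lambda t: (str(t[0]), str(t[1]))
            ):
                target = (*key, tid)
                mask = np.array([k == target for k in full_key], dtype=bool)
                hit = keep & mask
                report.removed[rule] += int(hit.sum())
                keep &= ~mask

    out = table.loc[keep].copy()
    report.n_retained = len(out)
    return out, report


def _as_tuple(key) -> tuple:
    return key if isinstance(key, tuple) else (key,)


def smooth_trajectory(
    xy: np.ndarray, window: int = 9, mode: str = "shrink"
) -> np.ndarray:
    """Centred moving average of an (n, d) position array.

    ``mode='shrink'`` shrinks the window symmetrically near the ends to
    the largest odd size that fits; ``mode='truncate'`` returns NaN for
    the half-window frames at each end.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    xy = np.asarray(xy, dtype=float)
    squeeze = xy.ndim == 1
    if squeeze:
        xy = xy[:, None]
    n = len(xy)
    half = window // 2
    out = np.full_like(xy, np.nan)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        if mode == "shrink":
            out[i] = xy[i - h : i + h + 1].mean(axis=0)
        elif mode == "truncate":
            if h == half:
                out[i] = xy[i - half : i + half + 1].mean(axis=0)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out[:, 0] if squeeze else out


def instantaneous_speed(xy: np.ndarray, frame_interval: float) -> np.ndarray:
    """ICS in um/min from a smoothed (n, 2) trajectory.

    One value per inter-frame interval, assigned to the later frame: an
    n-frame trajectory yields n-1 speeds (73 frames on the 5-minute,
    6-hour schedule give 72 values). A single-point trajectory yields an
    empty series.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return np.empty(0)
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return disp / frame_interval


def zscore(table: pd.DataFrame, feature_cols: list[str]) -> pd.DataFrame:
    """Standardise each feature to mean 0 and sample SD 1 (pooled).

    Zero-variance features are dropped with a warning.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 observations")
    out = table.copy()
    for col in feature_cols:
        x = out[col].to_numpy(float)
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"dropping zero-variance feature '{col}'", stacklevel=2)
            out = out.drop(columns=col)
            continue
        out[col] = (x - x.mean()) / sd
    return out


@dataclass
class PCAResult:
    """Loadings, scores and explained-variance fractions.

    Sign convention: within each component the largest-magnitude loading
    is positive, so results are deterministic across runs and solvers.
    """

    loadings: pd.DataFrame  # feature x component
    scores: pd.DataFrame  # observation x component
    explained_variance_ratio: np.ndarray


def pca(table: pd.DataFrame, feature_cols: list[str], n_components: int | None = None) -> PCAResult:
    """Principal component analysis of a z-scored feature table."""
    X = table[list(feature_cols)].to_numpy(float)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 observations")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # feature x component
    # deterministic sign: largest |loading| positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{j+1}" for j in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=list(feature_cols), columns=names),
        scores=pd.DataFrame(scores, index=table.index, columns=names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
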