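"""Cumulative-variability curves over the design hierarchy.

A hypothetical study of increasing complexity is emulated by
enumerating every consistent subdataset: k (2 or 3) units chosen at one
level (replicates, experiments, persons, or laboratories) that share a
single complete ancestry path, with all units below them complete. The
per-subdataset statistic is the sample variance of the technical
replicate means of the chosen feature; its distribution per level traces
how variability accumulates as higher design levels are allowed to vary.
A label-randomisation control permutes the replicate means across the
design positions before the same enumeration, flattening any real
hierarchy structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubdatasetSpec",
    "CUMULATIVE_LEVELS",
    "enumerate_subdatasets",
    "cumulative_variance",
    "cumulative_curve",
    "randomized_control",
    "level_means",
]

#: Levels at which subdatasets are formed, innermost to outermost, with
#: the hierarchy columns that identify a unit at that level.
CUMULATIVE_LEVELS = {
    "replicate": ("lab", "person", "experiment", "replicate"),
    "experiment": ("lab", "person", "experiment"),
    "person": ("lab", "person"),
    "laboratory": ("lab",),
}


@dataclass(frozen=True)
class SubdatasetSpec:
    """k units at one level sharing one complete parent path."""

    level: str
    k: int
    parent_path: tuple
    units: tuple

    def replicate_paths(self, replicate_index: pd.MultiIndex) -> pd.MultiIndex:
        """All replicate paths covered by this subdataset."""
        depth = len(self.parent_path)
        sel = [
            p
            for p in replicate_index
            if p[:depth] == self.parent_path and p[depth] in self.units
        ]
        return pd.MultiIndex.from_tuples(sel, names=replicate_index.names)


def _replicate_index(table: pd.DataFrame) -> pd.MultiIndex:
    cols = list(CUMULATIVE_LEVELS["replicate"])
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"table is missing hierarchy column(s): {missing}")
    if "condition" in table.columns and table["condition"].nunique() > 1:
        raise ValueError(
            "cumulative-variability curves are computed within one condition; "
            "filter the table first"
        )
    return pd.MultiIndex.from_frame(table[cols].drop_duplicates()).sortlevel()[0]


def enumerate_subdatasets(table: pd.DataFrame, level: str, k: int) -> list[SubdatasetSpec]:
    """All duplicate-free consistent subdatasets at one level.

    The count equals (number of complete parent paths above the level)
    x C(units at that level, k).
    """
    if level not in CUMULATIVE_LEVELS:
        raise ValueError(f"unknown level {level!r}; use one of {list(CUMULATIVE_LEVELS)}")
    reps = _replicate_index(table)
    cols = CUMULATIVE_LEVELS[level]
    depth = len(cols) - 1  # parent path length
    units_df = pd.DataFrame(list(reps), columns=reps.names)[list(cols)].drop_duplicates()

    out = []
    for parent, grp in _group_by_parent(units_df, depth):
        units = sorted(grp.iloc[:, -1].unique())
        if k > len(units):
            raise ValueError(
                f"k={k} exceeds the {len(units)} unit(s) available under {parent!r}"
            )
        for combo in itertools.combinations(units, k):
            out.append(SubdatasetSpec(level=level, k=k, parent_path=parent, units=combo))
    return out


def _group_by_parent(units_df: pd.DataFrame, depth: int):
    if depth == 0:
        yield (), units_df
    else:
        for key, grp in units_df.groupby(list(units_df.columns[:depth]), sort=True):
            yield (key if isinstance(key, tuple) else (key,)), grp


def _replicate_means(table: pd.DataFrame, feature: str) -> pd.Series:
    cols = list(CUMULATIVE_LEVELS["replicate"])
    return table.groupby(cols, sort=True)[feature].mean()


def cumulative_variance(
    sub: SubdatasetSpec, table: pd.DataFrame, feature: str
) -> float:
    """Sample variance of per-replicate feature means in one subdataset."""
    means = _replicate_means(table, feature)
    sel = sub.replicate_paths(means.index)
    vals = means.loc[sel]
    if len(vals) < 2:
        raise ValueError("subdataset covers fewer than 2 replicate means")
    return float(np.var(vals, ddof=1))


def cumulative_curve(
    table: pd.DataFrame,
    feature: str,
    ks: tuple[int, ...] = (2, 3),
    levels: tuple[str, ...] = ("replicate", "experiment", "person", "laboratory"),
    _means: pd.Series | None = None,
) -> pd.DataFrame:
    """Cumulative-variance distribution at each level.

    Returns one row per (level, k, subdataset) with its variance; the
    level means are the curve usually plotted.
    """
    means = _replicate_means(table, feature) if _means is None else _means
    rows = []
    for level in levels:
        for k in ks:
            for i, sub in enumerate(enumerate_subdatasets(table, level, k)):
                sel = sub.replicate_paths(means.index)
                vals = means.loc[sel]
                rows.append(
                    {
                        "level": level,
                        "k": k,
                        "subdataset": i,
                        "parent": "/".join(map(str, sub.parent_path)) or "-",
                        "units": "+".join(map(str, sub.units)),
                        "variance": float(np.var(vals, ddof=1)),
                    }
                )
    return pd.DataFrame(rows)


def randomized_control(
    table: pd.DataFrame,
    feature: str,
    seed: int,
    ks: tuple[int, ...] = (2, 3),
    levels: tuple[str, ...] = ("replicate", "experiment", "person", "laboratory"),
) -> pd.DataFrame:
    """Same curves after permuting replicate means across design paths.

    Permutation happens at the replicate-mean level (within-replicate
    structure is preserved), so real hierarchy structure is destroyed
    while the marginal distribution of replicate means is kept. A fixed
    seed gives an identical permutation and curve.
    """
    means = _replicate_means(table, feature)
    rng = np.random.default_rng(seed)
    permuted = pd.Series(
        rng.permutation(means.to_numpy()), index=means.index, name=means.name
    )
    return cumulative_curve(table, feature, ks=ks, levels=levels, _means=permuted)


def level_means(curve: pd.DataFrame) -> pd.Series:
    """Mean cumulative variance per level (the red-dot curve)."""
    order = [l for l in ("replicate", "experiment", "person", "laboratory")
             if l in set(curve["level"])]
    return curve.groupby("level")["variance"].mean().reindex(order)


def plot_cumulative(curve: pd.DataFrame, control: pd.DataFrame | None = None,
                    path=None, feature: str = ""):
    """Boxplots of the cumulative-variance distributions per level, with
    the per-level means connected; optionally overlay the randomised
    control's mean curve. Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [l for l in ("replicate", "experiment", "person", "laboratory")
             if l in set(curve["level"])]
    fig, ax = plt.subplots(figsize=(6, 4))
    data = [curve.loc[curve.level == l, "variance"] for l in order]
    ax.boxplot(data, tick_labels=order)
    means = level_means(curve)
    ax.plot(range(1, len(order) + 1), means[order], "o-", color="crimson",
            label="mean")
    if control is not None:
        cm = level_means(control)
        ax.plot(range(1, len(order) + 1), cm[order], "o-", color="darkcyan",
                label="randomised control")
    ax.set_ylabel(f"variance of replicate means{' (' + feature + ')' if feature else ''}")
    ax.set_xlabel("varied design level")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
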