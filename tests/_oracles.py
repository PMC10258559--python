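"""Independent reference implementations used only to check results.

Each oracle takes the slow-but-obvious route (dense covariance algebra,
per-pixel coordinate sets, exhaustive enumeration, optimal assignment)
so it shares no code path with the package implementation it validates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.optimize import linear_sum_assignment


def dense_neg2ll(table, spec, value_col, sigma2, sigma2_res):
    """-2 log L of the nested model via the explicit marginal covariance."""
    y = table[value_col].to_numpy(float)
    n = len(y)
    if spec.fixed_condition is not None:
        cond = table[spec.fixed_condition]
        labels = sorted(cond.unique())
        if "control" in labels:
            labels = ["control", *[l for l in labels if l != "control"]]
        X = np.column_stack([np.ones(n), (cond == labels[1]).astype(float)])
    else:
        X = np.ones((n, 1))
    V = sigma2_res * np.eye(n)
    for lvl in spec.levels:
        cols = list(spec.path_for(lvl))
        codes = pd.factorize(pd.MultiIndex.from_frame(table[cols]))[0]
        Z = (codes[:, None] == np.arange(codes.max() + 1)[None, :]).astype(float)
        V += sigma2[lvl] * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    sign, ld = np.linalg.slogdet(V)
    return n * math.log(2 * math.pi) + ld + r @ Vi @ r


def dense_ml_fit(table, spec, value_col, starts):
    """Best dense-covariance ML optimum found from the given log-variance
    starting points; returns the minimised -2 log L."""

    def fun(theta):
        sigma2 = {l: math.exp(t) for l, t in zip(spec.levels, theta[:-1])}
        try:
            return dense_neg2ll(table, spec, value_col, sigma2, math.exp(theta[-1]))
        except np.linalg.LinAlgError:
            return 1e12

    best = math.inf
    k = len(spec.levels) + 1
    for t0 in starts:
        res = scipy.optimize.minimize(
            fun,
            np.asarray(t0, dtype=float)[:k],
            method="L-BFGS-B",
            bounds=[(-30.0, 12.0)] * k,
            options={"maxiter": 500, "ftol": 1e-13},
        )
        best = min(best, float(res.fun))
    return best


def pixel_set_regions(masks: list[np.ndarray], label: int):
    """Per-frame protrusion/retraction/short-lived pixel counts for one
    label, using explicit coordinate sets."""
    coords = [
        {(int(y), int(x)) for y, x in zip(*np.nonzero(m == label))} for m in masks
    ]
    out = []
    for t in range(len(masks)):
        prev = coords[t - 1] if t > 0 else None
        nxt = coords[t + 1] if t < len(masks) - 1 else None
        prot = len(coords[t] - prev) if prev is not None else None
        ret = len(coords[t] - nxt) if nxt is not None else None
        short = (
            len(coords[t] - prev - nxt)
            if prev is not None and nxt is not None
            else None
        )
        out.append((prot, ret, short))
    return out


def rolling_mean_bruteforce(x: np.ndarray, window: int) -> np.ndarray:
    """Shrinking symmetric centred mean, one window at a time."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = x[i - h : i + h + 1].mean()
    return out


def optimal_matching_count(seg, ann, radius) -> int:
    """Maximum-cardinality one-to-one matching within the radius, via
    optimal assignment on a penalised cost matrix."""
    seg = np.atleast_2d(seg)
    ann = np.atleast_2d(ann)
    if len(seg) == 0 or len(ann) == 0:
        return 0
    d = np.linalg.norm(seg[:, None, :] - ann[None, :, :], axis=2)
    cost = np.where(d <= radius, d, 1e9)
    rows, cols = linear_sum_assignment(cost)
    return int(np.sum(d[rows, cols] <= radius))


def greedy_link_oracle(prev_pts, prev_ids, pts, labels, max_dist):
    """Frame-to-frame links by exhaustive distance-ordered assignment."""
    pairs = sorted(
        (
            (np.linalg.norm(np.asarray(p) - np.asarray(q)), pid, j)
            for pid, p in zip(prev_ids, prev_pts)
            for j, q in enumerate(pts)
            if np.linalg.norm(np.asarray(p) - np.asarray(q)) <= max_dist
        ),
        key=lambda t: (t[0], t[1], labels[t[2]]),
    )
    used_p, used_c, links = set(), set(), {}
    for _, pid, j in pairs:
        if pid in used_p or j in used_c:
            continue
        links[j] = pid
        used_p.add(pid)
        used_c.add(j)
    return links


def enumerate_subdatasets_bruteforce(table, level, k):
    """Exhaustive subdataset enumeration straight from the raw paths."""
    cols = {
        "replicate": ["lab", "person", "experiment", "replicate"],
        "experiment": ["lab", "person", "experiment"],
        "person": ["lab", "person"],
        "laboratory": ["lab"],
    }[level]
    paths = sorted(set(map(tuple, table[cols].drop_duplicates().itertuples(index=False))))
    parents = sorted({p[:-1] for p in paths})
    out = []
    for parent in parents:
        units = sorted({p[-1] for p in paths if p[:-1] == parent})
        for combo in itertools.combinations(units, k):
            out.append((parent, combo))
    return out
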