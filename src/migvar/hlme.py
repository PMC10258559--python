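"""Nested random-intercept linear mixed model, fitted by maximum likelihood.

The model for an observation y under unit path (lab, person, experiment,
replicate, cell) at one time point is

    y = beta0 + delta * 1[treated] + u_lab + u_person + u_experiment
        + u_replicate + u_cell + eps,

with each random intercept u ~ N(0, sigma2_level) independent across
units and levels, and eps i.i.d. N(0, sigma2_residual) across time
points (the residual variance is the temporal variability).

Because the levels are strictly nested, the marginal covariance of the
data is hierarchically block structured, and the Gaussian likelihood can
be evaluated exactly in O(n) by integrating the random effects out level
by level: each unit is collapsed with a rank-one Woodbury update of its
sufficient statistics (X'V^-1 X, X'V^-1 y, y'V^-1 y, log|V|, and the
projections onto the unit's all-ones vector), then summed into its
parent. Fixed effects are profiled out by generalised least squares, so
the optimiser works on the variance parameters only (on the log scale,
which enforces non-negativity; variances whose unconstrained optimum is
negative are reported as exactly zero after a pinned refit).

Random-intercept predictions (BLUPs) are obtained from Henderson's
mixed-model equations, solved sparsely.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "HLMEModelSpec",
    "FittedHLME",
    "VarianceTable",
    "StructureError",
    "ConvergenceError",
    "STUDY_MODEL",
    "fit_nested_lme",
    "predict_random_intercepts",
    "decompose_variance",
]


class StructureError(ValueError):
    """The table's keys do not form the nested structure the model needs."""


class ConvergenceError(RuntimeError):
    """Optimiser failed; carries the last iterate in ``last_estimates``."""

    def __init__(self, message, last_estimates=None):
        super().__init__(message)
        self.last_estimates = last_estimates


@dataclass(frozen=True)
class HLMEModelSpec:
    """Which columns form the nested random levels and the fixed effects.

    Parameters
    ----------
    levels
        Random-intercept level columns, outermost to innermost.
    path_columns
        All key columns, outermost to innermost, used to identify units;
        must contain ``levels`` as a subsequence. Extra columns (e.g. a
        condition column sitting between experiment and replicate) make
        unit identities unambiguous when labels repeat across parents.
        Defaults to ``levels``.
    fixed_condition
        Column holding a two-level treatment label; adds a treatment
        fixed effect delta to the intercept. ``None`` fits the
        intercept-only model.
    """

    levels: tuple[str, ...]
    path_columns: tuple[str, ...] | None = None
    fixed_condition: str | None = None

    def __post_init__(self):
        if not self.levels:
            raise ValueError("at least one random level is required")
        cols = self.path_columns
        if cols is not None:
            it = iter(cols)
            if not all(lv in it for lv in self.levels):
                raise StructureError(
                    "path_columns must contain levels as an ordered subsequence"
                )

    @property
    def paths(self) -> tuple[str, ...]:
        return self.path_columns if self.path_columns is not None else self.levels

    def path_for(self, level: str) -> tuple[str, ...]:
        cols = self.paths
        return cols[: cols.index(level) + 1]


#: Model of the multisite 2D migration study: five nested random levels
#: with the condition key separating replicates of the two arms.
STUDY_MODEL = HLMEModelSpec(
    levels=("lab", "person", "experiment", "replicate", "cell"),
    path_columns=("lab", "person", "experiment", "condition", "replicate", "cell"),
    fixed_condition="condition",
)


@dataclass
class FittedHLME:
    """Maximum-likelihood estimates of the nested mixed model."""

    spec: HLMEModelSpec
    value_col: str
    beta0: float
    delta: float | None
    sigma2: dict[str, float]
    sigma2_residual: float
    loglik: float
    blups: dict[str, pd.Series]
    treated_label: str | None
    n_obs: int
    converged: bool
    n_iter: int
    message: str = ""
    #: -2 log L at accepted optimiser iterates (when tracked)
    history: list[float] | None = None

    def variances(self) -> dict[str, float]:
        out = dict(self.sigma2)
        out["residual"] = self.sigma2_residual
        return out

    def to_dict(self) -> dict:
        """Plain-types summary suitable for a YAML dump."""
        return {
            "value": self.value_col,
            "levels": list(self.spec.levels),
            "fixed_effects": {
                "beta0": float(self.beta0),
                **({"delta": float(self.delta)} if self.delta is not None else {}),
            },
            "variance_components": {k: float(v) for k, v in self.variances().items()},
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


# ---------------------------------------------------------------------------
# Likelihood machinery


class _Structure:
    """Factorised hierarchy plus per-innermost-unit sufficient statistics."""

    def __init__(self, table: pd.DataFrame, spec: HLMEModelSpec, value_col: str):
        missing = [
            c
            for c in (*spec.paths, value_col, *( [spec.fixed_condition] if spec.fixed_condition else []))
            if c not in table.columns
        ]
        if missing:
            raise StructureError(f"table is missing required column(s): {missing}")

        self.spec = spec
        y = table[value_col].to_numpy(float)
        if np.isnan(y).any():
            raise StructureError(f"{value_col} contains missing values")
        self.y = y
        self.n = len(y)
        if self.n < 2:
            raise StructureError("need at least 2 observations")

        if spec.fixed_condition is not None:
            cond = table[spec.fixed_condition]
            labels = sorted(cond.unique())
            if len(labels) != 2:
                raise StructureError(
                    "treatment fixed effect requested but condition column "
                    f"has {len(labels)} distinct value(s); need exactly 2 "
                    "(the effect is undefined otherwise)"
                )
            # "control"-like label first if present, else lexicographic
            if "control" in labels:
                labels = ["control", *[l for l in labels if l != "control"]]
            self.treated_label = labels[1]
            x = (cond == self.treated_label).to_numpy(float)
            self.X = np.column_stack([np.ones(self.n), x])
        else:
            self.treated_label = None
            self.X = np.ones((self.n, 1))
        self.p = self.X.shape[1]

        # innermost units and parent chains, via cumulative path keys
        inner = spec.levels[-1]
        inner_path = list(spec.path_for(inner))
        codes, uniques = pd.factorize(
            pd.MultiIndex.from_frame(table[inner_path]), sort=True
        )
        self.inner_codes = codes
        self.units: dict[str, pd.Index] = {inner: uniques}

        # representative row per innermost unit to build outer-level codes
        first = np.zeros(len(uniques), dtype=np.int64)
        first[codes[::-1]] = np.arange(self.n)[::-1]
        rep = table.iloc[first]

        self.level_codes: dict[str, np.ndarray] = {inner: np.arange(len(uniques))}
        for level in spec.levels[:-1]:
            pcols = list(spec.path_for(level))
            c, u = pd.factorize(pd.MultiIndex.from_frame(rep[pcols]), sort=True)
            self.level_codes[level] = c  # innermost unit -> level unit
            self.units[level] = u

        # parent map: unit of level i+1 -> unit of level i
        self.parent: dict[str, np.ndarray] = {}
        lv = spec.levels
        for child, par in zip(lv[::-1], [*lv[-2::-1], None]):
            m = len(self.units[child])
            arr = np.zeros(m, dtype=np.int64)
            if par is None:
                self.parent[child] = arr  # root
            else:
                arr[self.level_codes[child]] = self.level_codes[par]
                self.parent[child] = arr
        self.n_units = {l: len(self.units[l]) for l in lv}

        # per-innermost-unit sufficient statistics
        m = len(uniques)
        p = self.p
        self.Sxx = np.zeros((m, p, p))
        for i in range(p):
            for j in range(i, p):
                v = np.bincount(codes, weights=self.X[:, i] * self.X[:, j], minlength=m)
                self.Sxx[:, i, j] = v
                self.Sxx[:, j, i] = v
        self.Sxy = np.zeros((m, p))
        for i in range(p):
            self.Sxy[:, i] = np.bincount(codes, weights=self.X[:, i] * y, minlength=m)
        self.Syy = np.bincount(codes, weights=y * y, minlength=m)
        self.Sx1 = np.zeros((m, p))
        for i in range(p):
            self.Sx1[:, i] = np.bincount(codes, weights=self.X[:, i], minlength=m)
        self.Sy1 = np.bincount(codes, weights=y, minlength=m)
        self.counts = np.bincount(codes, minlength=m).astype(float)

    # -- profiled -2 log likelihood ------------------------------------

    def neg2ll(
        self,
        sig2: dict[str, float],
        sig2_res: float,
        return_beta: bool = False,
        reml: bool = False,
    ):
        inv = 1.0 / sig2_res
        A = self.Sxx * inv
        b = self.Sxy * inv
        q = self.Syy * inv
        ld = self.counts * math.log(sig2_res)
        h = self.Sx1 * inv
        e = self.Sy1 * inv
        f = self.counts * inv

        for level in self.spec.levels[::-1]:
            s2 = sig2[level]
            if s2 > 0.0:
                k = s2 / (1.0 + s2 * f)
                A = A - k[:, None, None] * (h[:, :, None] * h[:, None, :])
                b = b - (k * e)[:, None] * h
                q = q - k * e * e
                ld = ld + np.log1p(s2 * f)
                denom = 1.0 + s2 * f
                h = h / denom[:, None]
                e = e / denom
                f = f / denom
            par = self.parent[level]
            nparent = par.max() + 1
            A = _agg(A, par, nparent)
            b = _agg(b, par, nparent)
            q = _agg(q, par, nparent)
            ld = _agg(ld, par, nparent)
            h = _agg(h, par, nparent)
            e = _agg(e, par, nparent)
            f = _agg(f, par, nparent)

        A0, b0, q0, ld0 = A[0], b[0], q[0], ld[0]
        beta = np.linalg.solve(A0, b0)
        n2ll = self.n * math.log(2 * math.pi) + ld0 + q0 - b0 @ beta
        if reml:
            # restricted likelihood: profile beta out by integration
            sign, ldA = np.linalg.slogdet(A0)
            n2ll += ldA - self.p * math.log(2 * math.pi)
        if return_beta:
            return n2ll, beta
        return n2ll


def _agg(arr: np.ndarray, codes: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, *arr.shape[1:]))
    np.add.at(out, codes, arr)
    return out


def _moments_start(st: _Structure) -> tuple[dict[str, float], float]:
    """Nested-ANOVA-flavoured method-of-moments starting values."""
    beta, *_ = np.linalg.lstsq(st.X, st.y, rcond=None)
    r = st.y - st.X @ beta
    var_r = float(np.var(r)) or 1.0
    floor = max(1e-8, 1e-4 * var_r)

    inner = st.spec.levels[-1]
    sums = np.bincount(st.inner_codes, weights=r, minlength=st.n_units[inner])
    sqs = np.bincount(st.inner_codes, weights=r * r, minlength=st.n_units[inner])
    cnt = st.counts
    means = sums / cnt
    within_ss = sqs - cnt * means**2
    dof = max(1.0, st.n - st.n_units[inner])
    res0 = max(float(within_ss.sum() / dof), floor)

    start: dict[str, float] = {}
    prev_disp = res0
    prev_m = st.n
    for level in st.spec.levels[::-1]:
        codes = st.level_codes[level]  # innermost unit -> level unit
        m = st.n_units[level]
        lsum = np.bincount(codes, weights=means * cnt, minlength=m)
        lcnt = np.bincount(codes, weights=cnt, minlength=m)
        lmeans = lsum / lcnt
        disp = float(np.var(lmeans, ddof=1)) if m > 1 else floor
        kbar = max(prev_m / m, 1.0)  # children per unit at this level
        start[level] = max(disp - prev_disp / kbar, floor)
        prev_disp, prev_m = disp, m
    return start, res0


def fit_nested_lme(
    table: pd.DataFrame,
    spec: HLMEModelSpec = STUDY_MODEL,
    value_col: str = "ics",
    compute_blups: bool = True,
    max_iter: int = 500,
    track_history: bool = False,
    reml: bool = False,
) -> FittedHLME:
    """Fit the nested random-intercept model by maximum likelihood.

    Deterministic given the data: starting values come from nested
    method-of-moments estimates and the quasi-Newton optimisation uses
    no randomness. Variances whose unconstrained optimum lies below
    zero are reported as exactly 0. ``reml=True`` maximises the
    restricted likelihood instead (sensitivity checks; ML is the
    default and the convention for the reported components).
    """
    st = _Structure(table, spec, value_col)
    for level in spec.levels:
        if st.n_units[level] < 2:
            warnings.warn(
                f"level '{level}' has a single unit; its variance is weakly identified",
                stacklevel=2,
            )

    # degenerate: data exactly on the fixed-effect plane
    beta_ols, *_ = np.linalg.lstsq(st.X, st.y, rcond=None)
    ssr = float(np.sum((st.y - st.X @ beta_ols) ** 2))
    scale = float(np.var(st.y)) or 1.0
    if ssr <= 1e-12 * max(1.0, float(st.y @ st.y)):
        blups = {
            level: pd.Series(0.0, index=st.units[level], name=level)
            for level in spec.levels
        }
        return FittedHLME(
            spec=spec,
            value_col=value_col,
            beta0=float(beta_ols[0]),
            delta=float(beta_ols[1]) if st.p == 2 else None,
            sigma2={level: 0.0 for level in spec.levels},
            sigma2_residual=0.0,
            loglik=math.inf,
            blups=blups,
            treated_label=st.treated_label,
            n_obs=st.n,
            converged=True,
            n_iter=0,
            message="degenerate fit: response exactly on the fixed-effect plane",
        )

    start, res0 = _moments_start(st)
    levels = list(spec.levels)
    history: list[float] = []

    def optimise(free: list[str], record: bool = False):
        """Maximise over log-variances of `free` levels (+ residual)."""
        theta0 = np.log([*(max(start[l], 1e-8) for l in free), max(res0, 1e-8)])
        lo, hi = math.log(scale) - 25.0, math.log(scale) + 12.0
        bounds = [(lo, hi)] * len(theta0)
        theta0 = np.clip(theta0, lo, hi)

        def fun(theta):
            sig2 = {l: 0.0 for l in levels}
            for l, t in zip(free, theta[:-1]):
                sig2[l] = math.exp(t)
            return st.neg2ll(sig2, math.exp(theta[-1]), reml=reml)

        callback = None
        if record:
            history.append(float(fun(theta0)))
            callback = lambda xk: history.append(float(fun(xk)))  # noqa: E731
        res = scipy.optimize.minimize(
            fun,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            callback=callback,
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-8},
        )
        sig2 = {l: 0.0 for l in levels}
        for l, t in zip(free, res.x[:-1]):
            sig2[l] = math.exp(t)
        return sig2, math.exp(res.x[-1]), res

    free = levels[:]
    sig2, s2res, res = optimise(free, record=track_history)
    if not np.isfinite(res.fun):
        raise ConvergenceError(
            f"likelihood optimisation failed: {res.message}",
            last_estimates={**sig2, "residual": s2res},
        )
    # boundary handling: pin near-zero variances to exactly 0 and refit;
    # the pinned fit is kept only if the likelihood is not meaningfully worse
    tol0 = 1e-5 * scale
    while True:
        pin = [l for l in free if sig2[l] < tol0]
        if not pin:
            break
        free = [l for l in free if l not in pin]
        sig2_new, s2res_new, res_new = optimise(free)
        if res_new.fun <= res.fun + 2e-5:
            sig2, s2res, res = sig2_new, s2res_new, res_new
        else:  # pinned fit genuinely worse; keep the interior estimates
            break

    n2ll, beta = st.neg2ll(sig2, s2res, return_beta=True, reml=reml)
    fitted = FittedHLME(
        spec=spec,
        value_col=value_col,
        beta0=float(beta[0]),
        delta=float(beta[1]) if st.p == 2 else None,
        sigma2={l: float(sig2[l]) for l in levels},
        sigma2_residual=float(s2res),
        loglik=-0.5 * n2ll,
        blups={},
        treated_label=st.treated_label,
        n_obs=st.n,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        history=history if track_history else None,
    )
    if not res.success and "ITERATIONS" in str(res.message).upper():
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations",
            last_estimates=fitted,
        )
    if compute_blups:
        fitted.blups = _henderson_blups(st, fitted, table)
    else:
        fitted.blups = {
            l: pd.Series(0.0, index=st.units[l], name=l) for l in levels
        }
    return fitted


def _henderson_blups(
    st: _Structure, fit: FittedHLME, table: pd.DataFrame
) -> dict[str, pd.Series]:
    """Empirical-Bayes random-intercept predictions from the MME.

    Levels with a zero variance estimate get BLUPs of exactly 0.
    """
    levels = list(fit.spec.levels)
    active = [l for l in levels if fit.sigma2[l] > 0.0]
    out = {l: pd.Series(0.0, index=st.units[l], name=l) for l in levels}
    if not active or fit.sigma2_residual <= 0.0:
        return out

    n = st.n
    blocks = [sp.csr_matrix(st.X)]
    sizes = []
    row_codes = st.inner_codes
    for l in active:
        codes = st.level_codes[l][row_codes]
        m = st.n_units[l]
        Z = sp.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, m)
        )
        blocks.append(Z)
        sizes.append(m)
    W = sp.hstack(blocks, format="csr")
    d = np.concatenate(
        [np.zeros(st.p), *[np.full(m, 1.0 / fit.sigma2[l]) for l, m in zip(active, sizes)]]
    )
    C = (W.T @ W) / fit.sigma2_residual + sp.diags(d)
    rhs = W.T @ st.y / fit.sigma2_residual
    sol = spla.spsolve(sp.csc_matrix(C), rhs)
    pos = st.p
    for l, m in zip(active, sizes):
        out[l] = pd.Series(sol[pos : pos + m], index=st.units[l], name=l)
        pos += m
    return out


def predict_random_intercepts(
    model: FittedHLME, table: pd.DataFrame
) -> pd.DataFrame:
    """Per-observation BLUP of each level's random intercept.

    Raises :class:`StructureError` for unit paths unseen at fit time.
    """
    if not model.blups:
        raise StructureError("model was fitted without BLUPs")
    out = {}
    for level in model.spec.levels:
        cols = list(model.spec.path_for(level))
        paths = pd.MultiIndex.from_frame(table[cols])
        vals = model.blups[level].reindex(paths)
        if vals.isna().any():
            unseen = paths[vals.isna().to_numpy()][0]
            raise StructureError(f"unit {unseen!r} at level '{level}' unseen at fit time")
        out[level] = vals.to_numpy()
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# Variance decomposition


TECHNICAL_LEVELS = ("lab", "person", "experiment", "replicate")
BIOLOGICAL_LEVELS = ("cell", "residual")


@dataclass
class VarianceTable:
    """Per-feature absolute and relative variance components.

    ``absolute`` and ``relative`` are feature x component frames (the
    components are the random levels plus the temporal residual);
    ``technical_share`` aggregates replicate/experiment/person/lab,
    ``biological_share`` aggregates cell and residual.
    """

    absolute: pd.DataFrame
    relative: pd.DataFrame
    technical_share: pd.Series
    biological_share: pd.Series

    @property
    def median_technical_share(self) -> float:
        return float(self.technical_share.median())

    def to_frame(self) -> pd.DataFrame:
        abs_ = self.absolute.add_suffix("_abs")
        rel = self.relative.add_suffix("_rel")
        out = pd.concat([abs_, rel], axis=1)
        out["technical_share"] = self.technical_share
        out["biological_share"] = self.biological_share
        return out


def decompose_variance(
    models: dict[str, FittedHLME],
    technical_levels: tuple[str, ...] = TECHNICAL_LEVELS,
) -> VarianceTable:
    """Split each feature's total variance into level components.

    Technical variability aggregates the design levels (replicate,
    experiment, person, laboratory); biological variability aggregates
    cell identity and the temporal residual.
    """
    rows_abs = {}
    for feat, m in models.items():
        rows_abs[feat] = m.variances()
    absolute = pd.DataFrame.from_dict(rows_abs, orient="index")
    total = absolute.sum(axis=1)
    relative = absolute.div(total, axis=0)
    tech_cols = [c for c in absolute.columns if c in technical_levels]
    technical = relative[tech_cols].sum(axis=1)
    biological = 1.0 - technical
    return VarianceTable(
        absolute=absolute,
        relative=relative,
        technical_share=technical,
        biological_share=biological,
    )
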