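"""Synthetic inputs with recorded ground truth.

Emulates a multisite live-cell imaging study: a nested design
(laboratories > persons > experiments > conditions > technical replicates
> cells > time points), Gaussian random intercepts at every hierarchy
level plus a treatment fixed effect, scripted label-mask movies whose
morphology and motion are known exactly, and 3D spheroid-invasion scenes
with known migration distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "GenerativeParams",
    "GroundTruth",
    "CellScript",
    "Bump",
    "MaskMovieSpec",
    "MaskMovie",
    "MovieGroundTruth",
    "SpheroidScene",
    "GenerationError",
    "HIERARCHY_COLUMNS",
    "generate_hierarchical_dataset",
    "generate_mask_movie",
    "generate_spheroid_scene",
]

#: Hierarchy key columns of an observation table, outermost to innermost.
HIERARCHY_COLUMNS = ("lab", "person", "experiment", "condition", "replicate", "cell")

#: Random-intercept levels, outermost to innermost (condition is a fixed
#: effect, not a random level).
RANDOM_LEVELS = ("lab", "person", "experiment", "replicate", "cell")


class GenerationError(ValueError):
    """Raised when a synthetic scene cannot be generated as scripted."""


@dataclass(frozen=True)
class DesignSpec:
    """Counts and acquisition schedule of the nested study design.

    The default instance reproduces the multisite study layout: three
    laboratories, three persons per laboratory, three experiments per
    person, two conditions, three technical replicates per condition,
    about 50 cells per replicate, imaged at 5-minute intervals for 6 h
    (72 observation time points per cell).
    """

    n_labs: int = 3
    n_persons_per_lab: int = 3
    n_experiments_per_person: int = 3
    conditions: tuple[str, ...] = ("control", "treated")
    n_replicates_per_condition: int = 3
    n_cells_per_replicate: int = 50
    n_timepoints: int = 72
    frame_interval: float = 5.0  # minutes

    def __post_init__(self):
        counts = (
            self.n_labs,
            self.n_persons_per_lab,
            self.n_experiments_per_person,
            len(self.conditions),
            self.n_replicates_per_condition,
            self.n_cells_per_replicate,
            self.n_timepoints,
        )
        if any(int(c) < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_observations(self) -> int:
        return (
            self.n_labs
            * self.n_persons_per_lab
            * self.n_experiments_per_person
            * len(self.conditions)
            * self.n_replicates_per_condition
            * self.n_cells_per_replicate
            * self.n_timepoints
        )

    def scaled(self, **overrides) -> "DesignSpec":
        """Return a copy with some counts overridden (for smaller runs)."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the hierarchical Gaussian generative model.

    y = beta0 + delta*1[treated] + u_lab + u_person + u_experiment
        + u_replicate + u_cell + eps

    with every random intercept drawn independently from a centred
    normal with the level's variance and eps i.i.d. white noise per
    time point.
    """

    beta0: float = 1.0
    delta: float = 0.0
    sigma2_lab: float = 0.0
    sigma2_person: float = 0.0
    sigma2_experiment: float = 0.0
    sigma2_replicate: float = 0.0
    sigma2_cell: float = 0.0
    sigma2_residual: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name, v in self.variances().items():
            if v < 0:
                raise ValueError(f"variance {name} must be >= 0, got {v}")

    def variances(self) -> dict[str, float]:
        return {
            "lab": self.sigma2_lab,
            "person": self.sigma2_person,
            "experiment": self.sigma2_experiment,
            "replicate": self.sigma2_replicate,
            "cell": self.sigma2_cell,
            "residual": self.sigma2_residual,
        }


@dataclass
class GroundTruth:
    """True random intercepts and residuals behind a generated table.

    ``intercepts[feature][level]`` maps each unit path (tuple of labels
    from the hierarchy root down to that unit) to its drawn intercept.
    ``residuals`` is aligned row-for-row with the observation table.
    """

    params: GenerativeParams
    design: DesignSpec
    intercepts: dict[str, dict[str, "pd.Series"]]
    residuals: pd.DataFrame

    def reconstruct(self, table: pd.DataFrame, feature: str) -> np.ndarray:
        """Rebuild y from the stored effects; equals table[feature] exactly."""
        p = self.params
        y = np.full(len(table), p.beta0, dtype=float)
        if len(self.design.conditions) > 1:
            treated_label = self.design.conditions[-1]
            y += p.delta * (table["condition"] == treated_label).to_numpy(float)
        for level, series in self.intercepts[feature].items():
            depth = _level_depth(level)
            paths = pd.MultiIndex.from_frame(table[list(HIERARCHY_COLUMNS[:depth])])
            y += series.reindex(paths).to_numpy()
        y += self.residuals[feature].to_numpy()
        return y


def _level_depth(level: str) -> int:
    # number of hierarchy columns that identify a unit of this level
    return {"lab": 1, "person": 2, "experiment": 3, "replicate": 5, "cell": 6}[level]


def generate_hierarchical_dataset(
    design: DesignSpec = DesignSpec(),
    params: GenerativeParams = GenerativeParams(),
    features: tuple[str, ...] = ("ics",),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a long-format observation table from the nested model.

    Returns one record per (lab, person, experiment, condition,
    replicate, cell, time) and the exact effects used to build it.
    Identical seeds give byte-identical tables. Features beyond the
    first are independent draws with the same parameters (no
    cross-feature correlation).
    """
    rng = np.random.default_rng(params.seed)

    labs = [f"L{i+1}" for i in range(design.n_labs)]
    persons = [f"P{i+1}" for i in range(design.n_persons_per_lab)]
    exps = [f"E{i+1}" for i in range(design.n_experiments_per_person)]
    reps = [f"R{i+1}" for i in range(design.n_replicates_per_condition)]
    cells = [f"C{i+1}" for i in range(design.n_cells_per_replicate)]
    times = (np.arange(design.n_timepoints) + 1) * design.frame_interval

    key = pd.MultiIndex.from_product(
        [labs, persons, exps, list(design.conditions), reps, cells, times],
        names=[*HIERARCHY_COLUMNS, "time_min"],
    )
    table = key.to_frame(index=False)

    sigmas = {
        "lab": params.sigma2_lab,
        "person": params.sigma2_person,
        "experiment": params.sigma2_experiment,
        "replicate": params.sigma2_replicate,
        "cell": params.sigma2_cell,
    }

    intercepts: dict[str, dict[str, pd.Series]] = {}
    residuals = {}
    # the last condition label is the perturbed arm carrying delta
    if len(design.conditions) > 1:
        treated = (table["condition"] == design.conditions[-1]).to_numpy(float)
    else:
        treated = np.zeros(len(table))

    for feat in features:
        per_level: dict[str, pd.Series] = {}
        y = np.full(len(table), params.beta0, dtype=float)
        y += params.delta * treated
        for level, s2 in sigmas.items():
            depth = _level_depth(level)
            units = pd.MultiIndex.from_frame(
                table[list(HIERARCHY_COLUMNS[:depth])].drop_duplicates()
            )
            draws = rng.normal(0.0, math.sqrt(s2), size=len(units))
            series = pd.Series(draws, index=units, name=level)
            per_level[level] = series
            paths = pd.MultiIndex.from_frame(table[list(HIERARCHY_COLUMNS[:depth])])
            y += series.reindex(paths).to_numpy()
        eps = rng.normal(0.0, math.sqrt(params.sigma2_residual), size=len(table))
        y += eps
        table[feat] = y
        intercepts[feat] = per_level
        residuals[feat] = eps

    truth = GroundTruth(
        params=params,
        design=design,
        intercepts=intercepts,
        residuals=pd.DataFrame(residuals),
    )
    return table, truth


def generate_invasion_study(
    n_labs: int = 2,
    n_experiments: int = 3,
    n_replicates: int = 3,
    n_spheroids: int = 5,
    n_nuclei: int = 40,
    conditions: tuple[str, ...] = ("collagen_2.5", "collagen_6.0"),
    beta0: float = 60.0,
    delta: float = -25.0,
    sigma2_lab: float = 100.0,
    sigma2_experiment: float = 25.0,
    sigma2_replicate: float = 10.0,
    sigma2_spheroid: float = 30.0,
    sigma2_residual: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-nucleus 3D migration distances with a nested lab structure.

    Emulates a two-site spheroid invasion study: labs > experiments >
    condition (collagen density) > replicates > spheroids, one record
    per nucleus. Defaults give a dense-collagen condition that reduces
    invasion distance. Reuses the hierarchical generator (the person
    level is collapsed), so the same ground-truth identity holds.
    """
    design = DesignSpec(
        n_labs=n_labs,
        n_persons_per_lab=1,
        n_experiments_per_person=n_experiments,
        conditions=conditions,
        n_replicates_per_condition=n_replicates,
        n_cells_per_replicate=n_spheroids,
        n_timepoints=n_nuclei,
        frame_interval=1.0,
    )
    params = GenerativeParams(
        beta0=beta0,
        delta=delta,
        sigma2_lab=sigma2_lab,
        sigma2_person=0.0,
        sigma2_experiment=sigma2_experiment,
        sigma2_replicate=sigma2_replicate,
        sigma2_cell=sigma2_spheroid,
        sigma2_residual=sigma2_residual,
        seed=seed,
    )
    table, truth = generate_hierarchical_dataset(
        design, params, features=("migration_distance",)
    )
    table = table.drop(columns=["person"]).rename(
        columns={"cell": "spheroid", "time_min": "nucleus"}
    )
    # treatment indicator: second condition label plays the "treated" arm
    table["condition"] = table["condition"].astype(str)
    return table, truth


# ---------------------------------------------------------------------------
# Scripted label-mask movies


@dataclass(frozen=True)
class Bump:
    """A transient circular protrusion scripted onto a cell boundary.

    The bump disk is centred on the cell outline at ``angle`` (radians)
    and exists for ``lifetime`` consecutive frames starting at ``frame``.
    """

    frame: int
    radius: float  # px
    angle: float  # radians, position on the cell boundary
    lifetime: int = 1


@dataclass(frozen=True)
class CellScript:
    """Deterministic program for one cell: a moving disk plus bumps."""

    label: int
    center: tuple[float, float]  # (x, y) px at frame 0
    radius: float  # px
    velocity: tuple[float, float] = (0.0, 0.0)  # px/frame
    bumps: tuple[Bump, ...] = ()

    def center_at(self, frame: int) -> tuple[float, float]:
        return (
            self.center[0] + self.velocity[0] * frame,
            self.center[1] + self.velocity[1] * frame,
        )


@dataclass(frozen=True)
class MaskMovieSpec:
    n_frames: int
    image_size: tuple[int, int]  # (height, width) px
    pixel_size: float  # um/px
    cells: tuple[CellScript, ...]
    nucleus_fraction: float = 0.4
    frame_interval: float = 5.0  # minutes
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 < self.nucleus_fraction < 1:
            raise ValueError("nucleus_fraction must be in (0, 1)")
        labels = [c.label for c in self.cells]
        if len(set(labels)) != len(labels) or any(l <= 0 for l in labels):
            raise ValueError("cell labels must be unique positive integers")


@dataclass
class MaskMovie:
    """Per-frame cell and nucleus label images sharing one label space."""

    cells: np.ndarray  # (T, H, W) uint16
    nuclei: np.ndarray  # (T, H, W) uint16
    pixel_size: float  # um/px
    frame_interval: float  # minutes

    @property
    def n_frames(self) -> int:
        return self.cells.shape[0]


@dataclass
class MovieGroundTruth:
    """Rendered truth per cell and frame.

    ``table`` has one row per (label, frame) with true area (um^2),
    centroid (um), nucleus centroid (um), speed of the scripted centre
    (um/min; NaN at frame 0) and the per-pixel-set protrusion /
    retraction / short-lived areas (um^2; NaN where undefined at the
    movie ends).
    """

    table: pd.DataFrame
    pixel_size: float
    frame_interval: float


def _disk_mask(h, w, cx, cy, r):
    yy, xx = np.mgrid[0:h, 0:w]
    # pixel-centre-in-shape rasterisation
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def generate_mask_movie(spec: MaskMovieSpec) -> tuple[MaskMovie, MovieGroundTruth]:
    """Render scripted cells into label movies with exact ground truth.

    Raises :class:`GenerationError` if the script makes two cells
    overlap or touch the image border on any frame.
    """
    h, w = spec.image_size
    cells = np.zeros((spec.n_frames, h, w), dtype=np.uint16)
    nuclei = np.zeros_like(cells)

    per_cell_masks: dict[int, list[np.ndarray]] = {c.label: [] for c in spec.cells}
    rows = []

    for t in range(spec.n_frames):
        occupied = np.zeros((h, w), dtype=bool)
        for script in spec.cells:
            cx, cy = script.center_at(t)
            mask = _disk_mask(h, w, cx, cy, script.radius)
            for bump in script.bumps:
                if bump.frame <= t < bump.frame + bump.lifetime:
                    bx = cx + script.radius * math.cos(bump.angle)
                    by = cy + script.radius * math.sin(bump.angle)
                    mask |= _disk_mask(h, w, bx, by, bump.radius)
            if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
                raise GenerationError(
                    f"cell {script.label} touches the image border at frame {t}"
                )
            if (mask & occupied).any():
                raise GenerationError(f"cell {script.label} overlaps another cell at frame {t}")
            occupied |= mask
            cells[t][mask] = script.label
            nuc = _disk_mask(h, w, cx, cy, script.radius * spec.nucleus_fraction)
            if (nuc & ~mask).any() or not nuc.any():
                raise GenerationError(
                    f"nucleus of cell {script.label} not strictly inside at frame {t}"
                )
            nuclei[t][nuc] = script.label
            per_cell_masks[script.label].append(mask)

    px2 = spec.pixel_size**2
    for script in spec.cells:
        masks = per_cell_masks[script.label]
        for t in range(spec.n_frames):
            mask = masks[t]
            ys, xs = np.nonzero(mask)
            nmask = nuclei[t] == script.label
            nys, nxs = np.nonzero(nmask)
            cx_true, cy_true = script.center_at(t)
            if t > 0:
                px_prev, py_prev = script.center_at(t - 1)
                speed = (
                    math.hypot(cx_true - px_prev, cy_true - py_prev)
                    * spec.pixel_size
                    / spec.frame_interval
                )
            else:
                speed = np.nan
            prot = ret = short = np.nan
            if 0 < t:
                prot = float((mask & ~masks[t - 1]).sum()) * px2
            if t < spec.n_frames - 1:
                ret = float((mask & ~masks[t + 1]).sum()) * px2
            if 0 < t < spec.n_frames - 1:
                short = float((mask & ~masks[t - 1] & ~masks[t + 1]).sum()) * px2
            rows.append(
                {
                    "label": script.label,
                    "frame": t,
                    "time_min": t * spec.frame_interval,
                    "area": float(mask.sum()) * px2,
                    "centroid_x": xs.mean() * spec.pixel_size,
                    "centroid_y": ys.mean() * spec.pixel_size,
                    "nucleus_area": float(nmask.sum()) * px2,
                    "nucleus_centroid_x": nxs.mean() * spec.pixel_size,
                    "nucleus_centroid_y": nys.mean() * spec.pixel_size,
                    "speed": speed,
                    "protrusion_area": prot,
                    "retraction_area": ret,
                    "shortlived_area": short,
                }
            )

    movie = MaskMovie(cells, nuclei, spec.pixel_size, spec.frame_interval)
    truth = MovieGroundTruth(pd.DataFrame(rows), spec.pixel_size, spec.frame_interval)
    return movie, truth


def random_mask_movie_spec(
    rng: np.random.Generator,
    n_frames: int = 5,
    image_size: tuple[int, int] = (96, 96),
    n_cells: int = 2,
    pixel_size: float = 1.0,
) -> MaskMovieSpec:
    """A random but valid movie script (well-separated drifting cells)."""
    h, w = image_size
    cells = []
    # place cells on a coarse grid so scripts can never collide
    slots = [(0.28, 0.28), (0.72, 0.72), (0.28, 0.72), (0.72, 0.28)]
    for i in range(n_cells):
        sx, sy = slots[i % len(slots)]
        radius = rng.uniform(6, 10)
        vel = rng.uniform(-1.2, 1.2, size=2)
        bumps = []
        if rng.random() < 0.8:
            bumps.append(
                Bump(
                    frame=int(rng.integers(1, max(2, n_frames - 1))),
                    radius=float(rng.uniform(2, 4)),
                    angle=float(rng.uniform(0, 2 * math.pi)),
                    lifetime=int(rng.integers(1, 3)),
                )
            )
        cells.append(
            CellScript(
                label=i + 1,
                center=(sx * w + rng.uniform(-3, 3), sy * h + rng.uniform(-3, 3)),
                radius=float(radius),
                velocity=(float(vel[0]), float(vel[1])),
                bumps=tuple(bumps),
            )
        )
    return MaskMovieSpec(
        n_frames=n_frames,
        image_size=image_size,
        pixel_size=pixel_size,
        cells=tuple(cells),
        seed=int(rng.integers(2**31)),
    )


# ---------------------------------------------------------------------------
# 3D spheroid scenes


@dataclass
class SpheroidScene:
    """Four core-surface points, the core sphere, and invading nuclei."""

    core_points: np.ndarray  # (4, 3) um, exactly on the core sphere
    center: np.ndarray  # (3,) um
    radius: float  # um
    nuclei: np.ndarray  # (n, 3) um
    true_distances: np.ndarray  # (n,) um, signed radial offsets

    def to_frame(self) -> pd.DataFrame:
        pts = pd.DataFrame(self.core_points, columns=["x", "y", "z"])
        pts.insert(0, "role", "core_point")
        nuc = pd.DataFrame(self.nuclei, columns=["x", "y", "z"])
        nuc.insert(0, "role", "nucleus")
        return pd.concat([pts, nuc], ignore_index=True)


def generate_spheroid_scene(
    core_center,
    core_radius: float,
    nucleus_radial_offsets,
    seed: int = 0,
    n_core_points: int = 4,
) -> SpheroidScene:
    """Place four non-coplanar points on the core sphere and nuclei at
    the given signed radial offsets (positive = outside the core)."""
    if core_radius <= 0:
        raise ValueError("core_radius must be positive")
    if n_core_points < 4:
        raise ValueError("at least four core points are required to define a sphere")
    rng = np.random.default_rng(seed)
    center = np.asarray(core_center, dtype=float)
    offsets = np.asarray(list(nucleus_radial_offsets), dtype=float)
    if np.any(core_radius + offsets < 0):
        raise ValueError("radial offsets must satisfy offset >= -core_radius")

    while True:
        dirs = rng.normal(size=(n_core_points, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = center + core_radius * dirs
        vol = abs(np.linalg.det(pts[1:4] - pts[0]))
        if vol > 1e-3 * core_radius**3:  # reject near-coplanar draws
            break

    nuc_dirs = rng.normal(size=(len(offsets), 3))
    nuc_dirs /= np.linalg.norm(nuc_dirs, axis=1, keepdims=True)
    nuclei = center + (core_radius + offsets)[:, None] * nuc_dirs

    return SpheroidScene(
        core_points=pts,
        center=center,
        radius=float(core_radius),
        nuclei=nuclei,
        true_distances=offsets,
    )
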