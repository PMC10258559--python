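"""Readers and writers for the pipeline's file formats.

Observation tables are UTF-8 CSV with "." decimals, keyed by
lab,person,experiment,condition,replicate,cell,time_min. Mask movies are
two multi-frame 16-bit TIFFs (cell and nucleus labels, frame order =
time order) plus a YAML sidecar holding pixel size and frame interval.
Spheroid scenes are CSV with a role column (core_point | nucleus).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import MaskMovie

__all__ = [
    "write_observation_table",
    "read_observation_table",
    "write_mask_movie",
    "read_mask_movie",
    "write_scene",
    "read_scene",
    "write_yaml",
    "read_yaml",
]


def write_observation_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_observation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_mask_movie(movie: MaskMovie, directory, stem: str = "movie") -> dict[str, Path]:
    """Write cell/nucleus label TIFFs and the metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": directory / f"{stem}_cells.tif",
        "nuclei": directory / f"{stem}_nuclei.tif",
        "meta": directory / f"{stem}_meta.yaml",
    }
    # one greyscale label page per frame (never RGB-guessed from shape)
    tifffile.imwrite(paths["cells"], movie.cells.astype(np.uint16),
                     photometric="minisblack")
    tifffile.imwrite(paths["nuclei"], movie.nuclei.astype(np.uint16),
                     photometric="minisblack")
    write_yaml(
        {"pixel_size_um": float(movie.pixel_size),
         "frame_interval_min": float(movie.frame_interval)},
        paths["meta"],
    )
    return paths


def read_mask_movie(directory, stem: str = "movie") -> MaskMovie:
    directory = Path(directory)
    cells = tifffile.imread(directory / f"{stem}_cells.tif")
    nuclei = tifffile.imread(directory / f"{stem}_nuclei.tif")
    meta = read_yaml(directory / f"{stem}_meta.yaml")
    if cells.ndim == 2:  # single frame
        cells = cells[None]
        nuclei = nuclei[None]
    return MaskMovie(
        cells=cells.astype(np.uint16),
        nuclei=nuclei.astype(np.uint16),
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_min"]),
    )


def write_scene(scene_table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scene_table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_scene(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def read_yaml(path):
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
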