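"""Batch-effect removal by subtracting fitted random intercepts.

Each observation is corrected by subtracting the predicted (BLUP)
random intercepts of the technical levels on its design path —
laboratory, person, experiment and technical replicate — while the
fixed effects (baseline and treatment) and the biological variation
(cell identity and temporal residual) are retained. The model must be
fitted jointly on both conditions with the treatment fixed effect, so
the correction cannot absorb the perturbation signal into the random
intercepts of one arm.

The same mechanics correct 3D spheroid-invasion migration distances,
with levels laboratory/experiment/replicate and the collagen density as
the condition.
"""

from __future__ import annotations

import pandas as pd

from .hlme import (
    FittedHLME,
    HLMEModelSpec,
    StructureError,
    fit_nested_lme,
    predict_random_intercepts,
)

__all__ = ["remove_batch_effects", "correct_3d", "condition_summary"]

TECHNICAL_2D = ("lab", "person", "experiment", "replicate")


def remove_batch_effects(
    table: pd.DataFrame,
    model: FittedHLME,
    levels_to_remove: tuple[str, ...] = TECHNICAL_2D,
    value_col: str | None = None,
) -> pd.DataFrame:
    """Subtract technical-level BLUPs from each observation.

    Returns a copy of the table with the corrected value column and a
    ``batch_corrected`` provenance column. Row count and hierarchy keys
    are untouched. Raises if the table has two conditions but the model
    was fitted without the treatment fixed effect, or if any observation
    lies on a unit path unseen at fit time.
    """
    value_col = value_col or model.value_col
    cond_col = model.spec.fixed_condition or "condition"
    if cond_col in table.columns and table[cond_col].nunique() > 1 and model.delta is None:
        raise StructureError(
            "table has two conditions but the model lacks the treatment fixed "
            "effect; fit the joint two-condition model first"
        )
    unknown = [l for l in levels_to_remove if l not in model.spec.levels]
    if unknown:
        raise ValueError(f"model has no random level(s) {unknown}")

    blups = predict_random_intercepts(model, table)
    out = table.copy()
    out[value_col] = out[value_col] - blups[list(levels_to_remove)].sum(axis=1)
    out["batch_corrected"] = True
    return out


def correct_3d(
    distances: pd.DataFrame,
    value_col: str = "migration_distance",
    condition_col: str = "condition",
    levels: tuple[str, ...] = ("lab", "experiment", "replicate"),
    unit_col: str = "spheroid",
) -> tuple[pd.DataFrame, FittedHLME]:
    """Batch-correct per-nucleus 3D migration distances.

    The table is keyed by lab/experiment/replicate/spheroid with a
    two-level condition (collagen density). A nested model with random
    levels lab, experiment, replicate and spheroid is fitted jointly on
    both conditions; the lab/experiment/replicate intercepts are then
    subtracted, retaining spheroid-level and residual variation.
    """
    if distances[condition_col].nunique() < 2:
        raise StructureError(
            "3D correction needs both conditions present (the condition fixed "
            "effect is undefined otherwise)"
        )
    if distances["lab"].nunique() < 2:
        raise StructureError("3D correction needs data from at least 2 labs")
    spec = HLMEModelSpec(
        levels=(*levels, unit_col),
        path_columns=(*levels[:-1], condition_col, levels[-1], unit_col),
        fixed_condition=condition_col,
    )
    model = fit_nested_lme(distances, spec, value_col=value_col)
    corrected = remove_batch_effects(
        distances, model, levels_to_remove=levels, value_col=value_col
    )
    return corrected, model


def condition_summary(
    table: pd.DataFrame,
    value_col: str,
    condition_col: str = "condition",
    by: tuple[str, ...] = ("lab",),
) -> pd.DataFrame:
    """Mean +/- SD per condition (overall and per group).

    The per-lab, per-condition means and SDs before and after the
    correction are the usual way to display how batch removal aligns
    the treatment contrast across sites.
    """
    rows = []
    for cond, grp in table.groupby(condition_col, sort=True):
        rows.append({"group": "all", condition_col: cond,
                     "mean": grp[value_col].mean(), "sd": grp[value_col].std(ddof=1)})
        for key, sub in grp.groupby(list(by), sort=True):
            key = key if isinstance(key, tuple) else (key,)
            rows.append({"group": "/".join(map(str, key)), condition_col: cond,
                         "mean": sub[value_col].mean(), "sd": sub[value_col].std(ddof=1)})
    return pd.DataFrame(rows)
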