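"""Raw luminescence → relative viability, and condition fold-change stats.

Normalization is strictly per plate AND per condition: each well is divided
by the mean vehicle (DMSO) luminescence of its own plate and condition.
Cross-plate pooling of vehicle wells is deliberately not supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NormalizationError, StatisticsError
from .model import VEHICLE_ID, WellMeasurement, measurements_to_frame

__all__ = ["FoldChangeResult", "relative_viability", "fold_change"]

VIABILITY_COLUMNS = (
    "plate_id",
    "compound_id",
    "replicate",
    "concentration_um",
    "condition",
    "viability",
)


@dataclass(frozen=True)
class FoldChangeResult:
    """Two-condition viability comparison with a Student's t-test."""

    group: str
    fold: float
    t_statistic: float
    p_value: float
    n_numerator: int
    n_denominator: int
    degenerate: bool = False  # zero within-group variance


def relative_viability(
    measurements: Iterable[WellMeasurement] | pd.DataFrame,
) -> pd.DataFrame:
    """Normalize each well to the mean DMSO luminescence of its plate+condition.

    Returns a long-format frame with columns
    ``plate_id, compound_id, replicate, concentration_um, condition, viability``.
    Raises :class:`NormalizationError` naming any plate that lacks vehicle
    wells in a condition it was measured in.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = measurements_to_frame(measurements)
    if df.empty:
        raise NormalizationError("no measurements to normalize")

    vehicle = df[df["compound_id"] == VEHICLE_ID]
    dmso_mean = (
        vehicle.groupby(["plate_id", "condition"])["luminescence"]
        .mean()
        .rename("dmso_mean")
    )
    merged = df.merge(
        dmso_mean, left_on=["plate_id", "condition"], right_index=True, how="left"
    )
    missing = merged[merged["dmso_mean"].isna()]
    if not missing.empty:
        plates = sorted(set(zip(missing["plate_id"], missing["condition"])))
        raise NormalizationError(
            "plate(s) without DMSO vehicle wells in the matching condition: "
            + ", ".join(f"{p} [{c}]" for p, c in plates)
        )
    merged["viability"] = merged["luminescence"] / merged["dmso_mean"]
    return merged[list(VIABILITY_COLUMNS)].copy()


def fold_change(
    numerator: Sequence[float],
    denominator: Sequence[float],
    group: str = "",
    *,
    equal_var: bool = True,
) -> FoldChangeResult:
    """Fold change mean(numerator)/mean(denominator) with a two-sided
    two-sample Student's t-test on the replicate values.

    The classical equal-variance test is the default; pass
    ``equal_var=False`` for Welch. Zero pooled variance yields a flagged
    degenerate result instead of raising.
    """
    a = np.asarray(numerator, dtype=float)
    b = np.asarray(denominator, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError(
            f"fold_change needs >= 2 replicates per group, "
            f"got {a.size} and {b.size}"
        )
    mean_b = float(b.mean())
    if mean_b == 0:
        raise StatisticsError("denominator group mean is zero")
    fold = float(a.mean()) / mean_b

    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # No within-group spread: the t statistic is undefined/infinite.
        diff = float(a.mean() - b.mean())
        t = math.inf * np.sign(diff) if diff != 0 else 0.0
        p = 0.0 if diff != 0 else 1.0
        return FoldChangeResult(group, fold, t, p, a.size, b.size, degenerate=True)

    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return FoldChangeResult(group, fold, float(t), float(p), a.size, b.size)
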