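"""Screen summary, mean±SD hit thresholds, hit calling and control QC.

Hits are called with strict inequalities against thresholds placed at
mean ± multiplier·SD of the library AUC distribution (controls and vehicle
excluded). A compound below the lower threshold marks its target as a
positive regulator of growth under the screening condition; above the
upper threshold, a negative regulator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .auc import AUCResult
from .errors import QCError, StatisticsError
from .model import (
    EIPA_GRID,
    EIPA_ID,
    TORIN1_GRID,
    TORIN1_ID,
    ConcentrationGrid,
)

__all__ = [
    "SdFlavor",
    "Direction",
    "RegulatorClass",
    "ScreenSummary",
    "HitCall",
    "QCResult",
    "summarize_screen",
    "call_hits",
    "qc_controls",
]


class SdFlavor(str, enum.Enum):
    SAMPLE = "SAMPLE"        # n-1 denominator (default)
    POPULATION = "POPULATION"  # n denominator


class Direction(str, enum.Enum):
    DECREASE = "DECREASE"
    NONE = "NONE"
    INCREASE = "INCREASE"


class RegulatorClass(str, enum.Enum):
    POSITIVE_REGULATOR_TARGET = "POSITIVE_REGULATOR_TARGET"
    NONE = "NONE"
    NEGATIVE_REGULATOR_TARGET = "NEGATIVE_REGULATOR_TARGET"


_DIRECTION_TO_CLASS = {
    Direction.DECREASE: RegulatorClass.POSITIVE_REGULATOR_TARGET,
    Direction.NONE: RegulatorClass.NONE,
    Direction.INCREASE: RegulatorClass.NEGATIVE_REGULATOR_TARGET,
}


@dataclass(frozen=True)
class ScreenSummary:
    """Library-wide AUC mean, dispersion and the two symmetric thresholds."""

    n_compounds: int
    mean_auc: float
    sd_auc: float
    threshold_multiplier: float = 1.0
    sd_flavor: SdFlavor = SdFlavor.SAMPLE

    @property
    def lower_threshold(self) -> float:
        return self.mean_auc - self.threshold_multiplier * self.sd_auc

    @property
    def upper_threshold(self) -> float:
        return self.mean_auc + self.threshold_multiplier * self.sd_auc

    def to_dict(self) -> dict:
        return {
            "n_compounds": self.n_compounds,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "lower_threshold": self.lower_threshold,
            "upper_threshold": self.upper_threshold,
            "threshold_multiplier": self.threshold_multiplier,
            "sd_flavor": self.sd_flavor.value,
        }


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    auc: float
    direction: Direction
    regulator_class: RegulatorClass


@dataclass(frozen=True)
class QCResult:
    """Outcome of the per-plate control-compound gates."""

    eipa_pass: bool
    torin1_pass: bool
    details: dict = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return self.eipa_pass and self.torin1_pass

    def to_dict(self) -> dict:
        return {
            "eipa_pass": self.eipa_pass,
            "torin1_pass": self.torin1_pass,
            "overall_pass": self.overall_pass,
            "details": self.details,
        }


def summarize_screen(
    auc_results: Iterable[AUCResult],
    *,
    threshold_multiplier: float = 1.0,
    sd_flavor: SdFlavor = SdFlavor.SAMPLE,
) -> ScreenSummary:
    """Mean and SD of the library AUCs and the mean ± multiplier·SD thresholds.

    Callers must pass library compounds only; controls and vehicle are not
    part of the screen distribution.
    """
    if threshold_multiplier <= 0:
        raise StatisticsError("threshold_multiplier must be > 0")
    aucs = np.array([r.auc for r in auc_results], dtype=float)
    if aucs.size < 2:
        raise StatisticsError(
            f"screen summary needs >= 2 library compounds, got {aucs.size}"
        )
    ddof = 1 if sd_flavor is SdFlavor.SAMPLE else 0
    return ScreenSummary(
        n_compounds=int(aucs.size),
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=ddof)),
        threshold_multiplier=threshold_multiplier,
        sd_flavor=sd_flavor,
    )


def call_hits(
    auc_results: Iterable[AUCResult], summary: ScreenSummary
) -> list[HitCall]:
    """Classify each compound against the summary thresholds.

    Strict inequalities on both sides: a compound exactly at a threshold
    is NONE.
    """
    calls = []
    for r in auc_results:
        if r.auc < summary.lower_threshold:
            direction = Direction.DECREASE
        elif r.auc > summary.upper_threshold:
            direction = Direction.INCREASE
        else:
            direction = Direction.NONE
        calls.append(
            HitCall(
                compound_id=r.compound_id,
                auc=r.auc,
                direction=direction,
                regulator_class=_DIRECTION_TO_CLASS[direction],
            )
        )
    return calls


def _control_means(
    viability: pd.DataFrame, compound_id: str, grid: ConcentrationGrid
) -> dict[float, float]:
    rows = viability[viability["compound_id"] == compound_id]
    if rows.empty:
        raise QCError(f"control series for {compound_id!r} is missing")
    means = rows.groupby("concentration_um")["viability"].mean()
    out: dict[float, float] = {}
    for level in grid.levels:
        if level not in means.index:
            raise QCError(
                f"control {compound_id!r}: no wells at {level} uM"
            )
        out[float(level)] = float(means.loc[level])
    return out


def qc_controls(
    viability: pd.DataFrame,
    *,
    eipa_grid: ConcentrationGrid = EIPA_GRID,
    torin1_grid: ConcentrationGrid = TORIN1_GRID,
    inhibition_fraction: float = 0.5,
    enhancement_factor: float = 1.2,
) -> QCResult:
    """Gate the run on the on-plate control compounds.

    The inhibitor control passes when mean viability at its top
    concentration drops below ``inhibition_fraction`` of the mean at its
    lowest concentration. The enhancer control passes when mean viability
    at either of its two intermediate concentrations exceeds
    ``enhancement_factor`` × vehicle (viability scale 1.0); a kill at the
    top concentration does not fail it.
    """
    eipa = _control_means(viability, EIPA_ID, eipa_grid)
    torin = _control_means(viability, TORIN1_ID, torin1_grid)

    lo, hi = eipa_grid.levels[0], eipa_grid.levels[-1]
    eipa_pass = bool(eipa[hi] < inhibition_fraction * eipa[lo])

    mid = [float(c) for c in torin1_grid.levels[1:3]]
    torin1_pass = bool(any(torin[c] > enhancement_factor for c in mid))

    return QCResult(
        eipa_pass=eipa_pass,
        torin1_pass=torin1_pass,
        details={
            "eipa_viability": {str(k): v for k, v in eipa.items()},
            "torin1_viability": {str(k): v for k, v in torin.items()},
            "inhibition_fraction": inhibition_fraction,
            "enhancement_factor": enhancement_factor,
        },
    )
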