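"""Per-compound dose-response AUC on the linear concentration axis.

The statistic is the trapezoidal area under the piecewise-linear relative
viability curve from 0 μM to the top tested concentration, with a fixed
vehicle anchor at (0 μM, viability 1.0) prepended. On the default
(0.2, 1, 5, 25) μM grid a compound with no effect (viability 1.0
everywhere) scores exactly 25; values below/above 25 indicate inhibition/
enhancement. The AUC is not normalized: hit thresholds live on this raw
μM·viability scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ScoringError
from .model import ConcentrationGrid, DoseResponseProfile

__all__ = ["AUCResult", "auc_single", "auc_compound"]

ANCHOR_VIABILITY = 1.0


@dataclass(frozen=True)
class AUCResult:
    """Replicate-averaged AUC for one compound."""

    compound_id: str
    auc: float
    replicate_aucs: tuple[float, ...]
    grid_max: float

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_aucs)


def auc_single(viability, grid: ConcentrationGrid) -> float:
    """Trapezoidal AUC of one replicate's viability row on ``grid``.

    ``viability`` must supply a finite, non-negative value at every grid
    level; anything else is a :class:`ScoringError` (no silent
    renormalization of incomplete rows).
    """
    v = np.asarray(viability, dtype=float)
    if v.shape != (len(grid),):
        raise ScoringError(
            f"viability has {v.shape} values for a {len(grid)}-level grid"
        )
    if not np.all(np.isfinite(v)):
        raise ScoringError("viability row contains missing/non-finite values")
    if np.any(v < 0):
        raise ScoringError("viability must be >= 0")
    x = np.concatenate(([0.0], grid.levels))
    y = np.concatenate(([ANCHOR_VIABILITY], v))
    return float(np.trapezoid(y, x))


def auc_compound(profile: DoseResponseProfile) -> AUCResult:
    """Per-replicate AUCs and their arithmetic mean for one compound."""
    if profile.viability.shape[0] == 0:
        raise ScoringError(
            f"profile for {profile.compound_id!r} has zero complete replicates"
        )
    replicate_aucs = tuple(
        auc_single(row, profile.grid) for row in profile.viability
    )
    return AUCResult(
        compound_id=profile.compound_id,
        auc=float(np.mean(replicate_aucs)),
        replicate_aucs=replicate_aucs,
        grid_max=profile.grid.grid_max,
    )
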