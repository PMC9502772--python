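"""Synthetic viability-screen generator with planted ground truth.

Emulates the screening design end to end: a compound library dosed on a
4-point grid in replicate plates, per-plate DMSO vehicle wells, per-plate
inhibitor (EIPA-like) and enhancer (Torin1-like) control series, and
multiplicative lognormal measurement noise. Dose-response shapes are
phenomenological Hill curves; every planted parameter is recorded in a
truth table so downstream recovery can be tested without any external
data.

Determinism contract: the same seed and config produce byte-identical
output. Per-plate random substreams are spawned from one master
SeedSequence in plate order, so appending plates never perturbs earlier
ones.
"""

from __future__ import annotations

import enum
import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError
from .model import (
    DEFAULT_GRID,
    EIPA_GRID,
    EIPA_ID,
    TORIN1_GRID,
    TORIN1_ID,
    VEHICLE_ID,
    CompoundRecord,
    ConcentrationGrid,
    Condition,
    Role,
    WellMeasurement,
)

__all__ = [
    "EffectKind",
    "EffectSpec",
    "ScreenConfig",
    "SyntheticScreen",
    "true_viability",
    "dilution",
    "plant_effects",
    "generate_screen",
    "generate_condition_comparison",
    "EIPA_EFFECT",
    "TORIN1_EFFECT",
]


class EffectKind(str, enum.Enum):
    INERT = "INERT"
    INHIBITOR = "INHIBITOR"
    ENHANCER = "ENHANCER"
    BIPHASIC = "BIPHASIC"


@dataclass(frozen=True)
class EffectSpec:
    """Hill-curve dose-response shape for one compound.

    INERT ignores all parameters. INHIBITOR decays from 1 to ``bottom``
    around ``ec50``; ENHANCER rises from 1 to ``emax``; BIPHASIC is the
    enhancer term multiplied by a second inhibitory Hill term centred at
    ``kill_ec50`` (> ec50), giving the rise-then-kill shape of the
    enhancer control.
    """

    kind: EffectKind
    ec50: float = 1.0
    hill: float = 1.0
    bottom: float = 0.0
    emax: float = 2.0
    kill_ec50: float = 10.0

    def __post_init__(self) -> None:
        if self.kind is EffectKind.INERT:
            return
        if self.ec50 <= 0 or self.hill <= 0:
            raise GenerationError("ec50 and hill must be > 0")
        if self.bottom < 0:
            raise GenerationError("bottom must be >= 0")
        if self.emax < 1:
            raise GenerationError("emax must be >= 1")
        if self.kind is EffectKind.BIPHASIC:
            if self.kill_ec50 <= 0:
                raise GenerationError("kill_ec50 must be > 0")
            if self.kill_ec50 <= self.ec50:
                raise GenerationError("BIPHASIC requires kill_ec50 > ec50")


INERT = EffectSpec(EffectKind.INERT)
#: On-plate controls mimic the qualitative shapes of the real compounds:
#: the inhibitor bites between its two top concentrations; the enhancer
#: peaks mid-series and kills at the top.
EIPA_EFFECT = EffectSpec(EffectKind.INHIBITOR, ec50=30.0, hill=2.0, bottom=0.0)
TORIN1_EFFECT = EffectSpec(
    EffectKind.BIPHASIC, ec50=0.05, hill=1.0, emax=1.8, kill_ec50=2.5
)


def true_viability(effect: EffectSpec, c: float) -> float:
    """Noise-free relative viability of ``effect`` at concentration ``c`` μM.

    Exactly 1.0 at c = 0 for every kind.
    """
    if c < 0:
        raise GenerationError(f"concentration must be >= 0, got {c}")
    if effect.kind is EffectKind.INERT or c == 0:
        return 1.0
    h = effect.hill
    if effect.kind is EffectKind.INHIBITOR:
        return effect.bottom + (1.0 - effect.bottom) / (1.0 + (c / effect.ec50) ** h)
    enhancer = 1.0 + (effect.emax - 1.0) * c**h / (c**h + effect.ec50**h)
    if effect.kind is EffectKind.ENHANCER:
        return enhancer
    # BIPHASIC: enhancer term damped by a second inhibitory phase
    return enhancer / (1.0 + (c / effect.kill_ec50) ** h)


def dilution(stock_um: float, stock_vol: float, well_vol: float) -> float:
    """Final in-well concentration after adding ``stock_vol`` μL of stock
    to a well already containing ``well_vol`` μL."""
    if stock_vol <= 0 or well_vol <= 0:
        raise GenerationError("volumes must be > 0")
    if stock_um < 0:
        raise GenerationError("stock concentration must be >= 0")
    return stock_um * stock_vol / (stock_vol + well_vol)


@dataclass(frozen=True)
class ScreenConfig:
    """Layout and noise parameters of a synthetic screen."""

    n_compounds: int = 225
    grid: ConcentrationGrid = DEFAULT_GRID
    n_replicates: int = 4
    noise_cv: float = 0.1
    compounds_per_plate: int = 20
    vehicle_wells_per_plate: int = 8
    baseline_luminescence: float = 100_000.0
    rescue_fold: float = 9.6
    complete_factor: float = 9.6
    condition: Condition = Condition.GLN_STARVED_BSA
    targets_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_replicates < 1:
            raise GenerationError("counts must be positive")
        if self.compounds_per_plate < 1 or self.vehicle_wells_per_plate < 1:
            raise GenerationError("per-plate counts must be positive")
        if self.noise_cv < 0:
            raise GenerationError("noise_cv must be >= 0")
        if self.baseline_luminescence <= 0:
            raise GenerationError("baseline_luminescence must be > 0")

    @property
    def n_plates_per_replicate(self) -> int:
        return math.ceil(self.n_compounds / self.compounds_per_plate)


@dataclass(frozen=True)
class SyntheticScreen:
    """Generated screen: raw wells, annotations, and planted truth."""

    measurements: tuple[WellMeasurement, ...]
    annotations: tuple[CompoundRecord, ...]
    truth: pd.DataFrame
    config: ScreenConfig


def _condition_factor(config: ScreenConfig, condition: Condition) -> float:
    if condition is Condition.GLN_STARVED:
        return 1.0
    if condition is Condition.GLN_STARVED_BSA:
        return config.rescue_fold
    return config.complete_factor


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _well_names(n: int) -> list[str]:
    """Row-letter + zero-padded column names, 12 columns per row."""
    rows = string.ascii_uppercase
    n_rows = math.ceil(n / 12)
    if n_rows > len(rows):
        raise GenerationError(f"plate with {n} wells exceeds supported geometry")
    return [f"{rows[i // 12]}{i % 12 + 1:02d}" for i in range(n)]


def _compound_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"C{i + 1:0{width}d}" for i in range(n)]


def plant_effects(
    config: ScreenConfig,
    *,
    n_inhibitors: int = 0,
    n_enhancers: int = 0,
    n_biphasic: int = 0,
    inhibitor: EffectSpec = EffectSpec(EffectKind.INHIBITOR, ec50=0.5, hill=1.0, bottom=0.0),
    enhancer: EffectSpec = EffectSpec(EffectKind.ENHANCER, ec50=0.5, hill=1.0, emax=2.0),
    biphasic: EffectSpec = EffectSpec(EffectKind.BIPHASIC, ec50=0.2, hill=1.0, emax=2.0, kill_ec50=10.0),
) -> dict[str, EffectSpec]:
    """Assign effects to the library: planted actives at random positions
    (deterministic in the config seed), INERT elsewhere."""
    n_active = n_inhibitors + n_enhancers + n_biphasic
    if n_active > config.n_compounds:
        raise GenerationError("more planted effects than compounds")
    ids = _compound_ids(config.n_compounds)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE44EC]))
    chosen = rng.choice(config.n_compounds, size=n_active, replace=False)
    effects: dict[str, EffectSpec] = {cid: INERT for cid in ids}
    for idx in chosen[:n_inhibitors]:
        effects[ids[idx]] = inhibitor
    for idx in chosen[n_inhibitors : n_inhibitors + n_enhancers]:
        effects[ids[idx]] = enhancer
    for idx in chosen[n_inhibitors + n_enhancers :]:
        effects[ids[idx]] = biphasic
    return effects


def _annotations(config: ScreenConfig, ids: Sequence[str]) -> list[CompoundRecord]:
    records = [
        CompoundRecord(
            compound_id=cid,
            name=f"compound-{cid[1:]}",
            targets=frozenset({f"T{i // config.targets_per_group + 1:02d}"}),
            role=Role.LIBRARY,
        )
        for i, cid in enumerate(ids)
    ]
    records.append(CompoundRecord(VEHICLE_ID, "dimethyl sulfoxide", frozenset(), Role.VEHICLE))
    records.append(CompoundRecord(EIPA_ID, "inhibitor control", frozenset({"NHE1"}), Role.CONTROL_INHIBITOR))
    records.append(CompoundRecord(TORIN1_ID, "enhancer control", frozenset({"MTOR"}), Role.CONTROL_ENHANCER))
    return records


def _truth_table(
    ids: Sequence[str], effects: Mapping[str, EffectSpec]
) -> pd.DataFrame:
    rows = []
    for cid in ids:
        e = effects[cid]
        rows.append(
            (cid, e.kind.value, e.ec50, e.hill, e.bottom, e.emax, e.kill_ec50)
        )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "kind", "ec50", "hill", "bottom", "emax", "kill_ec50"],
    )


def generate_screen(
    config: ScreenConfig, effects: Mapping[str, EffectSpec]
) -> SyntheticScreen:
    """Generate raw plate measurements for one full screen.

    Each replicate is laid out on its own set of plates; every plate holds
    up to ``compounds_per_plate`` library compounds across the full grid,
    plus DMSO vehicle wells and the two control series.
    luminescence = baseline × condition factor × true viability × noise.
    """
    ids = _compound_ids(config.n_compounds)
    missing = [cid for cid in ids if cid not in effects]
    if missing:
        raise GenerationError(
            f"effects missing for compound(s): {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )

    factor = _condition_factor(config, config.condition)
    base = config.baseline_luminescence * factor

    measurements: list[WellMeasurement] = []
    for rep in range(1, config.n_replicates + 1):
        for chunk_start in range(0, config.n_compounds, config.compounds_per_plate):
            chunk = ids[chunk_start : chunk_start + config.compounds_per_plate]
            plate_number = chunk_start // config.compounds_per_plate + 1
            plate_id = f"R{rep}P{plate_number:02d}"
            # Substream keyed by plate coordinates: adding plates or
            # replicates never perturbs previously generated plates.
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(rep, plate_number))
            )

            # (compound_id, concentration, true viability) for every well
            wells: list[tuple[str, float, float]] = []
            for cid in chunk:
                for c in config.grid.levels:
                    wells.append((cid, float(c), true_viability(effects[cid], c)))
            for _ in range(config.vehicle_wells_per_plate):
                wells.append((VEHICLE_ID, 0.0, 1.0))
            for c in EIPA_GRID.levels:
                wells.append((EIPA_ID, float(c), true_viability(EIPA_EFFECT, c)))
            for c in TORIN1_GRID.levels:
                wells.append((TORIN1_ID, float(c), true_viability(TORIN1_EFFECT, c)))

            noise = _lognormal_noise(rng, config.noise_cv, len(wells))
            names = _well_names(len(wells))
            for (cid, conc, viab), nz, well in zip(wells, noise, names):
                measurements.append(
                    WellMeasurement(
                        plate_id=plate_id,
                        well=well,
                        compound_id=cid,
                        concentration_um=conc,
                        condition=config.condition,
                        replicate=rep,
                        luminescence=base * viab * float(nz),
                    )
                )

    return SyntheticScreen(
        measurements=tuple(measurements),
        annotations=tuple(_annotations(config, ids)),
        truth=_truth_table(ids, effects),
        config=config,
    )


def generate_condition_comparison(
    config: ScreenConfig, n_wells: int = 3
) -> pd.DataFrame:
    """Vehicle-only wells under starvation, starvation+BSA and complete
    medium, for exercising the fold-change comparison.

    Returns a frame with columns ``condition, replicate, luminescence``;
    the planted BSA/starvation luminescence ratio is ``config.rescue_fold``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB5A]))
    rows = []
    for condition in Condition:
        factor = _condition_factor(config, condition)
        noise = _lognormal_noise(rng, config.noise_cv, n_wells)
        for i in range(n_wells):
            rows.append(
                (
                    condition.value,
                    i + 1,
                    config.baseline_luminescence * factor * float(noise[i]),
                )
            )
    return pd.DataFrame(rows, columns=["condition", "replicate", "luminescence"])
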