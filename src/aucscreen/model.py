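"""Domain types and tabular I/O for the viability screen.

All tables are long-format, comma-separated, UTF-8 with a mandatory header
row. One measurement per row. Sentinel compound ids mark vehicle and
control wells (``DMSO``, ``EIPA``, ``TORIN1``).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, ParseError, ScoringError

__all__ = [
    "Condition",
    "Role",
    "WellMeasurement",
    "CompoundRecord",
    "ConcentrationGrid",
    "DoseResponseProfile",
    "DEFAULT_GRID",
    "EIPA_GRID",
    "TORIN1_GRID",
    "VEHICLE_ID",
    "EIPA_ID",
    "TORIN1_ID",
    "SENTINEL_IDS",
    "MEASUREMENT_COLUMNS",
    "ANNOTATION_COLUMNS",
    "read_measurements",
    "write_measurements",
    "read_annotations",
    "write_annotations",
    "write_report",
    "read_report",
]

# Sentinel compound ids placed on every plate.
VEHICLE_ID = "DMSO"
EIPA_ID = "EIPA"
TORIN1_ID = "TORIN1"
SENTINEL_IDS = frozenset({VEHICLE_ID, EIPA_ID, TORIN1_ID})

MEASUREMENT_COLUMNS = (
    "plate_id",
    "well",
    "compound_id",
    "concentration_um",
    "condition",
    "replicate",
    "luminescence",
)
ANNOTATION_COLUMNS = ("compound_id", "name", "targets", "role")


class Condition(str, enum.Enum):
    """Culture condition of a well."""

    GLN_STARVED = "GLN_STARVED"
    GLN_STARVED_BSA = "GLN_STARVED_BSA"
    COMPLETE = "COMPLETE"


class Role(str, enum.Enum):
    """Role of a compound within the screen."""

    LIBRARY = "LIBRARY"
    VEHICLE = "VEHICLE"
    CONTROL_INHIBITOR = "CONTROL_INHIBITOR"
    CONTROL_ENHANCER = "CONTROL_ENHANCER"


@dataclass(frozen=True)
class WellMeasurement:
    """One raw luminescence reading with its plate coordinates."""

    plate_id: str
    well: str
    compound_id: str
    concentration_um: float
    condition: Condition
    replicate: int
    luminescence: float

    def __post_init__(self) -> None:
        if self.luminescence < 0:
            raise ValueError(
                f"luminescence must be >= 0, got {self.luminescence!r}"
            )
        if self.concentration_um < 0:
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration_um!r}"
            )
        if self.compound_id == VEHICLE_ID and self.concentration_um != 0:
            raise ValueError("vehicle wells must have concentration 0")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """Annotation record: compound identity, known targets and screen role."""

    compound_id: str
    name: str
    targets: frozenset[str]
    role: Role = Role.LIBRARY

    def __post_init__(self) -> None:
        if self.role is Role.LIBRARY and not self.targets:
            raise AnnotationError(
                f"LIBRARY compound {self.compound_id!r} has an empty target set"
            )
        if self.role is Role.VEHICLE and self.targets:
            raise AnnotationError(
                f"VEHICLE compound {self.compound_id!r} must have no targets"
            )


@dataclass(frozen=True)
class ConcentrationGrid:
    """Ordered positive concentration levels (μM) with an implicit
    zero-concentration anchor at relative viability 1.0."""

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("grid must have at least one level")
        arr = np.asarray(self.levels, dtype=float)
        if not np.all(arr > 0):
            raise ValueError(f"grid levels must all be > 0, got {self.levels}")
        if not np.all(np.diff(arr) > 0):
            raise ValueError(
                f"grid levels must be strictly increasing, got {self.levels}"
            )

    @property
    def grid_max(self) -> float:
        return float(self.levels[-1])

    def __len__(self) -> int:
        return len(self.levels)


#: Library dose grid: 0.2, 1, 5, 25 μM.
DEFAULT_GRID = ConcentrationGrid((0.2, 1.0, 5.0, 25.0))
#: Per-plate control series for the macropinocytosis inhibitor.
EIPA_GRID = ConcentrationGrid((0.8, 4.0, 20.0, 100.0))
#: Per-plate control series for the growth enhancer.
TORIN1_GRID = ConcentrationGrid((0.04, 0.2, 1.0, 5.0))


@dataclass(frozen=True)
class DoseResponseProfile:
    """Relative viability for one compound on a grid, one row per replicate.

    ``viability[i, j]`` is the relative viability of replicate
    ``replicates[i]`` at concentration ``grid.levels[j]``. Every cell must
    be present and finite; incomplete profiles are rejected at
    construction.
    """

    compound_id: str
    grid: ConcentrationGrid
    viability: np.ndarray
    replicates: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.viability, dtype=float)
        object.__setattr__(self, "viability", v)
        if v.ndim != 2 or v.shape != (len(self.replicates), len(self.grid)):
            raise ScoringError(
                f"profile for {self.compound_id!r}: viability shape {v.shape} "
                f"does not match {len(self.replicates)} replicates x "
                f"{len(self.grid)} levels"
            )
        if v.shape[0] == 0:
            raise ScoringError(
                f"profile for {self.compound_id!r} has zero replicates"
            )
        if not np.all(np.isfinite(v)):
            raise ScoringError(
                f"profile for {self.compound_id!r} has missing/non-finite cells"
            )
        if np.any(v < 0):
            raise ScoringError(
                f"profile for {self.compound_id!r} has negative viability"
            )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def to_csv_exact(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV with float columns in shortest-round-trip form, so the
    written text parses back to bit-identical values."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(repr)
    out.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_measurements(path: str | Path) -> list[WellMeasurement]:
    """Read a long-format measurement table.

    Raises :class:`ParseError` naming the offending data row (1-based,
    excluding the header) for any invariant violation.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"measurement file not found: {path}")
    df = pd.read_csv(
        path,
        dtype={"plate_id": str, "well": str, "compound_id": str},
        float_precision="round_trip",
    )
    _require_columns(df, MEASUREMENT_COLUMNS, path)

    records: list[WellMeasurement] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        key = (row.plate_id, row.well)
        if key in seen:
            raise ParseError(
                f"{path}: row {i}: duplicate (plate_id, well) = {key}"
            )
        seen.add(key)
        try:
            records.append(
                WellMeasurement(
                    plate_id=row.plate_id,
                    well=row.well,
                    compound_id=row.compound_id,
                    concentration_um=float(row.concentration_um),
                    condition=Condition(row.condition),
                    replicate=int(row.replicate),
                    luminescence=float(row.luminescence),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return records


def measurements_to_frame(measurements: Iterable[WellMeasurement]) -> pd.DataFrame:
    rows = [
        (
            m.plate_id,
            m.well,
            m.compound_id,
            m.concentration_um,
            m.condition.value,
            m.replicate,
            m.luminescence,
        )
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def write_measurements(
    measurements: Iterable[WellMeasurement], path: str | Path
) -> None:
    """Write measurements in the canonical CSV dialect (round-trip exact)."""
    to_csv_exact(measurements_to_frame(measurements), path)


def read_annotations(path: str | Path) -> list[CompoundRecord]:
    """Read a compound-annotation table; duplicate ids are rejected."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"annotation file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, path)

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.compound_id in seen:
            raise AnnotationError(
                f"{path}: row {i}: duplicate compound_id {row.compound_id!r}"
            )
        seen.add(row.compound_id)
        targets = frozenset(t for t in str(row.targets).split(";") if t)
        try:
            records.append(
                CompoundRecord(
                    compound_id=row.compound_id,
                    name=row.name,
                    targets=targets,
                    role=Role(row.role),
                )
            )
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_annotations(
    annotations: Iterable[CompoundRecord], path: str | Path
) -> None:
    rows = [
        (a.compound_id, a.name, ";".join(sorted(a.targets)), a.role.value)
        for a in annotations
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

REPORT_FILES = ("summary.json", "auc_table.csv", "hits.csv", "target_groups.csv")


def write_report(
    out_dir: str | Path,
    summary: Mapping,
    auc_table: pd.DataFrame,
    hits: pd.DataFrame,
    target_groups: pd.DataFrame,
) -> dict[str, Path]:
    """Write the four-file report bundle.

    ``summary`` is any JSON-serializable mapping (screen summary + QC).
    Floats are written shortest-round-trip, so re-reading reproduces every
    value bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out_dir / "summary.json",
        "auc_table": out_dir / "auc_table.csv",
        "hits": out_dir / "hits.csv",
        "target_groups": out_dir / "target_groups.csv",
    }
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    to_csv_exact(auc_table, paths["auc_table"])
    to_csv_exact(hits, paths["hits"])
    to_csv_exact(target_groups, paths["target_groups"])
    return paths


def read_report(out_dir: str | Path) -> dict:
    """Re-read a report bundle written by :func:`write_report`."""
    out_dir = Path(out_dir)
    with open(out_dir / "summary.json", encoding="utf-8") as fh:
        summary = json.load(fh)
    return {
        "summary": summary,
        "auc_table": pd.read_csv(out_dir / "auc_table.csv", float_precision="round_trip"),
        "hits": pd.read_csv(out_dir / "hits.csv", float_precision="round_trip"),
        "target_groups": pd.read_csv(
            out_dir / "target_groups.csv", float_precision="round_trip"
        ),
    }
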