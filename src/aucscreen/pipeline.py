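"""End-to-end orchestration: read → normalize → score → summarize →
call → group → report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import model
from .auc import AUCResult, auc_compound
from .errors import QCFailure, ScoringError
from .hits import (
    Direction,
    HitCall,
    QCResult,
    ScreenSummary,
    SdFlavor,
    call_hits,
    qc_controls,
    summarize_screen,
)
from .model import ConcentrationGrid, DoseResponseProfile, Role
from .normalization import relative_viability
from .synth import SyntheticScreen
from .targets import TargetGroup, completeness_flag, group_hits

__all__ = ["RunConfig", "RunResult", "run_screen", "build_profiles", "write_synthetic_screen"]

log = logging.getLogger("aucscreen")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run."""

    measurements: Path
    annotations: Path
    out_dir: Path
    threshold_multiplier: float = 1.0
    sd_flavor: SdFlavor = SdFlavor.SAMPLE
    qc_strict: bool = False

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")


@dataclass(frozen=True)
class RunResult:
    summary: ScreenSummary
    qc: QCResult
    auc_results: tuple[AUCResult, ...]
    hits: tuple[HitCall, ...]
    groups: tuple[TargetGroup, ...]
    viability: pd.DataFrame
    report_paths: dict


def build_profiles(
    viability: pd.DataFrame, library_ids: list[str]
) -> tuple[list[DoseResponseProfile], ConcentrationGrid]:
    """Pivot the long viability table into per-compound replicate × level
    matrices on the grid inferred from the library concentrations.

    Any compound with a missing (replicate, level) cell is rejected — the
    AUC calibration depends on the complete grid.
    """
    lib = viability[viability["compound_id"].isin(library_ids)]
    if lib.empty:
        raise ScoringError("no library compound wells found")
    levels = tuple(sorted(lib["concentration_um"].unique()))
    grid = ConcentrationGrid(levels)

    profiles = []
    for cid, sub in lib.groupby("compound_id", sort=True):
        wide = sub.pivot_table(
            index="replicate", columns="concentration_um", values="viability"
        )
        try:
            wide = wide.reindex(columns=levels)
            profiles.append(
                DoseResponseProfile(
                    compound_id=str(cid),
                    grid=grid,
                    viability=wide.to_numpy(dtype=float),
                    replicates=tuple(int(r) for r in wide.index),
                )
            )
        except ScoringError as exc:
            raise ScoringError(f"compound {cid!r}: {exc}") from exc
    return profiles, grid


def _auc_frame(results: list[AUCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.compound_id,
                r.auc,
                r.n_replicates,
                ";".join(repr(a) for a in r.replicate_aucs),
            )
            for r in results
        ],
        columns=["compound_id", "auc", "n_replicates", "replicate_aucs"],
    )


def _hits_frame(hits: list[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.compound_id, h.auc, h.direction.value, h.regulator_class.value)
            for h in hits
        ],
        columns=["compound_id", "auc", "direction", "regulator_class"],
    )


def _groups_frame(groups: list[TargetGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                g.target,
                g.direction.value,
                g.n_hits,
                g.n_in_library,
                completeness_flag(g),
                ";".join(g.compound_ids),
            )
            for g in groups
        ],
        columns=["target", "direction", "n_hits", "n_in_library", "complete", "compound_ids"],
    )


def run_screen(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle.

    Raises :class:`QCFailure` after writing the report when
    ``qc_strict`` is set and a control gate fails.
    """
    measurements = model.read_measurements(config.measurements)
    annotations = model.read_annotations(config.annotations)
    log.info("read %d measurements, %d annotations", len(measurements), len(annotations))

    library_ids = sorted(
        a.compound_id for a in annotations if a.role is Role.LIBRARY
    )
    viability = relative_viability(measurements)
    log.info("normalized %d wells against per-plate vehicle", len(viability))

    qc = qc_controls(viability)
    log.info(
        "QC: eipa_pass=%s torin1_pass=%s", qc.eipa_pass, qc.torin1_pass
    )

    profiles, grid = build_profiles(viability, library_ids)
    auc_results = [auc_compound(p) for p in profiles]
    log.info("scored %d compounds on grid %s", len(auc_results), grid.levels)

    summary = summarize_screen(
        auc_results,
        threshold_multiplier=config.threshold_multiplier,
        sd_flavor=config.sd_flavor,
    )
    hits = call_hits(auc_results, summary)
    n_dec = sum(h.direction is Direction.DECREASE for h in hits)
    n_inc = sum(h.direction is Direction.INCREASE for h in hits)
    log.info(
        "summary: mean=%.4g sd=%.4g thresholds=(%.4g, %.4g); %d decrease / %d increase hits",
        summary.mean_auc,
        summary.sd_auc,
        summary.lower_threshold,
        summary.upper_threshold,
        n_dec,
        n_inc,
    )

    groups = group_hits(hits, annotations)
    log.info("grouped hits into %d target groups", len(groups))

    summary_doc = {
        "screen": summary.to_dict(),
        "qc": qc.to_dict(),
        "n_hits_decrease": n_dec,
        "n_hits_increase": n_inc,
        "grid_levels": list(grid.levels),
    }
    report_paths = model.write_report(
        config.out_dir,
        summary_doc,
        _auc_frame(auc_results),
        _hits_frame(hits),
        _groups_frame(groups),
    )

    result = RunResult(
        summary=summary,
        qc=qc,
        auc_results=tuple(auc_results),
        hits=tuple(hits),
        groups=tuple(groups),
        viability=viability,
        report_paths=report_paths,
    )
    if config.qc_strict and not qc.overall_pass:
        raise QCFailure(
            f"control QC failed (eipa_pass={qc.eipa_pass}, "
            f"torin1_pass={qc.torin1_pass}); report written to {config.out_dir}"
        )
    return result


def write_synthetic_screen(screen: SyntheticScreen, out_dir: Path) -> dict:
    """Write measurements/annotations/truth plus a manifest with the seed
    and file hashes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out_dir / "measurements.csv",
        "annotations": out_dir / "annotations.csv",
        "truth": out_dir / "truth.csv",
    }
    model.write_measurements(screen.measurements, paths["measurements"])
    model.write_annotations(screen.annotations, paths["annotations"])
    model.to_csv_exact(screen.truth, paths["truth"])

    manifest = {
        "seed": screen.config.seed,
        "n_compounds": screen.config.n_compounds,
        "n_replicates": screen.config.n_replicates,
        "grid_levels": list(screen.config.grid.levels),
        "noise_cv": screen.config.noise_cv,
        "files": {
            name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in paths.items()
        },
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
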