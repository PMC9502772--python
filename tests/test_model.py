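import math

import numpy as np
import pandas as pd
import pytest

from aucscreen.errors import AnnotationError, ParseError, ScoringError
from aucscreen.model import (
    ANNOTATION_COLUMNS,
    DEFAULT_GRID,
    CompoundRecord,
    ConcentrationGrid,
    Condition,
    DoseResponseProfile,
    Role,
    WellMeasurement,
    read_annotations,
    read_measurements,
    read_report,
    write_annotations,
    write_measurements,
    write_report,
)
from aucscreen.synth import ScreenConfig, generate_screen, plant_effects


def make_well(**overrides) -> WellMeasurement:
    kwargs = dict(
        plate_id="R1P01",
        well="A01",
        compound_id="C001",
        concentration_um=0.2,
        condition=Condition.GLN_STARVED_BSA,
        replicate=1,
        luminescence=50_000.0,
    )
    kwargs.update(overrides)
    return WellMeasurement(**kwargs)


class TestWellMeasurement:
    def test_negative_luminescence_rejected(self):
        with pytest.raises(ValueError, match="luminescence"):
            make_well(luminescence=-5.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="concentration"):
            make_well(concentration_um=-1.0)

    def test_vehicle_must_be_concentration_zero(self):
        with pytest.raises(ValueError, match="vehicle"):
            make_well(compound_id="DMSO", concentration_um=1.0)
        make_well(compound_id="DMSO", concentration_um=0.0)  # ok

    def test_replicate_positive(self):
        with pytest.raises(ValueError, match="replicate"):
            make_well(replicate=0)


class TestCompoundRecord:
    def test_library_needs_targets(self):
        with pytest.raises(AnnotationError, match="empty target"):
            CompoundRecord("C001", "x", frozenset(), Role.LIBRARY)

    def test_vehicle_has_no_targets(self):
        with pytest.raises(AnnotationError, match="no targets"):
            CompoundRecord("DMSO", "x", frozenset({"HDAC"}), Role.VEHICLE)


class TestConcentrationGrid:
    def test_default_grid(self):
        assert DEFAULT_GRID.levels == (0.2, 1.0, 5.0, 25.0)
        assert DEFAULT_GRID.grid_max == 25.0

    @pytest.mark.parametrize("levels", [(1.0, 1.0), (5.0, 1.0), (0.0, 1.0), (-1.0, 2.0), ()])
    def test_bad_grids_rejected(self, levels):
        with pytest.raises(ValueError):
            ConcentrationGrid(levels)


class TestDoseResponseProfile:
    def test_incomplete_cell_rejected(self):
        v = np.array([[1.0, 1.0, np.nan, 1.0]])
        with pytest.raises(ScoringError, match="missing"):
            DoseResponseProfile("C001", DEFAULT_GRID, v, (1,))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ScoringError, match="shape"):
            DoseResponseProfile("C001", DEFAULT_GRID, np.ones((2, 3)), (1, 2))

    def test_negative_viability_rejected(self):
        v = np.array([[1.0, -0.1, 1.0, 1.0]])
        with pytest.raises(ScoringError, match="negative"):
            DoseResponseProfile("C001", DEFAULT_GRID, v, (1,))


class TestMeasurementIO:
    def test_three_row_round_trip(self, tmp_path):
        wells = [
            make_well(well="A01", compound_id="DMSO", concentration_um=0.0),
            make_well(well="A02", compound_id="C001", concentration_um=0.2),
            make_well(well="A03", compound_id="C001", concentration_um=1.0,
                      luminescence=12_345.678),
        ]
        path = tmp_path / "m.csv"
        write_measurements(wells, path)
        back = read_measurements(path)
        assert back == wells

    def test_negative_luminescence_names_row(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "plate_id,well,compound_id,concentration_um,condition,replicate,luminescence\n"
            "P1,A01,DMSO,0,GLN_STARVED_BSA,1,100\n"
            "P1,A02,C001,0.2,GLN_STARVED_BSA,1,-5\n"
        )
        with pytest.raises(ParseError, match="row 2"):
            read_measurements(path)

    def test_duplicate_plate_well_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "plate_id,well,compound_id,concentration_um,condition,replicate,luminescence\n"
            "P1,A01,DMSO,0,GLN_STARVED_BSA,1,100\n"
            "P1,A01,C001,0.2,GLN_STARVED_BSA,1,90\n"
        )
        with pytest.raises(ParseError, match=r"duplicate \(plate_id, well\)"):
            read_measurements(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("plate_id,well\nP1,A01\n")
        with pytest.raises(ParseError, match="missing column"):
            read_measurements(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ParseError, match="not found"):
            read_measurements(tmp_path / "nope.csv")

    def test_full_synthetic_screen_counts(self, tmp_path):
        # Expected counts derived from the generator configuration:
        # 225 compounds x 4 levels x 4 replicates library wells, plus
        # ceil(225/20)=12 plates/replicate x (8 vehicle + 4 + 4 control)
        # wells x 4 replicates.
        config = ScreenConfig(seed=1, noise_cv=0.1)
        screen = generate_screen(config, plant_effects(config))
        path = tmp_path / "m.csv"
        write_measurements(screen.measurements, path)
        back = read_measurements(path)
        n_library_expected = 225 * 4 * 4
        n_plates = math.ceil(225 / 20) * 4
        n_other_expected = n_plates * (8 + 4 + 4)
        assert len(back) == n_library_expected + n_other_expected
        n_library = sum(
            1 for m in back if m.compound_id not in {"DMSO", "EIPA", "TORIN1"}
        )
        assert n_library == n_library_expected
        assert back == list(screen.measurements)


class TestAnnotationIO:
    def test_single_row(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text(
            "compound_id,name,targets,role\nC001,romidepsin,HDAC,LIBRARY\n"
        )
        (rec,) = read_annotations(path)
        assert rec.targets == frozenset({"HDAC"})
        assert rec.name == "romidepsin"
        assert rec.role is Role.LIBRARY

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text(
            "compound_id,name,targets,role\n"
            "C001,a,HDAC,LIBRARY\nC001,b,HSP90,LIBRARY\n"
        )
        with pytest.raises(AnnotationError, match="duplicate compound_id"):
            read_annotations(path)

    def test_library_without_targets_rejected(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("compound_id,name,targets,role\nC001,a,,LIBRARY\n")
        with pytest.raises(AnnotationError, match="row 1"):
            read_annotations(path)

    def test_multi_target_round_trip(self, tmp_path):
        rec = CompoundRecord("C002", "dual", frozenset({"PI3K", "MTOR"}), Role.LIBRARY)
        path = tmp_path / "a.csv"
        write_annotations([rec], path)
        assert read_annotations(path) == [rec]

    def test_synthetic_annotation_count(self, small_screen, tmp_path):
        path = tmp_path / "a.csv"
        write_annotations(small_screen.annotations, path)
        back = read_annotations(path)
        libs = [a for a in back if a.role is Role.LIBRARY]
        assert len(libs) == small_screen.config.n_compounds
        assert list(back) == list(small_screen.annotations)


class TestReport:
    def test_mean_written_at_full_precision(self, tmp_path):
        summary = {"screen": {"mean_auc": 23.7}}
        empty = pd.DataFrame(columns=["compound_id", "auc"])
        write_report(tmp_path, summary, empty, empty, empty)
        back = read_report(tmp_path)
        assert back["summary"]["screen"]["mean_auc"] == 23.7

    def test_empty_hit_table_round_trips(self, tmp_path):
        empty_hits = pd.DataFrame(
            columns=["compound_id", "auc", "direction", "regulator_class"]
        )
        empty = pd.DataFrame(columns=["compound_id", "auc"])
        write_report(tmp_path, {}, empty, empty_hits, empty)
        back = read_report(tmp_path)
        assert len(back["hits"]) == 0
        assert list(back["hits"].columns) == list(empty_hits.columns)

    def test_full_value_round_trip(self, tmp_path):
        auc = pd.DataFrame(
            {"compound_id": ["C001", "C002"], "auc": [23.700000000001, 1 / 3]}
        )
        write_report(tmp_path, {"x": 0.1 + 0.2}, auc, auc, auc)
        back = read_report(tmp_path)
        assert back["summary"]["x"] == 0.1 + 0.2
        assert back["auc_table"]["auc"].tolist() == auc["auc"].tolist()
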