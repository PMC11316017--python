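"""File formats, validation and the command-line interface."""

import json
from pathlib import Path

import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import rardose as rd
from rardose import io, reference
from rardose.cli import main
from rardose.exceptions import ValidationError
from rardose.study import StudyDesign


@pytest.fixture
def study_dir(tmp_path):
    """A small synthetic study written in the on-disk formats."""
    config = rd.SyntheticConfig(markers=rd.default_markers(cv=0.05), seed=42)
    readings, truth = rd.generate_study(config)
    io.write_study(tmp_path, readings, config.design)
    truth.to_json(tmp_path / "ground_truth.json")
    return tmp_path


class TestStudyFiles:
    def test_round_trip_is_semantically_identical(self, study_dir):
        readings, design, config = io.read_study(
            study_dir / "readings.csv", study_dir / "design.yaml",
            study_dir / "config.yaml",
        )
        assert len(design) == 7
        assert set(readings["marker_id"]) == set(reference.RAR_MARKERS)
        assert sorted(readings["group_id"].unique()) == [f"G{i}" for i in range(1, 8)]
        assert (readings.groupby(["marker_id", "group_id"]).size() == 5).all()

        out2 = study_dir / "again"
        io.write_study(out2, readings, design, config)
        readings2, design2, _ = io.read_study(
            out2 / "readings.csv", out2 / "design.yaml", out2 / "config.yaml"
        )
        pd.testing.assert_frame_equal(readings, readings2)
        assert design.to_rows() == design2.to_rows()

    def test_unknown_group_reported_by_name(self, study_dir):
        readings = pd.read_csv(study_dir / "readings.csv")
        readings.loc[0, "group_id"] = "G9"
        readings.to_csv(study_dir / "readings.csv", index=False)
        with pytest.raises(ValidationError, match="G9"):
            io.read_study(study_dir / "readings.csv", study_dir / "design.yaml")

    def test_role_dose_inconsistency_rejected(self):
        rows = [dict(r) for r in reference.DEFAULT_DESIGN_ROWS]
        rows[1]["challenge_dose_mSv"] = 50.0  # acute group with a challenge dose
        with pytest.raises(ValidationError, match="role 'acute'"):
            StudyDesign.from_rows(rows)

    def test_mixed_units_rejected(self, study_dir):
        readings = pd.read_csv(study_dir / "readings.csv")
        readings.loc[readings.index[:2], "units"] = "mol/L"
        readings.to_csv(study_dir / "readings.csv", index=False)
        with pytest.raises(ValidationError, match="mixes units"):
            io.read_study(study_dir / "readings.csv", study_dir / "design.yaml")

    def test_calibration_json_round_trip(self, study_dir, tmp_path):
        readings, design, config = io.read_study(
            study_dir / "readings.csv", study_dir / "design.yaml"
        )
        results = rd.run_study(readings, design)
        path = tmp_path / "calibration.json"
        io.write_calibrations(path, results.calibrations)
        loaded = io.read_calibrations(path)
        for marker, model in results.calibrations.items():
            assert loaded[marker].to_dict() == model.to_dict()


class TestCli:
    def test_simulate_then_rar_composes(self, tmp_path):
        runner = CliRunner()
        demo = tmp_path / "demo"
        res = runner.invoke(main, ["simulate", "--seed", "42", "--out", str(demo)])
        assert res.exit_code == 0, res.output
        for name in ("readings.csv", "design.yaml", "config.yaml", "ground_truth.json"):
            assert (demo / name).exists()

        res = runner.invoke(main, ["rar", str(demo)])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(demo / "results" / "rar_table.csv")
        assert sorted(table["condition"].unique()) == ["10+50", "5+50"]
        assert all(m in table.columns for m in reference.RAR_MARKERS)

    def test_runs_are_byte_reproducible(self, tmp_path):
        runner = CliRunner()
        outputs = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            runner.invoke(main, ["simulate", "--seed", "7", "--out", str(d)])
            runner.invoke(main, ["rar", str(d)])
            outputs.append(
                {
                    "readings": (d / "readings.csv").read_bytes(),
                    "table": (d / "results" / "rar_table.csv").read_bytes(),
                    "calib": (d / "results" / "calibration.json").read_bytes(),
                }
            )
        assert outputs[0] == outputs[1]

    def test_calibrate_writes_models(self, tmp_path):
        runner = CliRunner()
        demo = tmp_path / "demo"
        runner.invoke(main, ["simulate", "--seed", "3", "--out", str(demo)])
        res = runner.invoke(main, ["calibrate", str(demo)])
        assert res.exit_code == 0, res.output
        doc = json.loads((demo / "calibration.json").read_text())
        assert set(doc) == set(reference.RAR_MARKERS)

    def test_invert_round_trips_a_curve_value(self, tmp_path):
        runner = CliRunner()
        demo = tmp_path / "demo"
        runner.invoke(main, ["simulate", "--seed", "3", "--cv", "0", "--out", str(demo)])
        runner.invoke(main, ["calibrate", str(demo)])
        res = runner.invoke(
            main,
            ["invert", "--calibration", str(demo / "calibration.json"),
             "--marker", "EPR", "--reading", "52.65"],
        )
        assert res.exit_code == 0, res.output
        assert "50 mSv" in res.output

    def test_reproduce_table7_flags_known_inconsistency(self):
        res = CliRunner().invoke(main, ["reproduce-table7"])
        assert res.exit_code == 0, res.output
        assert "FLAGGED" in res.output and "EPR" in res.output
        assert "23.1" in res.output and "7.5" in res.output

    def test_unknown_subcommand_fails_with_usage(self):
        res = CliRunner().invoke(main, ["frobnicate"])
        assert res.exit_code != 0
        assert "Usage" in res.output or "No such command" in res.output

    def test_validation_failure_exits_nonzero(self, study_dir):
        readings = pd.read_csv(study_dir / "readings.csv")
        readings.loc[0, "group_id"] = "G9"
        readings.to_csv(study_dir / "readings.csv", index=False)
        res = CliRunner().invoke(main, ["rar", str(study_dir)])
        assert res.exit_code != 0
        assert "validation" in res.output.lower() or "G9" in res.output
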