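"""Model/Results interface, end-to-end pipeline, manifests, and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from specell.cli import main as cli_main
from specell.model import CanonicalDiscriminantModel
from specell.pipeline import PipelineConfig, run_pipeline, verify_run
from specell.synthetic import (
    CohortConfig,
    default_spectra,
    effect_for_auc,
    generate_feature_cohort,
)
from specell.validation import CVConfig


@pytest.fixture(scope="module")
def feature_table():
    cfg = CohortConfig(
        seed=8,
        effect=effect_for_auc(0.92),
        n_patients_per_group=8,
        cells_per_group=(41, 84),
    )
    table, _ = generate_feature_cohort(cfg, default_spectra(seed=1))
    return table


@pytest.fixture(scope="module")
def tiny_pipeline_cfg():
    return PipelineConfig(
        seed=5,
        cohort=CohortConfig(
            n_patients_per_group=4,
            fields_per_patient=1,
            cells_per_field=3,
            image_shape=(64, 64),
        ),
        cv=CVConfig(outer_folds=3, inner_folds=2, n_grid=(2, 4)),
        n_features=4,
    )


class TestModelResults:
    def test_fit_returns_results_with_projection(self, feature_table):
        res = CanonicalDiscriminantModel(feature_table).fit(n_features=6)
        assert len(res.selected_features) == 6
        assert res.params.index.tolist() == res.selected_features
        assert np.linalg.norm(res.projection.w1) == pytest.approx(1.0)

    def test_summary_reports_key_quantities(self, feature_table):
        res = CanonicalDiscriminantModel(feature_table).fit(n_features=6)
        text = res.summary()
        assert "group 1: n = 41" in text and "group 2: n = 84" in text
        assert "training AUC" in text
        assert "Mann-Whitney" in text
        for name in res.selected_features:
            assert name in text

    def test_training_auc_high_on_strong_design(self, feature_table):
        res = CanonicalDiscriminantModel(feature_table).fit(n_features=6)
        assert res.training_roc().auc > 0.9
        assert res.group_test().tier == "***"

    def test_cross_validate_from_results(self, feature_table):
        res = CanonicalDiscriminantModel(feature_table).fit(n_features=4)
        rep = res.cross_validate(CVConfig(seed=1, n_grid=(2, 4)))
        assert 0.7 < rep.pooled_auc <= 1.0

    def test_projection_json_roundtrip(self, feature_table, tmp_path):
        from specell.discriminant import CanonicalProjection

        res = CanonicalDiscriminantModel(feature_table).fit(n_features=4)
        res.projection.to_json(tmp_path / "m.json")
        back = CanonicalProjection.from_json(tmp_path / "m.json")
        assert back.features == res.projection.features
        assert np.allclose(back.w1, res.projection.w1)


class TestPipeline:
    def test_end_to_end_emits_report_and_manifest(self, tiny_pipeline_cfg, tmp_path):
        summary = run_pipeline(tiny_pipeline_cfg, tmp_path / "run")
        report = json.loads((tmp_path / "run" / "report" / "report.json").read_text())
        assert 0.0 <= report["pooled_auc"] <= 1.0
        assert (tmp_path / "run" / "features.csv").exists()
        assert (tmp_path / "run" / "report" / "panels.png").exists()
        assert verify_run(tmp_path / "run") == []

    def test_same_seed_identical_feature_checksums(self, tiny_pipeline_cfg, tmp_path):
        run_pipeline(tiny_pipeline_cfg, tmp_path / "a")
        run_pipeline(tiny_pipeline_cfg, tmp_path / "b")
        ma = json.loads((tmp_path / "a" / "manifest.json").read_text())
        mb = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert ma["files"] == mb["files"]

    def test_tampering_detected(self, tiny_pipeline_cfg, tmp_path):
        run_pipeline(tiny_pipeline_cfg, tmp_path / "run")
        target = tmp_path / "run" / "features.csv"
        target.write_text(target.read_text().replace("0", "1", 1))
        assert "features.csv" in verify_run(tmp_path / "run")

    def test_selection_size_guard(self):
        with pytest.raises(Exception, match="cell count"):
            PipelineConfig(
                cohort=CohortConfig(n_patients_per_group=1, fields_per_patient=1),
                n_features=6,
            )

    def test_yaml_config_roundtrip(self, tmp_path):
        (tmp_path / "p.yaml").write_text(
            "cohort:\n"
            "  n_patients_per_group: 3\n"
            "  image_shape: [64, 64]\n"
            "  effect: 0.5\n"
            "cv:\n"
            "  outer_folds: 3\n"
            "  n_grid: [2, 4]\n"
            "n_features: 4\n"
            "seed: 9\n"
        )
        cfg = PipelineConfig.from_yaml(tmp_path / "p.yaml")
        assert cfg.cohort.n_patients_per_group == 3
        assert cfg.cohort.image_shape == (64, 64)
        assert cfg.cv.n_grid == (2, 4)
        assert cfg.seed == 9


class TestCLI:
    def test_simulate_and_validate_block_dir(self, tmp_path):
        runner = CliRunner()
        cfg_yaml = tmp_path / "c.yaml"
        cfg_yaml.write_text(
            "cohort:\n"
            "  n_patients_per_group: 1\n"
            "  fields_per_patient: 1\n"
            "  image_shape: [64, 64]\n"
        )
        out = tmp_path / "cohort"
        r = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg_yaml), "--out", str(out), "--seed", "3"],
        )
        assert r.exit_code == 0, r.output
        block_dirs = sorted(p.parent for p in out.glob("*/metadata.json"))
        assert len(block_dirs) == 2
        r = runner.invoke(cli_main, ["io-validate", str(block_dirs[0])])
        assert r.exit_code == 0 and "OK" in r.output

    def test_io_validate_rejects_corrupt_block(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cohort"
        cfg_yaml = tmp_path / "c.yaml"
        cfg_yaml.write_text(
            "cohort:\n"
            "  n_patients_per_group: 1\n"
            "  fields_per_patient: 1\n"
            "  image_shape: [64, 64]\n"
        )
        runner.invoke(
            cli_main, ["simulate", "--config", str(cfg_yaml), "--out", str(out), "--seed", "3"]
        )
        block_dir = next(out.glob("*/metadata.json")).parent
        (block_dir / "channels.tif").unlink()
        r = runner.invoke(cli_main, ["io-validate", str(block_dir)])
        assert r.exit_code == 2

    def test_discriminate_prints_summary(self, feature_table, tmp_path):
        from specell import io as dbio

        dbio.write_feature_table(feature_table, tmp_path / "f.csv")
        runner = CliRunner()
        r = runner.invoke(
            cli_main,
            ["discriminate", str(tmp_path / "f.csv"), "--n", "4", "--out", str(tmp_path / "m.json")],
        )
        assert r.exit_code == 0, r.output
        assert "Canonical discriminant" in r.output
        assert (tmp_path / "m.json").exists()
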