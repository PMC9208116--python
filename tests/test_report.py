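"""Batch evaluation driver: clipping, summaries, sampling, overlays, CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from segmetrics import (
    ClassConfig,
    RunConfig,
    ScoreRecord,
    clip_metric,
    make_truth,
    predict_scenario,
    render_overlay,
    run_evaluation,
    select_visual_samples,
    summarize_distribution,
    write_mask,
)
from segmetrics.cli import main as cli_main
from segmetrics.scenario_fixtures import Perturbation, ScenarioSpec


def ahd_records(values):
    return [ScoreRecord(f"s{i}", 1, "ahd", v) for i, v in enumerate(values)]


class TestClipMetric:
    def test_values_above_ceiling_replaced(self):
        records, fraction = clip_metric(ahd_records([10.0, 300.0, 5000.0]), "ahd", 250.0)
        assert [r.value for r in records] == [10.0, 250.0, 250.0]
        assert fraction == pytest.approx(2 / 3)

    def test_values_at_or_below_ceiling_unchanged(self):
        records, fraction = clip_metric(ahd_records([250.0, 3.0]), "ahd", 250.0)
        assert [r.value for r in records] == [250.0, 3.0]
        assert fraction == 0.0

    def test_undefined_records_do_not_count(self):
        records, fraction = clip_metric(ahd_records([None]), "ahd", 250.0)
        assert records[0].value is None and fraction == 0.0

    def test_other_metrics_untouched(self):
        recs = [ScoreRecord("s", 1, "dsc", 0.9)] + ahd_records([400.0])
        out, _ = clip_metric(recs, "ahd", 250.0)
        assert out[0].value == 0.9

    def test_clip_is_annotated_in_policy_note(self):
        out, _ = clip_metric(ahd_records([400.0]), "ahd", 250.0)
        assert "clipped" in out[0].policy_note


class TestSummarizeDistribution:
    def recs(self, values, metric="dsc"):
        return [ScoreRecord(f"s{i}", 1, metric, v) for i, v in enumerate(values)]

    def test_simple_quantiles(self):
        s = summarize_distribution(self.recs([0.0, 0.5, 1.0]), bins=4)
        assert s.median == 0.5 and s.mean == pytest.approx(0.5)
        assert s.min == 0.0 and s.max == 1.0

    def test_constant_values_occupy_one_bin(self):
        s = summarize_distribution(self.recs([0.8] * 100), bins=10)
        assert s.min == s.max == s.median == 0.8
        occupied = [c for _, c in s.histogram if c > 0]
        assert occupied == [100]

    def test_bin_membership_with_right_closed_final_bin(self):
        values = [round(0.1 * i, 1) for i in range(1, 11)]
        s = summarize_distribution(self.recs(values), bins=5)
        assert [c for _, c in s.histogram] == [1, 2, 2, 2, 3]
        assert s.count == 10

    def test_undefined_counted_but_excluded(self):
        s = summarize_distribution(self.recs([0.5, None, 1.0]), bins=2)
        assert s.count == 2 and s.n_undefined == 1
        assert sum(c for _, c in s.histogram) == s.count

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution(self.recs([None, None]))

    def test_kappa_histogram_spans_negative_range(self):
        s = summarize_distribution(self.recs([-0.5, 0.5], metric="kappa"), bins=4)
        assert s.histogram[0][0] == pytest.approx(-1.0)


class TestVisualSampling:
    def test_selection_is_seed_deterministic(self):
        ids = [f"s{i}" for i in range(20)]
        assert select_visual_samples(ids, 5, 7) == select_visual_samples(ids, 5, 7)

    def test_selection_frequency_is_uniform(self):
        # one sample "scores far above the rest" — but selection never sees
        # scores, so its pick frequency must match the uniform expectation
        ids = [f"s{i}" for i in range(10)]
        star = "s3"
        k, n_seeds = 2, 500
        hits = sum(star in select_visual_samples(ids, k, seed) for seed in range(n_seeds))
        q = k / len(ids)
        sigma = np.sqrt(q * (1 - q) / n_seeds)
        assert abs(hits / n_seeds - q) < 3 * sigma

    def test_request_larger_than_population(self):
        assert sorted(select_visual_samples(["a", "b"], 5, 0)) == ["a", "b"]


class TestRenderOverlay:
    def test_binary_panels_side_by_side(self, tmp_path, toy_pair):
        import imageio.v3 as iio

        truth, pred = toy_pair
        path = render_overlay(truth, pred, tmp_path / "o.png")
        panel = iio.imread(path)
        assert panel.shape == (2, 2 + 2 + 2)

    def test_color_overlay_pixel_categories(self, tmp_path, toy_pair):
        import imageio.v3 as iio

        truth, pred = toy_pair
        base = np.zeros((2, 2), dtype=np.uint8)
        path = render_overlay(
            truth, pred, tmp_path / "c.png", style="color-overlay", image=base
        )
        rgb = iio.imread(path)
        # exactly one TP (greenish), one FP (reddish), one FN (blueish), one untouched
        assert tuple(rgb[0, 0]) == (0, 100, 0)  # TP at half opacity over black
        assert tuple(rgb[1, 0]) == (110, 0, 0)  # FP
        assert tuple(rgb[0, 1]) == (0, 40, 128)  # FN
        assert tuple(rgb[1, 1]) == (0, 0, 0)  # TN untouched

    def test_color_overlay_requires_base_image(self, tmp_path, toy_pair):
        with pytest.raises(ValueError, match="base"):
            render_overlay(*toy_pair, tmp_path / "x.png", style="color-overlay")


@pytest.fixture
def mask_dataset(tmp_path):
    """Three perturbed truth/pred PNG pairs written through the package I/O."""
    truth_dir = tmp_path / "truth"
    pred_dir = tmp_path / "pred"
    truth_dir.mkdir()
    pred_dir.mkdir()
    for i in range(3):
        truth = make_truth((20, 20), 9.0)
        pred = predict_scenario(
            truth,
            ScenarioSpec("perturbed", perturb=Perturbation((i, 0), i % 2, 0), seed=i),
        )
        write_mask(truth, truth_dir / f"s{i}.png")
        write_mask(pred, pred_dir / f"s{i}.png")
    return truth_dir, pred_dir


class TestRunEvaluation:
    def test_pipeline_outputs_and_record_counts(self, mask_dataset, tmp_path):
        truth_dir, pred_dir = mask_dataset
        out = tmp_path / "report"
        cfg = RunConfig(truth_dir, pred_dir, out, metrics=("dsc",), seed=0)
        records = run_evaluation(cfg)
        per_class = [r for r in records if r.class_label != "all"]
        assert len(per_class) == 3 * 2  # 3 samples x 2 classes
        assert (out / "scores.csv").exists()
        assert (out / "summary.json").exists()
        assert (out / "manifest.json").exists()
        summary = json.loads((out / "summary.json").read_text())
        class1 = [
            s
            for s in summary["summaries"]
            if s["metric"] == "dsc" and s["class_label"] == 1
        ]
        assert class1[0]["count"] == 3

    def test_no_segmentation_scores_zero_dsc(self, tmp_path):
        truth_dir = tmp_path / "t"
        pred_dir = tmp_path / "p"
        truth_dir.mkdir(), pred_dir.mkdir()
        for i in range(2):
            truth = make_truth((10, 10), 9.0)
            pred = predict_scenario(truth, ScenarioSpec("no-segmentation"))
            write_mask(truth, truth_dir / f"s{i}.png")
            write_mask(pred, pred_dir / f"s{i}.png")
        records = run_evaluation(
            RunConfig(truth_dir, pred_dir, tmp_path / "out", metrics=("dsc",), macro=False)
        )
        class1 = [r for r in records if r.class_label == 1]
        assert all(r.value == 0.0 for r in class1)

    def test_byte_identical_outputs_for_same_config_and_seed(
        self, mask_dataset, tmp_path
    ):
        truth_dir, pred_dir = mask_dataset
        outputs = []
        for name in ("r1", "r2"):
            out = tmp_path / name
            run_evaluation(
                RunConfig(
                    truth_dir, pred_dir, out,
                    metrics=("dsc", "iou", "sens", "spec", "ahd"),
                    micro=True, seed=11,
                )
            )
            outputs.append(out)
        for fname in ("scores.csv", "summary.json"):
            assert (outputs[0] / fname).read_bytes() == (outputs[1] / fname).read_bytes()
        overlays = sorted(p.name for p in (outputs[0] / "overlays").iterdir())
        for name in overlays:
            assert (outputs[0] / "overlays" / name).read_bytes() == (
                outputs[1] / "overlays" / name
            ).read_bytes()

    def test_no_matching_filenames_rejected(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        a.mkdir(), b.mkdir()
        write_mask(make_truth((5, 5), 4.0), a / "x.png")
        write_mask(make_truth((5, 5), 4.0), b / "y.png")
        with pytest.raises(ValueError, match="no matching"):
            run_evaluation(RunConfig(a, b, tmp_path / "o"))

    def test_micro_rows_present_when_requested(self, mask_dataset, tmp_path):
        truth_dir, pred_dir = mask_dataset
        records = run_evaluation(
            RunConfig(
                truth_dir, pred_dir, tmp_path / "o",
                metrics=("dsc",), micro=True, macro=False,
            )
        )
        micro_rows = [r for r in records if "micro" in r.policy_note]
        assert len(micro_rows) == 3

    def test_accuracy_request_adds_imbalance_caveat(self, mask_dataset, tmp_path):
        truth_dir, pred_dir = mask_dataset
        out = tmp_path / "o"
        run_evaluation(RunConfig(truth_dir, pred_dir, out, metrics=("dsc", "acc")))
        summary = json.loads((out / "summary.json").read_text())
        assert any("background" in c for c in summary["caveats"])


class TestCli:
    def test_simulate_then_evaluate_round_trip(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        res = runner.invoke(
            cli_main,
            ["simulate", "--scenario", "perturbed", "--n", "3",
             "--shape", "16,16", "--ratio", "9", "--seed", "3",
             "--out", str(data)],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            ["evaluate", "--truth", str(data / "truth"), "--pred", str(data / "pred"),
             "--metrics", "dsc,iou,ahd", "--seed", "1", "--out", str(tmp_path / "rep")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "rep" / "scores.csv").exists()
        manifest = json.loads((tmp_path / "rep" / "manifest.json").read_text())
        assert manifest["seed"] == 1 and manifest["ahd_clip"] == 250.0

    def test_unknown_metric_fails_loudly(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "d"
        runner.invoke(
            cli_main,
            ["simulate", "--scenario", "none", "--n", "1", "--shape", "8,8",
             "--ratio", "3", "--out", str(data)],
        )
        res = runner.invoke(
            cli_main,
            ["evaluate", "--truth", str(data / "truth"), "--pred", str(data / "pred"),
             "--metrics", "dice", "--out", str(tmp_path / "r")],
        )
        assert res.exit_code != 0
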