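"""Pullback I/O round-trips, polar rendering geometry, and the CLI."""

import csv
import json
from pathlib import Path

import numpy as np
import pytest

from octaline.cli import cli_entry
from octaline.interface import (
    ClassificationMap,
    FormatError,
    VocabularyError,
    polar_to_cartesian,
    read_pullback,
    render_classification_rings,
    write_pullback,
)
from octaline.simdata import PolarBScan, simulate_dataset

from conftest import small_sim


@pytest.fixture(scope="module")
def pullback_dir(tmp_path_factory):
    pb = simulate_dataset(small_sim(4, seed=17, alines=128, depth=64))
    out = tmp_path_factory.mktemp("pb")
    write_pullback(pb, out)
    return out, pb


class TestPullbackIO:
    def test_round_trip_is_bit_identical(self, pullback_dir):
        out, pb = pullback_dir
        bscans, labels, manifest = read_pullback(out)
        assert manifest["n_bscans"] == 4
        for orig, loaded in zip(pb.bscans, bscans):
            np.testing.assert_array_equal(
                orig.intensity.astype(np.float32), loaded.intensity)
        for orig, loaded in zip(pb.labels, labels):
            np.testing.assert_array_equal(orig.class_idx, loaded.class_idx)

    def test_unknown_label_token_names_offending_row(self, pullback_dir, tmp_path):
        out, _ = pullback_dir
        rows = list(csv.reader(open(out / "labels.csv")))
        rows[5][2] = "fibrotic"  # not in the five-class vocabulary
        bad = tmp_path / "bad"
        bad.mkdir()
        (bad / "bscans.tif").write_bytes((out / "bscans.tif").read_bytes())
        (bad / "manifest.json").write_text((out / "manifest.json").read_text())
        with open(bad / "labels.csv", "w", newline="") as fh:
            csv.writer(fh).writerows(rows)
        with pytest.raises(VocabularyError, match="row 6"):
            read_pullback(bad)

    def test_geometry_mismatch_rejected(self, pullback_dir, tmp_path):
        out, _ = pullback_dir
        bad = tmp_path / "bad"
        bad.mkdir()
        (bad / "bscans.tif").write_bytes((out / "bscans.tif").read_bytes())
        (bad / "labels.csv").write_text((out / "labels.csv").read_text())
        manifest = json.loads((out / "manifest.json").read_text())
        manifest["alines_per_bscan"] = 1024
        (bad / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(FormatError):
            read_pullback(bad)


class TestPolarToCartesian:
    def test_constant_polar_image_gives_constant_disk(self):
        bscan = PolarBScan(np.full((128, 64), 5.0), angular_step_deg=2.8125)
        disk = polar_to_cartesian(bscan, out_size=64, background=-1.0)
        inside = disk != -1.0
        assert inside.any()
        np.testing.assert_allclose(disk[inside], 5.0)

    def test_bright_aline_at_angle_zero_points_up(self):
        intensity = np.zeros((128, 64))
        intensity[0] = 10.0  # A-line at angle 0 = 12 o'clock
        bscan = PolarBScan(intensity, angular_step_deg=2.8125)
        disk = polar_to_cartesian(bscan, out_size=65)
        c = 32
        assert disk[c - 20, c] == 10.0   # above centre
        assert disk[c + 20, c] == 0.0    # below centre
        assert disk[c, c + 20] == 0.0    # to the right (90 deg clockwise)

    def test_center_pixel_takes_radius_zero_value(self):
        intensity = np.zeros((128, 64))
        intensity[:, 0] = 7.0
        bscan = PolarBScan(intensity, angular_step_deg=2.8125)
        disk = polar_to_cartesian(bscan, out_size=65)
        assert disk[32, 32] == 7.0

    def test_angular_undercoverage_preserved(self):
        # 1024 sectors x 0.35 deg = 358.4 deg: a narrow background wedge
        # remains just counter-clockwise of 12 o'clock
        intensity = np.full((1024, 64), 3.0)
        bscan = PolarBScan(intensity, angular_step_deg=0.35)
        disk = polar_to_cartesian(bscan, out_size=129, background=-1.0)
        assert (disk == -1.0).any()


class TestRings:
    def _render(self, truth, pred, n=256):
        cmap = ClassificationMap(0, truth, pred, angular_step_deg=360.0 / n)
        base = np.zeros((128, 128))
        return render_classification_rings(cmap, base)

    def test_matching_truth_and_prediction_give_identical_rings(self):
        n = 256
        truth = (np.arange(n) < 64).astype(int)
        rgb = self._render(truth, truth, n)
        size = 128
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(xx - 63.5, yy - 63.5) / 64.0
        outer = (r >= 0.92) & (r < 1.0)
        inner = (r >= 0.82) & (r < 0.90)
        # same angular color pattern in both rings: compare sector colors
        theta = np.degrees(np.arctan2(xx - 63.5, -(yy - 63.5))) % 360
        for lo, hi in ((10, 20), (100, 110), (200, 210)):
            wedge = (theta >= lo) & (theta < hi)
            a = rgb[outer & wedge].mean(axis=0)
            b = rgb[inner & wedge].mean(axis=0)
            np.testing.assert_allclose(a, b, atol=0.05)

    def test_all_other_map_renders_blue_rings(self):
        rgb = self._render(np.zeros(256, dtype=int), np.zeros(256, dtype=int))
        size = 128
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(xx - 63.5, yy - 63.5) / 64.0
        ring = (r >= 0.92) & (r < 1.0)
        assert np.allclose(rgb[ring], [0.12, 0.35, 0.80], atol=1e-6)

    def test_quarter_arc_covers_quarter_of_sectors(self):
        # a 90 deg lipid arc at 0.35 deg/A-line spans ~257 native A-lines
        n = 1024
        n_arc = int(round(90.0 / 0.35))
        assert n_arc == 257
        truth = np.zeros(n, dtype=int)
        truth[:n_arc] = 1
        cmap = ClassificationMap(0, truth, truth, angular_step_deg=0.35)
        rgb = render_classification_rings(cmap, np.zeros((256, 256)))
        size = 256
        yy, xx = np.mgrid[0:size, 0:size]
        r = np.hypot(xx - 127.5, yy - 127.5) / 128.0
        ring = (r >= 0.93) & (r < 0.99)
        orange = (np.abs(rgb[:, :, 0] - 1.0) < 1e-6) & (np.abs(rgb[:, :, 1] - 0.55) < 1e-6)
        frac = orange[ring].sum() / ring.sum()
        assert frac == pytest.approx(90.0 / 358.4, abs=0.02)

    def test_rendering_is_pure(self):
        base = np.random.default_rng(0).random((64, 64))
        before = base.copy()
        truth = np.zeros(256, dtype=int)
        cmap = ClassificationMap(0, truth, truth, angular_step_deg=360.0 / 256)
        a = render_classification_rings(cmap, base)
        b = render_classification_rings(cmap, base)
        np.testing.assert_array_equal(base, before)
        np.testing.assert_array_equal(a, b)

    def test_coverage_gap_rejected(self):
        cmap = ClassificationMap(0, np.zeros(512, dtype=int),
                                 np.zeros(512, dtype=int), angular_step_deg=0.35)
        with pytest.raises(ValueError):
            render_classification_rings(cmap, np.zeros((64, 64)))


class TestCLI:
    def test_simulate_writes_pullback_and_exits_zero(self, tmp_path):
        cfg = tmp_path / "sim.yaml"
        cfg.write_text(
            "sim:\n  n_bscans: 1\n  alines_per_bscan: 128\n  depth_px: 64\n"
            "  angular_step_deg: 2.8\n  lumen_radius_px_range: [8, 16]\n")
        out = tmp_path / "out"
        status = cli_entry(["simulate", "--config", str(cfg),
                            "--out", str(out), "--seed", "4"])
        assert status == 0
        assert (out / "bscans.tif").exists()
        assert (out / "manifest.json").exists()
        assert (out / "labels.csv").exists()

    def test_missing_config_fails_nonzero_without_outputs(self, tmp_path):
        out = tmp_path / "nope"
        status = cli_entry(["simulate", "--config", str(tmp_path / "absent.yaml"),
                            "--out", str(out)])
        assert status != 0
        assert not out.exists()

    def test_unknown_subcommand_fails(self):
        assert cli_entry(["frobnicate"]) != 0

    def test_predict_emits_one_row_per_native_aline(self, tmp_path):
        import octaline as oc
        from octaline.preprocess import bscan_features, fit_standardizer

        pb = simulate_dataset(oc.SimConfig(n_bscans=1, seed=31))
        data = tmp_path / "native"
        from octaline.interface import write_pullback
        write_pullback(pb, data)
        clf = oc.build_classifier()  # seeded, untrained: predictions valid
        clf.save_weights(tmp_path / "w.npz")
        std = fit_standardizer(bscan_features(pb.bscans[0]))
        (tmp_path / "std.json").write_text(json.dumps(std.to_dict()))
        out = tmp_path / "pred.csv"
        assert cli_entry(["predict", "--data", str(data),
                          "--weights", str(tmp_path / "w.npz"),
                          "--standardizer", str(tmp_path / "std.json"),
                          "--out", str(out)]) == 0
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 + 1024  # header + one row per native A-line
        # 2x upsampling: row pairs share their downsampled prediction
        preds = [int(l.split(",")[2]) for l in lines[1:]]
        assert all(preds[2 * i] == preds[2 * i + 1] for i in range(512))

    def test_train_evaluate_render_round_trip(self, pullback_dir, tmp_path):
        data, pb = pullback_dir
        cfg = tmp_path / "train.yaml"
        cfg.write_text(
            "model:\n  input_len: 32\n  max_epochs: 1\n  early_stop_patience: 1\n"
            "test_fraction: 0.5\nval_fraction: 0.5\n")
        run = tmp_path / "run"
        assert cli_entry(["train", "--config", str(cfg), "--data", str(data),
                          "--out", str(run), "--seed", "2"]) == 0
        assert (run / "weights.npz").exists()
        assert (run / "standardizer.json").exists()
        assert json.loads((run / "manifest.json").read_text())["epochs_run"] == 1

        # hand-made per-native-A-line predictions: everything "other"
        pred_csv = tmp_path / "pred.csv"
        rows = ["bscan_index,aline_index,prediction"]
        for bi, lab in enumerate(pb.labels):
            rows += [f"{bi},{ai},0" for ai in range(len(lab))]
        pred_csv.write_text("\n".join(rows) + "\n")

        report = tmp_path / "report.json"
        assert cli_entry(["evaluate", "--data", str(data),
                          "--predictions", str(pred_csv),
                          "--out", str(report)]) == 0
        summary = json.loads(report.read_text())
        truth = np.concatenate([l.binary for l in pb.labels])
        assert summary["accuracy"] == pytest.approx(1 - truth.mean())
        assert summary["sensitivity"] == 0.0

        png = tmp_path / "map.png"
        assert cli_entry(["render", "--data", str(data),
                          "--predictions", str(pred_csv),
                          "--bscan", "0", "--out", str(png)]) == 0
        assert png.stat().st_size > 0
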