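"""CSV assembly, batch/single entry points, overlays, template I/O."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from PIL import Image

import neglectscore as ns
from neglectscore.cli import main as cli_main
from neglectscore.report import (REPORT_COLUMNS, default_sv_tables,
                                 load_templates, read_report, run_batch,
                                 run_single, render_overlay, write_report)


@pytest.fixture(scope="module")
def batch_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("batch")
    ns.make_batch(d, 2, 77)
    return d


@pytest.fixture(scope="module")
def batch_result(batch_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("out") / "report.csv"
    templates = load_templates(batch_dir / "templates")
    csv_path, code, log = run_batch(batch_dir, templates, out_csv=out)
    return csv_path, code, log


class TestTemplateIO:
    def test_yaml_roundtrip(self, batch_dir):
        for subtest in ns.SUBTESTS:
            loaded = ns.LayoutTemplate.load(
                batch_dir / "templates" / f"{subtest}.yaml")
            built = ns.make_template(subtest)
            assert loaded.to_dict() == built.to_dict()

    def test_invalid_template_rejected(self):
        with pytest.raises(ValueError):
            ns.LayoutTemplate("line_bisection")   # needs 3 lines
        with pytest.raises(ValueError):
            ns.LayoutTemplate("unknown_subtest")


class TestBatch:
    def test_rows_match_ground_truth(self, batch_dir, batch_result):
        csv_path, code, log = batch_result
        df = read_report(csv_path)
        assert list(df.columns) == REPORT_COLUMNS
        assert len(df) == 2
        import json
        for _, row in df.iterrows():
            truth = json.loads(
                (batch_dir / f"{row.patient_id}_letter_cancellation"
                             ".truth.json").read_text())
            expected = sum(truth["crossed"].values())
            assert int(row["LetC"]) == expected

    def test_battery_columns_recomputable(self, batch_result, batch_dir):
        csv_path, _, _ = batch_result
        templates = load_templates(batch_dir / "templates")
        df = read_report(csv_path)
        from neglectscore import battery
        for _, row in df.iterrows():
            subtests = sorted(ns.SUBTESTS)
            raws = {"line_crossing": int(row.LineC),
                    "letter_cancellation": int(row.LetC),
                    "star_cancellation": int(row.StarC),
                    "line_bisection": int(row.LineB),
                    "copy_star": int(row.CopyStar),
                    "copy_diamond": int(row.CopyDiamond)}
            w = battery.subset_weights(
                [templates[s].max_raw_score for s in subtests], subtests)
            total, _ = battery.weighted_total([raws[s] for s in subtests], w)
            assert f"{total:.2f}" == row.BIT_weighted_total
            svs = [float(row[c]) for c in
                   ("LineC_SV", "LetC_SV", "StarC_SV", "LineB_SV",
                    "CopyStar_SV", "CopyDiamond_SV")]
            assert f"{sum(svs):.1f}" == row.NET_SV_total

    def test_rescoring_reproduces_csv_byte_identically(self, batch_dir,
                                                       batch_result,
                                                       tmp_path):
        csv_path, _, _ = batch_result
        templates = load_templates(batch_dir / "templates")
        again = tmp_path / "again.csv"
        run_batch(batch_dir, templates, out_csv=again)
        assert again.read_bytes() == csv_path.read_bytes()

    def test_csv_roundtrip(self, batch_result, tmp_path):
        csv_path, _, _ = batch_result
        df = read_report(csv_path)
        p2 = tmp_path / "rt.csv"
        df.to_csv(p2, index=False)
        assert read_report(p2).equals(df)

    def test_empty_directory_header_only(self, tmp_path):
        (tmp_path / "manifest.csv").write_text("patient_id,subtest,file\n")
        out = tmp_path / "r.csv"
        csv_path, code, log = run_batch(tmp_path, {}, out_csv=out)
        df = read_report(csv_path)
        assert len(df) == 0 and list(df.columns) == REPORT_COLUMNS
        assert code == 0

    def test_unreadable_manifest_aborts(self, tmp_path):
        with pytest.raises(ns.InputError):
            run_batch(tmp_path, {}, out_csv=tmp_path / "r.csv")

    def test_multiple_marks_leaves_cells_empty_and_flags(self, tmp_path):
        from neglectscore.synthetic import write_sheet
        templates = {"line_bisection": ns.make_template("line_bisection")}
        spec = ns.SyntheticSpec(
            subtest_id="line_bisection", seed=4,
            bisect_offsets={"T": -50.0, "M": 0.0, "B": 30.0},
            bisect_extra_mark_offset=-150.0)
        sheet, truth = ns.render_sheet(spec)
        write_sheet(tmp_path, "P0_line_bisection", sheet, truth)
        (tmp_path / "manifest.csv").write_text(
            "patient_id,subtest,file\nP0,line_bisection,"
            "P0_line_bisection.png\n")
        csv_path, code, log = run_batch(tmp_path, templates,
                                        out_csv=tmp_path / "r.csv")
        assert code == 2
        row = read_report(csv_path).iloc[0]
        assert row.LineB == "" and row.LineB_SV == ""
        assert "needs_review" in log[0]["flags"] or \
               "multiple_bisection_marks" in log[0]["flags"]


class TestRunSingle:
    def test_cancellation_tuple_order(self, batch_dir):
        tpl = ns.LayoutTemplate.load(
            batch_dir / "templates" / "line_crossing.yaml")
        out = run_single("line_crossing",
                         batch_dir / "P000_line_crossing.png", tpl)
        ls, rs, total, sv = out
        assert total == ls + rs

    def test_star_copy_tuple(self, batch_dir):
        tpl = ns.LayoutTemplate.load(
            batch_dir / "templates" / "copy_star.yaml")
        out = run_single("copy_star", batch_dir / "P000_copy_star.png", tpl)
        s, d, a, net, bit, sv = out
        assert net == s + d + a and bit == int(bool(s and d))

    def test_diamond_tuple_ends_with_hierarchical(self, batch_dir):
        tpl = ns.LayoutTemplate.load(
            batch_dir / "templates" / "copy_diamond.yaml")
        out = run_single("copy_diamond",
                         batch_dir / "P000_copy_diamond.png", tpl)
        assert len(out) == 7
        assert out[6] <= out[3]        # hierarchical <= plain sum

    def test_template_mismatch_rejected(self, batch_dir):
        tpl = ns.make_template("copy_star")
        with pytest.raises(ns.InputError):
            run_single("line_crossing",
                       batch_dir / "P000_line_crossing.png", tpl)


class TestOverlays:
    def _score(self, subtest, **kw):
        tpl = ns.make_template(subtest)
        sheet, _ = ns.render_sheet(
            ns.SyntheticSpec(subtest_id=subtest, seed=6, **kw))
        norm = ns.normalize_sheet(sheet.pixels, tpl)
        tables = default_sv_tables({s: ns.make_template(s)
                                    for s in ns.SUBTESTS})
        score = ns.score_sheet_image(norm, tpl, tables)
        return norm, score, tpl

    def test_line_crossing_midpoint_colors(self):
        norm, score, tpl = self._score("line_crossing", severity=0.9)
        img = render_overlay(norm, score, tpl)
        by_id = {r.target_id: r for r in score.result.records}
        for t in tpl.targets:
            color = tuple(img[int(t.y), int(t.x)])
            if by_id[t.id].crossed:
                assert color == (128, 128, 128)    # grey midpoint
            else:
                assert color == (0, 0, 0)          # black midpoint

    def test_star_cancellation_excluded_targets_yellow(self):
        norm, score, tpl = self._score("star_cancellation", severity=0.5)
        img = render_overlay(norm, score, tpl)
        for t in tpl.targets:
            color = tuple(img[int(t.y), int(t.x)])
            if t.excluded:
                assert color == (235, 200, 0)
            else:
                assert color in ((0, 170, 0), (220, 0, 0))

    def test_diamond_overlay_green_drawing_red_archetype(self):
        norm, score, tpl = self._score("copy_diamond")
        img = render_overlay(norm, score, tpl)
        flat = img.reshape(-1, 3)
        assert (flat == (0, 170, 0)).all(axis=1).any()     # drawing
        assert (flat == (220, 0, 0)).all(axis=1).any()     # archetype


class TestCLI:
    def test_make_and_score_roundtrip(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(cli_main, ["make-synthetic", "--out",
                                       str(tmp_path / "b"), "--patients",
                                       "1", "--seed", "5"])
        assert out.exit_code == 0, out.output
        out = runner.invoke(cli_main, [
            "score-batch", str(tmp_path / "b"),
            "--out", str(tmp_path / "r.csv")])
        assert out.exit_code in (0, 2), out.output
        df = read_report(tmp_path / "r.csv")
        assert len(df) == 1

    def test_score_single_prints_tuple(self, batch_dir):
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "score-single", "letter_cancellation",
            str(batch_dir / "P000_letter_cancellation.png"),
            "--template",
            str(batch_dir / "templates" / "letter_cancellation.yaml")])
        assert out.exit_code == 0, out.output
        assert out.output.strip().startswith("(")

    def test_compare_scores(self, batch_result, tmp_path):
        csv_path, _, _ = batch_result
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "compare-scores", str(csv_path), str(csv_path),
            "--out", str(tmp_path / "conc.json")])
        assert out.exit_code == 0, out.output
        import json
        rep = json.loads((tmp_path / "conc.json").read_text())
        assert rep["LetC"]["exact_agreement_pct"] == 100.0
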