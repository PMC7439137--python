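"""End-to-end coding pipeline: stages, fallbacks, batch processing, CLI."""

import io

import pytest

from occucoder import (CodingInput, NocError, NocParseError, PipelineConfig,
                       SearchStrategy, code_batch, code_record,
                       read_input_csv, write_results_csv)

from conftest import make_inputs_for


class TestCodeRecord:
    def test_verbatim_title_is_an_exact_step1_hit(self, fixture_db):
        result = code_record(CodingInput(job_title="legislators"), fixture_db)
        assert result.assigned == "0011"
        assert result.pipeline_step == 1
        assert result.strategy is SearchStrategy.EXACT

    def test_case_and_whitespace_invariance(self, fixture_db):
        result = code_record(CodingInput(job_title="  LEGISLATORS  "), fixture_db)
        assert result.assigned == "0011"
        assert result.strategy is SearchStrategy.EXACT

    def test_transposed_title_recovered_by_spell_corrected_search(self, fixture_db):
        result = code_record(CodingInput(job_title="legislatros"), fixture_db)
        assert result.assigned == "0011"
        assert result.strategy is SearchStrategy.MINOR_EXACT

    def test_uncodable_record_is_returned_unassigned(self, fixture_db):
        result = code_record(CodingInput(job_title="zzzz qqqq"), fixture_db)
        assert result.assigned is None
        assert result.pipeline_step is None and result.strategy is None

    def test_industry_used_when_title_absent(self, fixture_db):
        result = code_record(CodingInput(industry="legislators"), fixture_db)
        assert result.assigned == "0011" and result.pipeline_step == 1

    def test_slash_compound_first_part_has_priority(self, table2_db):
        cfg = PipelineConfig(strategies=(SearchStrategy.EXACT,
                                         SearchStrategy.MINOR_EXACT))
        result = code_record(
            CodingInput(job_title="manager/owner of cleaning business"),
            table2_db, cfg)
        assert result.assigned == "0311"   # "manager" splits out first
        assert result.pipeline_step == 2

    def test_teacher_education_resolves_through_hierarchy(self, fixture_db):
        result = code_record(
            CodingInput(job_title="TEACHER", industry="EDUCATION"), fixture_db)
        assert result.assigned == "4031"
        assert result.filter_trace is not None
        assert dict(result.filter_trace.surviving_codes_per_step)[4] == \
            ("4031", "4032")

    def test_input_without_title_or_industry_rejected(self):
        with pytest.raises(NocError):
            CodingInput(job_title="  ", industry=None)

    def test_exactly_one_or_none(self, synthetic_db):
        from occucoder import generate_inputs, NoiseConfig
        records = generate_inputs(synthetic_db, 40,
                                  NoiseConfig(typo_rate=0.5, seed=3))
        for record in records:
            result = code_record(record, synthetic_db)
            assert (result.assigned is None) or (
                len(result.assigned) == 4 and result.assigned.isdigit())
            assert (result.pipeline_step is None) == (result.assigned is None)

    def test_repair_disabled_equals_pure_exact_lookup(self, fixture_db):
        cfg = PipelineConfig(split_titles=False, combine_title_industry=False,
                             stop_word_removal=False, stemming=False,
                             noun_extraction=False, industry_fallback=False,
                             spell_correction=False,
                             strategies=(SearchStrategy.EXACT,))
        for unit in fixture_db.unit_groups.values():
            result = code_record(CodingInput(job_title=unit.example_titles[0]),
                                 fixture_db, cfg)
            assert result.assigned == unit.code
            assert result.strategy is SearchStrategy.EXACT


class TestGenerationPresets:
    def test_g0_disables_later_updates(self):
        g0 = PipelineConfig.generation("g0")
        assert not g0.split_titles and not g0.spell_correction
        assert SearchStrategy.MINOR_EXACT not in g0.strategies
        assert len(g0.strategies) == 4

    def test_g4_is_the_default(self):
        assert PipelineConfig.generation("g4") == PipelineConfig()

    def test_unknown_preset_rejected(self):
        with pytest.raises(NocError):
            PipelineConfig.generation("g9")

    def test_g0_cannot_code_what_g1_corrects(self, fixture_db):
        record = CodingInput(job_title="legislatros")
        assert code_record(record, fixture_db,
                           PipelineConfig.generation("g0")).assigned is None
        assert code_record(record, fixture_db,
                           PipelineConfig.generation("g1")).assigned == "0011"


class TestCodeBatch:
    def test_table2_shaped_batch_fully_coded(self, table2_db):
        records = [
            CodingInput("Owner of cleaning business", "Service industry", "0651"),
            CodingInput("Managing website", "Computer technology", "0213"),
            CodingInput("Manager", "Health care", "0311"),
        ]
        results, report = code_batch(records, table2_db)
        assert len(results) == 3
        assert report["production_rate"] == 1.0

    def test_output_preserves_input_order(self, synthetic_db):
        records = make_inputs_for(synthetic_db)
        results, _ = code_batch(records, synthetic_db)
        assert [r.input for r in results] == records

    def test_report_counts_steps_and_strategies(self, fixture_db):
        records = [CodingInput(job_title="legislators"),
                   CodingInput(job_title="zzzz qqqq")]
        results, report = code_batch(records, fixture_db)
        assert report["n_records"] == 2 and report["n_coded"] == 1
        assert report["by_strategy"] == {"EXACT": 1}
        assert results[1].assigned is None  # unassigned emitted, not dropped

    def test_empty_batch_rejected(self, fixture_db):
        with pytest.raises(NocError):
            code_batch([], fixture_db)


class TestBatchIO:
    CSV = ("job_title,industry,gold_code\n"
           "legislators,,0011\n"
           "TEACHER,EDUCATION,4032\n")

    def test_read_write_round_trip(self, fixture_db, tmp_path):
        records = read_input_csv(io.StringIO(self.CSV))
        assert records[0].job_title == "legislators"
        results, _ = code_batch(records, fixture_db)
        out = tmp_path / "coded.csv"
        write_results_csv(results, str(out))
        text = out.read_text()
        assert "assigned_code" in text and "0011" in text

    def test_blank_row_rejected_with_row_number(self):
        bad = "job_title,industry,gold_code\nlegislators,,\n , ,\n"
        with pytest.raises(NocParseError, match="row 3"):
            read_input_csv(io.StringIO(bad))


class TestCli:
    def test_fixtures_code_eval_flow(self, tmp_path):
        from click.testing import CliRunner
        from occucoder.cli import main

        runner = CliRunner()
        fx = tmp_path / "fx"
        result = runner.invoke(main, ["fixtures", "--out", str(fx),
                                      "--seed", "1", "--n-inputs", "30"])
        assert result.exit_code == 0, result.output
        coded = tmp_path / "coded.csv"
        result = runner.invoke(main, [
            "code", "--noc", str(fx / "noc_synthetic.csv"),
            "--input", str(fx / "inputs_synthetic.csv"),
            "--output", str(coded)])
        assert result.exit_code == 0, result.output
        assert "production rate" in result.output
        result = runner.invoke(main, ["eval", "--coded", str(coded)])
        assert result.exit_code == 0, result.output
        assert "accuracy_4digit_pct" in result.output

    def test_code_fails_cleanly_on_missing_file(self, tmp_path):
        from click.testing import CliRunner
        from occucoder.cli import main

        result = CliRunner().invoke(main, [
            "code", "--noc", str(tmp_path / "nope.csv"),
            "--input", str(tmp_path / "nope.csv"),
            "--output", str(tmp_path / "out.csv")])
        assert result.exit_code != 0
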