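"""CSV reader/writer, synthetic generator and CLI plumbing."""

import io

import numpy as np
import pytest
from click.testing import CliRunner
from scipy import stats

from cardiotriage import (
    SyntheticConfig,
    classify,
    generate_synthetic_records,
    read_uci_csv,
    write_records_csv,
)
from cardiotriage.cli import main as cli_main

# three well-formed rows in the UCI processed-Cleveland layout:
# age,sex,cp,trestbps,chol,fbs,restecg,thalach,exang,oldpeak,slope,ca,thal,num
TOY_CSV = """\
63,1,1,145,233,1,2,150,0,2.3,3,0,6,0
67,1,4,160,286,0,2,108,1,1.5,2,3,3,2
41,0,2,130,204,0,2,172,0,1.4,1,0,3,0
"""


class TestReadUciCsv:
    def test_well_formed_rows_all_parse(self):
        table = read_uci_csv(io.StringIO(TOY_CSV))
        assert len(table) == 3
        assert table.n_rejected == 0
        assert table.missing_key == [False, False, False]

    def test_column_mapping(self):
        rec = read_uci_csv(io.StringIO(TOY_CSV)).records[0]
        assert rec.age == 63
        assert rec.gender == 1
        assert rec.chest_pain == 1
        assert rec.blood_pressure == 145
        assert rec.cholesterol == 233
        assert rec.ecg == 2
        assert rec.max_heart_rate == 150
        assert rec.old_peak == 2.3
        assert rec.thallium == 6

    def test_fbs_flag_maps_to_one_hot_sugar(self, variables):
        from cardiotriage import fuzzify

        table = read_uci_csv(io.StringIO(TOY_CSV))
        hi = fuzzify(table.records[0], variables).degrees["blood_sugar"]
        lo = fuzzify(table.records[1], variables).degrees["blood_sugar"]
        assert hi == {"normal": 0.0, "very_high": 1.0}
        assert lo == {"normal": 1.0, "very_high": 0.0}

    def test_missing_thallium_flagged_not_dropped(self):
        text = TOY_CSV.replace("1.4,1,0,3,0", "1.4,1,0,?,0")
        table = read_uci_csv(io.StringIO(text))
        assert len(table) == 3
        assert table.missing_key == [False, False, True]
        assert len(table.classifiable()) == 2

    def test_wrong_field_count_reports_line(self):
        with pytest.raises(ValueError, match="line 2"):
            read_uci_csv(io.StringIO("63,1,1,145,233,1,2,150,0,2.3,3,0,6,0\n1,2,3\n"))

    def test_non_numeric_field_reports_column(self):
        bad = TOY_CSV.replace("145", "abc")
        with pytest.raises(ValueError, match="trestbps"):
            read_uci_csv(io.StringIO(bad))

    def test_out_of_domain_row_rejected_with_reason(self):
        bad = TOY_CSV.replace("63,1,1,145", "63,1,9,145")  # chest pain code 9
        table = read_uci_csv(io.StringIO(bad))
        assert len(table) == 2
        assert table.n_rejected == 1
        assert "chest_pain" in table.reject_reasons[0]

    def test_num_label_carried_through(self):
        table = read_uci_csv(io.StringIO(TOY_CSV))
        assert table.num_labels == [0, 2, 0]


class TestRoundTrip:
    def test_write_then_read_is_identity(self):
        table = generate_synthetic_records(SyntheticConfig(n=25, seed=3))
        buf = io.StringIO()
        write_records_csv(table, buf)
        buf.seek(0)
        back = read_uci_csv(buf)
        assert len(back) == len(table)
        for a, b in zip(table.records, back.records):
            for name in ("chest_pain", "blood_pressure", "cholesterol",
                         "blood_sugar", "max_heart_rate", "ecg", "old_peak",
                         "thallium", "gender", "age"):
                assert a.value(name) == pytest.approx(b.value(name), abs=1e-9)


class TestSyntheticGenerator:
    def test_seeded_determinism(self):
        a = generate_synthetic_records(SyntheticConfig(n=100, seed=42))
        b = generate_synthetic_records(SyntheticConfig(n=100, seed=42))
        assert a.records == b.records

    def test_different_seeds_differ(self):
        a = generate_synthetic_records(SyntheticConfig(n=20, seed=1))
        b = generate_synthetic_records(SyntheticConfig(n=20, seed=2))
        assert a.records != b.records

    def test_all_records_valid_and_complete(self, variables):
        table = generate_synthetic_records(SyntheticConfig(n=2000, seed=5))
        for rec in table.records:
            rec.validate(variables)  # raises on violation
            assert not rec.missing()

    def test_chest_pain_codes_uniform(self):
        table = generate_synthetic_records(SyntheticConfig(n=10000, seed=9))
        codes = [r.chest_pain for r in table.records]
        counts = [codes.count(float(c)) for c in (1, 2, 3, 4)]
        assert stats.chisquare(counts).pvalue > 0.001

    def test_generator_output_always_classifiable(self, canonical_base, canonical_index):
        table = generate_synthetic_records(SyntheticConfig(n=200, seed=13))
        for rec in table.records:
            res = classify(rec, canonical_base, canonical_index)
            assert res.criticality_class in (1, 2, 3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n=0)
        with pytest.raises(ValueError):
            SyntheticConfig(n=5, critical_skew=2.0)


class TestCli:
    def test_simulate_then_classify_pipeline(self, tmp_path):
        runner = CliRunner()
        records = tmp_path / "records.csv"
        results = tmp_path / "results.csv"
        r = runner.invoke(cli_main, ["simulate", "--n", "10", "--seed", "1",
                                     "--out", str(records)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["classify", str(records),
                                     "--out", str(results)])
        assert r.exit_code == 0, r.output
        lines = results.read_text().splitlines()
        assert lines[0].startswith("record_id,z_star,class,ring")
        assert len(lines) == 11  # header + 10 records

    def test_generate_rules_line_count(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "rules.jsonl"
        r = runner.invoke(cli_main, ["generate-rules", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert len(out.read_text().splitlines()) == 82944 + 1  # header + rules

    def test_benchmark_prints_ratio_24(self, tmp_path):
        runner = CliRunner()
        records = tmp_path / "records.csv"
        runner.invoke(cli_main, ["simulate", "--n", "3", "--seed", "2",
                                 "--out", str(records)])
        r = runner.invoke(cli_main, ["benchmark", str(records)])
        assert r.exit_code == 0, r.output
        lines = r.output.strip().splitlines()
        assert lines[0] == "n_rules,scanned_exhaustive,scanned_indexed,ratio"
        for line in lines[1:]:
            n, ex, ix, ratio = line.split(",")
            assert (n, ex, ix) == ("82944", "82944", "3456")
            assert float(ratio) == 24.0

    def test_usage_error_nonzero_exit(self):
        r = CliRunner().invoke(cli_main, ["classify"])  # missing argument
        assert r.exit_code != 0

    def test_show_variables_round_trips(self):
        from cardiotriage import canonical_variables, variables_from_json

        r = CliRunner().invoke(cli_main, ["show-variables"])
        assert r.exit_code == 0
        assert variables_from_json(r.output) == canonical_variables()
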