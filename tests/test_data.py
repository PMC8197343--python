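"""Quantal / summary CSV round trips, validation, and report writing."""

import json

import pandas as pd
import pytest

from isoquantal.data import (DoseResponseDataset, FormatError,
                             QuantalDoseGroup, SummaryEffectRecord,
                             ValidationError, read_quantal_csv,
                             read_summary_csv, write_quantal_csv,
                             write_report, write_summary_csv)
from isoquantal.pipeline import study_results


def _write(tmp_path, text, name="in.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestQuantalCSV:
    def test_single_label_parsed_and_sorted(self, tmp_path):
        p = _write(tmp_path, "subject_label,dose,n_subjects,n_responders\n"
                             "LCM,4,8,4\nLCM,2,8,1\nLCM,8,8,7\n")
        (ds,) = read_quantal_csv(p)
        assert ds.subject_label == "LCM"
        assert ds.doses == (2.0, 4.0, 8.0)
        assert [g.n_responders for g in ds.groups] == [1, 4, 7]

    def test_two_labels_give_two_datasets(self, tmp_path):
        p = _write(tmp_path, "subject_label,dose,n_subjects,n_responders\n"
                             "B,1,8,2\nA,10,8,6\nA,5,8,2\nB,2,8,5\n")
        a, b = read_quantal_csv(p)
        assert (a.subject_label, b.subject_label) == ("A", "B")
        assert a.doses == (5.0, 10.0) and b.doses == (1.0, 2.0)

    def test_responders_exceeding_subjects_cites_row(self, tmp_path):
        p = _write(tmp_path, "subject_label,dose,n_subjects,n_responders\n"
                             "LCM,2,8,1\nLCM,4,8,9\n")
        with pytest.raises(ValidationError, match="row 3"):
            read_quantal_csv(p)

    def test_missing_column_named(self, tmp_path):
        p = _write(tmp_path, "subject_label,dose,n_subjects\nLCM,2,8\n")
        with pytest.raises(FormatError, match="n_responders"):
            read_quantal_csv(p)

    def test_nonpositive_dose_rejected(self, tmp_path):
        p = _write(tmp_path, "subject_label,dose,n_subjects,n_responders\n"
                             "LCM,0,8,1\n")
        with pytest.raises(ValidationError, match="dose"):
            read_quantal_csv(p)

    def test_metadata_columns_pass_through(self, tmp_path):
        p = _write(tmp_path,
                   "subject_label,dose,n_subjects,n_responders,route\n"
                   "LCM,2,8,1,ip\nLCM,4,8,4,ip\n")
        (ds,) = read_quantal_csv(p)
        assert ds.metadata == {"route": "ip"}

    def test_round_trip_identity(self, tmp_path):
        ds = DoseResponseDataset("MIX", (QuantalDoseGroup(2.5, 8, 1),
                                         QuantalDoseGroup(5.0, 8, 6)),
                                 metadata={"vehicle": "tween"})
        out = tmp_path / "rt.csv"
        write_quantal_csv([ds], out)
        (back,) = read_quantal_csv(out)
        assert back == ds

    def test_parsing_is_row_order_independent(self, tmp_path):
        rows = ["X,8,8,6", "Y,1,8,0", "X,2,8,1", "Y,4,8,7", "X,4,8,3"]
        header = "subject_label,dose,n_subjects,n_responders\n"
        a = read_quantal_csv(_write(tmp_path, header + "\n".join(rows), "a.csv"))
        b = read_quantal_csv(_write(tmp_path, header + "\n".join(rows[::-1]),
                                    "b.csv"))
        assert a == b


class TestSummaryCSV:
    def test_parse_summary_row(self, tmp_path):
        p = _write(tmp_path, "label,ed50,sem,n\nLCM+TPM+PGB_exp,35.50,5.28,24\n")
        (rec,) = read_summary_csv(p)
        assert rec == SummaryEffectRecord("LCM+TPM+PGB_exp", 35.50, 5.28, 24)

    @pytest.mark.parametrize("row", ["X,10,0,8", "X,-1,2,8", "X,10,2,1"])
    def test_invalid_record_rejected(self, tmp_path, row):
        p = _write(tmp_path, f"label,ed50,sem,n\n{row}\n")
        with pytest.raises(ValidationError):
            read_summary_csv(p)

    def test_round_trip_identity(self, tmp_path):
        recs = [SummaryEffectRecord("a", 12.345678, 1.2345, 24),
                SummaryEffectRecord("b", 64.8, 5.02, 50)]
        out = tmp_path / "s.csv"
        write_summary_csv(recs, out)
        assert read_summary_csv(out) == recs


class TestReport:
    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_report([], tmp_path / "r")

    def test_six_results_ranked_descending_by_index(self, tmp_path):
        paths = write_report(study_results(), tmp_path / "r")
        df = pd.read_csv(paths["csv"])
        assert len(df) == 6
        assert list(df.interaction_index) == sorted(df.interaction_index,
                                                    reverse=True)
        assert df.combination_label.iloc[0] == "LCM + OXC + TPM"
        assert df.combination_label.iloc[-1] == "LCM + TPM + PGB"
        assert "Synergy" in df.classification.values

    def test_json_keeps_full_precision(self, tmp_path):
        results = study_results()
        paths = write_report(results, tmp_path / "r")
        rows = json.loads(paths["json"].read_text())
        by_label = {r["combination_label"]: r for r in rows}
        for res in results:
            assert by_label[res.combination_label]["t"] == res.t
            assert (by_label[res.combination_label]["interaction_index"]
                    == res.interaction_index)
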