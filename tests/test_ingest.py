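"""Diary reading, cleaning rules, composites, standardization."""

import numpy as np
import pandas as pd
import pytest

from esmlag import (
    DiaryPanel,
    IngestError,
    compute_composites,
    dedupe_daily,
    exclude_subjects,
    preprocess,
    read_diary_csv,
    standardize,
    write_diary_csv,
)
from esmlag.items import SYMPTOM_ITEMS
from tests.conftest import make_diary_frame


def _one_record(**overrides):
    row = {"subject_id": "P1", "date": "2020-01-01", "sleep_duration": 7.5,
           "sleep_quality": 3}
    row.update({item: 4 for item in SYMPTOM_ITEMS})
    row.update(overrides)
    return row


class TestReader:
    def test_wide_fixture_parses(self, tmp_path, diary_frame):
        path = tmp_path / "d.csv"
        diary_frame.to_csv(path, index=False)
        panel = read_diary_csv(path, "wide")
        assert len(panel.data) == len(diary_frame)
        assert panel.report.n_rows_rejected == 0
        assert pd.api.types.is_datetime64_any_dtype(panel.data["date"])

    def test_out_of_range_row_rejected_and_counted(self, tmp_path):
        df = pd.DataFrame([_one_record(), _one_record(date="2020-01-02", sleep_quality=9)])
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        panel = read_diary_csv(path, "wide")
        assert len(panel.data) == 1
        assert panel.report.reject_reasons["sleep_quality out of range"] == 1

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(IngestError, match="no such file"):
            read_diary_csv(tmp_path / "missing.csv")

    def test_unparseable_date_rejected(self, tmp_path):
        df = pd.DataFrame([_one_record(), _one_record(date="not-a-date"),
                           _one_record(date="2020-01-03")])
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        panel = read_diary_csv(path, "wide")
        assert len(panel.data) == 2
        assert panel.report.reject_reasons["unparseable date"] == 1

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(IngestError, match="no records"):
            read_diary_csv(path)

    def test_mostly_invalid_file_errors(self, tmp_path):
        rows = [_one_record(date=f"2020-01-{d:02d}", sleep_quality=99) for d in range(1, 8)]
        rows.append(_one_record(date="2020-02-01"))
        path = tmp_path / "bad.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        with pytest.raises(IngestError, match="invalid"):
            read_diary_csv(path)

    def test_unknown_column_errors(self, tmp_path):
        df = pd.DataFrame([{**_one_record(), "mystery": 1}])
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        with pytest.raises(IngestError, match="unknown column"):
            read_diary_csv(path)

    def test_round_trip_wide_and_long(self, tmp_path, diary_frame):
        panel = DiaryPanel(diary_frame)
        for dialect in ("wide", "long"):
            path = tmp_path / f"{dialect}.csv"
            write_diary_csv(panel, path, dialect)
            back = read_diary_csv(path, dialect)
            a = panel.data.sort_values(["subject_id", "date"]).reset_index(drop=True)
            b = back.data[a.columns].sort_values(["subject_id", "date"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b, check_dtype=False)


class TestCleaning:
    def test_dedupe_keeps_first_entry(self):
        rows = [
            _one_record(sleep_quality=2),
            _one_record(sleep_quality=5),  # same subject-date duplicate
            _one_record(date="2020-01-02"),
        ]
        panel = dedupe_daily(DiaryPanel(pd.DataFrame(rows)))
        assert len(panel.data) == 2
        assert panel.report.duplicates_removed == 1
        kept = panel.data[panel.data["date"] == "2020-01-01"]["sleep_quality"].iloc[0]
        assert kept == 2

    def test_dedupe_identity_without_duplicates(self, diary_panel):
        before = diary_panel.data.copy()
        after = dedupe_daily(diary_panel)
        pd.testing.assert_frame_equal(before, after.data)
        assert after.report.duplicates_removed == 0

    def test_triple_entry_keeps_one(self):
        rows = [_one_record(sleep_quality=q) for q in (1, 2, 3)]
        panel = dedupe_daily(DiaryPanel(pd.DataFrame(rows)))
        assert len(panel.data) == 1
        assert panel.report.duplicates_removed == 2

    def test_composites_arithmetic(self):
        row = _one_record(cheerful=5, relaxed=3, in_control=4,
                          suspicious=7, others_dislike_me=1,
                          unusual_sights_sounds=2)
        panel = compute_composites(DiaryPanel(pd.DataFrame([row])))
        rec = panel.data.iloc[0]
        assert rec["positive_affect"] == pytest.approx(4.0)
        assert rec["paranoia"] == pytest.approx(4.0)
        assert rec["hallucinations"] == pytest.approx(2.0)
        assert rec["negative_affect"] == pytest.approx(4.0)
        assert rec["psychosis"] == pytest.approx((7 + 4 + 1 + 4 + 2) / 5)

    def test_missing_item_drops_composite_not_record(self):
        row = _one_record()
        row["confused"] = np.nan
        panel = compute_composites(DiaryPanel(pd.DataFrame([row])))
        rec = panel.data.iloc[0]
        assert np.isnan(rec["cognitive"])
        assert rec["positive_affect"] == pytest.approx(4.0)

    def test_exclusion_reasons(self):
        frames = [make_diary_frame(1, 40, seed=1)]
        short = make_diary_frame(1, 20, seed=2)
        short["subject_id"] = "SHORT"
        flat = make_diary_frame(1, 40, seed=3)
        flat["subject_id"] = "FLAT"
        for item in SYMPTOM_ITEMS:
            flat[item] = 4
        df = pd.concat(frames + [short, flat], ignore_index=True)
        panel = exclude_subjects(compute_composites(DiaryPanel(df)), min_days=30)
        assert panel.subjects == ["P1"]
        assert panel.report.subjects_excluded == {
            "SHORT": "duration",
            "FLAT": "no variability",
        }

    def test_all_subjects_excluded_errors(self):
        df = make_diary_frame(1, 10)
        with pytest.raises(IngestError, match="all subjects excluded"):
            exclude_subjects(compute_composites(DiaryPanel(df)), min_days=30)


class TestStandardize:
    def test_three_point_series_forced_z_scores(self):
        df = pd.DataFrame(
            {
                "subject_id": "P1",
                "date": pd.date_range("2020-01-01", periods=3),
                "sleep_quality": [1, 2, 3],
            }
        )
        sp = standardize(DiaryPanel(df), variables=["sleep_quality"])
        assert np.allclose(sp.data["sleep_quality"], [-1, 0, 1])

    def test_constant_series_dropped_with_warning(self):
        df = pd.DataFrame(
            {
                "subject_id": "P1",
                "date": pd.date_range("2020-01-01", periods=5),
                "sleep_quality": 3,
                "sleep_duration": [6, 7, 8, 7, 6],
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            sp = standardize(DiaryPanel(df), variables=["sleep_quality", "sleep_duration"])
        assert sp.data["sleep_quality"].isna().all()
        assert sp.data["sleep_duration"].notna().all()

    def test_mean_zero_sd_one_identity(self, diary_panel):
        sp = preprocess(diary_panel, min_days=30)
        for var in sp.variables:
            for _, g in sp.data.groupby("subject_id"):
                vals = g[var].dropna()
                if len(vals) > 1:
                    assert abs(vals.mean()) < 1e-10
                    assert abs(vals.std(ddof=1) - 1) < 1e-10

    def test_pipeline_idempotent(self, diary_panel):
        once = preprocess(diary_panel, min_days=30)
        twice = preprocess(DiaryPanel(once.data), min_days=30)
        for var in once.variables:
            np.testing.assert_allclose(
                once.data[var].to_numpy(), twice.data[var].to_numpy(), atol=1e-12
            )

    def test_response_rate_arithmetic(self, diary_panel):
        summ = diary_panel.subject_summary()
        assert (summ["submitted"] <= summ["span_days"]).all()
        assert ((summ["response_rate"] > 0) & (summ["response_rate"] <= 1)).all()
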