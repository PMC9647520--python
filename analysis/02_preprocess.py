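"""Clean the diary cohort and build the person-standardized panel.

Applies the fixed cleaning order — duplicate removal, composite scoring
(positive/negative affect, cognitive, psychosis, paranoia, hallucinations),
exclusion of short-enrolment and no-variability subjects, person-centred
z-scoring — and writes the standardized panel plus the cleaning report.

Run after 01_simulate.py:  python analysis/02_preprocess.py
"""

from pathlib import Path

from esmlag import preprocess, read_diary_csv

IN = Path("results/cohort/diary.csv")
OUT = Path("results/cohort")


def main() -> None:
    panel = preprocess(read_diary_csv(IN, "wide"))
    panel.data.to_csv(OUT / "standardized_panel.csv", index=False)
    panel.stats.to_csv(OUT / "standardization_stats.csv", index=False)
    panel.report.write_json(OUT / "cleaning_report.json")
    rep = panel.report
    print(f"retained {len(panel.subjects)} subjects "
          f"({len(rep.subjects_excluded)} excluded: {rep.subjects_excluded})")
    print(f"duplicates removed: {rep.duplicates_removed}; "
          f"rows rejected: {rep.n_rows_rejected}")


if __name__ == "__main__":
    main()
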