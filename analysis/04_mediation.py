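"""Mediation of the sleep -> psychosis effect by affect and cognition.

For each sleep variable and each putative mediator (negative affect,
cognitive symptoms) runs the Baron-Kenny / joint-significance procedure in
lag space — path a (sleep -> mediator), total effect (sleep -> psychosis),
the joint mediated model giving direct and indirect effects, BIC comparison
— plus the oppositional model with the sleep variable as mediator.  Writes
the mediation table and text path diagrams under results/.

Run after 02_preprocess.py:  python analysis/04_mediation.py
"""

from pathlib import Path

import pandas as pd

from esmlag import DiaryPanel, path_diagram, run_mediation, standardize

IN = Path("results/cohort/standardized_panel.csv")
OUT = Path("results/mediation")

TRIPLES = [
    ("sleep_quality", "negative_affect", "psychosis"),
    ("sleep_quality", "cognitive", "psychosis"),
    ("sleep_duration", "negative_affect", "psychosis"),
    ("sleep_duration", "cognitive", "psychosis"),
]


def main() -> None:
    df = pd.read_csv(IN, parse_dates=["date"])
    panel = standardize(DiaryPanel(df))
    OUT.mkdir(parents=True, exist_ok=True)
    rows, diagrams = [], []
    for x, m, y in TRIPLES:
        cmp_ = run_mediation(panel, x, m, y)
        for label, res in (("forward", cmp_.forward), ("oppositional", cmp_.oppositional)):
            row = res.to_dict()
            row["model"] = label
            row["preferred"] = cmp_.preferred
            rows.append(row)
            diagrams.append(f"[{label}] {row['triple']}\n{path_diagram(res)}\n")
        fw = cmp_.forward
        print(f"{x} | {m} | {y}: verdict {fw.verdict}; total "
              f"{fw.total_effect:+.3f} = direct {fw.direct_effect:+.3f} + "
              f"indirect {fw.indirect_effect:+.3f}  (preferred: {cmp_.preferred})")
    pd.DataFrame(rows).to_csv(OUT / "mediation_table.csv", index=False)
    (OUT / "path_diagrams.txt").write_text("\n".join(diagrams))
    print(f"\nwrote {OUT / 'mediation_table.csv'}")


if __name__ == "__main__":
    main()
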