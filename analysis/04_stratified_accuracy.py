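"""Stratified accuracy report and between-group delta-age comparisons.

Computes MAD, SEE, PCP (5/7.5/10 y) and R² per (age group x sex) stratum,
then rank-sum comparisons of delta age: adult vs old, young vs adult, and
male vs female — the full accuracy-evaluation layout of a clock
validation study.
"""

import argparse
import csv
from pathlib import Path

from pyroclock import Sex, compare_delta_age, evaluate_strata, read_predictions, write_report

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--predictions", type=Path, default=RESULTS / "predictions.csv")
    args = ap.parse_args()

    records = read_predictions(args.predictions)
    reports = evaluate_strata(records)
    out = RESULTS / "accuracy_report.csv"
    write_report(reports, out)
    for rep in reports:
        if rep.sex == "all":
            see = f"{rep.see:.2f}" if rep.see is not None else "--"
            r2 = f"{rep.r2:.3f}" if rep.r2 is not None else "--"
            print(f"{rep.age_group:6s} all  n={rep.n:3d}  MAD {rep.mad:5.2f}  "
                  f"SEE {see:>5s}  R^2 {r2:>5s}  PCP5 {rep.pcp[5.0]:5.1f}%")

    groups = {g: [r for r in records if r.age_group == g] for g in ("young", "adult", "old")}
    comparisons = []
    for a, b in (("adult", "old"), ("young", "adult")):
        if groups[a] and groups[b]:
            comparisons.append(compare_delta_age(groups[a], groups[b], a, b))
    males = [r for r in records if r.sex is Sex.MALE]
    females = [r for r in records if r.sex is Sex.FEMALE]
    if males and females:
        comparisons.append(compare_delta_age(males, females, "male", "female"))
    cmp_out = RESULTS / "comparisons.csv"
    with open(cmp_out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["group_a", "group_b", "n_a", "n_b", "statistic", "p_value", "method"])
        for c in comparisons:
            w.writerow([c.group_a, c.group_b, c.n_a, c.n_b,
                        f"{c.statistic:g}", f"{c.p_value:.4g}", c.method])
            print(f"delta age {c.group_a} vs {c.group_b}: p = {c.p_value:.4g} ({c.method})")
    print(f"wrote {out} and {cmp_out}")


if __name__ == "__main__":
    main()
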