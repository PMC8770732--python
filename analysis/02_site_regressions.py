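"""Per-site linear regressions of methylation on age.

For each CpG site in the simulated cohort, fit OLS of percent methylation
on chronological age and report slope, Pearson r and R² — the standard
first look at whether each site carries an age signal strong enough to
feed a clock (ELOVL2-class sites should reach |r| ~ 0.9, ASPA-class ~0.8).
"""

import argparse
import csv
from pathlib import Path

from pyroclock import read_samples, regress_site_on_age

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=RESULTS / "cohort.csv")
    args = ap.parse_args()

    samples = read_samples(args.cohort)
    site_ids = sorted({sid for s in samples for sid in s.methylation})
    out = RESULTS / "site_regressions.csv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site", "slope_pct_per_year", "intercept_pct", "pearson_r", "r_squared", "n"])
        for sid in site_ids:
            r = regress_site_on_age(samples, sid)
            w.writerow([sid, f"{r.slope:.4f}", f"{r.intercept:.2f}",
                        f"{r.pearson_r:.3f}", f"{r.r_squared:.3f}", r.n])
            print(f"{sid:12s} slope {r.slope:+.3f} %/y   r {r.pearson_r:+.3f}   R^2 {r.r_squared:.3f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
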