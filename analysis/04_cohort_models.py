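"""Scalar-outcome models of the demonstration cohort.

Fits the chronicity regressions (outcome: years of chronic low back pain;
predictors: subject-mean deep15 or overall FI%, mean disc degeneration, age,
sex, BMI), the physical-activity regression, and the two linear mixed-effects
models of per-level FI (deep15 and overall outcomes) with a subject random
intercept. Coefficient tables are written under results/demo/.
"""

import sys
from pathlib import Path

import pandas as pd

from fatmap.models import (activity_regression, build_long_table, chronicity_regression,
                           mixed_fi_model, subject_mean_metrics)

DEMO = Path(__file__).resolve().parents[1] / "results" / "demo"


def main():
    cohort = pd.read_csv(DEMO / "cohort.csv")
    metrics = pd.read_csv(DEMO / "metrics.csv")
    per_subject = subject_mean_metrics(metrics, cohort)
    long_table = build_long_table(metrics, cohort)

    fits = {
        "chronicity_deep15": chronicity_regression(per_subject, "deep15"),
        "chronicity_overall": chronicity_regression(per_subject, "overall"),
        "activity": activity_regression(per_subject),
        "mixed_deep15": mixed_fi_model(long_table, "deep15"),
        "mixed_overall": mixed_fi_model(long_table, "overall"),
    }
    for name, fit in fits.items():
        out = DEMO / f"model_{name}.csv"
        fit.table.round(4).to_csv(out, index_label="term")
        print(f"\n{name}  (n_obs={fit.n_obs}, converged={fit.converged})")
        print(fit.table.round(3).to_string())
    print(f"\nwrote model_*.csv under {DEMO}")


if __name__ == "__main__":
    sys.exit(main())
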