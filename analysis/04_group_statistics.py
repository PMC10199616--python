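"""Genotype x sex group comparisons on synthetic behavioral-style tables.

Exercises the statistics layer the way downstream measures are compared:
a two-way ANOVA (genotype x sex) with Holm-Sidak-adjusted pairwise tests on
an activity-like measure with a genotype main effect, and an unpaired-t
comparison of per-subject relearning slopes over trials 9-12 of a
maze-style learning curve.

Writes results/group_anova.csv, results/group_pairwise.csv and
results/group_slopes.csv.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from hippoephys import stats_compare  # noqa: E402

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)


def main():
    rng = np.random.default_rng(4)

    # activity measure: genotype main effect (mutants less active), both sexes
    rows = []
    for geno, shift in (("control", 0.0), ("mutant", -8.0)):
        for sex, n in (("male", 10), ("female", 12)):
            for i in range(n):
                rows.append((f"{geno}_{sex}_{i}", geno, sex,
                             30.0 + shift + rng.normal(0, 4.0)))
    tbl = pd.DataFrame(rows, columns=["subject", "factor1", "factor2", "value"])
    anova = stats_compare.two_way_anova(tbl)
    pd.DataFrame(
        [{"effect": r.name, "F": r.statistic, "df1": r.df[0], "df2": r.df[1],
          "p": r.p} for r in anova]
    ).to_csv(os.path.join(OUT, "group_anova.csv"), index=False)
    for r in anova:
        print(f"{r.name}: F={r.statistic:.2f}, p={r.p:.4g}")

    pairs = []
    for sex in ("male", "female"):
        sub = tbl[tbl.factor2 == sex]
        pairs.append(
            (f"control vs mutant ({sex})",
             sub[sub.factor1 == "control"].value.to_numpy(),
             sub[sub.factor1 == "mutant"].value.to_numpy())
        )
    pw = stats_compare.pairwise_tests(pairs, method="t_unpaired",
                                      adjust="holm_sidak")
    pd.DataFrame(
        [{"comparison": r.name, "statistic": r.statistic, "p": r.p,
          "adjusted_p": r.adjusted_p} for r in pw]
    ).to_csv(os.path.join(OUT, "group_pairwise.csv"), index=False)
    for r in pw:
        print(f"{r.name}: p={r.p:.4g}, Holm-Sidak adjusted p={r.adjusted_p:.4g}")

    # relearning slopes, trials 9-12: mutants relearn more slowly
    def learning_rows(group, n, relearn_slope):
        out = []
        for i in range(n):
            for trial in range(1, 13):
                latency = (60.0 * np.exp(-0.4 * min(trial, 8))
                           + (40.0 + relearn_slope * (trial - 9) * 4
                              if trial >= 9 else 0.0)
                           + rng.normal(0, 3.0))
                out.append((f"{group}{i}", group, trial, latency))
        return out

    learn = pd.DataFrame(
        learning_rows("control", 10, -2.5) + learning_rows("mutant", 11, -0.8),
        columns=["subject", "group", "trial", "value"],
    )
    res = stats_compare.slope_compare(
        learn[learn.group == "control"], learn[learn.group == "mutant"],
        trial_range=(9, 12),
    )
    print(f"relearning slopes trials 9-12: t={res.statistic:.2f}, p={res.p:.4g}")
    pd.DataFrame(
        [{"comparison": "relearning slope trials 9-12, control vs mutant",
          "statistic": res.statistic, "df": res.df, "p": res.p}]
    ).to_csv(os.path.join(OUT, "group_slopes.csv"), index=False)


if __name__ == "__main__":
    main()
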