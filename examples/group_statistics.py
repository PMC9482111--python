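"""Assumption-gated group comparison on a made-up measurement table.

Three loading groups are screened with Anderson-Darling (normality, per
group) and Bartlett (equal variances); if all pass, one-way ANOVA with
Tukey HSD follows, otherwise Kruskal-Wallis with Dunn/Bonferroni pairwise
comparisons.  Stars follow the usual convention (* <0.05, ** <0.01,
*** <0.001).
"""

import numpy as np
import pandas as pd

from fibroquant import compare_groups, summarise_box

rng = np.random.default_rng(3)
table = pd.DataFrame(
    {
        "group": np.repeat(["unloaded", "physiological", "pathological"], 40),
        "value": np.concatenate(
            [
                rng.normal(0.12, 0.03, 40),   # baseline anisotropy
                rng.normal(0.30, 0.05, 40),   # aligned after physiological load
                rng.normal(0.13, 0.03, 40),   # unchanged after pathological load
            ]
        ),
    }
)

result = compare_groups(table, metric_name="anisotropy", timepoint="1h")
print(f"gate     : {result.gate}")
print(f"omnibus  : stat={result.omnibus_stat:.2f}  p={result.omnibus_p:.3g}\n")
for pair in result.pairwise:
    print(f"{pair.group_a:>14} vs {pair.group_b:<14} p={pair.p:.3g} {pair.stars}")

print("\nbox-whisker summaries (median [Q1, Q3], whiskers, outliers):")
for box in summarise_box(table):
    print(
        f"{box.group:>14}: {box.median:.3f} [{box.q1:.3f}, {box.q3:.3f}] "
        f"whiskers ({box.whisker_low:.3f}, {box.whisker_high:.3f}) "
        f"outliers {list(box.outliers)}"
    )

print(
    "\nOnly the pairs involving the physiologically loaded group should be"
    "\nsignificant: its alignment is three-plus standard deviations above"
    "\nthe other two groups."
)
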