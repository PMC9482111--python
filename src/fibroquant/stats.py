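"""Group-comparison statistics with assumption gating.

For each (metric, timepoint) family the three loading groups are compared
with the classical gated workflow: every group is screened for normality
(Anderson-Darling) and the set for variance homogeneity (Bartlett).  If all
gates pass, a one-way ANOVA with Tukey's HSD post-hoc follows; otherwise a
Kruskal-Wallis omnibus test with Dunn's pairwise comparisons under
Bonferroni correction.  Significance is declared at alpha = 0.05 and
annotated with the conventional star codes (* < 0.05, ** < 0.01,
*** < 0.001).

Box-whisker summaries report median, quartiles (linear-interpolation /
type-7 quantiles) and Tukey-fence whiskers (most extreme observations
within 1.5 IQR of the box), with points beyond the fences listed as
outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "ALPHA",
    "PairwiseComparison",
    "ComparisonResult",
    "BoxSummary",
    "stars",
    "gate_assumptions",
    "compare_groups",
    "summarise_box",
]

ALPHA = 0.05
VALID_GROUPS = {"unloaded", "physiological", "pathological"}


def stars(p: float) -> str:
    """Conventional significance stars for a p-value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    p: float
    significant: bool
    stars: str


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one gated family comparison."""

    metric_name: str
    timepoint: str
    gate: str  # "parametric" | "nonparametric"
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


@dataclass(frozen=True)
class BoxSummary:
    """Box-whisker summary of one group (type-7 quantiles, 1.5 IQR fences)."""

    group: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    mean: float
    sd: float


def _extract_groups(
    table: pd.DataFrame, value_col: str = "value", group_col: str = "group"
) -> dict[str, np.ndarray]:
    if group_col not in table or value_col not in table:
        raise ValueError(f"table needs columns {group_col!r} and {value_col!r}")
    bad = set(table[group_col].unique()) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    out = {
        g: np.asarray(sub[value_col], dtype=np.float64)
        for g, sub in table.groupby(group_col, sort=False)
    }
    if len(out) < 2:
        raise ValueError("need at least 2 groups to compare")
    return out


def gate_assumptions(table: pd.DataFrame, alpha_gate: float = ALPHA) -> str:
    """Choose the test family: ``"parametric"`` or ``"nonparametric"``.

    Parametric requires every group to pass the Anderson-Darling normality
    test at ``alpha_gate`` *and* the k-sample Bartlett homogeneity test to
    pass.  Groups smaller than 3, or with degenerate (zero) variance, force
    the nonparametric branch with a warning.
    """
    groups = _extract_groups(table)
    for g, vals in groups.items():
        if len(vals) < 3:
            warnings.warn(
                f"group {g!r} has n={len(vals)} < 3; falling back to nonparametric",
                stacklevel=2,
            )
            return "nonparametric"
        if np.ptp(vals) == 0:
            warnings.warn(
                f"group {g!r} has zero variance; falling back to nonparametric",
                stacklevel=2,
            )
            return "nonparametric"
        _, p_ad = normal_ad(vals)
        if p_ad < alpha_gate:
            return "nonparametric"
    _, p_bart = sps.bartlett(*groups.values())
    if p_bart < alpha_gate:
        return "nonparametric"
    return "parametric"


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> list[PairwiseComparison]:
    """Dunn's rank-sum z tests with tie correction and Bonferroni adjustment."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = float(ranks[start : start + k].mean())
        start += k
    # Tie correction term for the rank variance.
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            se = np.sqrt(base_var * (1.0 / len(groups[ga]) + 1.0 / len(groups[gb])))
            if se == 0:
                p = 1.0
            else:
                z = (mean_ranks[ga] - mean_ranks[gb]) / se
                p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)  # Bonferroni
            out.append(
                PairwiseComparison(ga, gb, float(p), p < ALPHA, stars(p))
            )
    return out


def compare_groups(
    table: pd.DataFrame,
    metric_name: str = "",
    timepoint: str = "",
    alpha_gate: float = ALPHA,
) -> ComparisonResult:
    """Run the gated omnibus + post-hoc comparison on one family.

    ``table`` needs ``group`` and ``value`` columns restricted to one
    (metric, timepoint) family.  The parametric branch is one-way ANOVA with
    Tukey's HSD; the nonparametric branch Kruskal-Wallis with Dunn/Bonferroni
    pairwise follow-up.  Degenerate input (all values identical) yields
    p = 1 and no significant pairs.
    """
    groups = _extract_groups(table)
    names = list(groups)
    all_vals = np.concatenate(list(groups.values()))
    if np.ptp(all_vals) == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gate = gate_assumptions(table, alpha_gate)
        pairs = [
            PairwiseComparison(a, b, 1.0, False, "ns")
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
        return ComparisonResult(metric_name, timepoint, gate, 0.0, 1.0, pairs)

    gate = gate_assumptions(table, alpha_gate)
    if gate == "parametric":
        stat, p = sps.f_oneway(*groups.values())
        hsd = sps.tukey_hsd(*groups.values())
        pairs = []
        for i, ga in enumerate(names):
            for j in range(i + 1, len(names)):
                pp = float(hsd.pvalue[i, j])
                pairs.append(PairwiseComparison(ga, names[j], pp, pp < ALPHA, stars(pp)))
    else:
        try:
            stat, p = sps.kruskal(*groups.values())
        except ValueError:  # all numbers identical within float tolerance
            stat, p = 0.0, 1.0
        pairs = _dunn_pairwise(groups)
    return ComparisonResult(metric_name, timepoint, gate, float(stat), float(p), pairs)


def summarise_box(
    table: pd.DataFrame, value_col: str = "value", group_col: str = "group"
) -> list[BoxSummary]:
    """Per-group box-whisker summary.

    Quartiles use linear interpolation (numpy's default, type 7); whiskers
    reach to the most extreme observations within ``[Q1 - 1.5 IQR,
    Q3 + 1.5 IQR]``; observations outside are reported as outliers.  Mean
    and SD accompany the order statistics so either median+-SD or box
    conventions can be rendered.
    """
    out = []
    for g, sub in table.groupby(group_col, sort=False):
        vals = np.sort(np.asarray(sub[value_col], dtype=np.float64))
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = tuple(float(v) for v in vals[(vals < lo_fence) | (vals > hi_fence)])
        out.append(
            BoxSummary(
                group=str(g),
                n=len(vals),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()),
                outliers=outliers,
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            )
        )
    return out
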