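"""Stage-relative ratios and the significance-testing cascade.

Each per-stage parameter Y is referenced to the baseline stage 1D through
the bounded relative change

    R(Y_S) = (Y_S - Y_1D) / (Y_S + Y_1D),        S in {3D, 5, 3A, 1A},

which minimises intersubject variance and lies in (-1, 1] for non-negative
parameters.  Per stage, the ratio sample is tested against zero with a
paired t-test when Shapiro-Wilk accepts normality (alpha = 0.05), otherwise
a Wilcoxon signed-rank test; significance is starred at alpha in {0.05,
0.01, 0.001}.  Across the four stages, a repeated-measures ANOVA (all-normal
case) or Friedman omnibus is followed by Bonferroni-corrected pairwise
comparisons, reported as directional arrows (which stage exceeds which).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["relative_change", "paired_stage_tests", "multi_stage_comparison",
           "StageTestResult", "PairwiseResult", "ratio_table"]

TEST_STAGES = ("3D", "5", "3A", "1A")
ALPHAS = (0.05, 0.01, 0.001)


def relative_change(y_s, y_ref):
    """Bounded relative change of ``y_s`` versus the baseline value.

    Antisymmetric in its arguments; a zero denominator yields NaN with a
    warning (flagged missing downstream).
    """
    y_s = np.asarray(y_s, dtype=float)
    y_ref = np.asarray(y_ref, dtype=float)
    den = y_s + y_ref
    bad = den == 0
    if np.any(bad):
        warnings.warn("zero denominator in relative change; value(s) flagged "
                      "missing", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(bad, np.nan, (y_s - y_ref) / np.where(bad, 1.0, den))
    return r if r.ndim else float(r)


def ratio_table(features: pd.DataFrame, baseline: str = "1D") -> pd.DataFrame:
    """Eq-style ratio features from a (subject, stage) x parameter table.

    ``features`` is indexed by (subject, stage); each non-baseline stage row
    is referenced to that subject's baseline row.  Subjects lacking the
    baseline stage are dropped.
    """
    out = []
    for sid, grp in features.groupby(level="subject"):
        grp = grp.droplevel("subject")
        if baseline not in grp.index:
            continue
        ref = grp.loc[baseline]
        for stage in grp.index:
            if stage == baseline:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = relative_change(grp.loc[stage].to_numpy(),
                                       ref.to_numpy())
            out.append(pd.Series(vals, index=grp.columns,
                                 name=(sid, stage)))
    tab = pd.DataFrame(out)
    tab.index = pd.MultiIndex.from_tuples(tab.index,
                                          names=["subject", "stage"])
    return tab


@dataclass
class StageTestResult:
    parameter: str
    stage: str
    test: str           # "t" or "wilcoxon"
    p_value: float
    stars: int          # 0-3, significance at 0.05 / 0.01 / 0.001
    n: int


def _stars(p: float) -> int:
    return int(sum(p < a for a in ALPHAS))


def paired_stage_tests(ratios: pd.DataFrame, normality_alpha: float = 0.05,
                       ) -> list[StageTestResult]:
    """Per-parameter, per-stage tests of the ratios against zero.

    Shapiro-Wilk on each ratio sample gates the branch: paired t-test
    (one-sample on the ratios) when normal, Wilcoxon signed-rank otherwise.
    Constant samples take the Wilcoxon branch with a zero-method warning.
    """
    results: list[StageTestResult] = []
    for param in ratios.columns:
        for stage in TEST_STAGES:
            try:
                x = ratios.xs(stage, level="stage")[param].dropna().to_numpy()
            except KeyError:
                continue
            if x.size < 6:
                continue
            constant = np.allclose(x, x[0])
            if constant:
                results.append(StageTestResult(param, stage, "wilcoxon", 1.0,
                                               0, x.size))
                continue
            sw_p = stats.shapiro(x).pvalue
            if sw_p >= normality_alpha:
                test, p = "t", stats.ttest_1samp(x, 0.0).pvalue
            else:
                try:
                    p = stats.wilcoxon(x, zero_method="wilcox").pvalue
                except ValueError:
                    p = 1.0
                test = "wilcoxon"
            results.append(StageTestResult(param, stage, test, float(p),
                                           _stars(float(p)), x.size))
    return results


@dataclass
class PairwiseResult:
    parameter: str
    omnibus: str        # "anova-rm" or "friedman"
    omnibus_p: float
    #: (higher_stage, lower_stage, corrected_p) for significant pairs
    arrows: list[tuple[str, str, float]]


def multi_stage_comparison(ratios: pd.DataFrame, alpha: float = 0.05,
                           normality_alpha: float = 0.05,
                           ) -> list[PairwiseResult]:
    """Repeated-measures omnibus plus Bonferroni pairwise stage comparison.

    Complete cases only (subjects missing any of the four stages are
    dropped).  The omnibus is a repeated-measures ANOVA when all four stage
    samples pass Shapiro-Wilk, else a Friedman test; pairwise paired t /
    Wilcoxon p-values are Bonferroni-corrected by the 6 comparisons and
    reported with the direction of the median difference.
    """
    results: list[PairwiseResult] = []
    pairs = [(a, b) for i, a in enumerate(TEST_STAGES)
             for b in TEST_STAGES[i + 1:]]
    for param in ratios.columns:
        wide = ratios[param].unstack("stage").reindex(columns=TEST_STAGES)
        wide = wide.dropna()
        if wide.shape[0] < 6:
            continue
        samples = [wide[s].to_numpy() for s in TEST_STAGES]
        normal = all(
            not np.allclose(s, s[0]) and
            stats.shapiro(s).pvalue >= normality_alpha for s in samples)
        if normal:
            from statsmodels.stats.anova import AnovaRM
            long = wide.reset_index().melt(id_vars="subject",
                                           var_name="stage")
            res = AnovaRM(long, depvar="value", subject="subject",
                          within=["stage"]).fit()
            om_p = float(res.anova_table["Pr > F"].iloc[0])
            omnibus = "anova-rm"
        else:
            om_p = float(stats.friedmanchisquare(*samples).pvalue)
            omnibus = "friedman"
        arrows: list[tuple[str, str, float]] = []
        for a, b in pairs:
            xa, xb = wide[a].to_numpy(), wide[b].to_numpy()
            if np.allclose(xa, xb):
                continue
            if normal:
                p = stats.ttest_rel(xa, xb).pvalue
            else:
                try:
                    p = stats.wilcoxon(xa, xb, zero_method="wilcox").pvalue
                except ValueError:
                    continue
            p_corr = min(1.0, float(p) * len(pairs))
            if p_corr < alpha:
                hi, lo = (a, b) if np.median(xa) > np.median(xb) else (b, a)
                arrows.append((hi, lo, p_corr))
        results.append(PairwiseResult(param, omnibus, om_p, arrows))
    return results
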