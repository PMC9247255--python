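"""Normality-gated group statistics.

Paired comparisons use a Shapiro-Wilk gate: if both samples and their
paired differences pass normality at alpha = 0.05, a paired t-test is run;
otherwise the Wilcoxon signed-rank test.  Omnibus comparisons across three
within-subject conditions use one-way repeated-measures ANOVA with
Greenhouse-Geisser correction when sphericity is violated, followed by
Bonferroni-adjusted pairwise paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestOutcome:
    test_name: str
    statistic: float
    p_value: float
    n: int
    normality_p: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "normality_p": self.normality_p,
        }
        out.update(self.extra)
        return out


def _shapiro_gate(samples: list[np.ndarray], alpha: float) -> tuple[bool, float]:
    """True (parametric ok) iff every sample passes Shapiro-Wilk.

    Returns the minimum normality p across samples; constant samples fail
    the gate (Shapiro is undefined on them)."""
    p_min = 1.0
    for s in samples:
        if np.ptp(s) == 0:
            return False, 0.0
        p = float(sps.shapiro(s).pvalue)
        p_min = min(p_min, p)
    return p_min > alpha, p_min


def gated_paired_test(
    values_a: np.ndarray, values_b: np.ndarray, alpha_normality: float = 0.05
) -> TestOutcome:
    """Paired t-test when both samples and their differences are normal
    (Shapiro-Wilk at ``alpha_normality``), Wilcoxon signed-rank otherwise.

    Raises on all-zero differences, where the signed-rank test is undefined
    and the comparison is vacuous.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length paired samples of size >= 3")
    diff = a - b
    if np.all(diff == 0):
        raise ValueError("all paired differences are zero")
    normal, p_norm = _shapiro_gate([a, b, diff], alpha_normality)
    if normal:
        res = sps.ttest_rel(a, b)
        return TestOutcome("paired_t", float(res.statistic), float(res.pvalue), a.size, p_norm)
    res = sps.wilcoxon(a, b)
    return TestOutcome("wilcoxon", float(res.statistic), float(res.pvalue), a.size, p_norm)


def gated_unpaired_test(
    values_a: np.ndarray, values_b: np.ndarray, alpha_normality: float = 0.05
) -> TestOutcome:
    """Two-sample variant: unpaired t-test behind the same normality gate,
    Mann-Whitney U otherwise."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need samples of size >= 3")
    normal, p_norm = _shapiro_gate([a, b], alpha_normality)
    if normal:
        res = sps.ttest_ind(a, b)
        return TestOutcome("unpaired_t", float(res.statistic), float(res.pvalue), a.size + b.size, p_norm)
    res = sps.mannwhitneyu(a, b)
    return TestOutcome("mannwhitneyu", float(res.statistic), float(res.pvalue), a.size + b.size, p_norm)


def rm_anova_posthoc(values: np.ndarray, condition_names: list[str] | None = None) -> list[TestOutcome]:
    """One-way repeated-measures ANOVA over (subjects x 3 conditions), with
    Greenhouse-Geisser-corrected df when sphericity is violated, plus
    Bonferroni-adjusted pairwise paired t-tests.

    Returns the omnibus outcome first, then the three pairwise outcomes
    (adjusted p = min(1, 3 * raw p)).
    """
    import pingouin as pg

    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError("expected subjects x 3 within-subject conditions")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(values).all():
        raise ValueError("missing cells in the within-subject design")
    n_subj = values.shape[0]
    names = condition_names or [f"cond{i}" for i in range(3)]
    if np.ptp(values, axis=1).max() == 0:
        # no within-subject variation at all: F = 0 by definition, nothing
        # to test pairwise
        outcomes = [TestOutcome("rm_anova", 0.0, 1.0, n_subj,
                                extra={"df1": 2.0, "df2": 2.0 * (n_subj - 1),
                                       "gg_corrected": False})]
        for i, j in ((0, 1), (0, 2), (1, 2)):
            outcomes.append(
                TestOutcome("bonferroni_pairwise", 0.0, 1.0, n_subj,
                            extra={"pair": f"{names[i]} vs {names[j]}",
                                   "p_raw": 1.0})
            )
        return outcomes
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), 3),
            "condition": np.tile(names, n_subj),
            "value": values.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="value", within="condition", subject="subject",
        correction=True, detailed=False,
    )
    # column names differ across pingouin versions (p-unc vs p_unc)
    cols = {c.replace("-", "_"): c for c in aov.columns}
    row = aov.iloc[0]
    sphericity_ok = bool(row[cols["sphericity"]]) if "sphericity" in cols else True
    use_gg = "p_GG_corr" in cols and not sphericity_ok
    if use_gg:
        eps = float(row[cols["eps"]])
        p = float(row[cols["p_GG_corr"]])
        df1, df2 = eps * row[cols["ddof1"]], eps * row[cols["ddof2"]]
    else:
        p = float(row[cols["p_unc"]])
        df1, df2 = float(row[cols["ddof1"]]), float(row[cols["ddof2"]])
    outcomes = [
        TestOutcome(
            "rm_anova",
            float(row["F"]),
            p,
            n_subj,
            extra={"df1": float(df1), "df2": float(df2), "gg_corrected": bool(use_gg)},
        )
    ]
    for i, j in ((0, 1), (0, 2), (1, 2)):
        res = sps.ttest_rel(values[:, i], values[:, j])
        outcomes.append(
            TestOutcome(
                "bonferroni_pairwise",
                float(res.statistic),
                float(min(1.0, 3.0 * res.pvalue)),
                n_subj,
                extra={"pair": f"{names[i]} vs {names[j]}", "p_raw": float(res.pvalue)},
            )
        )
    return outcomes
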