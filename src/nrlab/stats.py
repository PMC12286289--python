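"""Outcome statistics for the NR study design.

Covers the statistical battery applied to the behavioral and neural
measures: one-way repeated-measures ANOVA over the three listening
conditions (NR off, NR 1, NR 2), Bonferroni-corrected paired post hocs,
Pearson correlations of the neural SNR with outcomes, and cluster
comparisons via Welch two-sample t-tests with Holm-Bonferroni correction
across the three outcome measures. Two-sample tests are Welch throughout:
unequal variances and fractional Welch-Satterthwaite degrees of freedom.
All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "StatResult",
    "rm_anova",
    "paired_t_bonferroni",
    "pearson_corr",
    "welch_t",
    "holm_bonferroni",
    "compare_clusters",
]

CONDITIONS = ("acc_nr_off", "acc_nr1", "acc_nr2")


@dataclass(frozen=True)
class StatResult:
    """One test's report: statistic, df (possibly fractional), p-values."""

    name: str
    statistic: float
    df: tuple[float, ...] | float
    p: float
    p_adjusted: float | None = None
    adjustment: str | None = None

    @property
    def direction(self) -> int:
        return int(np.sign(self.statistic))


def _check_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CONDITIONS if c not in outcomes.columns]
    if missing:
        raise InvalidArgumentError(f"outcome table missing columns {missing}")
    if outcomes[list(CONDITIONS)].isna().any().any():
        raise InvalidArgumentError("incomplete within-subject design (missing cells)")
    return outcomes


def rm_anova(outcomes: pd.DataFrame) -> StatResult:
    """One-way repeated-measures ANOVA over the three NR conditions.

    Uncorrected degrees of freedom ``(c-1, (c-1)(n-1))`` — (2, 82) for the
    reference cohort of 42 — matching the uncorrected univariate test.
    """
    outcomes = _check_outcomes(outcomes)
    y = outcomes[list(CONDITIONS)].to_numpy(float)
    if np.allclose(y, y[:, [0]]):
        # no within-subject variation at all: no condition effect by definition
        return StatResult("rm_anova", 0.0, (2.0, 2.0 * (len(y) - 1)), 1.0)
    long = outcomes.melt(
        id_vars=["participant"],
        value_vars=list(CONDITIONS),
        var_name="condition",
        value_name="accuracy",
    )
    res = AnovaRM(long, depvar="accuracy", subject="participant", within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return StatResult(
        name="rm_anova",
        statistic=float(row["F Value"]),
        df=(float(row["Num DF"]), float(row["Den DF"])),
        p=float(row["Pr > F"]),
    )


def paired_t_bonferroni(outcomes: pd.DataFrame) -> list[StatResult]:
    """Paired t-tests for the three condition pairs, Bonferroni-adjusted (×3)."""
    outcomes = _check_outcomes(outcomes)
    if len(outcomes) < 2:
        raise InvalidArgumentError("need at least two participants")
    pairs = [(a, b) for i, a in enumerate(CONDITIONS) for b in CONDITIONS[i + 1:]]
    results = []
    for a, b in pairs:
        diff = outcomes[a].to_numpy(float) - outcomes[b].to_numpy(float)
        if np.all(diff == 0.0):
            stat, p = 0.0, 1.0  # identical paired vectors: no effect
        else:
            res = sps.ttest_rel(outcomes[a], outcomes[b])
            stat, p = float(res.statistic), float(res.pvalue)
        results.append(
            StatResult(
                name=f"{a}_vs_{b}",
                statistic=stat,
                df=float(len(outcomes) - 1),
                p=p,
                p_adjusted=float(min(1.0, len(pairs) * p)),
                adjustment="bonferroni",
            )
        )
    return results


def pearson_corr(x, y, name: str = "pearson") -> StatResult:
    """Pearson correlation with the two-sided p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidArgumentError("need two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("values must be finite")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero-variance input")
    res = sps.pearsonr(x, y)
    return StatResult(name=name, statistic=float(res.statistic), df=float(len(x) - 2), p=float(res.pvalue))


def welch_t(group_a, group_b, name: str = "welch") -> StatResult:
    """Welch two-sample t-test with Welch-Satterthwaite (fractional) df."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        raise DegenerateInputError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(name=name, statistic=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm adjustment, order-preserving, monotonicity enforced."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def compare_clusters(outcomes: pd.DataFrame, labels, alpha: float = 0.05) -> dict:
    """Two-cluster comparison of neural SNR and the three outcome measures.

    Neural SNR is tested alone (no correction); the three outcome measures
    (NR-off accuracy, NR 1- and NR 2-driven accuracy changes) form one
    Holm-Bonferroni family. The report carries every statistic plus an audit
    of the corrections applied; it deliberately encodes no significance
    verdict for the corrected family.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) != 2:
        raise InvalidArgumentError("exactly two clusters required")
    split = {g: outcomes[labels == g] for g in ids}

    neural = welch_t(
        split[ids[0]]["neural_snr_db"], split[ids[1]]["neural_snr_db"], name="neural_snr_db"
    )
    family = [
        welch_t(split[ids[0]][m], split[ids[1]][m], name=m)
        for m in ("acc_nr_off", "d_acc_nr1", "d_acc_nr2")
    ]
    adjusted = holm_bonferroni([r.p for r in family])
    family = [
        StatResult(r.name, r.statistic, r.df, r.p, float(pa), "holm-bonferroni")
        for r, pa in zip(family, adjusted)
    ]
    return {
        "neural_snr": neural,
        "outcomes": family,
        "audit": {
            "neural_snr": "uncorrected Welch t",
            "outcomes": "Welch t, Holm-Bonferroni across the three outcome measures",
            "alpha": alpha,
        },
    }
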