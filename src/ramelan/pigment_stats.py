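"""Per-sample / per-class pigment-score summaries and between-class tests.

Sample summaries are the mean and sd of each pigment score over that
sample's spectra; class summaries are unweighted means of the per-sample
means (standard error over samples). Class comparisons use Welch's
unequal-variance two-sided t-test on the per-sample means, with the usual
significance stars (* p < 0.05, ** p < 0.01, *** p < 0.001, strict
inequality at each boundary). No multiple-testing correction is applied;
the three pairwise comparisons are reported raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CLASS_LABELS
from .errors import ConsistencyError, StatTestError

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("dhica_score", "eumelanin_score")


def disagreement_percent(n_disagree: int, n_total: int) -> float:
    """Share of cases (percent, one decimal) where two diagnostic readings
    disagree — e.g. clinical versus histological diagnosis of a lesion."""
    if n_total <= 0 or n_disagree < 0 or n_disagree > n_total:
        raise ConsistencyError("need 0 <= n_disagree <= n_total with n_total > 0")
    return round(100.0 * n_disagree / n_total, 1)


def stars(p_value: float) -> str:
    """Map a p-value to its significance stars (strict thresholds)."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class PairwiseTest:
    class_a: str
    class_b: str
    component: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def summarize_samples(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean and sd (ddof=1; 0 for singleton samples) of each
    pigment score."""
    if len(scores) == 0:
        raise ConsistencyError("empty score table")
    required = {"sample_id", "class_label", *SCORE_COLUMNS}
    missing = required - set(scores.columns)
    if missing:
        raise ConsistencyError(f"score table misses columns {sorted(missing)}")
    if scores["sample_id"].isna().any() or scores["class_label"].isna().any():
        raise ConsistencyError("every spectrum needs sample_id and class_label")

    grouped = scores.groupby("sample_id", sort=True)
    if (grouped["class_label"].nunique() > 1).any():
        raise ConsistencyError("a sample carries more than one class label")
    rows = []
    for sample_id, g in grouped:
        record = {
            "sample_id": sample_id,
            "class_label": g["class_label"].iloc[0],
            "n_spectra": len(g),
        }
        if len(g) == 1:
            logger.warning("sample %s has a single spectrum; sd set to 0", sample_id)
        for col in SCORE_COLUMNS:
            record[f"{col}_mean"] = float(g[col].mean())
            record[f"{col}_sd"] = float(g[col].std(ddof=1)) if len(g) > 1 else 0.0
        rows.append(record)
    return pd.DataFrame(rows)


def summarize_classes(sample_summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean-of-sample-means and standard error over samples."""
    bad = set(sample_summaries["class_label"].unique()) - set(CLASS_LABELS)
    if bad:
        raise ConsistencyError(f"unknown class labels {sorted(bad)}")
    rows = []
    for label, g in sample_summaries.groupby("class_label", sort=True):
        record = {"class_label": label, "n_samples": len(g)}
        if len(g) == 1:
            logger.warning("class %s has a single sample; SE reported as 0", label)
        for col in SCORE_COLUMNS:
            means = g[f"{col}_mean"].to_numpy()
            record[f"{col}_mean"] = float(means.mean())
            record[f"{col}_se"] = (
                float(means.std(ddof=1) / np.sqrt(len(means))) if len(g) > 1 else 0.0
            )
        rows.append(record)
    return pd.DataFrame(rows)


def welch_t_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    class_a: str = "a",
    class_b: str = "b",
    component: str = "",
) -> PairwiseTest:
    """Welch's two-sided unequal-variance t-test with Satterthwaite df."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatTestError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            # zero difference with zero variance: t = 0, p = 1 by convention
            return PairwiseTest(class_a, class_b, component, 0.0,
                                float(a.size + b.size - 2), 1.0)
        raise StatTestError("both groups have zero variance but different means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return PairwiseTest(
        class_a=class_a,
        class_b=class_b,
        component=component,
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
    )


def pairwise_class_tests(sample_summaries: pd.DataFrame) -> pd.DataFrame:
    """All pairwise class comparisons of per-sample mean scores."""
    rows = []
    for col in SCORE_COLUMNS:
        component = col.replace("_score", "")
        for class_a, class_b in combinations(
            sorted(sample_summaries["class_label"].unique()), 2
        ):
            a = sample_summaries.loc[
                sample_summaries["class_label"] == class_a, f"{col}_mean"
            ]
            b = sample_summaries.loc[
                sample_summaries["class_label"] == class_b, f"{col}_mean"
            ]
            test = welch_t_test(a, b, class_a, class_b, component)
            rows.append(
                {
                    "component": component,
                    "class_a": class_a,
                    "class_b": class_b,
                    "t_statistic": test.t_statistic,
                    "degrees_of_freedom": test.degrees_of_freedom,
                    "p_value": test.p_value,
                    "stars": test.stars,
                }
            )
    return pd.DataFrame(rows)
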