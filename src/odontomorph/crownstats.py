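"""Morphotype frequencies, measurement tests, DE-gene marking and qPCR math."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from odontomorph.dataio import DomainError, MORPHOTYPE_TRAITS, MorphotypeTable


@dataclass(frozen=True)
class FrequencyReport:
    """Counts of one morphotype state among the scored sides of a cohort.

    ``percentage`` is 100 * observed / scored, or NaN when nothing was
    scored. Sides recorded as "missing" are excluded from the denominator.
    """

    cohort: str
    trait: str
    state: str
    count_observed: int
    count_scored: int

    @property
    def percentage(self) -> float:
        if self.count_scored == 0:
            return float("nan")
        return 100.0 * self.count_observed / self.count_scored


def morphotype_frequencies(
    table: MorphotypeTable, cohort: str, trait: str, state: str
) -> FrequencyReport:
    """Frequency of ``state`` for ``trait`` among scored sides of ``cohort``."""
    if trait not in MORPHOTYPE_TRAITS:
        raise DomainError(f"unknown trait {trait!r}; choose from {sorted(MORPHOTYPE_TRAITS)}")
    vocab = MORPHOTYPE_TRAITS[trait]
    if state not in vocab:
        raise DomainError(f"unknown state {state!r} for trait {trait!r}")
    sub = table.frame[table.frame["cohort"] == cohort]
    scored = sub[sub[trait] != "missing"]
    observed = int((scored[trait] == state).sum())
    return FrequencyReport(cohort=cohort, trait=trait, state=state,
                           count_observed=observed, count_scored=len(scored))


@dataclass(frozen=True)
class TwoSampleTestResult:
    statistic: float
    p_value: float
    test_kind: str          # "student_t" or "variance_F"
    n_x: int
    n_y: int


def student_t_test(x: Sequence[float], y: Sequence[float]) -> TwoSampleTestResult:
    """Two-sided pooled-variance (Student) t test for equal means.

    The statistic carries the sign of mean(x) - mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("each sample needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TwoSampleTestResult(float(res.statistic), float(res.pvalue),
                               "student_t", len(x), len(y))


def variance_f_test(x: Sequence[float], y: Sequence[float]) -> TwoSampleTestResult:
    """Two-sided variance-ratio F test (F = s²_x / s²_y) for equal variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("each sample needs at least 2 observations")
    var_x = float(np.var(x, ddof=1))
    var_y = float(np.var(y, ddof=1))
    if var_y == 0:
        raise DomainError("zero variance in second sample")
    f_stat = var_x / var_y
    df1, df2 = len(x) - 1, len(y) - 1
    cdf = stats.f.cdf(f_stat, df1, df2)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return TwoSampleTestResult(f_stat, float(min(p, 1.0)), "variance_F", len(x), len(y))


def mark_de_genes(
    records: pd.DataFrame,
    group_labels: Sequence[str],
    count_columns: Sequence[str] | None = None,
    p_column: str = "p_value",
    fc_column: str = "log2fc",
    min_count: int = 10,
    max_p: float = 0.05,
    min_abs_log2fc: float = 0.5,
) -> pd.DataFrame:
    """Flag differentially expressed genes by the three-part marking rule.

    A gene is marked DE when (i) at least ``min_count`` counts occur in at
    least half the samples (ceiling of the group size) of one group, (ii) its
    p value is <= ``max_p``, and (iii) |log2 fold change| >=
    ``min_abs_log2fc``. The fold-change cutoff is interpreted on the log2
    scale, symmetric in direction. Returns a copy with a boolean ``de_flag``
    column.
    """
    if count_columns is None:
        count_columns = [c for c in records.columns if c not in (p_column, fc_column)]
    if len(count_columns) != len(group_labels):
        raise DomainError("one group label per count column required")
    counts = records[list(count_columns)].to_numpy()
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    labels = np.asarray(group_labels)
    crit_counts = np.zeros(len(records), dtype=bool)
    for g in np.unique(labels):
        cols = counts[:, labels == g]
        need = math.ceil(cols.shape[1] / 2)
        crit_counts |= (cols >= min_count).sum(axis=1) >= need
    crit_p = records[p_column].to_numpy(dtype=float) <= max_p
    crit_fc = np.abs(records[fc_column].to_numpy(dtype=float)) >= min_abs_log2fc
    out = records.copy()
    out["de_flag"] = crit_counts & crit_p & crit_fc
    return out


def fisher_enrichment(k_sig_in: int, k_sig_out: int, k_ns_in: int, k_ns_out: int) -> float:
    """Two-sided Fisher's exact p value for a 2x2 significant-by-category table."""
    table = [[k_sig_in, k_sig_out], [k_ns_in, k_ns_out]]
    if min(min(row) for row in table) < 0:
        raise DomainError("contingency counts must be non-negative")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def delta_ct_expression(ct_target: float, ct_housekeeping: float) -> float:
    """Relative expression by the comparative ΔCt method: 2^-(Ct_t - Ct_hk)."""
    return float(2.0 ** -(ct_target - ct_housekeeping))
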