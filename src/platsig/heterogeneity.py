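"""Intratumoral-heterogeneity metrics and paired load comparisons.

Heterogeneity is summarized two ways per patient: the proportion of a
tumor's mutations inferred subclonal (computed separately for the pre-
and post-treatment tumor), and the total number of subclones across the
pair, counting subclones private to either tumor and shared ones.
High/low flags at the conventional cutoffs (0.2 subclonal proportion; 6
subclones) are emitted as covariates for external survival tooling;
survival modeling itself is out of scope here.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class Subclone:
    """A subclone with its cancer-cell fraction in each tumor of a pair."""

    id: int
    pre_ccf: float
    post_ccf: float
    n_mutations: int = 0

    def __post_init__(self) -> None:
        if self.pre_ccf <= 0 and self.post_ccf <= 0:
            raise ValueError("a subclone absent from both tumors is not a subclone")


def proportion_subclonal(clonality: Sequence[str] | pd.Series) -> float:
    """Fraction of labeled mutations that are subclonal.

    Labels other than clonal/subclonal are excluded; with no labeled
    mutations the proportion is undefined (NaN, with a warning).
    """
    labels = pd.Series(list(clonality), dtype=str)
    labeled = labels.isin(["clonal", "subclonal"])
    n = int(labeled.sum())
    if n == 0:
        warnings.warn("no clonal/subclonal labels: proportion undefined", UserWarning, stacklevel=2)
        return float("nan")
    return float((labels[labeled] == "subclonal").sum() / n)


def count_subclones(subclones: Iterable[Subclone]) -> int:
    """Number of subclones present (CCF > 0) in either tumor of the pair."""
    return sum(1 for s in subclones if s.pre_ccf > 0 or s.post_ccf > 0)


@dataclasses.dataclass
class HeterogeneityMetrics:
    patient: str
    prop_subclonal_pre: float
    prop_subclonal_post: float
    n_subclones: int
    high_pre: bool
    high_post: bool
    high_subclones: bool
    # boundary-inclusive variants, recorded because the cutoffs' boundary
    # handling is a convention
    high_pre_inclusive: bool
    high_post_inclusive: bool
    high_subclones_inclusive: bool


def heterogeneity_metrics(
    patient: str,
    pre_clonality: Sequence[str],
    post_clonality: Sequence[str],
    subclones: Iterable[Subclone],
    prop_cutoff: float = 0.2,
    subclone_cutoff: int = 6,
) -> HeterogeneityMetrics:
    """Per-patient heterogeneity covariates.

    "High" means strictly greater than the cutoff; the inclusive (>=)
    flags are also recorded.
    """
    p_pre = proportion_subclonal(pre_clonality)
    p_post = proportion_subclonal(post_clonality)
    n_sub = count_subclones(subclones)
    return HeterogeneityMetrics(
        patient=patient,
        prop_subclonal_pre=p_pre,
        prop_subclonal_post=p_post,
        n_subclones=n_sub,
        high_pre=bool(p_pre > prop_cutoff),
        high_post=bool(p_post > prop_cutoff),
        high_subclones=bool(n_sub > subclone_cutoff),
        high_pre_inclusive=bool(p_pre >= prop_cutoff),
        high_post_inclusive=bool(p_post >= prop_cutoff),
        high_subclones_inclusive=bool(n_sub >= subclone_cutoff),
    )


@dataclasses.dataclass
class LoadComparison:
    mean_change: float
    t_statistic: float
    t_p_value: float
    n: int
    degenerate: bool  # zero-variance differences: t-test undefined
    pre_vs_shared_p: float | None = None
    shared_vs_post_p: float | None = None


def compare_loads(
    pre_counts: Sequence[float],
    post_counts: Sequence[float],
    pre_private: Sequence[float] | None = None,
    shared: Sequence[float] | None = None,
    post_private: Sequence[float] | None = None,
) -> LoadComparison:
    """Paired pre/post mutation-load comparison.

    Mean change (post - pre) with a two-sided paired t-test against a
    null difference of 0; optionally rank-sum (Mann-Whitney U)
    comparisons of per-patient pre-private vs shared and shared vs
    post-private mutation counts. Constant differences make the t-test
    degenerate (flagged, p NaN).
    """
    pre = np.asarray(pre_counts, dtype=float)
    post = np.asarray(post_counts, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post load vectors must be paired (equal length)")
    if len(pre) < 2:
        raise ValueError("paired comparison needs n >= 2 patients")
    diff = post - pre
    mean_change = float(diff.mean())
    degenerate = bool(np.ptp(diff) == 0)
    if degenerate and diff[0] == 0:
        t_stat, t_p = 0.0, 1.0
    elif degenerate:
        warnings.warn("constant nonzero shift: paired t-test degenerate", UserWarning, stacklevel=2)
        t_stat, t_p = np.inf if mean_change > 0 else -np.inf, float("nan")
    else:
        res = stats.ttest_rel(post, pre)
        t_stat, t_p = float(res.statistic), float(res.pvalue)
    pre_shared_p = shared_post_p = None
    if pre_private is not None and shared is not None:
        pre_shared_p = float(stats.mannwhitneyu(pre_private, shared, alternative="two-sided").pvalue)
    if shared is not None and post_private is not None:
        shared_post_p = float(stats.mannwhitneyu(shared, post_private, alternative="two-sided").pvalue)
    return LoadComparison(mean_change, t_stat, t_p, len(pre), degenerate, pre_shared_p, shared_post_p)


def build_covariate_table(
    metrics: Sequence[HeterogeneityMetrics],
    clinical: pd.DataFrame | None = None,
    patient_col: str = "patient",
) -> pd.DataFrame:
    """Per-patient covariate table for external survival tooling.

    Heterogeneity metrics plus pass-through clinical columns (age, sex,
    regimen, stage, ...) joined on the patient id.
    """
    table = pd.DataFrame([dataclasses.asdict(m) for m in metrics])
    if clinical is not None:
        if patient_col not in clinical.columns:
            raise ValueError(f"clinical table lacks the {patient_col!r} column")
        table = table.merge(clinical, left_on="patient", right_on=patient_col, how="left")
        if patient_col != "patient":
            table = table.drop(columns=[patient_col])
    return table
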