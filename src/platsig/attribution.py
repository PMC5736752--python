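"""Per-mutation signature attribution and subclonal-enrichment testing.

Each mutation's credit is split across signatures in proportion to
h_k * W[channel, k] — the product of the signature's activity in that
tumor and its probability mass on the mutation's channel. Summing
credits over clonal and subclonal mutations gives each signature's
clonal/subclonal activity, and a chi-squared test with K-1 degrees of
freedom asks whether the subclonal proportion differs across signatures.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .nmf import ActivityMatrix, SignatureSet

_CLAMP = 1e-12

#: CCF within this tolerance of 1.0 counts as clonal.
CLONAL_CCF_TOL = 1e-3


def clonality_from_ccf(ccf: float | np.ndarray, tol: float = CLONAL_CCF_TOL) -> np.ndarray:
    """'clonal' iff the subclone CCF equals 1 within tolerance, else 'subclonal'."""
    ccf = np.asarray(ccf, dtype=float)
    out = np.where(np.isnan(ccf), "unknown", np.where(ccf >= 1.0 - tol, "clonal", "subclonal"))
    return out if out.ndim else out[()]


def attribute_mutation(
    channel: int,
    signatures: SignatureSet,
    activities: np.ndarray,
) -> np.ndarray:
    """Credit vector over signatures for one mutation.

    credit_k = h_k * W[channel, k] / sum_j h_j * W[channel, j]; sums to
    1 and is invariant to rescaling the activity vector. Raises when no
    signature has mass on the channel.
    """
    h = np.asarray(activities, dtype=float)
    if (h < 0).any() or h.sum() <= 0:
        raise ValueError("activities must be non-negative with positive total")
    weights = h * signatures.W[channel, :]
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"no signature has activity mass on channel {channel}: unattributable")
    credit = weights / total
    credit[credit < _CLAMP] = 0.0
    return credit


@dataclasses.dataclass
class AttributionResult:
    table: pd.DataFrame  # signature, clonal_credit, subclonal_credit, subclonal_fraction
    overall_subclonal_fraction: float
    n_attributed: int
    n_excluded_clonality: int
    n_unattributable: int


def aggregate_attributions(
    mutations: pd.DataFrame,
    signatures: SignatureSet,
    activities: ActivityMatrix,
) -> AttributionResult:
    """Cohort clonal/subclonal credit per signature.

    ``mutations`` needs columns ``sample``, ``channel96`` and
    ``clonality`` (clonal/subclonal; others are excluded and counted).
    Credits are identical for mutations sharing (sample, channel), so
    the sum is computed over grouped counts; the result equals
    per-mutation iteration exactly. Total credit equals the number of
    attributed mutations.
    """
    required = {"sample", "channel96", "clonality"}
    missing = required - set(mutations.columns)
    if missing:
        raise ValueError(f"mutation table is missing columns: {sorted(missing)}")
    known = mutations["clonality"].isin(["clonal", "subclonal"])
    n_excluded = int((~known).sum())
    work = mutations.loc[known]
    K = signatures.k
    clonal = np.zeros(K)
    subclonal = np.zeros(K)
    n_unattributable = 0
    n_attributed = 0
    sample_col = {s: j for j, s in enumerate(activities.samples)}
    grouped = work.groupby(["sample", "channel96", "clonality"], observed=True).size()
    for (sample, channel, clonality), count in grouped.items():
        j = sample_col.get(sample)
        if j is None:
            raise KeyError(f"sample {sample!r} has no activity column")
        h = activities.H[:, j]
        weights = h * signatures.W[int(channel), :]
        total = weights.sum()
        if total <= 0 or h.sum() <= 0:
            n_unattributable += int(count)
            continue
        credit = weights / total
        credit[credit < _CLAMP] = 0.0
        credit = credit / credit.sum()  # re-close after clamping
        if clonality == "clonal":
            clonal += count * credit
        else:
            subclonal += count * credit
        n_attributed += int(count)
    totals = clonal + subclonal
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, subclonal / totals, np.nan)
    table = pd.DataFrame({
        "signature": signatures.names,
        "clonal_credit": clonal,
        "subclonal_credit": subclonal,
        "subclonal_fraction": frac,
    })
    overall = float(subclonal.sum() / totals.sum()) if totals.sum() > 0 else np.nan
    return AttributionResult(table, overall, n_attributed, n_excluded, n_unattributable)


@dataclasses.dataclass
class EnrichmentTest:
    statistic: float
    df: int
    p_value: float
    dropped: list[str]


def subclonal_enrichment_test(table: pd.DataFrame) -> EnrichmentTest:
    """Chi-squared homogeneity test of subclonal proportion across signatures.

    The K x 2 clonal/subclonal credit table is tested with Pearson's
    chi-squared at K - 1 degrees of freedom, treating credits as counts
    (credits are real-valued; the test is approximate in that respect).
    Signatures with zero total credit are dropped with a warning.
    """
    credits = table[["clonal_credit", "subclonal_credit"]].to_numpy(dtype=float)
    names = list(table["signature"])
    keep = credits.sum(axis=1) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping zero-credit signatures from the enrichment test: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        credits = credits[keep]
    if len(credits) < 2:
        raise ValueError("enrichment test needs at least 2 signatures with credit")
    if credits.sum() <= 0:
        raise ValueError("enrichment test needs positive total credit")
    if np.isclose(credits[:, 1], 0).all() or np.isclose(credits[:, 0], 0).all():
        # all-clonal (or all-subclonal) table: proportions are identical
        return EnrichmentTest(0.0, len(credits) - 1, 1.0, dropped)
    stat, p, df, _ = stats.chi2_contingency(credits, correction=False)
    return EnrichmentTest(float(stat), int(df), float(p), dropped)
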