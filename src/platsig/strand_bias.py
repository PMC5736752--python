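"""Transcriptional strand-bias tests on 192-channel catalogs.

With no transcription-coupled effect, a substitution class should hit
the coding (untranscribed) and noncoding (transcribed) strand equally
often; asymmetry is tested per substitution class with an exact
two-sided binomial test at success probability 0.5. Counts can be raw
class totals or mutations attributed to a specific signature via the
activity-weighted credit rule.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MutationCatalog
from .channels import CHANNELS_192, SUBSTITUTION_CLASSES, substitution_class
from .nmf import ActivityMatrix, SignatureSet


@dataclasses.dataclass
class StrandBiasResult:
    snv_class: str
    coding_count: float
    noncoding_count: float
    p_value: float
    direction: str  # coding_depleted | coding_enriched | none


def test_strand_asymmetry(coding: int, noncoding: int) -> StrandBiasResult:
    """Exact two-sided binomial test of a coding/noncoding count split.

    Two-sided by doubling the smaller tail of Binomial(total, 0.5),
    capped at 1. Direction reflects the raw imbalance.
    """
    coding, noncoding = int(coding), int(noncoding)
    if coding < 0 or noncoding < 0:
        raise ValueError("counts must be non-negative")
    total = coding + noncoding
    if total == 0:
        raise ValueError("strand test undefined with zero mutations")
    lower = stats.binom.cdf(coding, total, 0.5)
    upper = stats.binom.sf(coding - 1, total, 0.5)
    p = min(1.0, 2.0 * min(lower, upper))
    if coding < noncoding:
        direction = "coding_depleted"
    elif coding > noncoding:
        direction = "coding_enriched"
    else:
        direction = "none"
    return StrandBiasResult("", coding, noncoding, float(p), direction)


def class_strand_counts(catalog_192: MutationCatalog) -> pd.DataFrame:
    """Coding/noncoding totals per substitution class of a stranded catalog."""
    if catalog_192.channels != CHANNELS_192:
        raise ValueError("a 192-channel catalog is required")
    totals = catalog_192.counts.sum(axis=1)
    rows = []
    for cls in SUBSTITUTION_CLASSES:
        mask_c = np.array([substitution_class(ch) == cls and ch.endswith("+") for ch in CHANNELS_192])
        mask_n = np.array([substitution_class(ch) == cls and ch.endswith("-") for ch in CHANNELS_192])
        rows.append((cls, totals[mask_c].sum(), totals[mask_n].sum()))
    return pd.DataFrame(rows, columns=["snv_class", "coding", "noncoding"])


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = n - rank_from_top  # 1-based rank of this p in ascending order
        running = min(running, p[idx] * n / i)
        adj[idx] = running
    return adj


def stranded_signature_bias(
    signatures_192: SignatureSet | None,
    activities: ActivityMatrix | None,
    catalog_192: MutationCatalog,
) -> pd.DataFrame:
    """Per-class strand-asymmetry tests, raw and per attributed signature.

    Raw class totals are always tested (rows with signature
    ``"(all)"``). When a stranded signature set and activities are
    given, each catalog count is additionally split across signatures by
    the credit weights h_k * W[channel, k] (per sample), and the
    attributed coding/noncoding sums are tested per signature with
    counts rounded to integers. Classes where a signature has no mass
    are reported with NaN p. A Benjamini-Hochberg column is included for
    transparency; the per-class p-values themselves are uncorrected.
    """
    if catalog_192.channels != CHANNELS_192:
        raise ValueError("a 192-channel catalog is required")
    records = []
    for row in class_strand_counts(catalog_192).itertuples():
        if row.coding + row.noncoding == 0:
            records.append(("(all)", row.snv_class, 0.0, 0.0, np.nan, "n/a"))
            continue
        res = test_strand_asymmetry(row.coding, row.noncoding)
        records.append(("(all)", row.snv_class, res.coding_count, res.noncoding_count,
                        res.p_value, res.direction))
    if signatures_192 is not None and activities is not None:
        if signatures_192.channels != CHANNELS_192:
            raise ValueError("signature set must be on 192 channels")
        if activities.samples != catalog_192.samples:
            raise ValueError("activities and catalog sample orderings differ")
        V = np.asarray(catalog_192.counts, dtype=float)  # (192, S)
        W = signatures_192.W  # (192, K)
        H = activities.H  # (K, S)
        # credit[c, k, s] ∝ W[c,k] H[k,s]; attributed[c,k] = Σ_s V[c,s]·credit
        num = W[:, :, None] * H[None, :, :]
        denom = num.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            credit = np.where(denom > 0, num / denom, 0.0)
        attributed = (credit * V[:, None, :]).sum(axis=2)  # (192, K)
        cls_of = np.array([substitution_class(ch) for ch in CHANNELS_192])
        is_coding = np.array([ch.endswith("+") for ch in CHANNELS_192])
        for k, name in enumerate(signatures_192.names):
            for cls in SUBSTITUTION_CLASSES:
                sel = cls_of == cls
                cod = attributed[sel & is_coding, k].sum()
                non = attributed[sel & ~is_coding, k].sum()
                cod_i, non_i = int(round(cod)), int(round(non))
                if cod_i + non_i == 0:
                    records.append((name, cls, cod, non, np.nan, "n/a"))
                    continue
                res = test_strand_asymmetry(cod_i, non_i)
                records.append((name, cls, cod, non, res.p_value, res.direction))
    out = pd.DataFrame(
        records,
        columns=["signature", "snv_class", "coding", "noncoding", "p_value", "direction"],
    )
    tested = out["p_value"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = _bh_adjust(out.loc[tested, "p_value"].to_numpy())
    return out
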