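"""Cross-territory signature renormalization and activity-correlation tests.

A mutational signature measured in one territory (e.g. a chicken or
nematode genome) is mapped into another (e.g. the human exome) by
scaling each channel by the ratio of target to source trinucleotide
context frequencies and renormalizing. To ask whether an externally
derived signature explains the same activity as a candidate signature
discovered in tumors, the candidate column is swapped for the external
signature, activities are re-inferred with the signature set otherwise
fixed, and the two activity profiles are correlated across samples;
significance comes from permutation null distributions of that
correlation.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import stats

from .catalog import ContextFrequencyTable, MutationCatalog
from .channels import channel_context, context_index
from .nmf import SignatureSet
from .refit import RefitConfig, infer_activities


def renormalize_signature(
    signature: np.ndarray,
    source: ContextFrequencyTable,
    target: ContextFrequencyTable,
    channels: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Adjust a 96-channel signature from one territory's context
    frequencies to another's.

    Each channel is scaled by target_freq/source_freq of its
    pyrimidine-centered trinucleotide context (the 3 channels sharing a
    context share a ratio) and the result renormalized to sum 1.
    Exactly invertible when all frequencies are strictly positive.
    """
    sig = np.asarray(signature, dtype=float)
    if sig.ndim != 1:
        raise ValueError("signature must be a 1-D channel vector")
    from .channels import CHANNELS_96

    channels = channels or CHANNELS_96
    if sig.shape[0] != len(channels):
        raise ValueError("signature length does not match the channel list")
    ctx_idx = np.array([context_index(channel_context(ch)) for ch in channels])
    src = source.frequency[ctx_idx]
    tgt = target.frequency[ctx_idx]
    bad = (src == 0) & (sig > 0)
    if bad.any():
        raise ValueError(
            "zero source frequency on channels with signature mass: "
            + ", ".join(np.asarray(channels)[bad][:5])
        )
    out = np.where(src > 0, sig * np.divide(tgt, src, out=np.zeros_like(tgt), where=src > 0), 0.0)
    total = out.sum()
    if total <= 0:
        raise ValueError("renormalized signature has zero mass")
    return out / total


@dataclasses.dataclass
class SubstitutionResult:
    """Correlation between candidate and stand-in signature activities."""

    pearson_r: float
    candidate_activities: np.ndarray
    replacement_activities: np.ndarray
    samples: list[str]
    unstable: bool  # True when either activity vector is (near-)constant


def substitute_and_correlate(
    catalog: MutationCatalog,
    signatures: SignatureSet,
    candidate_name: str,
    replacement: np.ndarray,
    refit_config: RefitConfig | None = None,
    _candidate_activities: np.ndarray | None = None,
) -> SubstitutionResult:
    """Swap the candidate signature for a replacement and correlate activities.

    Activities are inferred twice over the same catalog — once with the
    original signature set and once with the candidate column replaced —
    and the candidate's activity profile across samples is Pearson-
    correlated with the replacement's. A pre-computed candidate activity
    vector may be passed to avoid re-fitting the unchanged set.
    """
    refit_config = refit_config or RefitConfig()
    if candidate_name not in signatures.names:
        raise KeyError(f"{candidate_name!r} is not in the signature set")
    if _candidate_activities is None:
        original = infer_activities(catalog, signatures, refit_config)
        cand = original.activities.row(candidate_name)
    else:
        cand = np.asarray(_candidate_activities, dtype=float)
    swapped = signatures.replace(candidate_name, replacement)
    refit = infer_activities(catalog, swapped, refit_config)
    repl = refit.activities.row(candidate_name)
    unstable = bool(np.std(cand) < 1e-9 or np.std(repl) < 1e-9)
    if unstable:
        warnings.warn(
            "constant activity vector: correlation is undefined/unstable",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.nan
    else:
        r = float(stats.pearsonr(cand, repl).statistic)
    return SubstitutionResult(r, cand, repl, list(catalog.samples), unstable)


@dataclasses.dataclass
class NullDistribution:
    """Permutation null of activity correlations with its empirical p.

    The empirical p is the plain proportion of null correlations at
    least as large as the observed one (no small-sample correction).
    """

    method: str
    values: np.ndarray
    n: int
    observed: float
    empirical_p: float
    seed: int

    @classmethod
    def from_values(
        cls, values: np.ndarray, observed: float, method: str = "", seed: int = 0
    ) -> "NullDistribution":
        values = np.asarray(values, dtype=float)
        p = float(np.mean(values >= observed))
        return cls(method, values, len(values), float(observed), p, seed)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "n": self.n,
            "seed": self.seed,
            "observed": self.observed,
            "empirical_p": self.empirical_p,
        }

    def to_files(self, values_path: str | Path, summary_path: str | Path) -> None:
        np.savetxt(values_path, self.values, fmt="%.10g", header="null_r", comments="")
        Path(summary_path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def _draw_replacement(
    method: str,
    base: np.ndarray,
    reference_panel: SignatureSet | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if method == "permute_channels":
        return base[rng.permutation(len(base))]
    if method == "reference_combination":
        assert reference_panel is not None
        a, b = rng.choice(reference_panel.k, size=2, replace=False)
        w = rng.uniform()
        mix = w * reference_panel.W[:, a] + (1 - w) * reference_panel.W[:, b]
        return mix / mix.sum()
    raise ValueError(f"unknown null method: {method!r}")


def permutation_null(
    catalog: MutationCatalog,
    signatures: SignatureSet,
    candidate_name: str,
    replacement: np.ndarray,
    method: str = "permute_channels",
    n: int = 10_000,
    reference_panel: SignatureSet | None = None,
    seed: int = 0,
    refit_config: RefitConfig | None = None,
    observed: float | None = None,
) -> NullDistribution:
    """Null distribution of the substitution correlation.

    Each draw builds a surrogate replacement — a full random permutation
    of the replacement's 96 entries, or a random convex combination
    w*ref_a + (1-w)*ref_b of two distinct randomly chosen reference
    signatures — reruns the substitution refit, and records the Pearson
    correlation with the candidate's activities. The empirical p is the
    proportion of null correlations >= the observed correlation (which
    is computed from ``replacement`` unless supplied).
    """
    if n < 100:
        warnings.warn(f"n={n} null draws gives an unstable empirical p", UserWarning, stacklevel=2)
    if method == "reference_combination":
        if reference_panel is None or reference_panel.k < 2:
            raise ValueError("reference_combination needs a panel of >= 2 signatures")
    refit_config = refit_config or RefitConfig()
    original = infer_activities(catalog, signatures, refit_config)
    cand = original.activities.row(candidate_name)
    if observed is None:
        observed = substitute_and_correlate(
            catalog, signatures, candidate_name, replacement, refit_config,
            _candidate_activities=cand,
        ).pearson_r
    rng = np.random.default_rng(seed)
    values = np.empty(n)
    for i in range(n):
        surrogate = _draw_replacement(method, replacement, reference_panel, rng)
        res = substitute_and_correlate(
            catalog, signatures, candidate_name, surrogate, refit_config,
            _candidate_activities=cand,
        )
        values[i] = res.pearson_r
    nd = NullDistribution.from_values(values, observed, method=method, seed=seed)
    return nd
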