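"""Activity inference for a fixed signature set.

Given a catalog V and a fixed signature matrix W, infer the per-sample
activities H by multiplicative updates of H only, starting from a random
non-negative H0 and stopping when the Frobenius error trace has gone
flat: when the drop in ||V - W H|| over the last `window` iterations,
divided by the window, falls below `tol`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .nmf import ActivityMatrix, SignatureSet

_EPS = 1e-12


@dataclasses.dataclass
class RefitConfig:
    """Stopping rule and initialization for fixed-signature refitting.

    ``tol`` is the threshold on the per-iteration error drop averaged
    over the trailing ``window`` iterations; ``max_iter`` caps runaway
    tolerance settings; ``update`` chooses the multiplicative rule
    ("frobenius", monotone in the tracked error, or "kl").
    """

    tol: float = 1e-4
    window: int = 20
    max_iter: int = 10_000
    seed: int = 0
    update: str = "frobenius"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.max_iter <= self.window:
            raise ValueError("max_iter must exceed window")


@dataclasses.dataclass
class RefitResult:
    activities: ActivityMatrix
    error_trace: np.ndarray
    converged: bool
    n_iter: int


def infer_activities(
    catalog: MutationCatalog,
    signatures: SignatureSet,
    config: RefitConfig | None = None,
) -> RefitResult:
    """Infer H for fixed W by multiplicative updates with flat-trace stopping.

    H0 entries are i.i.d. uniform(0,1) scaled by (sample total / K) so
    the start is on the mutation-count scale; all-zero sample columns
    get zero activities. The returned error trace contains
    ``||V - W H_i||_F`` for every iteration including the start.
    """
    config = config or RefitConfig()
    if catalog.channels != signatures.channels:
        raise ValueError("catalog and signature set use different channel orderings")
    V = np.asarray(catalog.counts, dtype=float)
    W = signatures.W
    K = signatures.k
    rng = np.random.default_rng(config.seed)
    col_totals = V.sum(axis=0)
    H = rng.uniform(size=(K, V.shape[1])) * (col_totals / K)[None, :]

    WtV = W.T @ V
    WtW = W.T @ W
    errors = [float(np.linalg.norm(V - W @ H))]
    converged = False
    for i in range(1, config.max_iter + 1):
        if config.update == "frobenius":
            H *= WtV / (WtW @ H + _EPS)
        elif config.update == "kl":
            WH = W @ H + _EPS
            H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        else:
            raise ValueError(f"unknown update rule: {config.update!r}")
        errors.append(float(np.linalg.norm(V - W @ H)))
        if i >= config.window:
            if (errors[i - config.window] - errors[i]) / config.window < config.tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"refit hit max_iter={config.max_iter} before the error trace went flat",
            RuntimeWarning,
            stacklevel=2,
        )
    return RefitResult(
        activities=ActivityMatrix(list(signatures.names), list(catalog.samples), H),
        error_trace=np.asarray(errors),
        converged=converged,
        n_iter=len(errors) - 1,
    )


@dataclasses.dataclass
class ActivityFractions:
    per_sample: pd.DataFrame  # K x samples, columns sum to 1
    cohort: pd.Series  # per-signature share of total activity mass


def attribute_activity_fractions(activities: ActivityMatrix) -> ActivityFractions:
    """Per-sample and cohort-level signature activity fractions.

    The cohort fraction of a signature is its total activity mass over
    the total activity mass of all signatures (the "x% of mutations are
    associated with signature S" quantity).
    """
    H = activities.H
    total = H.sum()
    if total <= 0:
        raise ValueError("activity matrix has zero total mass")
    col = H.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample = np.where(col > 0, H / col, np.nan)
    return ActivityFractions(
        per_sample=pd.DataFrame(per_sample, index=activities.names, columns=activities.samples),
        cohort=pd.Series(H.sum(axis=1) / total, index=activities.names, name="cohort_fraction"),
    )
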