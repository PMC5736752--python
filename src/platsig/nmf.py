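"""De-novo mutational-signature discovery by multiplicative-update NMF.

The catalog V (channels x samples) is factorized as V ~ W @ H with W the
signature matrix (each column a distribution over channels) and H the
activity matrix (mutations attributed to each signature per sample).
Because NMF is non-convex, discovery runs many independently initialized
factorizations and keeps the run with the minimum Frobenius
reconstruction error; rank diagnostics (cophenetic coefficient,
residuals, RSS) are reported for manual rank selection.

Two multiplicative update rules are provided: the Euclidean rule, which
monotonically decreases the Frobenius reconstruction error that run
selection and the refit stopping rule are defined on (the default), and
the KL-divergence ("brunet") rule, monotone in generalized KL.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .catalog import MutationCatalog

_EPS = 1e-12


@dataclasses.dataclass
class SignatureSet:
    """Channel distributions of K signatures (columns of W sum to 1)."""

    channels: tuple[str, ...]
    names: list[str]
    W: np.ndarray  # (n_channels, K)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.channels), len(self.names)):
            raise ValueError("W shape does not match channels x names")
        if (self.W < 0).any():
            raise ValueError("signatures must be non-negative")
        colsums = self.W.sum(axis=0)
        if np.abs(colsums - 1.0).max() > 1e-9:
            raise ValueError("signature columns must sum to 1 (within 1e-9)")

    @property
    def k(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.W[:, self.names.index(name)]

    def replace(self, name: str, vector: np.ndarray, new_name: str | None = None) -> "SignatureSet":
        """A copy with one signature column replaced (renormalized)."""
        W = self.W.copy()
        j = self.names.index(name)
        v = np.asarray(vector, dtype=float)
        W[:, j] = v / v.sum()
        names = list(self.names)
        if new_name is not None:
            names[j] = new_name
        return SignatureSet(self.channels, names, W)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=list(self.channels), columns=self.names)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("channel").to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, normalize: bool = False) -> "SignatureSet":
        W = frame.to_numpy(dtype=float)
        if normalize:
            W = W / W.sum(axis=0, keepdims=True)
        return cls(tuple(frame.index), [str(c) for c in frame.columns], W)

    @classmethod
    def from_tsv(cls, path: str | Path, normalize: bool = False) -> "SignatureSet":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0), normalize=normalize)


@dataclasses.dataclass
class ActivityMatrix:
    """Signature activities per sample, on the mutation-count scale."""

    names: list[str]
    samples: list[str]
    H: np.ndarray  # (K, n_samples)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if self.H.shape != (len(self.names), len(self.samples)):
            raise ValueError("H shape does not match names x samples")
        if (self.H < 0).any():
            raise ValueError("activities must be non-negative")

    def row(self, name: str) -> np.ndarray:
        return self.H[self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.H, index=self.names, columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("signature").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in frame.index], [str(c) for c in frame.columns], frame.to_numpy())


@dataclasses.dataclass
class RankDiagnostics:
    rank: int
    cophenetic: float
    rss: float
    residual: float
    best_run_seed: int


@dataclasses.dataclass
class DiscoveryResult:
    signatures: SignatureSet
    activities: ActivityMatrix
    residual: float
    error_trace: np.ndarray
    run_log: pd.DataFrame  # columns: run, seed, residual, n_iter


def _init_factors(V: np.ndarray, rank: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """i.i.d. uniform(0,1) factors scaled so W@H has the catalog's mean mass."""
    scale = np.sqrt(V.mean() / rank) + _EPS
    W = rng.uniform(size=(V.shape[0], rank)) * scale
    H = rng.uniform(size=(rank, V.shape[1])) * scale
    return W, H


def _nmf_single_run(
    V: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    update: str = "frobenius",
    max_iter: int = 2000,
    rel_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative-update factorization; returns (W, H, error trace)."""
    W, H = _init_factors(V, rank, rng)
    errors = np.empty(max_iter + 1)
    errors[0] = np.linalg.norm(V - W @ H)
    n = 0
    for it in range(1, max_iter + 1):
        if update == "frobenius":
            H *= (W.T @ V) / (W.T @ W @ H + _EPS)
            W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        elif update == "kl":
            WH = W @ H + _EPS
            H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
            WH = W @ H + _EPS
            W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        else:
            raise ValueError(f"unknown update rule: {update!r}")
        errors[it] = np.linalg.norm(V - W @ H)
        n = it
        prev = errors[it - 1]
        if prev > 0 and abs(prev - errors[it]) / prev < rel_tol:
            break
    return W, H, errors[: n + 1]


def _normalize_factors(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale so W columns sum to 1, compensating in H rows (WH unchanged)."""
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    return W / scale, H * scale[:, None]


def discover_signatures(
    catalog: MutationCatalog,
    rank: int,
    n_runs: int = 200,
    seed: int = 0,
    update: str = "frobenius",
    max_iter: int = 2000,
    rel_tol: float = 1e-6,
    names: Sequence[str] | None = None,
) -> DiscoveryResult:
    """Multi-run signature discovery; keeps the minimum-residual run.

    Runs ``n_runs`` independently initialized factorizations (run r uses
    seed ``seed + r``) and returns the factors of the run with the
    minimum Frobenius reconstruction error, with W columns renormalized
    to distributions and H carrying the mutation-count scale.
    """
    V = np.asarray(catalog.counts, dtype=float)
    if rank < 1 or rank >= min(V.shape):
        raise ValueError(f"rank {rank} must satisfy 1 <= rank < min{V.shape}")
    if V.sum() <= 0:
        raise ValueError("catalog has no mutations to factorize")
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    best_err = np.inf
    best_seed = -1
    log_rows = []
    for r in range(n_runs):
        run_seed = seed + r
        rng = np.random.default_rng(run_seed)
        W, H, trace = _nmf_single_run(V, rank, rng, update, max_iter, rel_tol)
        log_rows.append((r, run_seed, trace[-1], len(trace) - 1))
        if trace[-1] < best_err:
            best_err = float(trace[-1])
            best = (W, H, trace)
            best_seed = run_seed
    assert best is not None
    W, H, trace = best
    W, H = _normalize_factors(W, H)
    sig_names = list(names) if names is not None else [f"S{i + 1}" for i in range(rank)]
    return DiscoveryResult(
        signatures=SignatureSet(catalog.channels, sig_names, W),
        activities=ActivityMatrix(sig_names, list(catalog.samples), H),
        residual=best_err,
        error_trace=trace,
        run_log=pd.DataFrame(log_rows, columns=["run", "seed", "residual", "n_iter"]),
    )


def _cophenetic_from_assignments(assignments: np.ndarray) -> float:
    """Cophenetic correlation of the consensus over per-run sample clusterings.

    ``assignments`` is (n_runs, n_samples) of dominant-signature labels.
    The consensus matrix C is the fraction of runs co-clustering each
    sample pair; the coefficient is the Pearson correlation between the
    cophenetic distances of an average-linkage tree on 1 - C and 1 - C
    itself. A degenerate consensus (all pairs always/never together)
    has no dispersion and is reported as 1.0.
    """
    n_samples = assignments.shape[1]
    if n_samples < 2:
        return 1.0
    consensus = np.zeros((n_samples, n_samples))
    for run in assignments:
        consensus += run[:, None] == run[None, :]
    consensus /= len(assignments)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if condensed.std() < 1e-12:
        return 1.0
    Z = hierarchy.linkage(condensed, method="average")
    coph, _ = hierarchy.cophenet(Z, condensed)
    return float(coph)


def rank_survey(
    catalog: MutationCatalog,
    ranks: Sequence[int],
    n_runs: int = 50,
    seed: int = 0,
    update: str = "frobenius",
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Diagnostics over candidate ranks for manual rank selection.

    For each rank: the minimum Frobenius residual over ``n_runs`` runs,
    its square (RSS), the seed of the best run, and the cophenetic
    coefficient of sample co-clustering (by dominant signature) across
    runs. Rank choice is not automated.
    """
    V = np.asarray(catalog.counts, dtype=float)
    rows = []
    for rank in ranks:
        if rank < 1 or rank >= min(V.shape):
            raise ValueError(f"rank {rank} must satisfy 1 <= rank < min{V.shape}")
        assignments = np.empty((n_runs, V.shape[1]), dtype=np.int64)
        best_err, best_seed = np.inf, -1
        for r in range(n_runs):
            run_seed = seed + 1000 * rank + r
            rng = np.random.default_rng(run_seed)
            W, H, trace = _nmf_single_run(V, rank, rng, update, max_iter)
            assignments[r] = H.argmax(axis=0)
            if trace[-1] < best_err:
                best_err, best_seed = float(trace[-1]), run_seed
        rows.append(
            RankDiagnostics(
                rank=rank,
                cophenetic=_cophenetic_from_assignments(assignments),
                rss=best_err**2,
                residual=best_err,
                best_run_seed=best_seed,
            )
        )
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity dot(a,b)/(|a||b|) of two non-negative channel vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclasses.dataclass
class MatchResult:
    table: pd.DataFrame  # discovered, best_match, cosine, matched, tie
    pair_similarities: pd.DataFrame | None = None


def match_signatures(
    discovered: SignatureSet,
    reference: SignatureSet,
    threshold: float = 0.85,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> MatchResult:
    """Best-cosine matching of discovered signatures to a reference panel.

    A discovered signature is ``matched`` when its best cosine reaches
    ``threshold``; otherwise its best_match is reported as ``"UNK"``.
    Exact ties go to the lower reference index and are flagged.
    Optionally also reports each discovered signature's similarity to
    the mean of named reference pairs (some processes are best described
    by an average of two canonical signatures).
    """
    if discovered.channels != reference.channels:
        raise ValueError("discovered and reference panels use different channel orderings")
    rows = []
    for i, name in enumerate(discovered.names):
        sims = np.array([
            cosine_similarity(discovered.W[:, i], reference.W[:, j])
            for j in range(reference.k)
        ])
        j_best = int(sims.argmax())
        tie = bool((sims == sims[j_best]).sum() > 1)
        matched = bool(sims[j_best] >= threshold)
        rows.append({
            "discovered": name,
            "best_match": reference.names[j_best] if matched else "UNK",
            "best_reference": reference.names[j_best],
            "cosine": float(sims[j_best]),
            "matched": matched,
            "tie": tie,
        })
    pair_frame = None
    if pairs:
        data = {}
        for (na, nb) in pairs:
            mean_sig = 0.5 * (reference[na] + reference[nb])
            data[f"mean({na},{nb})"] = [
                cosine_similarity(discovered.W[:, i], mean_sig) for i in range(discovered.k)
            ]
        pair_frame = pd.DataFrame(data, index=discovered.names)
    return MatchResult(table=pd.DataFrame(rows), pair_similarities=pair_frame)
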