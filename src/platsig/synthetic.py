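"""Synthetic paired pre/post-treatment cohorts with known truth.

The generator emulates the statistical structure the rest of the
pipeline assumes: each patient carries a truncal clone (CCF 1 in both
tumors), shared subclonal subclones, and subclones private to the pre-
or post-treatment tumor (CCF 0 in the other). Mutation channels are
drawn i.i.d. from planted signature mixtures; a designated treatment
signature is drawn only for post-private (hence subclonal) mutations at
a configured fraction of the post-tumor load, mimicking a mutagenic
exposure between the two biopsies. Transcriptional strand labels can be
biased per signature and substitution class, and per-site sequencing
depths exercise the detection-power filter. Every mutation's generating
signature, subclone, CCF and timing are emitted so downstream modules
can be scored against truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS_96, SUBSTITUTION_CLASSES, revcomp
from .heterogeneity import Subclone
from .nmf import SignatureSet

TREATMENT = "treatment"


def generate_signatures(
    k: int,
    concentration: float = 0.5,
    seed: int = 0,
    n_channels: int = 96,
    max_pairwise_cosine: float = 0.8,
    max_draws: int = 1000,
    names: list[str] | None = None,
) -> SignatureSet:
    """K Dirichlet-distributed channel distributions, kept mutually distinct.

    Signatures are drawn one at a time and rejected when their cosine to
    any accepted signature reaches ``max_pairwise_cosine``, so recovery
    tests work on an identifiable basis.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    draws = 0
    while len(accepted) < k:
        if draws >= max_draws:
            raise RuntimeError(
                f"could not draw {k} signatures with pairwise cosine < "
                f"{max_pairwise_cosine} in {max_draws} draws (concentration too high?)"
            )
        cand = rng.dirichlet(np.full(n_channels, concentration))
        draws += 1
        ok = all(
            cand @ a / (np.linalg.norm(cand) * np.linalg.norm(a)) < max_pairwise_cosine
            for a in accepted
        )
        if ok:
            accepted.append(cand)
    W = np.column_stack(accepted)
    names = names or [f"S{i + 1}" for i in range(k)]
    channels = tuple(CHANNELS_96[:n_channels]) if n_channels <= 96 else tuple(CHANNELS_96)
    return SignatureSet(channels, names, W)


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for a paired pre/post cohort.

    Defaults describe the reference cohort used throughout the test
    suite: 30 patients, 2,000 mutations per tumor, 3 background
    signatures with Dirichlet(1) patient exposures, and a treatment
    signature contributing 15% of each post-treatment tumor's mutations,
    confined to post-private subclones.
    """

    n_patients: int = 30
    mutations_per_tumor: int = 2000
    n_signatures: int = 3
    signature_concentration: float = 0.5
    exposure_concentration: float = 1.0
    treatment_fraction: float = 0.15
    treatment_concentration: float = 12.0  # Beta concentration of per-patient exposure
    shared_fraction: float = 0.65
    clonal_fraction: float = 0.75  # of shared mutations on the truncal clone
    n_shared_subclones: int = 2  # including the truncal clone
    n_pre_private_subclones: int = 1
    n_post_private_subclones: int = 1
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.8)
    strand_bias: dict | None = None  # {signature: {snv_class: noncoding/coding ratio}}
    depth_mean: float = 150.0
    depth_dispersion: float = 5.0
    mate_low_coverage_fraction: float = 0.05
    mate_low_depth_mean: float = 10.0
    purity_range: tuple[float, float] = (0.5, 0.9)
    purine_spelling_fraction: float = 0.5  # records written on the purine strand
    ccf_noise: bool = False
    ccf_noise_kappa: float = 100.0
    signatures: SignatureSet | None = None  # planted truth incl. treatment column
    exposures: np.ndarray | None = None  # (n_patients, n_signatures) background mixing
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("treatment_fraction", "shared_fraction", "clonal_fraction",
                     "mate_low_coverage_fraction", "purine_spelling_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        n_private = self.mutations_per_tumor - round(self.shared_fraction * self.mutations_per_tumor)
        if round(self.treatment_fraction * self.mutations_per_tumor) > n_private:
            raise ValueError(
                "treatment_fraction exceeds the post-private mutation budget; "
                "lower it or lower shared_fraction"
            )
        if self.treatment_concentration <= 0:
            raise ValueError("treatment_concentration must be positive")
        if self.n_shared_subclones < 1:
            raise ValueError("need at least the truncal clone")


@dataclasses.dataclass
class CohortData:
    pre: pd.DataFrame
    post: pd.DataFrame
    signatures: SignatureSet  # background + treatment columns
    exposures: pd.DataFrame  # per-patient background mixing proportions
    subclones: dict[str, list[Subclone]]
    config: SimulationConfig

    def mutations(self) -> pd.DataFrame:
        return pd.concat([self.pre, self.post], ignore_index=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pre.to_csv(outdir / "pre.tsv", sep="\t", index=False)
        self.post.to_csv(outdir / "post.tsv", sep="\t", index=False)
        self.signatures.to_tsv(outdir / "signatures_true.tsv")
        truth = {
            "exposures": self.exposures.round(6).to_dict(orient="index"),
            "subclones": {
                p: [dataclasses.asdict(s) for s in subs] for p, subs in self.subclones.items()
            },
            "seed": self.config.seed,
            "n_patients": self.config.n_patients,
            "mutations_per_tumor": self.config.mutations_per_tumor,
            "treatment_fraction": self.config.treatment_fraction,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def _draw_channels(rng: np.random.Generator, sig: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(96, size=n, p=sig)


def _strand_for(
    rng: np.random.Generator,
    channels: np.ndarray,
    sig_name: str,
    bias: dict | None,
) -> np.ndarray:
    """Draw coding/noncoding labels with a per-class noncoding:coding ratio."""
    p_coding = np.full(len(channels), 0.5)
    if bias and sig_name in bias:
        per_class = bias[sig_name]
        for cls, ratio in per_class.items():
            cls_idx = SUBSTITUTION_CLASSES.index(cls)
            mask = channels // 16 == cls_idx
            p_coding[mask] = 1.0 / (1.0 + float(ratio))
    return np.where(rng.uniform(size=len(channels)) < p_coding, "coding", "noncoding")


def _nb_depths(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def generate_paired_cohort(config: SimulationConfig | None = None) -> CohortData:
    """Generate matched pre/post mutation tables plus the truth bundle.

    Each tumor receives exactly ``mutations_per_tumor`` mutations:
    shared ones (identical sites in both tables, on the truncal clone or
    shared subclonal subclones) and private ones confined to that
    tumor's private subclones. The treatment signature is drawn only for
    post-private mutations. Records are written on the purine strand
    with the configured probability to exercise pyrimidine collapsing;
    the ``channel_truth`` column always holds the collapsed label.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    K = config.n_signatures
    if config.signatures is not None:
        sigset = config.signatures
        if TREATMENT not in sigset.names:
            raise ValueError(f"planted signature set must contain a {TREATMENT!r} column")
        bg_names = [n for n in sigset.names if n != TREATMENT]
        if len(bg_names) != K:
            K = len(bg_names)
    else:
        sigset = generate_signatures(
            K + 1,
            concentration=config.signature_concentration,
            seed=config.seed,
            names=[f"BG{i + 1}" for i in range(K)] + [TREATMENT],
        )
        bg_names = [n for n in sigset.names if n != TREATMENT]
    bg_W = np.column_stack([sigset[n] for n in bg_names])
    treat_sig = sigset[TREATMENT]

    if config.exposures is not None:
        exposures = np.asarray(config.exposures, dtype=float)
        if exposures.shape != (config.n_patients, K):
            raise ValueError("exposures must be (n_patients, n_background_signatures)")
    else:
        exposures = rng.dirichlet(np.full(K, config.exposure_concentration), size=config.n_patients)

    m = config.mutations_per_tumor
    n_shared = round(config.shared_fraction * m)
    n_private = m - n_shared
    n_clonal = round(config.clonal_fraction * n_shared) if config.n_shared_subclones > 1 else n_shared

    lo, hi = config.subclonal_ccf_range
    pre_rows: list[pd.DataFrame] = []
    post_rows: list[pd.DataFrame] = []
    subclone_truth: dict[str, list[Subclone]] = {}
    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    exposure_frame = pd.DataFrame(exposures, index=patients, columns=bg_names)

    for pi, patient in enumerate(patients):
        purity_pre, purity_post = rng.uniform(*config.purity_range, size=2)
        # per-patient treatment exposure: Beta around the cohort mean
        # (patients differ in mutagenic response), capped by the
        # post-private budget
        f_mean, kappa = config.treatment_fraction, config.treatment_concentration
        if f_mean <= 0:
            n_treat = 0
        elif f_mean >= 1:
            n_treat = n_private
        else:
            f_i = rng.beta(f_mean * kappa, (1 - f_mean) * kappa)
            n_treat = min(round(f_i * m), n_private)
        # --- subclone architecture ---
        subs: list[Subclone] = [Subclone(1, 1.0, 1.0)]
        next_id = 2
        for _ in range(config.n_shared_subclones - 1):
            subs.append(Subclone(next_id, float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi))))
            next_id += 1
        pre_private_ids, post_private_ids = [], []
        for _ in range(config.n_pre_private_subclones):
            subs.append(Subclone(next_id, float(rng.uniform(lo, hi)), 0.0))
            pre_private_ids.append(next_id)
            next_id += 1
        for _ in range(config.n_post_private_subclones):
            subs.append(Subclone(next_id, 0.0, float(rng.uniform(lo, hi))))
            post_private_ids.append(next_id)
            next_id += 1
        subclone_truth[patient] = subs
        by_id = {s.id: s for s in subs}

        # --- mutation plan: (n, signature kind, subclone ids, timing) ---
        shared_sub_ids = [s.id for s in subs if s.id != 1 and s.pre_ccf > 0 and s.post_ccf > 0]

        def _assign_subclones(n: int, ids: list[int]) -> np.ndarray:
            if n > 0 and not ids:
                raise ValueError(
                    "private mutations requested but no private subclones configured"
                )
            return np.array(ids)[rng.integers(len(ids), size=n)] if ids else np.empty(0, dtype=np.int64)

        plan = []
        # shared mutations: truncal + shared subclonal, background signatures
        plan.append(("shared", n_clonal, np.full(n_clonal, 1), "background"))
        n_shared_sub = n_shared - n_clonal
        plan.append(("shared", n_shared_sub, _assign_subclones(n_shared_sub, shared_sub_ids), "background"))
        # pre-private: background only
        plan.append(("pre_only", n_private, _assign_subclones(n_private, pre_private_ids), "background"))
        # post-private: treatment + background
        plan.append(("post_only", n_treat, _assign_subclones(n_treat, post_private_ids), TREATMENT))
        plan.append(("post_only", n_private - n_treat,
                     _assign_subclones(n_private - n_treat, post_private_ids), "background"))

        sig_label: list[str] = []
        channels: list[np.ndarray] = []
        timing: list[str] = []
        subclone_ids: list[np.ndarray] = []
        for t, n, sub_ids, kind in plan:
            if n == 0:
                continue
            if kind == TREATMENT:
                ch = _draw_channels(rng, treat_sig, n)
                names = np.full(n, TREATMENT, dtype=object)
            else:
                which = rng.choice(K, size=n, p=exposures[pi])
                ch = np.empty(n, dtype=np.int64)
                for k in range(K):
                    mask = which == k
                    if mask.any():
                        ch[mask] = _draw_channels(rng, bg_W[:, k], int(mask.sum()))
                names = np.array(bg_names, dtype=object)[which]
            sig_label.append(names)
            channels.append(ch)
            timing.extend([t] * n)
            subclone_ids.append(sub_ids)
        sig_label = np.concatenate(sig_label)
        channels = np.concatenate(channels)
        subclone_ids = np.concatenate(subclone_ids)
        timing = np.array(timing)
        n_tot = len(channels)

        # strand labels with per-signature/class bias
        strand = np.empty(n_tot, dtype=object)
        for name in sorted(set(sig_label)):
            mask = sig_label == name
            strand[mask] = _strand_for(rng, channels[mask], str(name), config.strand_bias)

        # spelling: channel label gives pyrimidine-strand alleles; flip some
        labels = np.array(CHANNELS_96, dtype=object)[channels]
        ref = np.array([lab[2] for lab in labels], dtype=object)
        alt = np.array([lab[4] for lab in labels], dtype=object)
        f5 = np.array([lab[0] for lab in labels], dtype=object)
        f3 = np.array([lab[6] for lab in labels], dtype=object)
        flip = rng.uniform(size=n_tot) < config.purine_spelling_fraction
        for i in np.flatnonzero(flip):
            ref[i], alt[i] = revcomp(ref[i]), revcomp(alt[i])
            f5[i], f3[i] = revcomp(f3[i]), revcomp(f5[i])

        pos = pi * 10_000_000 + np.arange(1, n_tot + 1) * 3  # unique, non-adjacent
        ccf_pre = np.array([by_id[s].pre_ccf for s in subclone_ids])
        ccf_post = np.array([by_id[s].post_ccf for s in subclone_ids])
        if config.ccf_noise:
            kap = config.ccf_noise_kappa
            for arr in (ccf_pre, ccf_post):
                noisy = (arr > 0) & (arr < 1)
                arr[noisy] = rng.beta(kap * arr[noisy], kap * (1 - arr[noisy]))

        base = pd.DataFrame({
            "patient": patient,
            "chrom": "chr1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "context5": f5,
            "context3": f3,
            "strand": strand,
            "subclone": subclone_ids,
            "timing_truth": timing,
            "signature_truth": sig_label,
            "channel_truth": labels,
        })

        for side, ccf_own, ccf_mate, purity_own, purity_mate, sample in (
            ("pre", ccf_pre, ccf_post, purity_pre, purity_post, f"{patient}_pre"),
            ("post", ccf_post, ccf_pre, purity_post, purity_pre, f"{patient}_post"),
        ):
            present = ccf_own > 0
            tbl = base.loc[present].copy()
            own = ccf_own[present]
            tbl.insert(0, "sample", sample)
            tbl["ccf"] = own
            tbl["clonality"] = np.where(own >= 1.0 - 1e-3, "clonal", "subclonal")
            depth = _nb_depths(rng, config.depth_mean, config.depth_dispersion, len(tbl))
            vaf = purity_own * own / 2.0
            tbl["t_depth"] = depth
            tbl["t_alt_count"] = np.maximum(rng.binomial(depth, np.clip(vaf, 0, 1)), 1)
            # mate-tumor depth/VAF at private sites, for the power filter
            private = ~np.asarray(ccf_mate[present] > 0)
            mate_depth = np.full(len(tbl), np.nan)
            mate_vaf = np.full(len(tbl), np.nan)
            if private.any():
                n_priv = int(private.sum())
                low = rng.uniform(size=n_priv) < config.mate_low_coverage_fraction
                md = _nb_depths(rng, config.depth_mean, config.depth_dispersion, n_priv).astype(float)
                md[low] = _nb_depths(
                    rng, config.mate_low_depth_mean, config.depth_dispersion, int(low.sum())
                )
                mate_depth[private] = md
                mate_vaf[private] = purity_mate * own[private] / 2.0
            tbl["mate_depth"] = mate_depth
            tbl["mate_vaf"] = mate_vaf
            (pre_rows if side == "pre" else post_rows).append(tbl)

    return CohortData(
        pre=pd.concat(pre_rows, ignore_index=True),
        post=pd.concat(post_rows, ignore_index=True),
        signatures=sigset,
        exposures=exposure_frame,
        subclones=subclone_truth,
        config=config,
    )
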