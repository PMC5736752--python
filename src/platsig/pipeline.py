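"""Stage orchestration: simulate -> catalog -> discover -> refit ->
compare -> strand bias -> attribution -> heterogeneity.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so any stage can be re-run in isolation from its persisted
inputs; ``run_pipeline`` chains the enabled stages and aggregates a
machine-readable JSON report. A single nested config drives everything;
unspecified keys fall back to defaults.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as cat
from . import compare as cmp
from . import heterogeneity as het
from . import nmf, refit, strand_bias, synthetic
from .attribution import aggregate_attributions, subclonal_enrichment_test
from .nmf import SignatureSet

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

STAGES = (
    "simulate", "catalog", "discover", "refit",
    "compare", "strandbias", "attribute", "heterogeneity",
)

DEFAULT_CONFIG: dict = {
    "stages": list(STAGES),
    "seed": 0,
    "simulate": {},  # SimulationConfig keyword overrides
    "catalog": {
        "pre_table": None,   # default: the simulate stage's output
        "post_table": None,
        "reference_fasta": None,
        "min_alt_reads": 3,
        "power_threshold": 0.8,
    },
    "discover": {
        "rank": 4,       # rank for the post-only discovery
        "bg_rank": 3,    # rank for the pre-treatment (background) discovery
        "n_runs": 50,
        "max_iter": 2000,
        "match_threshold": 0.85,
        "reference_panel": None,  # default: simulated truth signatures
    },
    "refit": {"tol": 1e-4, "window": 20, "max_iter": 10_000},
    "compare": {
        "method": "permute_channels",
        "n": 1000,
        "replacement_signature": None,  # default: simulated truth treatment signature
        "candidate": None,  # default: the unmatched ("UNK") discovered signature
    },
    "strandbias": {"rank": 2, "n_runs": 20, "max_iter": 2000},
    "attribute": {},
    "heterogeneity": {"prop_cutoff": 0.2, "subclone_cutoff": 6},
}


def merge_config(overrides: dict | None) -> dict:
    """Deep-merge user overrides onto the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(base: dict, extra: dict) -> None:
        for key, value in extra.items():
            if isinstance(value, dict) and isinstance(base.get(key), dict):
                _merge(base[key], value)
            else:
                base[key] = value

    if overrides:
        _merge(cfg, overrides)
    return cfg


def validate_config(cfg: dict) -> None:
    """Pre-flight check: every referenced input file must exist."""
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage, key in (
        ("catalog", "pre_table"), ("catalog", "post_table"), ("catalog", "reference_fasta"),
        ("discover", "reference_panel"), ("compare", "replacement_signature"),
    ):
        path = cfg.get(stage, {}).get(key)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"config {stage}.{key} points to a missing file: {path}")


def extract_post_only(classified: pd.DataFrame) -> pd.DataFrame:
    """Mutations private to the post-treatment tumor (timing == post_only).

    The input is a cohort table classified by the detection-power rule;
    the output feeds a validation-style discovery run on
    chemotherapy-era mutations.
    """
    out = classified[classified["timing"] == "post_only"].reset_index(drop=True)
    if out.empty:
        logger.warning("no post_only mutations after the power filter")
    return out


def _power_model(ccfg: dict) -> cat.PowerModel:
    return cat.PowerModel(
        min_alt_reads=int(ccfg.get("min_alt_reads", 3)),
        power_threshold=float(ccfg.get("power_threshold", 0.8)),
    )


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> dict:
    sim_cfg = synthetic.SimulationConfig(**{**cfg["simulate"], "seed": seed})
    cohort = synthetic.generate_paired_cohort(sim_cfg)
    cohort.write(outdir / "cohort")
    return {
        "n_patients": sim_cfg.n_patients,
        "mutations_per_tumor": sim_cfg.mutations_per_tumor,
        "n_pre_records": len(cohort.pre),
        "n_post_records": len(cohort.post),
        "seed": seed,
    }


def _load_tables(cfg: dict, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    ccfg = cfg["catalog"]
    pre_path = ccfg["pre_table"] or outdir / "cohort" / "pre.tsv"
    post_path = ccfg["post_table"] or outdir / "cohort" / "post.tsv"
    return cat.read_mutation_table(pre_path), cat.read_mutation_table(post_path)


def stage_catalog(cfg: dict, outdir: Path) -> dict:
    ccfg = cfg["catalog"]
    pre, post = _load_tables(cfg, outdir)
    reference = None
    if ccfg["reference_fasta"]:
        import pyfaidx

        reference = pyfaidx.Fasta(ccfg["reference_fasta"])
    model = _power_model(ccfg)
    classified = cat.classify_cohort(pre, post, model=model)
    classified.to_csv(outdir / "classified.tsv", sep="\t", index=False)
    post_only = extract_post_only(classified)
    post_only.to_csv(outdir / "post_only.tsv", sep="\t", index=False)

    qc: dict = {}
    pre_catalog, qc_pre = cat.build_catalog(pre, reference)
    post_catalog, qc_post = cat.build_catalog(post, reference)
    pre_catalog.to_tsv(outdir / "pre_catalog.tsv")
    post_catalog.to_tsv(outdir / "post_catalog.tsv")
    qc["pre"], qc["post"] = qc_pre.as_dict(), qc_post.as_dict()
    if not post_only.empty:
        po_catalog, qc_po = cat.build_catalog(post_only, reference)
        po_catalog.to_tsv(outdir / "post_only_catalog.tsv")
        qc["post_only"] = qc_po.as_dict()
    if "strand" in post.columns:
        stranded, qc_strand = cat.build_stranded_catalog(post, reference)
        stranded.to_tsv(outdir / "post_stranded_catalog.tsv")
        qc["post_stranded"] = qc_strand.as_dict()
        if not post_only.empty and "strand" in post_only.columns:
            po_stranded, _ = cat.build_stranded_catalog(post_only, reference)
            po_stranded.to_tsv(outdir / "post_only_stranded_catalog.tsv")
    qc["timing_counts"] = classified["timing"].value_counts().to_dict()
    return qc


def _truth_signatures(outdir: Path) -> SignatureSet | None:
    path = outdir / "cohort" / "signatures_true.tsv"
    return SignatureSet.from_tsv(path) if path.exists() else None


def stage_discover(cfg: dict, outdir: Path, seed: int) -> dict:
    """Two-catalog discovery mirroring a paired-cohort study design.

    Background signatures are discovered on the pre-treatment catalog
    (no treatment-era mutations there); a separate discovery on the
    post-only catalog isolates the signature that does not match any
    background — the treatment-signature candidate ("UNK"). The
    combined set (backgrounds + UNK) is the basis for refitting.
    """
    dcfg = cfg["discover"]
    n_runs, max_iter = int(dcfg["n_runs"]), int(dcfg["max_iter"])
    threshold = float(dcfg["match_threshold"])

    pre_catalog = cat.MutationCatalog.from_tsv(outdir / "pre_catalog.tsv")
    disc_pre = nmf.discover_signatures(
        pre_catalog, rank=int(dcfg["bg_rank"]), n_runs=n_runs, seed=seed,
        max_iter=max_iter, names=[f"BG-D{i + 1}" for i in range(int(dcfg["bg_rank"]))],
    )
    disc_pre.signatures.to_tsv(outdir / "signatures_pre.tsv")

    po_path = outdir / "post_only_catalog.tsv"
    source = po_path if po_path.exists() else outdir / "post_catalog.tsv"
    catalog = cat.MutationCatalog.from_tsv(source)
    result = nmf.discover_signatures(
        catalog, rank=int(dcfg["rank"]), n_runs=n_runs, seed=seed + 1, max_iter=max_iter,
    )
    result.signatures.to_tsv(outdir / "signatures_post_only.tsv")
    result.activities.to_tsv(outdir / "activities_discovery.tsv")
    result.run_log.to_csv(outdir / "discovery_runs.tsv", sep="\t", index=False)

    # the candidate is the post-only signature least like any background
    vs_bg = nmf.match_signatures(result.signatures, disc_pre.signatures, threshold)
    vs_bg.table.to_csv(outdir / "post_only_vs_background.tsv", sep="\t", index=False)
    unk_name = str(vs_bg.table.loc[vs_bg.table["cosine"].idxmin(), "discovered"])
    combined = SignatureSet(
        catalog.channels,
        list(disc_pre.signatures.names) + ["UNK"],
        np.column_stack([disc_pre.signatures.W, result.signatures[unk_name]]),
    )
    combined.to_tsv(outdir / "signatures_discovered.tsv")

    summary = {
        "bg_rank": dcfg["bg_rank"], "rank": dcfg["rank"], "n_runs": n_runs,
        "pre_residual": disc_pre.residual, "post_only_residual": result.residual,
        "post_only_catalog": str(source.name), "unk_source": unk_name, "seed": seed,
    }
    panel = (
        SignatureSet.from_tsv(dcfg["reference_panel"])
        if dcfg["reference_panel"] else _truth_signatures(outdir)
    )
    if panel is not None:
        match = nmf.match_signatures(combined, panel, threshold)
        match.table.to_csv(outdir / "signature_matches.tsv", sep="\t", index=False)
        summary["matches"] = match.table[["discovered", "best_match", "cosine"]].to_dict("records")
    return summary


def _refit_config(cfg: dict, seed: int) -> refit.RefitConfig:
    rcfg = cfg["refit"]
    return refit.RefitConfig(
        tol=float(rcfg["tol"]), window=int(rcfg["window"]),
        max_iter=int(rcfg["max_iter"]), seed=seed,
    )


def stage_refit(cfg: dict, outdir: Path, seed: int) -> dict:
    catalog = cat.MutationCatalog.from_tsv(outdir / "post_catalog.tsv")
    signatures = SignatureSet.from_tsv(outdir / "signatures_discovered.tsv")
    result = refit.infer_activities(catalog, signatures, _refit_config(cfg, seed))
    result.activities.to_tsv(outdir / "activities_post.tsv")
    np.savetxt(outdir / "refit_error_trace.txt", result.error_trace, fmt="%.6f")
    fractions = refit.attribute_activity_fractions(result.activities)
    fractions.cohort.rename_axis("signature").to_csv(outdir / "activity_fractions.tsv", sep="\t")
    return {
        "converged": result.converged,
        "n_iter": result.n_iter,
        "final_error": float(result.error_trace[-1]),
        "cohort_fractions": fractions.cohort.round(4).to_dict(),
    }


def _pick_candidate(cfg: dict, outdir: Path, signatures: SignatureSet) -> str:
    configured = cfg["compare"]["candidate"]
    if configured:
        return str(configured)
    if "UNK" in signatures.names:
        return "UNK"
    return signatures.names[-1]


def stage_compare(cfg: dict, outdir: Path, seed: int) -> dict:
    pcfg = cfg["compare"]
    catalog = cat.MutationCatalog.from_tsv(outdir / "post_catalog.tsv")
    signatures = SignatureSet.from_tsv(outdir / "signatures_discovered.tsv")
    if pcfg["replacement_signature"]:
        replacement_set = SignatureSet.from_tsv(pcfg["replacement_signature"], normalize=True)
        replacement = replacement_set.W[:, 0]
    else:
        truth = _truth_signatures(outdir)
        if truth is None or synthetic.TREATMENT not in truth.names:
            raise FileNotFoundError(
                "compare stage needs compare.replacement_signature or a simulated truth bundle"
            )
        replacement = truth[synthetic.TREATMENT]
    candidate = _pick_candidate(cfg, outdir, signatures)
    refit_config = _refit_config(cfg, seed)
    sub = cmp.substitute_and_correlate(catalog, signatures, candidate, replacement, refit_config)
    panel = None
    if pcfg["method"] == "reference_combination":
        truth = _truth_signatures(outdir)
        bg = [n for n in truth.names if n != synthetic.TREATMENT] if truth else []
        if len(bg) >= 2:
            panel = SignatureSet(truth.channels, bg, np.column_stack([truth[n] for n in bg]))
    null = cmp.permutation_null(
        catalog, signatures, candidate, replacement,
        method=pcfg["method"], n=int(pcfg["n"]), reference_panel=panel,
        seed=seed, refit_config=refit_config, observed=sub.pearson_r,
    )
    null.to_files(outdir / "null_values.tsv", outdir / "null_summary.json")
    return {
        "candidate": candidate,
        "pearson_r": sub.pearson_r,
        "unstable": sub.unstable,
        "method": null.method,
        "n": null.n,
        "empirical_p": null.empirical_p,
    }


def stage_strandbias(cfg: dict, outdir: Path, seed: int) -> dict:
    scfg = cfg["strandbias"]
    po_stranded = outdir / "post_only_stranded_catalog.tsv"
    path = po_stranded if po_stranded.exists() else outdir / "post_stranded_catalog.tsv"
    if not path.exists():
        return {"skipped": "no stranded catalog (mutation tables lack strand labels)"}
    catalog = cat.MutationCatalog.from_tsv(path)
    signatures = activities = None
    rank = int(scfg["rank"])
    if 1 <= rank < min(len(catalog.samples), 192):
        disc = nmf.discover_signatures(
            catalog, rank=rank, n_runs=int(scfg["n_runs"]), seed=seed,
            max_iter=int(scfg["max_iter"]),
        )
        signatures, activities = disc.signatures, disc.activities
        signatures.to_tsv(outdir / "signatures_stranded.tsv")
    table = strand_bias.stranded_signature_bias(signatures, activities, catalog)
    table.to_csv(outdir / "strand_bias.tsv", sep="\t", index=False)
    raw = table[table["signature"] == "(all)"]
    return {
        "catalog": path.name,
        "class_p_values": dict(zip(raw["snv_class"], raw["p_value"])),
    }


def stage_attribute(cfg: dict, outdir: Path) -> dict:
    classified = cat.read_mutation_table(outdir / "classified.tsv")
    post = classified[classified["sample"].str.endswith("_post")].copy()
    signatures = SignatureSet.from_tsv(outdir / "signatures_discovered.tsv")
    activities = nmf.ActivityMatrix.from_tsv(outdir / "activities_post.tsv")
    annotated = cat.assign_channels(post)
    if "clonality" not in annotated.columns:
        from .attribution import clonality_from_ccf

        annotated["clonality"] = clonality_from_ccf(annotated["ccf"].to_numpy())
    result = aggregate_attributions(annotated, signatures, activities)
    result.table.to_csv(outdir / "attribution.tsv", sep="\t", index=False)
    test = subclonal_enrichment_test(result.table)
    summary = {
        "overall_subclonal_fraction": result.overall_subclonal_fraction,
        "subclonal_fraction": dict(zip(result.table["signature"],
                                       result.table["subclonal_fraction"].round(4))),
        "chi2": test.statistic,
        "df": test.df,
        "p_value": test.p_value,
        "n_attributed": result.n_attributed,
    }
    (outdir / "attribution_test.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def stage_heterogeneity(cfg: dict, outdir: Path) -> dict:
    hcfg = cfg["heterogeneity"]
    classified = cat.read_mutation_table(outdir / "classified.tsv")
    if "clonality" not in classified.columns:
        from .attribution import clonality_from_ccf

        classified["clonality"] = clonality_from_ccf(classified["ccf"].to_numpy())
    truth_path = outdir / "cohort" / "truth.json"
    subclone_map: dict[str, list[het.Subclone]] = {}
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        for patient, subs in truth.get("subclones", {}).items():
            subclone_map[patient] = [
                het.Subclone(s["id"], s["pre_ccf"], s["post_ccf"], s.get("n_mutations", 0))
                for s in subs
            ]
    metrics = []
    pre_loads, post_loads = [], []
    patients = sorted(classified["patient"].unique())
    for patient in patients:
        rows = classified[classified["patient"] == patient]
        pre_rows = rows[rows["sample"].str.endswith("_pre")]
        post_rows = rows[rows["sample"].str.endswith("_post")]
        metrics.append(het.heterogeneity_metrics(
            patient, pre_rows["clonality"], post_rows["clonality"],
            subclone_map.get(patient, []),
            prop_cutoff=float(hcfg["prop_cutoff"]),
            subclone_cutoff=int(hcfg["subclone_cutoff"]),
        ))
        powered_pre = pre_rows[pre_rows["timing"] != "unpowered"]
        powered_post = post_rows[post_rows["timing"] != "unpowered"]
        pre_loads.append(len(powered_pre))
        post_loads.append(len(powered_post))
    table = het.build_covariate_table(metrics)
    table.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    loads = het.compare_loads(pre_loads, post_loads)
    summary = {
        "n_patients": len(patients),
        "mean_load_change": loads.mean_change,
        "paired_t_p": loads.t_p_value,
        "mean_prop_subclonal_pre": float(np.nanmean(table["prop_subclonal_pre"])),
        "mean_prop_subclonal_post": float(np.nanmean(table["prop_subclonal_post"])),
        "mean_n_subclones": float(table["n_subclones"].mean()),
    }
    (outdir / "loads.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def run_pipeline(config: dict | None, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the enabled stages in order and write ``report.json``.

    A stage failure raises (the CLI maps this to a nonzero exit) after
    the partial report is written with the failing stage named.
    """
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_val = int(cfg["seed"])
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": seed_val, "stages": {}}
    runners = {
        "simulate": lambda: stage_simulate(cfg, outdir, seed_val),
        "catalog": lambda: stage_catalog(cfg, outdir),
        "discover": lambda: stage_discover(cfg, outdir, seed_val + 1),
        "refit": lambda: stage_refit(cfg, outdir, seed_val + 2),
        "compare": lambda: stage_compare(cfg, outdir, seed_val + 3),
        "strandbias": lambda: stage_strandbias(cfg, outdir, seed_val + 4),
        "attribute": lambda: stage_attribute(cfg, outdir),
        "heterogeneity": lambda: stage_heterogeneity(cfg, outdir),
    }
    for stage in STAGES:
        if stage not in cfg["stages"]:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: starting (seed=%d)", stage, seed_val)
        try:
            summary = runners[stage]()
        except Exception:
            report["failed_stage"] = stage
            (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
            logger.exception("stage %s failed; partial report written", stage)
            raise
        summary["runtime_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = summary
        logger.info("stage %s: done in %.2fs", stage, summary["runtime_s"])
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
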