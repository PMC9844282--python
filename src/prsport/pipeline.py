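"""End-to-end orchestration: QC -> structure -> clump/score -> evaluate.

A single flat config (YAML-compatible dict, one section per stage) carries
every threshold under a named key so the defaults are self-documenting.
The run produces a manifest (config hash, per-stage row counts, seeds,
version) and one evaluation report per requested analysis.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clumping, cohort, evaluate, simulate, structure, sumstats

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "sumstats_qc": {"info_min": 0.8, "maf_min": 0.01},
    "cohort_qc": {"info_min": 0.9, "het_sd_mult": 3.0, "rel_cutoff": 0.125},
    "structure": {"window_kb": 250.0, "step_variants": 1, "r2_max": 0.1, "n_pcs": 6},
    "clump_score": {"p_max": 5e-4, "window_kb": 250.0, "r2": 0.1, "mode": "average"},
    "evaluate": {"tails": 0.05, "dichotomize": None},
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the offending stage's name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list = field(default_factory=list)

    def add(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: re-raise any error with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: dict | str | Path) -> tuple[RunManifest, dict[str, evaluate.EvalReport], dict]:
    """Execute every stage in order on simulated or file-based inputs.

    Returns the manifest, a dict of named EvalReports, and an artifacts dict
    (scores, PCs, clump set, QC'd genotypes) for callers that want to write
    or inspect intermediates.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = merge_config(config)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(config_hash=config_hash(cfg), seed=seed, version=__version__)
    artifacts: dict = {}

    # ---- inputs -----------------------------------------------------------
    with _stage("inputs"):
        if "simulate" in cfg and cfg["simulate"]:
            sim_kwargs = dict(cfg["simulate"])
            sim_kwargs.setdefault("seed", seed)
            if "maf_range" in sim_kwargs:
                sim_kwargs["maf_range"] = tuple(sim_kwargs["maf_range"])
            if "thresholds" in sim_kwargs:
                sim_kwargs["thresholds"] = tuple(sim_kwargs["thresholds"])
            if "info_range" in sim_kwargs:
                sim_kwargs["info_range"] = tuple(sim_kwargs["info_range"])
            sim_config = simulate.SimConfig(**sim_kwargs)
            exp = simulate.make_portability_experiment(sim_config)
            records = simulate.sumstats_frame_to_records(exp.sumstats)
            geno = exp.target_geno
            pheno_raw = exp.target_pheno
            trait = sim_config.trait
            artifacts["experiment"] = exp
        else:
            inputs = cfg["inputs"]
            records, row_errors = sumstats.read_sumstats(
                inputs["sumstats"], column_map=inputs.get("column_map")
            )
            from . import io as prs_io

            if "geno_vcf" in inputs:
                geno = prs_io.read_vcf(inputs["geno_vcf"])
            else:
                geno = prs_io.read_dosage_tsv(inputs["geno_dosages"], inputs["geno_variants"])
            pheno_raw = pd.read_csv(inputs["pheno"], sep="\t", dtype={"sample": str})
            trait = inputs.get("trait", "trait")
        manifest.add(
            "inputs",
            n_sumstats=len(records),
            n_samples=geno.n_samples,
            n_variants=geno.n_variants,
        )

    # ---- discovery-side sumstats QC --------------------------------------
    with _stage("sumstats_qc"):
        sq = cfg["sumstats_qc"]
        kept, excl = sumstats.filter_sumstats(
            records, info_min=sq["info_min"], maf_min=sq["maf_min"]
        )
        manifest.add("sumstats_qc", n_kept=len(kept), excluded=excl)

    # ---- target cohort QC -------------------------------------------------
    with _stage("cohort_qc"):
        cq = cfg["cohort_qc"]
        geno = cohort.filter_variants_target(geno, info_min=cq["info_min"])
        geno, qc_report = cohort.sample_qc(
            geno, sd_mult=cq["het_sd_mult"], rel_cut=cq["rel_cutoff"]
        )
        artifacts["sample_qc"] = qc_report
        manifest.add(
            "cohort_qc",
            n_samples=geno.n_samples,
            n_variants=geno.n_variants,
            n_removed=int((~qc_report.kept).sum()),
        )

    # ---- structure covariates --------------------------------------------
    with _stage("structure"):
        st = cfg["structure"]
        pruned = structure.ld_prune(
            geno,
            window_kb=st["window_kb"],
            step_variants=st["step_variants"],
            r2_max=st["r2_max"],
        )
        pcs = structure.pca(geno, variant_idx=pruned, k=st["n_pcs"])
        artifacts["pcs"] = pcs
        manifest.add("structure", n_pruned=len(pruned), n_pcs=pcs.scores.shape[1])

    # ---- clump + score ----------------------------------------------------
    with _stage("clump_score"):
        cs = cfg["clump_score"]
        target_vars = [
            (c, p, ca, oa)
            for c, p, ca, oa in zip(
                geno.variants["chrom"].astype(str),
                geno.variants["pos"].astype(int),
                geno.variants["counted_allele"],
                geno.variants["other_allele"],
            )
        ]
        weights, n_mismatch = sumstats.harmonize_weights(kept, target_vars)
        clump_set = clumping.clump(
            kept, geno, p_max=cs["p_max"], window_kb=cs["window_kb"], r2=cs["r2"]
        )
        if len(clump_set) == 0:
            raise PipelineError("clump_score", "no eligible variants")
        index_keys = set(clump_set.index_keys())
        index_weights = [w for w in weights if (w.chrom, w.pos) in index_keys]
        scores = clumping.compute_prs(geno, index_weights, mode=cs["mode"])
        artifacts["clump_set"] = clump_set
        artifacts["scores"] = scores
        manifest.add(
            "clump_score",
            n_indices=len(clump_set),
            n_score_variants=scores.n_variants,
            n_allele_mismatch=n_mismatch,
        )

    # ---- evaluation -------------------------------------------------------
    with _stage("evaluate"):
        ev = cfg["evaluate"]
        pheno, prep_counts = evaluate.prepare_phenotypes(
            pheno_raw, seed=seed, trait_cols=tuple(
                c for c in pheno_raw.columns if c not in ("sample", "age", "sex")
            ),
        )
        merged = pheno.merge(scores.to_frame(), on="sample").merge(
            pcs.to_frame(), on="sample"
        )
        pc_cols = [c for c in merged.columns if c.startswith("PC")]
        covars = merged[["age", "sex"] + pc_cols]
        prs = merged["score_avg"].to_numpy()

        reports: dict[str, evaluate.EvalReport] = {}
        reports["linear"] = evaluate.linear_incremental_r2(
            merged[trait].to_numpy(), prs, covars
        )
        rule = ev.get("dichotomize")
        if rule:
            dich_col = ev.get("dichotomize_column", trait)
            labels, _ = evaluate.dichotomize(merged[dich_col].to_numpy(), rule)
            if np.isfinite(labels).sum() and len(np.unique(labels[np.isfinite(labels)])) == 2:
                reports["logistic"] = evaluate.logistic_pseudo_r2(labels, prs, covars)
                reports["group"] = evaluate.group_prs_compare(prs, labels)
        reports["tail"] = evaluate.tail_contrast(prs, merged[trait].to_numpy(), q=ev["tails"])
        manifest.add("evaluate", n=int(len(merged)), prep_counts=prep_counts)

    artifacts["geno"] = geno
    return manifest, reports, artifacts


def write_run_outputs(
    manifest: RunManifest,
    reports: dict[str, evaluate.EvalReport],
    artifacts: dict,
    outdir: str | Path,
) -> None:
    """Write the manifest, reports and tabular intermediates to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    report_dict = {name: rep.to_dict() for name, rep in reports.items()}
    (outdir / "reports.json").write_text(
        json.dumps(report_dict, indent=2, sort_keys=True) + "\n"
    )
    if "scores" in artifacts:
        artifacts["scores"].to_frame().to_csv(outdir / "scores.tsv", sep="\t", index=False)
    if "pcs" in artifacts:
        artifacts["pcs"].to_frame().to_csv(outdir / "pcs.tsv", sep="\t", index=False)
    if "clump_set" in artifacts:
        artifacts["clump_set"].to_frame().to_csv(outdir / "clumps.tsv", sep="\t", index=False)
    if "sample_qc" in artifacts:
        artifacts["sample_qc"].to_frame().to_csv(outdir / "sample_qc.tsv", sep="\t", index=False)
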