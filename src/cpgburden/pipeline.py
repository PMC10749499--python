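"""End-to-end orchestration: classify-variants -> pca -> burden -> twohit ->
classify-genes -> tscore on a directory of compliant inputs.

A :class:`RunConfig` (YAML-loadable) names the input files, thresholds and
seed; :func:`run_all` executes the configured stages, writes each stage's
TSV artifacts with a provenance header (tool version + config hash) and a
``manifest.json`` recording versions, seed, thresholds and input checksums.
Stages whose inputs are absent are skipped; any stage error halts the run
with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as cio
from .burden import GeneSetDefinition, run_burden, single_cancer_run
from .cpgclass import classify_genes, label_clusters
from .popstruct import compute_pcs, select_common_variants
from .tscore import compute_ts, resample_null
from .twohit import call_loh, run_twohit
from .varfilter import build_carrier_matrix, classify_variants

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = f"E_{stage.upper().replace('-', '_')}"


@dataclass
class RunConfig:
    """Paths, thresholds and analysis list for one pipeline run."""

    out_dir: str
    samples: str | None = None
    variants_vcf: str | None = None
    variants_tsv: str | None = None
    carriers: str | None = None
    common_vcf: str | None = None
    minor_cn: str | None = None
    features: str | None = None
    expr_observed: str | None = None
    expr_comparison: str | None = None
    panel: str | None = None
    gene_sets_gmt: str | None = None

    maf_threshold: float = 0.005
    cohort_threshold: float = 0.01
    spliceai_threshold: float = 0.8
    class_mode: str = "union"
    pca_k: int = 4
    fdr_alpha: float = 0.20
    cluster_k: int = 4
    ts_subsample: int = 45
    ts_resamples: int = 1000
    analyses: list[str] = field(default_factory=lambda: ["pan_cancer"])
    majority_population: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.maf_threshold < 0 or self.cohort_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        for attr in (
            "samples",
            "variants_vcf",
            "variants_tsv",
            "carriers",
            "common_vcf",
            "minor_cn",
            "features",
            "expr_observed",
            "expr_comparison",
            "panel",
            "gene_sets_gmt",
        ):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")


def _checksum(path: str | Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _results_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        d = asdict(r)
        d["log2_or"] = r.log2_or
        rows.append(d)
    return pd.DataFrame(rows).set_index("gene_id")


def run_all(config: RunConfig, dry_run: bool = False) -> Path:
    """Execute the configured stages; returns the output directory."""
    config.validate()
    if dry_run:
        logger.info("dry run: config valid")
        return Path(config.out_dir)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # Hash the analysis settings, not the output location.
    chash = cio.config_hash({k: v for k, v in sorted(asdict(config).items()) if k != "out_dir"})
    header = cio.provenance_header(chash)
    manifest: dict = {
        "tool": "cpgburden",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "stages": [],
    }
    for attr in ("samples", "variants_vcf", "variants_tsv", "carriers", "common_vcf", "minor_cn", "features"):
        p = getattr(config, attr)
        if p is not None:
            manifest["inputs"][attr] = {"path": str(p), "sha1": _checksum(p)}

    samples = cio.read_samples_tsv(config.samples) if config.samples else None

    # Stage: classify-variants
    carriers = None
    if config.carriers:
        carriers = cio.read_carriers_tsv(config.carriers, class_mode=config.class_mode)
    elif config.variants_vcf or config.variants_tsv:
        try:
            if config.variants_vcf:
                variants, genotype_map, vcf_samples = cio.read_variants_vcf(config.variants_vcf)
            else:
                variants = cio.read_variants_tsv(config.variants_tsv)
                genotype_map, vcf_samples = {}, []
            calls = classify_variants(
                variants,
                maf_threshold=config.maf_threshold,
                cohort_threshold=config.cohort_threshold,
                spliceai_threshold=config.spliceai_threshold,
            )
            sample_ids = list(samples.index) if samples is not None else vcf_samples
            carriers = build_carrier_matrix(calls, genotype_map, sample_ids, class_mode=config.class_mode)
            calls_df = pd.DataFrame(
                {
                    "variant_id": [c.variant.variant_id for c in calls],
                    "gene_id": [c.variant.gene_id for c in calls],
                    "class_flags": ["|".join(sorted(c.class_flags)) for c in calls],
                }
            )
            with open(out / "pathogenic_calls.tsv", "w") as fh:
                fh.write(header)
                calls_df.to_csv(fh, sep="\t", index=False)
            cio.write_carriers_tsv(carriers, out / "carriers.tsv", header)
            manifest["stages"].append("classify-variants")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("classify-variants", str(exc)) from exc

    # Stage: pca
    pcs = None
    if config.common_vcf:
        try:
            dosages = cio.read_common_vcf(config.common_vcf)
            groups = samples["population"] if samples is not None and "population" in samples else None
            sub = select_common_variants(pd.DataFrame(index=dosages.columns), dosages, groups=groups)
            pcs = compute_pcs(sub, k=config.pca_k)
            with open(out / "pcs.tsv", "w") as fh:
                fh.write(header)
                pcs.scores.to_csv(fh, sep="\t")
            pd.DataFrame({"variance_explained": pcs.variance_explained}).to_csv(
                out / "pca_variance.tsv", sep="\t"
            )
            manifest["stages"].append("pca")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("pca", str(exc)) from exc

    # Stage: burden
    if carriers is not None and samples is not None:
        try:
            case_status = (samples["cohort"] == "case").astype(int)
            for analysis in config.analyses:
                if analysis == "pan_cancer":
                    results = run_burden(carriers, case_status, pcs, analysis="pan_cancer", alpha=config.fdr_alpha)
                    name = "burden_results.tsv"
                else:
                    majority = config.majority_population.get(analysis)
                    if majority is None:
                        counts = samples.loc[
                            (samples["cohort"] == "case") & (samples["cancer_type"] == analysis), "population"
                        ].value_counts()
                        if counts.empty:
                            raise ValueError(f"no cases of cancer type {analysis!r}")
                        majority = counts.idxmax()
                    results, _meta = single_cancer_run(
                        carriers, samples, analysis, majority, pcs, alpha=config.fdr_alpha
                    )
                    name = f"burden_results_{analysis}.tsv"
                with open(out / name, "w") as fh:
                    fh.write(header)
                    _results_frame(results).to_csv(fh, sep="\t")
            manifest["stages"].append("burden")
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("burden", str(exc)) from exc

    # Stage: twohit (cancer samples only; cancer-only PCA)
    if config.minor_cn and carriers is not None and samples is not None:
        try:
            minor_cn = cio.read_gene_table(config.minor_cn)
            loh = call_loh(minor_cn)
            case_ids = [s for s in carriers.samples if samples.loc[s, "cohort"] == "case"]
            from .varfilter import CarrierMatrix

            case_carriers = CarrierMatrix(
                carriers.data.loc[loh.genes, case_ids], class_mode=carriers.class_mode
            )
            cancer_pcs = None
            if config.common_vcf:
                dosages = cio.read_common_vcf(config.common_vcf).loc[case_ids]
                groups = samples.loc[case_ids, "population"] if "population" in samples else None
                sub = select_common_variants(pd.DataFrame(index=dosages.columns), dosages, groups=groups)
                cancer_pcs = compute_pcs(sub, k=config.pca_k)
            results = run_twohit(case_carriers, loh, cancer_pcs, alpha=config.fdr_alpha)
            with open(out / "twohit_results.tsv", "w") as fh:
                fh.write(header)
                _results_frame(results).to_csv(fh, sep="\t")
            manifest["stages"].append("twohit")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("twohit", str(exc)) from exc

    # Stage: classify-genes
    if config.features:
        try:
            features = cio.read_gene_table(config.features)
            assignment = classify_genes(features, k=config.cluster_k, seed=config.seed)
            if config.cluster_k == 4:
                assignment = label_clusters(assignment, features)
            with open(out / "clusters.tsv", "w") as fh:
                fh.write(header)
                assignment.assignments.to_csv(fh, sep="\t")
            manifest["stages"].append("classify-genes")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("classify-genes", str(exc)) from exc

    # Stage: tscore
    if config.expr_observed and config.expr_comparison:
        try:
            obs = cio.read_gene_table(config.expr_observed)
            comp = cio.read_gene_table(config.expr_comparison)
            if config.panel:
                panel = [line.strip() for line in open(config.panel) if line.strip()]
                obs, comp = obs.loc[panel], comp.loc[panel]
            ts = compute_ts(obs)
            res = resample_null(
                comp,
                ts,
                subsample_size=config.ts_subsample,
                n_resample=config.ts_resamples,
                seed=config.seed,
            )
            summary = pd.DataFrame(
                {
                    "observed_ts": [res.observed_ts],
                    "null_mean": [res.null_mean],
                    "null_sd": [res.null_sd],
                    "empirical_p": [res.empirical_p],
                    "n_resample": [res.n_resample],
                    "subsample_size": [res.subsample_size],
                }
            )
            with open(out / "ts_result.tsv", "w") as fh:
                fh.write(header)
                summary.to_csv(fh, sep="\t", index=False)
            np.savetxt(out / "ts_null_values.tsv", res.null_values, fmt="%.6f")
            manifest["stages"].append("tscore")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("tscore", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
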