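"""Seeded synthetic case-control cohorts with known ground truth.

Every downstream stage (variant filtering, PC adjustment, burden testing,
two-hit analysis, gene classification, transcriptional score) is exercised
on cohorts generated here, so each planted parameter is recoverable and
each null is calibrated by construction:

* Population structure follows the Balding-Nichols model: each common
  variant has an ancestral frequency uniform on [0.05, 0.5] and per-
  subpopulation frequencies drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) at the
  configured divergence F (Fst); genotypes are Binomial(2, freq) dosages.
* Per-gene carrier status follows a logistic model
  logit P(carrier) = alpha_g + beta_g * I(case) + gamma_pop, with
  beta_g = planted_log2_or * ln 2, so the burden test's estimand equals the
  planted log2 odds ratio. Carrier status is simulated directly at the gene
  level and each carrier receives one qualifying truncating variant —
  collapsing makes this equivalent to variant-by-variant simulation.
* Tumor LOH (case samples only) follows logit P(minor CN = 0) =
  a_g + d_g * I(carrier), the two-hit coupling the LOH test estimates.
* Gene features (two-hit log2 OR, TAU, LOEUF) are drawn from planted
  Gaussian clusters; panel expression per group is multivariate normal with
  constant within-panel correlation rho.

One integer seed drives everything; each simulator stage derives an
independent deterministic stream from it, so identical config + seed gives
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .varfilter import CarrierMatrix, Consequence, VariantRecord

__all__ = [
    "Population",
    "GeneSpec",
    "TwoHitSpec",
    "FeatureCluster",
    "ExpressionSpec",
    "SimConfig",
    "CohortData",
    "simulate_cohort",
    "simulate_loh",
    "simulate_features_and_expression",
    "write_fixture",
]

_LN2 = np.log(2.0)

# Stream indices: each stage draws from SeedSequence([seed, index]).
_STREAM_SAMPLES = 0
_STREAM_COMMON = 1
_STREAM_CARRIERS = 2
_STREAM_LOH = 3
_STREAM_FEATURES = 4
_STREAM_EXPRESSION = 5


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class Population:
    """One discrete subpopulation with cohort proportions and divergence."""

    label: str
    case_frac: float
    control_frac: float
    fst: float = 0.0


@dataclass(frozen=True)
class GeneSpec:
    """One gene's carrier model.

    ``log2_or`` is the planted case-vs-control effect; ``population_offsets``
    shift the carrier log-odds per population (confounding when paired with
    biased cohort composition); ``cancer_type`` restricts the effect to
    cases of that type.
    """

    gene_id: str
    baseline_carrier_freq: float
    log2_or: float = 0.0
    population_offsets: Mapping[str, float] = field(default_factory=dict)
    cancer_type: str | None = None


@dataclass(frozen=True)
class TwoHitSpec:
    """LOH model for one gene: baseline LOH probability and the planted
    log2 odds ratio of LOH given germline carriage."""

    baseline_loh_prob: float
    loh_log2_or: float = 0.0


@dataclass(frozen=True)
class FeatureCluster:
    """Gaussian feature cluster for the gene-classification stage."""

    cluster_id: int
    n_genes: int
    twohit_mean: float
    tau_mean: float
    loeuf_mean: float
    twohit_sd: float = 0.3
    tau_sd: float = 0.05
    loeuf_sd: float = 0.1


@dataclass(frozen=True)
class ExpressionSpec:
    """Panel expression: per-group sample sizes and within-panel correlation."""

    panel_genes: tuple[str, ...]
    n_samples: Mapping[str, int]
    rho: Mapping[str, float]
    noise_sd: float = 1.0


@dataclass
class SimConfig:
    """Full study-condition description for one synthetic experiment."""

    n_cases: int
    n_controls: int
    populations: list[Population] = field(
        default_factory=lambda: [Population("POP1", 1.0, 1.0, 0.0)]
    )
    n_common_variants: int = 0
    genes: list[GeneSpec] = field(default_factory=list)
    twohit_genes: dict[str, TwoHitSpec] = field(default_factory=dict)
    feature_clusters: list[FeatureCluster] = field(default_factory=list)
    expression: ExpressionSpec | None = None
    cancer_types: dict[str, float] = field(default_factory=lambda: {"Pan": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample counts must be positive")
        if not self.populations:
            raise ValueError("at least one population required")
        for attr in ("case_frac", "control_frac"):
            total = sum(getattr(p, attr) for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"population {attr} must sum to 1, got {total}")
            if any(getattr(p, attr) < 0 for p in self.populations):
                raise ValueError("population proportions must be non-negative")
        for p in self.populations:
            if not 0.0 <= p.fst <= 1.0:
                raise ValueError(f"Fst must be in [0, 1], got {p.fst} for {p.label}")
        for g in self.genes:
            if not 0.0 < g.baseline_carrier_freq < 1.0:
                raise ValueError(f"baseline_carrier_freq must be in (0, 1) for {g.gene_id}")
        for gid, th in self.twohit_genes.items():
            if not 0.0 <= th.baseline_loh_prob < 1.0:
                raise ValueError(f"baseline_loh_prob out of [0, 1) for {gid}")
        if self.expression is not None:
            for group, rho in self.expression.rho.items():
                if not -1.0 <= rho <= 1.0:
                    raise ValueError(f"rho must be in [-1, 1], got {rho} for group {group}")
        if abs(sum(self.cancer_types.values()) - 1.0) > 1e-9:
            raise ValueError("cancer_type proportions must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class CohortData:
    """Everything :func:`simulate_cohort` produces."""

    samples: pd.DataFrame  # sample_id index; cohort, cancer_type, population, sex
    common_genotypes: pd.DataFrame  # samples x variants dosages
    common_variant_info: pd.DataFrame  # variant annotation for the PCA filter
    carriers: CarrierMatrix
    variants: list[VariantRecord]
    genotypes: dict[str, list[str]]  # variant id -> carrier sample ids
    truth: pd.DataFrame  # planted per-gene parameters


def _allocate(n: int, labels: Sequence[str], fracs: Sequence[float]) -> list[str]:
    """Largest-remainder allocation: exact counts, deterministic order."""
    raw = np.asarray(fracs, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in order[:short]:
        counts[i] += 1
    out = []
    for label, c in zip(labels, counts):
        out.extend([label] * int(c))
    return out


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate samples, common genotypes, carrier matrix and variants."""
    n = config.n_cases + config.n_controls
    sample_ids = [f"case_{i + 1:05d}" for i in range(config.n_cases)] + [
        f"control_{i + 1:05d}" for i in range(config.n_controls)
    ]
    cohort = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)

    pop_labels = [p.label for p in config.populations]
    pops = _allocate(config.n_cases, pop_labels, [p.case_frac for p in config.populations])
    pops += _allocate(config.n_controls, pop_labels, [p.control_frac for p in config.populations])
    pops = np.array(pops)

    ct_labels = list(config.cancer_types)
    cancer = _allocate(config.n_cases, ct_labels, list(config.cancer_types.values()))
    cancer = np.array(cancer + ["none"] * config.n_controls)

    rng_s = config.rng(_STREAM_SAMPLES)
    sex = rng_s.choice(["M", "F"], size=n)

    samples = pd.DataFrame(
        {"cohort": cohort, "cancer_type": cancer, "population": pops, "sex": sex},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # Common variants under Balding-Nichols.
    rng_c = config.rng(_STREAM_COMMON)
    m = config.n_common_variants
    geno = np.zeros((n, m), dtype=float)
    var_ids = [f"cv{j + 1:05d}" for j in range(m)]
    if m:
        p_anc = rng_c.uniform(0.05, 0.5, size=m)
        for pop in config.populations:
            mask = pops == pop.label
            if not mask.any():
                continue
            if pop.fst > 0:
                a = p_anc * (1.0 - pop.fst) / pop.fst
                b = (1.0 - p_anc) * (1.0 - pop.fst) / pop.fst
                p_pop = rng_c.beta(a, b)
            else:
                p_pop = p_anc
            geno[mask] = rng_c.binomial(2, np.clip(p_pop, 1e-6, 1 - 1e-6), size=(int(mask.sum()), m))
    common = pd.DataFrame(geno, index=samples.index, columns=var_ids)
    common_info = pd.DataFrame({"consequence": "missense"}, index=pd.Index(var_ids, name="variant_id"))

    # Gene-level carrier status under the planted logistic model.
    rng_g = config.rng(_STREAM_CARRIERS)
    is_case = (cohort == "case").astype(float)
    carrier_rows = {}
    variants: list[VariantRecord] = []
    genotype_map: dict[str, list[str]] = {}
    truth_rows = []
    for i, gene in enumerate(config.genes):
        beta = gene.log2_or * _LN2
        effect_on = is_case.copy()
        if gene.cancer_type is not None:
            effect_on = ((cohort == "case") & (cancer == gene.cancer_type)).astype(float)
        eta = _logit(gene.baseline_carrier_freq) + beta * effect_on
        if gene.population_offsets:
            offsets = np.array([gene.population_offsets.get(p, 0.0) for p in pops])
            eta = eta + offsets
        carrier = rng_g.random(n) < _sigmoid(eta)
        carrier_rows[gene.gene_id] = carrier

        v = VariantRecord(
            chrom="1",
            pos=1000 + i,
            ref="G",
            alt="T",
            gene_id=gene.gene_id,
            consequence=Consequence.STOP_GAIN,
        )
        variants.append(v)
        genotype_map[v.variant_id] = [s for s, c in zip(sample_ids, carrier) if c]
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "baseline_carrier_freq": gene.baseline_carrier_freq,
                "log2_or": gene.log2_or,
                "cancer_type": gene.cancer_type or "",
            }
        )

    carrier_df = pd.DataFrame(carrier_rows, index=samples.index).T
    carrier_df.index.name = "gene_id"
    carriers = CarrierMatrix(data=carrier_df, class_mode="union")
    truth = pd.DataFrame(truth_rows).set_index("gene_id") if truth_rows else pd.DataFrame()

    return CohortData(
        samples=samples,
        common_genotypes=common,
        common_variant_info=common_info,
        carriers=carriers,
        variants=variants,
        genotypes=genotype_map,
        truth=truth,
    )


def simulate_loh(
    config: SimConfig, carriers: CarrierMatrix, samples: pd.DataFrame
) -> pd.DataFrame:
    """Gene x sample minor-copy-number table for case samples.

    For each configured two-hit gene, P(minor CN = 0) follows
    logit = a_g + d_g * I(carrier) with a_g = logit(baseline_loh_prob) and
    d_g = loh_log2_or * ln 2. Samples without LOH get minor CN 1 or 2.
    Only tumors have copy-number states, so controls are absent entirely.
    """
    rng = config.rng(_STREAM_LOH)
    case_ids = [s for s in carriers.samples if samples.loc[s, "cohort"] == "case"]
    rows = {}
    for gene_id, spec in config.twohit_genes.items():
        if gene_id not in carriers.data.index:
            raise KeyError(f"two-hit gene {gene_id!r} absent from carrier matrix")
        carrier = carriers.data.loc[gene_id, case_ids].to_numpy(dtype=float)
        if spec.baseline_loh_prob == 0.0:
            loh = np.zeros(len(case_ids), dtype=bool)
        else:
            eta = _logit(spec.baseline_loh_prob) + spec.loh_log2_or * _LN2 * carrier
            loh = rng.random(len(case_ids)) < _sigmoid(eta)
        minor = np.where(loh, 0, rng.choice([1, 2], size=len(case_ids), p=[0.8, 0.2]))
        rows[gene_id] = minor
    out = pd.DataFrame(rows, index=pd.Index(case_ids, name="sample_id")).T
    out.index.name = "gene_id"
    return out


def simulate_features_and_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Planted feature clusters and block-correlated panel expression.

    Features: per cluster, (two-hit log2 OR, TAU, LOEUF) drawn from
    independent Gaussians; TAU clipped to [0, 1], LOEUF clipped positive.
    Expression: per group, a genes x samples matrix from a multivariate
    normal with constant within-panel correlation rho (valid range
    [-1/(p-1), 1]; rho = 1 yields a rank-one, perfectly correlated panel).
    """
    rng = config.rng(_STREAM_FEATURES)
    rows = []
    gene_counter = 0
    for cl in config.feature_clusters:
        for _ in range(cl.n_genes):
            gene_counter += 1
            rows.append(
                {
                    "gene_id": f"FG{gene_counter:04d}",
                    "twohit_log2or": rng.normal(cl.twohit_mean, cl.twohit_sd),
                    "tau": float(np.clip(rng.normal(cl.tau_mean, cl.tau_sd), 0.0, 1.0)),
                    "loeuf": float(max(rng.normal(cl.loeuf_mean, cl.loeuf_sd), 1e-3)),
                    "true_cluster": cl.cluster_id,
                }
            )
    features = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()

    expr: dict[str, pd.DataFrame] = {}
    if config.expression is not None:
        spec = config.expression
        p = len(spec.panel_genes)
        if p < 2:
            raise ValueError("expression panel needs >= 2 genes")
        rng_e = config.rng(_STREAM_EXPRESSION)
        for group, n_s in spec.n_samples.items():
            rho = float(spec.rho.get(group, 0.0))
            if rho < -1.0 / (p - 1) - 1e-12:
                raise ValueError(
                    f"rho={rho} makes the {p}-gene equicorrelation matrix indefinite"
                )
            cov = spec.noise_sd**2 * ((1.0 - rho) * np.eye(p) + rho * np.ones((p, p)))
            X = rng_e.multivariate_normal(np.zeros(p), cov, size=n_s, method="eigh").T
            expr[group] = pd.DataFrame(
                X, index=pd.Index(spec.panel_genes, name="gene_id"),
                columns=[f"{group}_{i + 1:04d}" for i in range(n_s)],
            )
    return features, expr


def write_fixture(
    out_dir: str | Path,
    cohort: CohortData | None = None,
    minor_cn: pd.DataFrame | None = None,
    features: pd.DataFrame | None = None,
    expr: Mapping[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write simulator outputs as the on-disk dialects the CLI consumes.

    Emits (when available): samples.tsv, common.vcf, variants.tsv,
    variants.vcf, carriers.tsv, truth.tsv, minor_cn.tsv, features.tsv and
    expr_<group>.tsv. Returns the written paths. Round-trips losslessly
    through the readers in :mod:`cpgburden.io`.
    """
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if cohort is not None:
        written["samples"] = cio.write_samples_tsv(cohort.samples, out / "samples.tsv")
        written["carriers"] = cio.write_carriers_tsv(cohort.carriers, out / "carriers.tsv")
        written["variants_tsv"] = cio.write_variants_tsv(cohort.variants, out / "variants.tsv")
        written["variants_vcf"] = cio.write_variants_vcf(
            cohort.variants, cohort.genotypes, list(cohort.samples.index), out / "variants.vcf"
        )
        if cohort.common_genotypes.shape[1]:
            written["common_vcf"] = cio.write_common_vcf(cohort.common_genotypes, out / "common.vcf")
        if len(cohort.truth):
            written["truth"] = cio.write_gene_table(cohort.truth, out / "truth.tsv")
    if minor_cn is not None:
        written["minor_cn"] = cio.write_gene_table(minor_cn, out / "minor_cn.tsv")
    if features is not None and len(features):
        written["features"] = cio.write_gene_table(features, out / "features.tsv")
    if expr:
        for group, mat in expr.items():
            written[f"expr_{group}"] = cio.write_gene_table(mat, out / f"expr_{group}.tsv")
    return written
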