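"""Gene-level and gene-set case-control burden testing.

For each eligible gene the fraction of rare-pathogenic-variant carriers is
compared between cases and controls with a collapsing logistic regression

    logit P(case) = b0 + b1 * carrier + b2..b5 * PC1..PC4

where ``carrier`` indicates carriage of at least one qualifying variant in
the gene and the principal components adjust for population stratification.
``b1`` is the natural-log odds ratio; it is reported alongside its base-2
transform (log2 OR), the convention used for effect sizes throughout.
Multiplicity is controlled per analysis (pan-cancer, or one cancer type)
with Benjamini-Hochberg FDR at 20% by default.

Gene sets (disease classes, pathways) are tested two ways: a rank-based
summary of member-gene log2 ORs (:func:`geneset_summary`) and a pooled
regression in which the indicator is carriage in any member gene
(:func:`class_enrichment`). :func:`overlap_fisher` tests the overlap of two
significant-gene lists (e.g. pan-cancer vs single-cancer hits) with Fisher's
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._glm import _LN2, LogitFit, fit_carrier_logit
from .popstruct import PCResult
from .varfilter import CarrierMatrix

__all__ = [
    "BurdenResult",
    "GeneSetDefinition",
    "PAN_CANCER_MIN_CARRIERS",
    "SINGLE_CANCER_MIN_CARRIERS",
    "eligible_genes",
    "fit_burden",
    "run_burden",
    "adjust_fdr",
    "summarize_significance",
    "genomic_inflation",
    "geneset_summary",
    "class_enrichment",
    "single_cancer_run",
    "overlap_fisher",
]

#: Pan-cancer eligibility: at least this many total carriers.
PAN_CANCER_MIN_CARRIERS = 3

#: Per-cancer eligibility: strictly more than this many total carriers.
SINGLE_CANCER_MIN_CARRIERS = {
    "CNS-Medullo": 2,
    "Liver-HCC": 2,
    "Kidney-RCC": 3,
    "Lymph-BNHL": 3,
    "Ovary-AdenoCA": 3,
    "Panc-AdenoCA": 3,
    "Prost-AdenoCA": 3,
    "Skin-Melanoma": 3,
    "Breast-AdenoCA": 4,
}


@dataclass
class BurdenResult:
    """Per-gene burden test summary."""

    gene_id: str
    n_case_carriers: int
    n_control_carriers: int
    eligible: bool
    coef: float = np.nan  # natural-log odds ratio
    se: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan
    significant: bool = False
    converged: bool = False
    separation_flag: bool = False
    penalized: bool = False

    @property
    def log2_or(self) -> float:
        return self.coef / _LN2


@dataclass
class GeneSetDefinition:
    """A named gene set (disease class, GO term, pathway)."""

    set_id: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")


def _carrier_threshold(analysis: str, thresholds: dict | None) -> tuple[int, bool]:
    """(threshold, strict) — strict means 'more than', else 'at least'."""
    if analysis == "pan_cancer":
        t = PAN_CANCER_MIN_CARRIERS if thresholds is None else thresholds.get("pan_cancer", PAN_CANCER_MIN_CARRIERS)
        return int(t), False
    table = SINGLE_CANCER_MIN_CARRIERS if thresholds is None else {**SINGLE_CANCER_MIN_CARRIERS, **thresholds}
    if analysis not in table:
        raise KeyError(f"no carrier threshold configured for analysis {analysis!r}")
    return int(table[analysis]), True


def eligible_genes(
    carriers: CarrierMatrix,
    analysis: str = "pan_cancer",
    thresholds: dict | None = None,
) -> set[str]:
    """Genes with enough total carriers to be tested.

    Pan-cancer: at least three total carriers. Single-cancer analyses use
    strict per-type minima (more than two for CNS-Medullo and Liver-HCC, more
    than three for six other types, more than four for Breast-AdenoCA),
    overridable via ``thresholds``.
    """
    threshold, strict = _carrier_threshold(analysis, thresholds)
    totals = carriers.carrier_counts()
    keep = totals > threshold if strict else totals >= threshold
    return set(totals.index[keep])


def _aligned_pcs(pcs: PCResult | None, samples: list[str]) -> np.ndarray | None:
    if pcs is None:
        return None
    return pcs.scores.loc[samples].to_numpy()


def fit_burden(
    gene: str,
    carriers: CarrierMatrix,
    case_status: pd.Series,
    pcs: PCResult | None = None,
) -> BurdenResult:
    """Logistic burden fit for one gene.

    ``case_status`` maps sample id to 1 (case) / 0 (control). Without PCs the
    estimate equals the crude 2x2 log odds ratio (the no-covariate MLE).
    Perfect separation or non-convergence is flagged and the estimate comes
    from a Jeffreys-penalized refit.
    """
    samples = carriers.samples
    y = case_status.loc[samples].to_numpy(dtype=float)
    x = carriers.data.loc[gene].to_numpy(dtype=float)
    fit = fit_carrier_logit(y, x, covariates=_aligned_pcs(pcs, samples))
    return BurdenResult(
        gene_id=gene,
        n_case_carriers=int(x[y == 1].sum()),
        n_control_carriers=int(x[y == 0].sum()),
        eligible=True,
        coef=fit.coef,
        se=fit.se,
        p_value=fit.p_value,
        converged=fit.converged,
        separation_flag=fit.separation,
        penalized=fit.penalized,
    )


def adjust_fdr(results: list[BurdenResult], alpha: float = 0.20) -> list[BurdenResult]:
    """Benjamini-Hochberg step-up over eligible genes; flags q < alpha."""
    tested = [r for r in results if r.eligible and np.isfinite(r.p_value)]
    if tested:
        _, qvals, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
        for r, q in zip(tested, qvals):
            r.q_value = float(q)
            r.significant = bool(q < alpha)
    return results


def run_burden(
    carriers: CarrierMatrix,
    case_status: pd.Series,
    pcs: PCResult | None = None,
    analysis: str = "pan_cancer",
    thresholds: dict | None = None,
    alpha: float = 0.20,
) -> list[BurdenResult]:
    """Eligibility, per-gene fits and FDR control for one analysis."""
    keep = eligible_genes(carriers, analysis, thresholds)
    results = []
    for gene in carriers.genes:
        if gene in keep:
            results.append(fit_burden(gene, carriers, case_status, pcs))
        else:
            x = carriers.data.loc[gene]
            y = case_status.loc[carriers.samples]
            results.append(
                BurdenResult(
                    gene_id=gene,
                    n_case_carriers=int(x[y == 1].sum()),
                    n_control_carriers=int(x[y == 0].sum()),
                    eligible=False,
                )
            )
    return adjust_fdr(results, alpha)


def summarize_significance(results: list[BurdenResult]) -> pd.Series:
    """Count significant results among tested ones, with the percent share
    (one decimal, the convention for headline fractions)."""
    tested = [r for r in results if r.eligible and np.isfinite(r.p_value)]
    n_sig = sum(r.significant for r in tested)
    out = {"n_tested": len(tested), "n_significant": n_sig}
    if tested:
        out["pct_significant"] = round(100.0 * n_sig / len(tested), 1)
    return pd.Series(out)


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median observed 1-df chi-square statistic
    over its null median (0.4549). Values near 1 indicate calibrated tests;
    values above ~1.2 indicate confounding (e.g. population stratification)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def geneset_summary(
    results: list[BurdenResult],
    sets: list[GeneSetDefinition],
    reference: str = "complement",
    other: GeneSetDefinition | None = None,
) -> pd.DataFrame:
    """Median member log2 OR per set with a rank-based p-value.

    ``reference`` selects the comparison: ``"zero"`` (Wilcoxon signed-rank of
    member log2 ORs against zero), ``"complement"`` (rank-sum against all
    tested genes outside the set) or ``"other_set"`` (rank-sum against
    ``other``'s members). Sets with no eligible member gene are reported
    untested (NaN p).
    """
    if reference not in {"zero", "complement", "other_set"}:
        raise ValueError(f"unknown reference {reference!r}")
    by_gene = {r.gene_id: r.log2_or for r in results if r.eligible and np.isfinite(r.coef)}
    rows = []
    for s in sets:
        member = np.array([by_gene[g] for g in s.genes if g in by_gene])
        row = {"set_id": s.set_id, "n_tested": len(member), "median_log2_or": np.nan, "p_value": np.nan}
        if len(member):
            row["median_log2_or"] = float(np.median(member))
            if reference == "zero":
                nonzero = member[member != 0]
                if len(nonzero):
                    row["p_value"] = float(stats.wilcoxon(nonzero).pvalue)
            else:
                if reference == "complement":
                    ref_genes = set(by_gene) - set(s.genes)
                    ref = np.array([by_gene[g] for g in ref_genes])
                else:
                    if other is None:
                        raise ValueError("reference='other_set' requires `other`")
                    ref = np.array([by_gene[g] for g in other.genes if g in by_gene])
                if len(ref):
                    row["p_value"] = float(
                        stats.mannwhitneyu(member, ref, alternative="two-sided").pvalue
                    )
        rows.append(row)
    return pd.DataFrame(rows).set_index("set_id")


def class_enrichment(
    geneset: GeneSetDefinition,
    carriers: CarrierMatrix,
    case_status: pd.Series,
    pcs: PCResult | None = None,
) -> BurdenResult:
    """Set-level burden fit: the indicator is carriage in any member gene."""
    member = [g for g in geneset.genes if g in carriers.data.index]
    if not member:
        raise KeyError(f"no member of set {geneset.set_id!r} in carrier matrix")
    samples = carriers.samples
    pooled = carriers.data.loc[member].any(axis=0)
    y = case_status.loc[samples].to_numpy(dtype=float)
    x = pooled.to_numpy(dtype=float)
    fit = fit_carrier_logit(y, x, covariates=_aligned_pcs(pcs, samples))
    return BurdenResult(
        gene_id=geneset.set_id,
        n_case_carriers=int(x[y == 1].sum()),
        n_control_carriers=int(x[y == 0].sum()),
        eligible=True,
        coef=fit.coef,
        se=fit.se,
        p_value=fit.p_value,
        converged=fit.converged,
        separation_flag=fit.separation,
        penalized=fit.penalized,
    )


def single_cancer_run(
    carriers: CarrierMatrix,
    samples: pd.DataFrame,
    cancer_type: str,
    majority_population: str,
    pcs: PCResult | None = None,
    thresholds: dict | None = None,
    alpha: float = 0.20,
    min_cases: int = 50,
) -> tuple[list[BurdenResult], dict]:
    """Case-control burden run for one cancer type.

    Cases are restricted to the given cancer type and controls to the same
    (majority) population label, the composition under which a small
    single-cancer cohort can be compared against the full control set without
    gross stratification. Returns the results plus restriction metadata.
    Raises ``ValueError`` when fewer than ``min_cases`` cases remain.
    """
    is_case = samples["cohort"] == "case"
    keep_case = is_case & (samples["cancer_type"] == cancer_type) & (samples["population"] == majority_population)
    keep_control = ~is_case & (samples["population"] == majority_population)
    n_cases = int(keep_case.sum())
    if n_cases < min_cases:
        raise ValueError(
            f"only {n_cases} {cancer_type} cases in population {majority_population!r}"
            f" (minimum {min_cases}); refusing to run an underpowered analysis"
        )
    subset = samples.index[keep_case | keep_control]
    sub_carriers = CarrierMatrix(carriers.data[subset], class_mode=carriers.class_mode)
    sub_status = is_case.loc[subset].astype(int)
    sub_pcs = None
    if pcs is not None:
        sub_pcs = PCResult(
            scores=pcs.scores.loc[subset],
            variance_explained=pcs.variance_explained,
            k=pcs.k,
        )
    results = run_burden(sub_carriers, sub_status, sub_pcs, analysis=cancer_type, thresholds=thresholds, alpha=alpha)
    meta = {
        "cancer_type": cancer_type,
        "majority_population": majority_population,
        "n_cases": n_cases,
        "n_controls": int(keep_control.sum()),
    }
    return results, meta


def overlap_fisher(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[float, float, float]:
    """Fisher's exact test of two gene-list memberships over a universe.

    Returns (sample cross-product OR, conditional-MLE OR of the noncentral
    hypergeometric model, exact two-sided p).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a_set, b_set = set(set_a) & universe, set(set_b) & universe
    both = len(a_set & b_set)
    a_only = len(a_set) - both
    b_only = len(b_set) - both
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    with np.errstate(divide="ignore", invalid="ignore"):
        sample_or = float(table[0, 0] * table[1, 1]) / float(table[0, 1] * table[1, 0]) if table[0, 1] * table[1, 0] else np.inf
    cond = stats.contingency.odds_ratio(table, kind="conditional")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return sample_or, float(cond.statistic), float(p)
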