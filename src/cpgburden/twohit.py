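"""Two-hit preference: pathogenic-variant excess in LOH tumors.

Knudson's two-hit model predicts that for a recessive-acting predisposition
gene, tumors of germline carriers lose the remaining wild-type allele
somatically. Gene-level loss of heterozygosity (LOH) is called where the
minor copy number — the least amplified allele — equals zero. Per gene, LOH
status across tumors is regressed on the germline carrier indicator (plus
cancer-only principal components), the same logistic contract as the
case-control burden fit with LOH tumors playing the role of cases. A
positive coefficient means carriers preferentially lose their second allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import _LN2, fit_carrier_logit
from .popstruct import PCResult
from .varfilter import CarrierMatrix

__all__ = ["LOHTable", "TwoHitResult", "call_loh", "cna_composition", "fit_twohit", "run_twohit"]


@dataclass
class LOHTable:
    """Gene x sample minor copy number with derived LOH calls.

    ``minor_cn`` holds non-negative integers or NaN (no call); ``loh`` is
    True exactly where a call is present and equals zero. Missing cells are
    excluded from every downstream test.
    """

    minor_cn: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.minor_cn.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("minor copy number must be non-negative")

    @property
    def loh(self) -> pd.DataFrame:
        return self.minor_cn.eq(0) & self.minor_cn.notna()

    @property
    def genes(self) -> list[str]:
        return list(self.minor_cn.index)

    @property
    def samples(self) -> list[str]:
        return list(self.minor_cn.columns)


@dataclass
class TwoHitResult:
    """Per-gene two-hit preference summary."""

    gene_id: str
    n_loh: int
    n_noloh: int
    n_loh_carriers: int
    n_noloh_carriers: int
    eligible: bool
    coef: float = np.nan
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


def call_loh(minor_cn: pd.DataFrame) -> LOHTable:
    """LOH calls from a gene x sample minor-copy-number table.

    Threshold-free: LOH iff minor CN == 0. Missing entries stay missing.
    """
    return LOHTable(minor_cn=minor_cn)


def cna_composition(loh: LOHTable, total_cn_calls: pd.DataFrame) -> pd.DataFrame:
    """Percentage of loss / wild / gain total-CN calls within each LOH class.

    A diagnostic cross-check of the LOH calls against independent total
    copy-number categories: LOH cells should be dominated by losses. Classes
    with no cells are reported as all-NaN rows.
    """
    if total_cn_calls.shape != loh.minor_cn.shape or not (
        total_cn_calls.index.equals(loh.minor_cn.index) and total_cn_calls.columns.equals(loh.minor_cn.columns)
    ):
        raise ValueError("total_cn_calls must align with the LOH table")
    mask = loh.minor_cn.notna()
    loh_flags = loh.loh
    rows = {}
    for label, sel in (("LOH", loh_flags & mask), ("no-LOH", ~loh_flags & mask)):
        cats = total_cn_calls.to_numpy()[sel.to_numpy()]
        n = cats.size
        if n == 0:
            rows[label] = {"loss": np.nan, "wild": np.nan, "gain": np.nan, "n": 0}
        else:
            rows[label] = {
                "loss": 100.0 * np.sum(cats == "loss") / n,
                "wild": 100.0 * np.sum(cats == "wild") / n,
                "gain": 100.0 * np.sum(cats == "gain") / n,
                "n": n,
            }
    return pd.DataFrame(rows).T


def fit_twohit(
    gene: str,
    carriers: CarrierMatrix,
    loh: LOHTable,
    cancer_pcs: PCResult | None = None,
) -> TwoHitResult:
    """Logistic fit of LOH status on the carrier indicator for one gene.

    Operates on cancer samples only (``carriers`` restricted upstream);
    samples without a copy-number call for the gene are dropped. PCs must be
    computed on the cancer samples themselves.
    """
    if gene not in loh.minor_cn.index:
        raise KeyError(f"gene {gene!r} has no copy-number row")
    common = [s for s in carriers.samples if s in loh.minor_cn.columns]
    cn = loh.minor_cn.loc[gene, common]
    called = cn.notna()
    samples = list(cn.index[called])
    y = (cn[called] == 0).to_numpy(dtype=float)
    x = carriers.data.loc[gene, samples].to_numpy(dtype=float)
    cov = cancer_pcs.scores.loc[samples].to_numpy() if cancer_pcs is not None else None
    n_loh = int(y.sum())
    n_noloh = int(len(y) - n_loh)
    base = dict(
        gene_id=gene,
        n_loh=n_loh,
        n_noloh=n_noloh,
        n_loh_carriers=int(x[y == 1].sum()),
        n_noloh_carriers=int(x[y == 0].sum()),
    )
    if n_loh == 0 or n_noloh == 0:
        return TwoHitResult(eligible=False, **base)
    fit = fit_carrier_logit(y, x, covariates=cov)
    return TwoHitResult(
        eligible=True,
        coef=fit.coef,
        se=fit.se,
        p_value=fit.p_value,
        converged=fit.converged,
        separation_flag=fit.separation,
        penalized=fit.penalized,
        **base,
    )


def run_twohit(
    carriers: CarrierMatrix,
    loh: LOHTable,
    cancer_pcs: PCResult | None = None,
    min_group_carriers: int | None = None,
    alpha: float = 0.20,
) -> list[TwoHitResult]:
    """Two-hit fits for every gene with copy-number data, with BH FDR.

    ``min_group_carriers`` optionally applies the per-cancer eligibility rule
    (more than N carriers in either the LOH or the no-LOH group).
    """
    from statsmodels.stats.multitest import multipletests

    results = []
    for gene in loh.genes:
        if gene not in carriers.data.index:
            raise KeyError(f"gene {gene!r} in copy-number table but not in carrier matrix")
        r = fit_twohit(gene, carriers, loh, cancer_pcs)
        if min_group_carriers is not None and not (
            r.n_loh_carriers > min_group_carriers or r.n_noloh_carriers > min_group_carriers
        ):
            r.eligible = False
        results.append(r)
    tested = [r for r in results if r.eligible and np.isfinite(r.p_value)]
    if tested:
        _, q, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
        for r, qv in zip(tested, q):
            r.q_value = float(qv)
            r.significant = bool(qv < alpha)
    return results
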