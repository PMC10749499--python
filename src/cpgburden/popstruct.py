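"""Population structure from common variants.

Case and control cohorts with different ancestry compositions inflate a
case-control burden test: any variant whose frequency differs between
subpopulations looks associated with case status. The standard remedy is to
regress case status on the leading principal components of the common-variant
genotype matrix. This module selects common variants (MAF >= 5% globally and
in every annotated group, call rate >= 90%, non-synonymous by default) and
computes PC scores used as covariates downstream. Two PCAs are run in the
full pipeline: case+control samples for the burden test, and cancer samples
only for the two-hit test — the same operation on different sample subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PCResult", "select_common_variants", "compute_pcs"]


@dataclass
class PCResult:
    """Principal-component scores for a sample set.

    ``scores`` is a samples x k DataFrame (columns PC1..PCk);
    ``variance_explained`` the fraction of total variance per component,
    non-increasing.
    """

    scores: pd.DataFrame
    variance_explained: np.ndarray
    k: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def select_common_variants(
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    groups: pd.Series | None = None,
    require_nonsynonymous: bool = True,
) -> pd.DataFrame:
    """Filter a dosage matrix to common, well-genotyped variants.

    ``genotypes`` is samples x variants with dosages in {0, 1, 2, NaN}.
    ``variants`` carries per-variant annotation indexed by variant id; a
    ``consequence`` column (when present and ``require_nonsynonymous``)
    restricts to non-synonymous variants, and ``maf_global`` /
    ``maf_<group>`` columns supply annotated reference frequencies. When no
    annotated frequencies exist, MAFs are computed empirically from the
    dosages, per group when ``groups`` (sample id -> group label) is given.
    Raises if nothing survives.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    keep = pd.Series(True, index=genotypes.columns)

    ann = variants.reindex(genotypes.columns)
    if require_nonsynonymous and "consequence" in ann.columns:
        keep &= ann["consequence"].ne("synonymous").fillna(True)

    call_rate = genotypes.notna().mean(axis=0)
    keep &= call_rate >= call_rate_min

    maf_cols = [c for c in ann.columns if c == "maf_global" or c.startswith("maf_")]
    if maf_cols:
        for c in maf_cols:
            maf = pd.to_numeric(ann[c], errors="coerce")
            folded = np.minimum(maf, 1.0 - maf)
            keep &= (folded >= maf_min) | folded.isna()
    else:
        freq = genotypes.mean(axis=0) / 2.0
        keep &= np.minimum(freq, 1 - freq) >= maf_min
        if groups is not None:
            for label in groups.loc[genotypes.index].unique():
                sub = genotypes.loc[groups.loc[genotypes.index] == label]
                f = sub.mean(axis=0) / 2.0
                keep &= np.minimum(f, 1 - f) >= maf_min

    out = genotypes.loc[:, keep[genotypes.columns].to_numpy()]
    if out.shape[1] == 0:
        raise ValueError(
            "no variant passes the common-variant filters; relax maf_min or call_rate_min"
        )
    return out


def compute_pcs(genotypes: pd.DataFrame, k: int = 4) -> PCResult:
    """PCA of a standardized dosage matrix.

    Missing dosages are mean-imputed per variant; each variant is centered
    and scaled to unit variance; scores come from the truncated SVD. The sign
    of each component is fixed so its largest-magnitude variant loading is
    positive, making scores reproducible across runs.
    """
    X = genotypes.to_numpy(dtype=float)
    n, m = X.shape
    if n < k + 1 or m < k:
        raise ValueError(f"need >= {k + 1} samples and >= {k} variants for k={k}")

    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    if idx[0].size:
        X = X.copy()
        X[idx] = col_mean[idx[1]]

    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    nondegenerate = sd > 0
    if not nondegenerate.all():
        logger.info("dropping %d zero-variance variants before PCA", int((~nondegenerate).sum()))
        X = X[:, nondegenerate]
        sd = sd[nondegenerate]
    if X.shape[1] == 0:
        raise ValueError("all variants have zero variance")
    X = X / sd

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # Deterministic sign: largest-|loading| positive per component.
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1

    total_var = float(np.sum(S**2))
    var_explained = (S[:k] ** 2) / total_var
    scores = U[:, :k] * S[:k]
    return PCResult(
        scores=pd.DataFrame(
            scores, index=genotypes.index, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
        ),
        variance_explained=var_explained,
        k=k,
    )
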