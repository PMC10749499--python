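"""Immune-checkpoint transcriptional score with a resampling null.

The transcriptional score (TS) of a sample group summarizes how strongly a
gene panel (canonically 38 immune-checkpoint modulatory genes) co-varies
within the group: the absolute sum of Pearson correlation coefficients,
either over all unordered panel-gene pairs (pairwise mode) or between each
panel gene and a designated anchor gene (anchor mode). A high TS indicates a
coordinated immune transcriptional microenvironment.

Because TS grows with panel size and depends on sample number, an observed
group's TS is compared against a null built by repeatedly drawing
equally-sized subsamples (default 45, 1,000 draws) from a larger comparison
group and recomputing TS on each draw; the empirical p-value uses the
add-one correction so it is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TSResult", "compute_ts", "resample_null"]


@dataclass
class TSResult:
    """Observed TS with its resampled null distribution."""

    observed_ts: float
    mode: str
    null_values: np.ndarray = field(repr=False)
    null_mean: float = np.nan
    null_sd: float = np.nan
    empirical_p: float = np.nan
    n_resample: int = 0
    subsample_size: int = 0
    seed: int | None = None


def compute_ts(
    expr: pd.DataFrame,
    mode: str = "pairwise",
    anchor_gene: str | None = None,
) -> float:
    """Transcriptional score of one sample group.

    ``expr`` is genes x samples. Pairwise mode sums |Pearson r| over
    unordered panel-gene pairs; anchor mode sums |r| between ``anchor_gene``
    and every other panel gene. Zero-variance genes contribute zero to every
    pair they appear in.
    """
    if expr.shape[1] < 3:
        raise ValueError("TS needs at least 3 samples")
    if mode not in {"pairwise", "anchor"}:
        raise ValueError(f"unknown mode {mode!r}")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.info("%d zero-variance genes contribute 0 to TS", int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    if mode == "pairwise":
        if expr.shape[0] < 2:
            raise ValueError("pairwise TS needs >= 2 panel genes")
        iu = np.triu_indices(corr.shape[0], k=1)
        return float(np.abs(corr[iu]).sum())
    if anchor_gene is None or anchor_gene not in expr.index:
        raise ValueError("anchor mode requires anchor_gene present in the panel expression")
    a = expr.index.get_loc(anchor_gene)
    others = [i for i in range(corr.shape[0]) if i != a]
    return float(np.abs(corr[a, others]).sum())


def resample_null(
    expr_comparison: pd.DataFrame,
    observed_ts: float,
    subsample_size: int = 45,
    n_resample: int = 1000,
    seed: int | None = None,
    mode: str = "pairwise",
    anchor_gene: str | None = None,
) -> TSResult:
    """Subsampling null for an observed TS.

    Draws ``n_resample`` subsamples of ``subsample_size`` columns without
    replacement from the comparison group's genes x samples matrix, computes
    TS on each, and reports the add-one empirical p-value
    ``(1 + #{null >= observed}) / (n_resample + 1)`` with the null mean/sd.
    """
    n_available = expr_comparison.shape[1]
    if subsample_size >= n_available:
        raise ValueError(
            f"subsample_size ({subsample_size}) must be smaller than the comparison group ({n_available})"
        )
    rng = np.random.default_rng(seed)
    cols = np.arange(n_available)
    X = expr_comparison.to_numpy(dtype=float)
    nulls = np.empty(n_resample)
    frame = pd.DataFrame(X, index=expr_comparison.index)
    for i in range(n_resample):
        pick = rng.choice(cols, size=subsample_size, replace=False)
        nulls[i] = compute_ts(frame.iloc[:, pick], mode=mode, anchor_gene=anchor_gene)
    p = (1.0 + np.sum(nulls >= observed_ts)) / (n_resample + 1.0)
    return TSResult(
        observed_ts=float(observed_ts),
        mode=mode,
        null_values=nulls,
        null_mean=float(nulls.mean()),
        null_sd=float(nulls.std(ddof=1)),
        empirical_p=float(p),
        n_resample=n_resample,
        subsample_size=subsample_size,
        seed=seed,
    )
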