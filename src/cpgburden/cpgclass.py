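"""Four-class gene classification from two-hit, tissue-specificity and
constraint features.

Each candidate predisposition gene is summarized by three features: its
pan-cancer two-hit log2 odds ratio (does LOH co-occur with germline
carriage), its TAU tissue-specificity index (0 = broadly expressed,
1 = single-tissue), and its LOEUF loss-of-function constraint (< 0.35 means
intolerant to inactivation). The features are z-standardized, reduced by
PCA, and clustered with multi-restart k-means at k=4. Clusters are then
named by median-feature rules: the lowest-TAU cluster is "broadly
expressed"; of the rest, the highest two-hit cluster is "canonical two-hit";
the remaining two tissue-specific clusters split by LOEUF into pLoF-tolerant
(high LOEUF) and less-tolerant (low LOEUF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["ClusterAssignment", "classify_genes", "label_clusters", "FEATURE_COLUMNS", "CLUSTER_LABELS"]

FEATURE_COLUMNS = ("twohit_log2or", "tau", "loeuf")

CLUSTER_LABELS = (
    "broadly_expressed",
    "tissue_specific_pLoF_tolerant",
    "tissue_specific_less_pLoF_tolerant",
    "canonical_two_hit",
)


@dataclass
class ClusterAssignment:
    """Cluster memberships with PC coordinates and (optional) labels."""

    assignments: pd.DataFrame  # index gene_id; columns cluster, PC1.., label
    k: int

    @property
    def clusters(self) -> pd.Series:
        return self.assignments["cluster"]

    @property
    def labels(self) -> pd.Series | None:
        return self.assignments["label"] if "label" in self.assignments else None


def _validate_features(features: pd.DataFrame) -> pd.DataFrame:
    missing_cols = set(FEATURE_COLUMNS) - set(features.columns)
    if missing_cols:
        raise KeyError(f"feature table lacks columns {sorted(missing_cols)}")
    feat = features.loc[:, list(FEATURE_COLUMNS)].apply(pd.to_numeric)
    complete = feat.notna().all(axis=1)
    if not complete.all():
        logger.warning("excluding %d genes with missing features", int((~complete).sum()))
        feat = feat.loc[complete]
    bad_tau = ~feat["tau"].between(0, 1)
    if bad_tau.any():
        raise ValueError(f"TAU outside [0, 1] for genes {list(feat.index[bad_tau])}")
    if (feat["loeuf"] <= 0).any():
        raise ValueError("LOEUF must be positive")
    return feat


def classify_genes(
    features: pd.DataFrame,
    k: int = 4,
    n_restarts: int = 25,
    seed: int | None = 0,
) -> ClusterAssignment:
    """Z-standardize, PCA to full rank, k-means on the PC scores.

    ``features`` is indexed by gene id with columns ``twohit_log2or``,
    ``tau``, ``loeuf``. K-means runs ``n_restarts`` initializations keeping
    the lowest within-cluster sum of squares; deterministic given ``seed``.
    """
    feat = _validate_features(features)
    if len(feat) < k:
        raise ValueError(f"need >= {k} genes with complete features, have {len(feat)}")
    X = feat.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        degenerate = [FEATURE_COLUMNS[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance feature(s) {degenerate}: clustering is degenerate")
    Z = (X - X.mean(axis=0)) / sd
    pcs = PCA(n_components=min(Z.shape)).fit_transform(Z)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(pcs)
    out = pd.DataFrame(
        {"cluster": km.labels_ + 1},
        index=feat.index,
    )
    for j in range(pcs.shape[1]):
        out[f"PC{j + 1}"] = pcs[:, j]
    return ClusterAssignment(assignments=out, k=k)


def label_clusters(assignment: ClusterAssignment, features: pd.DataFrame) -> ClusterAssignment:
    """Attach semantic labels to a 4-cluster solution via median rules.

    broadly_expressed: lowest median TAU. canonical_two_hit: highest median
    two-hit log2 OR among the rest. Of the two remaining (tissue-specific)
    clusters, higher median LOEUF is pLoF-tolerant, lower is less tolerant.
    Ties break by LOEUF, then two-hit log2 OR. With k != 4 labels are
    skipped.
    """
    if assignment.k != 4:
        logger.warning("cluster labels are defined for k=4 only (k=%d); skipping", assignment.k)
        return assignment
    feat = _validate_features(features).loc[assignment.assignments.index]
    med = feat.groupby(assignment.clusters).median()

    remaining = list(med.index)
    # Lowest TAU -> broadly expressed (ties: lower LOEUF first, then two-hit).
    order = med.loc[remaining].sort_values(["tau", "loeuf", "twohit_log2or"]).index
    broadly = order[0]
    remaining.remove(broadly)
    # Highest two-hit preference -> canonical two-hit.
    order = med.loc[remaining].sort_values(["twohit_log2or", "loeuf"], ascending=False).index
    canonical = order[0]
    remaining.remove(canonical)
    # Remaining two: split by LOEUF.
    order = med.loc[remaining].sort_values(["loeuf", "twohit_log2or"], ascending=False).index
    tolerant, less_tolerant = order[0], order[1]

    mapping = {
        broadly: "broadly_expressed",
        canonical: "canonical_two_hit",
        tolerant: "tissue_specific_pLoF_tolerant",
        less_tolerant: "tissue_specific_less_pLoF_tolerant",
    }
    out = assignment.assignments.copy()
    out["label"] = assignment.clusters.map(mapping)
    return ClusterAssignment(assignments=out, k=assignment.k)
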