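"""Expression-matrix preprocessing, clustering and gene ranking.

The unsupervised-profiling recipe applied to tumour FPKM matrices:

* gene filtering by mean expression (> 1.5 FPKM) and coefficient of
  variation (> 0.3, sample standard deviation), optionally dropping
  RPL/RPS ribosomal-protein genes by identifier prefix;
* hierarchical clustering of samples with UPGMA (average) agglomeration on
  a (1 - Spearman correlation) distance;
* signal-to-noise gene ranking between two phenotypes,
  ``(mean_A - mean_B) / (sd_A + sd_B)`` with each standard deviation
  floored at 20% of the group-mean magnitude (0.2 when the mean is zero),
  the conventional default of gene-set enrichment tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_MIN_MEAN = 1.5
DEFAULT_MIN_CV = 0.3
SD_FLOOR_FRAC = 0.2
RIBOSOMAL_PREFIXES = ("RPL", "RPS")


def filter_genes(
    matrix: pd.DataFrame,
    min_mean: float = DEFAULT_MIN_MEAN,
    min_cv: float = DEFAULT_MIN_CV,
    *,
    drop_ribosomal: bool = False,
) -> pd.DataFrame:
    """Keep genes with mean > ``min_mean`` and CV > ``min_cv`` (strict).

    CV uses the sample standard deviation (ddof=1), so at least two samples
    are required.  Idempotent: filtering a filtered matrix is a no-op.
    """
    if matrix.shape[1] < 2:
        raise ValueError("CV is undefined for a single-sample matrix")
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    keep = (mean > min_mean) & (cv > min_cv)
    if drop_ribosomal:
        rib = matrix.index.to_series().str.upper().str.startswith(RIBOSOMAL_PREFIXES)
        keep &= ~rib
    return matrix.loc[keep.fillna(False)]


@dataclass
class ClusterResult:
    """Sample dendrogram from UPGMA on (1 - Spearman) distances."""

    linkage: np.ndarray  # scipy linkage matrix
    distance: pd.DataFrame  # condensed-to-square sample distance matrix
    samples: list[str]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels from cutting the dendrogram into k groups."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.samples, name="cluster")

    def merge_order(self) -> list[tuple[frozenset, frozenset]]:
        """Sample-name sets merged at each agglomeration step."""
        n = len(self.samples)
        members = {i: frozenset([self.samples[i]]) for i in range(n)}
        order = []
        for step, (a, b, _, _) in enumerate(self.linkage):
            ia, ib = int(a), int(b)
            order.append((members[ia], members[ib]))
            members[n + step] = members[ia] | members[ib]
        return order

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.samples[node.id]
            left = rec(node.get_left())
            right = rec(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def spearman_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """(1 - Spearman correlation) distance between sample columns.

    Ties receive average ranks.  A zero-variance sample has undefined
    correlation and is reported by name.
    """
    sds = matrix.std(axis=0, ddof=0)
    dead = sds[sds == 0]
    if len(dead):
        raise ValueError(
            f"zero-variance sample(s): {', '.join(map(str, dead.index))}"
        )
    rho = matrix.corr(method="spearman")
    return 1.0 - rho


def cluster_samples(matrix: pd.DataFrame) -> ClusterResult:
    """UPGMA clustering of samples on (1 - Spearman) distance."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    dist = spearman_distance(matrix)
    condensed = squareform(dist.values, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    return ClusterResult(
        linkage=link, distance=dist, samples=list(matrix.columns)
    )


def signal_to_noise_rank(
    matrix: pd.DataFrame,
    labels: pd.Series,
    *,
    sd_floor_frac: float = SD_FLOOR_FRAC,
) -> pd.DataFrame:
    """Rank genes by the two-phenotype signal-to-noise metric.

    Score = (mean_A - mean_B) / (sd_A + sd_B), with each group sd floored
    at ``sd_floor_frac * |group mean|`` (and at ``sd_floor_frac`` itself
    when the group mean is zero).  Phenotype A is the first label in
    sorted order unless the labels carry exactly two categories in a
    pandas Categorical with a defined order.  Returns a DataFrame sorted
    by descending score with columns ``score, mean_a, mean_b, sd_a, sd_b``.
    """
    labels = labels.reindex(matrix.columns)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two phenotypes, got {groups}")
    a, b = groups
    if (labels == a).sum() < 2 or (labels == b).sum() < 2:
        raise ValueError("each phenotype needs at least 2 samples")

    def stats(cols):
        sub = matrix.loc[:, cols]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        floor = sd_floor_frac * mean.abs()
        floor = floor.where(floor > 0, sd_floor_frac)
        return mean, sd.where(sd > floor, floor)

    mean_a, sd_a = stats(labels[labels == a].index)
    mean_b, sd_b = stats(labels[labels == b].index)
    score = (mean_a - mean_b) / (sd_a + sd_b)
    out = pd.DataFrame(
        {"score": score, "mean_a": mean_a, "mean_b": mean_b,
         "sd_a": sd_a, "sd_b": sd_b}
    )
    # descending score; gene id breaks ties deterministically
    return out.sort_index().sort_values("score", ascending=False, kind="mergesort")


def read_fpkm_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
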