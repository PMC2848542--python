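"""Cross-contrast comparison and phenotype correlation of reporter sets.

Two downstream views on fitted reporter results: (1) how similar the reporter
sets of different contrasts are — Jaccard distances and average-linkage
hierarchical clustering of the contrasts; (2) whether the collective expression
of a reporter metabolite's neighbor genes tracks a macroscopic phenotype —
Pearson correlation of a per-sample centroid profile (mean of per-gene z-scored
expression) with the phenotype, per clinical group and pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _linkage
from scipy.spatial.distance import squareform

from .network import MetabolicNetwork, neighbor_enzymes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastResult:
    """Reporter-metabolite set of one pairwise contrast."""

    contrast_id: str
    reporter_ids: frozenset[str]


def jaccard_distance(a: Iterable[str], b: Iterable[str]) -> float:
    """1 - |a n b| / |a u b|: the fraction of non-overlapping reporters.

    Two empty sets are defined as distance 0 (identical, logged).
    """
    sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        logger.info("jaccard_distance of two empty sets defined as 0")
        return 0.0
    return 1.0 - len(sa & sb) / len(union)


@dataclass
class ContrastClustering:
    labels: list[str]
    distance: pd.DataFrame
    linkage_matrix: np.ndarray
    newick: str


def cluster_contrasts(
    results: Sequence[ContrastResult] | Mapping[str, Iterable[str]],
    linkage: str = "average",
) -> ContrastClustering:
    """Agglomerative clustering of contrasts on pairwise Jaccard distances.

    Contrasts are ordered by id before computing, so the result is invariant to
    input order; branch lengths in the Newick tree are the merge heights.
    """
    if isinstance(results, Mapping):
        items = [(str(k), frozenset(v)) for k, v in results.items()]
    else:
        items = [(r.contrast_id, frozenset(r.reporter_ids)) for r in results]
    ids = [k for k, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contrast ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 contrasts to cluster")
    items.sort(key=lambda kv: kv[0])
    labels = [k for k, _ in items]
    sets = [s for _, s in items]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jaccard_distance(sets[i], sets[j])
    Z = _linkage(squareform(D, checks=False), method=linkage)
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, labels)
    newick = str(tree).strip()
    dist_df = pd.DataFrame(D, index=labels, columns=labels)
    return ContrastClustering(labels, dist_df, Z, newick)


# ---------------------------------------------------------------------------------
# centroid expression vs phenotype


def centroid_profile(
    expr: pd.DataFrame,
    network: MetabolicNetwork,
    metabolite_id: str,
    mode: str = "zscore",
    dedup: bool = True,
) -> pd.Series:
    """Per-sample centroid of a metabolite's neighbor-gene expression.

    ``expr`` is a genes x samples matrix.  With ``mode="zscore"`` (default) each
    gene is standardized over all samples (mean 0, SD 1; zero-SD genes dropped)
    before averaging; ``mode="raw"`` averages unstandardized rows.
    """
    units = neighbor_enzymes(network, metabolite_id, dedup=dedup)
    genes = sorted({g for u in units for g in u.gene_ids})
    present = [g for g in genes if g in expr.index]
    missing = len(genes) - len(present)
    if missing:
        logger.info(
            "metabolite %s: %d neighbor genes lack expression rows",
            metabolite_id,
            missing,
        )
    if not present:
        raise ValueError(f"metabolite {metabolite_id}: no neighbor gene expression")
    sub = expr.loc[present].astype(float)
    if mode == "zscore":
        sd = sub.std(axis=1, ddof=1)
        keep = sd > 0
        sub = sub.loc[keep].sub(sub.loc[keep].mean(axis=1), axis=0).div(
            sd[keep], axis=0
        )
        if sub.empty:
            raise ValueError(
                f"metabolite {metabolite_id}: all neighbor genes constant"
            )
    elif mode != "raw":
        raise ValueError(f"unknown centroid mode {mode!r}")
    return sub.mean(axis=0)


def centroid_correlation(
    expr: pd.DataFrame,
    network: MetabolicNetwork,
    metabolite_id: str,
    phenotype: Mapping[str, float],
    groups: Mapping[str, str],
    mode: str = "zscore",
) -> pd.DataFrame:
    """Pearson correlation of centroid expression with a phenotype.

    Computed per clinical group and for all samples pooled ("all").  Rows with
    fewer than 3 paired observations or zero variance are marked not computable
    (computable = False, r/p = NaN).  The two-sided p comes from the exact t
    transform of r.
    """
    centroid = centroid_profile(expr, network, metabolite_id, mode=mode)
    samples = [s for s in centroid.index if s in phenotype]
    rows = []
    labels = sorted(set(groups.get(s) for s in samples) - {None})
    for label in labels + ["all"]:
        sel = (
            samples
            if label == "all"
            else [s for s in samples if groups.get(s) == label]
        )
        x = centroid[sel].to_numpy(dtype=float)
        y = np.array([phenotype[s] for s in sel], dtype=float)
        n = len(sel)
        if n < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append((metabolite_id, label, n, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((metabolite_id, label, n, float(r), float(p), True))
    return pd.DataFrame(
        rows, columns=["metabolite_id", "group", "n", "r", "p", "computable"]
    )
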