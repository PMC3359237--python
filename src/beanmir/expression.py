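"""Family-level expression: count pooling, median-of-ratios size factors,
a blind variance-stabilizing transformation, and hierarchical clustering.

Counts of mature (never mature-star) miRNAs are pooled by family into a
families x organs matrix.  Library depth is normalized with the
median-of-ratios estimator (each library's median ratio of counts to the
per-family geometric mean across libraries).  Without biological
replicates, a single common negative-binomial dispersion is fitted
"blind" — treating the organ libraries as if they were replicates — by
moment matching of Var(q) ~ mean + alpha * mean^2, and counts are
transformed with the closed-form NB variance stabilizer
t = (2/sqrt(alpha)) * asinh(sqrt(alpha * q)), which tends to 2*sqrt(q) as
alpha -> 0.  Organs and families are then clustered with Euclidean
distance and complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .conserved import AnnotationHit
from .isoforms import VariantCall


def pool_families(kept_hits: Iterable[AnnotationHit],
                  rescued: Iterable[AnnotationHit] = (),
                  promoted_variants: Iterable[VariantCall] = (),
                  promoted_families: set[str] | None = None,
                  libraries: Sequence[str] = ("LL", "FL", "RL", "SL"),
                  ) -> pd.DataFrame:
    """Sum member-miRNA counts per family; star references are excluded.

    ``rescued`` carries miRNAs that failed the conservation filter but
    aligned perfectly with validated precursors; ``promoted_variants``
    contributes the retained isomiRs of newly promoted families (only
    families in ``promoted_families`` are added).
    """
    rows: dict[str, np.ndarray] = {}

    def bump(family: str, counts: Mapping[str, int]) -> None:
        vec = rows.setdefault(family, np.zeros(len(libraries), dtype=int))
        for k, lib in enumerate(libraries):
            vec[k] += counts.get(lib, 0)

    for hit in list(kept_hits) + list(rescued):
        if not hit.ref.is_star:
            bump(hit.ref.family, hit.counts)
    promoted_families = promoted_families or set()
    for call in promoted_variants:
        if call.ref.family in promoted_families and not call.ref.is_star:
            bump(call.ref.family, call.counts)

    if not rows:
        raise ValueError("no non-star hits to pool")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(libraries))
    df.index.name = "family"
    return df.sort_index(key=lambda idx: idx.astype(int))


def size_factors(k: pd.DataFrame) -> pd.Series:
    """Median-of-ratios effective library sizes.

    s_j = median over families i (with an all-positive row) of
    k_ij / geometric_mean_v(k_iv).  Scale-equivariant: doubling a column
    doubles its factor.
    """
    counts = k.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no family has positive counts in every library; size factors "
            "need at least one all-positive row — pool more families or "
            "drop empty libraries")
    logs = np.log(counts[positive])
    log_gm = logs.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logs - log_gm, axis=0))
    return pd.Series(s, index=k.columns, name="size_factor")


@dataclass
class VSTResult:
    t: pd.DataFrame              # transformed matrix
    dispersion: float            # fitted common dispersion alpha
    q: pd.DataFrame              # size-factor-normalized counts


def fit_common_dispersion(q: np.ndarray) -> float:
    """Blind moment-matching common dispersion across rows.

    For each row with positive mean, alpha_i = (var_i - mean_i)/mean_i^2;
    the estimate is the median over rows, clamped at 0 (a negative moment
    estimate means the data are at or below Poisson variation).
    """
    mean = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    ok = mean > 0
    if not ok.any():
        return 0.0
    alpha = float(np.median((var[ok] - mean[ok]) / mean[ok] ** 2))
    if alpha < 0:
        warnings.warn("moment dispersion estimate < 0; clamping to 0")
        alpha = 0.0
    return alpha


def vst(k: pd.DataFrame, s: pd.Series | None = None,
        dispersion: float | None = None) -> VSTResult:
    """Variance-stabilize normalized counts with the closed NB form.

    t = (2/sqrt(alpha)) * asinh(sqrt(alpha*q)); alpha = 0 falls back to
    2*sqrt(q).  Monotone in the counts at fixed size factors.
    """
    if s is None:
        s = size_factors(k)
    q = k.div(s, axis=1)
    alpha = fit_common_dispersion(q.to_numpy(float)) if dispersion is None else dispersion
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    qv = q.to_numpy(float)
    if alpha == 0.0:
        t = 2.0 * np.sqrt(qv)
    else:
        t = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * qv))
    return VSTResult(pd.DataFrame(t, index=k.index, columns=k.columns),
                     alpha, q)


@dataclass
class HCAResult:
    organ_linkage: np.ndarray
    family_linkage: np.ndarray
    organ_labels: list[str]      # input column order (linkage leaf ids)
    family_labels: list[str]     # input row order
    organ_order: list[str]       # dendrogram leaf order
    family_order: list[str]
    heatmap: pd.DataFrame        # t reordered by both leaf orders

    def organ_newick(self) -> str:
        return linkage_to_newick(self.organ_linkage, self.organ_labels)

    def family_newick(self) -> str:
        return linkage_to_newick(self.family_linkage, self.family_labels)


def hca(t: pd.DataFrame) -> HCAResult:
    """Hierarchical clustering of organs (columns) and families (rows):
    Euclidean distance, complete linkage on both axes."""
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    organ_Z = hierarchy.linkage(pdist(t.to_numpy(float).T), method="complete")
    family_Z = hierarchy.linkage(pdist(t.to_numpy(float)), method="complete")
    organ_order = [t.columns[i] for i in hierarchy.leaves_list(organ_Z)]
    family_order = [t.index[i] for i in hierarchy.leaves_list(family_Z)]
    return HCAResult(organ_Z, family_Z, list(t.columns), list(t.index),
                     organ_order, family_order,
                     t.loc[family_order, organ_order])


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def first_merge_pair(Z: np.ndarray, labels: Sequence[str], a: str, b: str) -> bool:
    """True when leaves a and b join each other before joining anything else
    (i.e. they are sisters in the dendrogram)."""
    n = len(labels)
    ia, ib = labels.index(a), labels.index(b)
    for left, right, _, _ in Z:
        left, right = int(left), int(right)
        if {left, right} == {ia, ib}:
            return True
        if left in (ia, ib) or right in (ia, ib):
            return False
    return False
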