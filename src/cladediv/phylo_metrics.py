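"""Abundance-weighted phylogeny-based diversity metrics.

Per-site (plot) metrics for the three dimensions of phylogenetic diversity:

* richness — abundance-weighted Faith's PD (branch-length sum of the subtree
  spanning the plot's species, Barker-style branch weighting);
* divergence — abundance-weighted mean pairwise patristic distance (MPD);
* regularity — abundance-weighted variance of pairwise distances (VPD;
  lower VPD means higher regularity).

Abundances are normalized to proportions internally, so all metrics are
invariant under rescaling a site's covers. Sites with fewer than two species
get missing values: pairwise quantities are undefined there.

Weighted Faith's PD uses the branch weighting

    PD_w = B * sum_i(lambda_i * Abar_i) / sum_i(Abar_i)

over the B branches of the plot subtree (stem above the plot MRCA excluded),
where lambda_i is the branch length and Abar_i the mean relative abundance of
the plot species descended from branch i. With equal abundances this reduces
exactly to unweighted Faith's PD = sum_i(lambda_i).

VPD is the weighted *population* variance of pairwise distances with pair
weights f_j * f_k over unordered pairs j < k.
"""

from __future__ import annotations

from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataio import TreeDataError, tip_labels

__all__ = [
    "weighted_faith_pd",
    "weighted_mpd",
    "weighted_vpd",
    "diversity_table",
]


class _TreeArrays:
    """Array view of a tree for vectorized per-site PD.

    Nodes are indexed in preorder (root = 0). ``anc`` is a sparse
    nodes × tips ancestor-or-self incidence matrix, so ``anc @ F`` gives,
    for any tips × sites matrix F, the per-node column sums over descendant
    tips.
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.lengths = np.zeros(n)
        self.is_tip = np.zeros(n, dtype=bool)
        self.tips: list[str] = []
        rows, cols = [], []
        child_rows, child_cols = [], []
        tip_pos: dict[int, int] = {}
        for i, nd in enumerate(nodes):
            if i > 0:
                self.lengths[i] = nd.edge.length or 0.0
                child_rows.append(index[id(nd.parent_node)])
                child_cols.append(i)
            if nd.is_leaf():
                self.is_tip[i] = True
                tip_pos[i] = len(self.tips)
                self.tips.append(nd.taxon.label)
        for i, nd in enumerate(nodes):
            if nd.is_leaf():
                j = tip_pos[i]
                a = nd
                while a is not None:
                    rows.append(index[id(a)])
                    cols.append(j)
                    a = a.parent_node
        n_tips = len(self.tips)
        self.anc = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n_tips)
        )
        self.children = sp.csr_matrix(
            (np.ones(len(child_rows)), (child_rows, child_cols)), shape=(n, n)
        )
        self.tip_index = {lab: j for j, lab in enumerate(self.tips)}


def _site_pd_batch(arrays: _TreeArrays, F: np.ndarray) -> np.ndarray:
    """Weighted Faith's PD for many sites at once.

    F is tips × sites with per-site relative abundances (columns sum to 1
    over each site's species). Sites with fewer than 2 species yield NaN.
    """
    P = (F > 0).astype(float)
    S = P.sum(axis=0)  # per-site species count
    cnt = arrays.anc @ P  # node x site: plot species below each node
    sumf = arrays.anc @ F
    with np.errstate(invalid="ignore", divide="ignore"):
        meanf = np.where(cnt > 0, sumf / np.where(cnt > 0, cnt, 1.0), 0.0)
    below_mrca = (cnt > 0) & (cnt < S[None, :])  # edges of the plot subtree
    # a node heads a branch of the pruned subtree iff it is a plot tip or a
    # true branching point (>= 2 children with plot species below)
    pos_children = arrays.children @ (cnt > 0).astype(float)
    heads = below_mrca & (arrays.is_tip[:, None] | (pos_children >= 2))
    num = arrays.lengths @ (below_mrca * meanf)
    denom = (heads * meanf).sum(axis=0)
    n_branches = heads.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pd_w = n_branches * num / denom
    pd_w = np.where(S >= 2, pd_w, np.nan)
    return pd_w


def _relative(abundances: Mapping[str, float]) -> dict[str, float]:
    pos = {k: float(v) for k, v in abundances.items() if v > 0}
    if any(v < 0 for v in abundances.values()):
        raise ValueError("negative abundance")
    total = sum(pos.values())
    return {k: v / total for k, v in pos.items()} if total > 0 else {}


def weighted_faith_pd(tree: dendropy.Tree, abundances: Mapping[str, float]) -> float:
    """Abundance-weighted Faith's PD of one plot.

    ``abundances`` maps species to nonnegative covers; only species with
    positive cover enter. Returns NaN for fewer than two species. Raises if
    a positive-cover species is missing from the tree.
    """
    rel = _relative(abundances)
    labels = set(tip_labels(tree))
    missing = sorted(set(rel) - labels)
    if missing:
        raise TreeDataError(f"taxa not in tree: {', '.join(missing)}")
    if len(rel) < 2:
        return float("nan")
    arrays = _TreeArrays(tree)
    F = np.zeros((len(arrays.tips), 1))
    for k, v in rel.items():
        F[arrays.tip_index[k], 0] = v
    return float(_site_pd_batch(arrays, F)[0])


def _pair_moments(
    dist: pd.DataFrame, abundances: Mapping[str, float]
) -> tuple[float, float] | None:
    """(weighted mean, weighted mean-square) of pairwise distances, or None
    when fewer than two species have positive abundance."""
    rel = _relative(abundances)
    missing = sorted(set(rel) - set(dist.index))
    if missing:
        raise TreeDataError(f"taxa not in distance matrix: {', '.join(missing)}")
    if len(rel) < 2:
        return None
    sp_names = list(rel)
    f = np.array([rel[s] for s in sp_names])
    D = dist.loc[sp_names, sp_names].to_numpy()
    wsum = 0.5 * (f.sum() ** 2 - (f**2).sum())  # sum_{j<k} f_j f_k
    m1 = 0.5 * (f @ D @ f) / wsum
    m2 = 0.5 * (f @ (D**2) @ f) / wsum
    return m1, m2


def weighted_mpd(dist: pd.DataFrame, abundances: Mapping[str, float]) -> float:
    """Abundance-weighted mean pairwise distance of one plot."""
    mom = _pair_moments(dist, abundances)
    if mom is None:
        return float("nan")
    return float(mom[0])


def weighted_vpd(dist: pd.DataFrame, abundances: Mapping[str, float]) -> float:
    """Abundance-weighted variance of pairwise distances of one plot."""
    mom = _pair_moments(dist, abundances)
    if mom is None:
        return float("nan")
    m1, m2 = mom
    return float(max(m2 - m1**2, 0.0))


def diversity_table(
    tree: dendropy.Tree,
    comm: pd.DataFrame,
    *,
    dist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site S, PD, MPD and VPD for a community matrix.

    Every species with positive abundance anywhere must be a tip of ``tree``.
    ``dist`` may supply a precomputed patristic distance matrix for the
    tree's tips. Sites with S < 2 get NA metrics.
    """
    from .dataio import pairwise_distances

    arrays = _TreeArrays(tree)
    present = [s for s in comm.columns if comm[s].gt(0).any()]
    missing = sorted(set(present) - set(arrays.tips))
    if missing:
        raise TreeDataError(f"taxa not in tree: {', '.join(missing)}")
    if (comm.to_numpy() < 0).any():
        raise ValueError("negative abundance in community matrix")
    if dist is None:
        dist = pairwise_distances(tree)

    X = comm.reindex(columns=arrays.tips, fill_value=0.0).to_numpy(dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = comm.index[(totals[:, 0] == 0)].tolist()
        raise ValueError(f"sites with zero total abundance: {bad}")
    F = (X / totals).T  # tips x sites, relative abundances
    S = (F > 0).sum(axis=0)
    pd_vals = _site_pd_batch(arrays, F)

    Dfull = dist.loc[arrays.tips, arrays.tips].to_numpy()
    mpd_vals = np.full(len(comm), np.nan)
    vpd_vals = np.full(len(comm), np.nan)
    for i in range(len(comm)):
        idx = np.flatnonzero(F[:, i] > 0)
        if idx.size < 2:
            continue
        f = F[idx, i]
        D = Dfull[np.ix_(idx, idx)]
        wsum = 0.5 * (f.sum() ** 2 - (f**2).sum())
        m1 = 0.5 * (f @ D @ f) / wsum
        m2 = 0.5 * (f @ (D**2) @ f) / wsum
        mpd_vals[i] = m1
        vpd_vals[i] = max(m2 - m1**2, 0.0)

    return pd.DataFrame(
        {"S": S.astype(int), "PD": pd_vals, "MPD": mpd_vals, "VPD": vpd_vals},
        index=comm.index.copy(),
    )


def write_diversity_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", index_label="site")
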