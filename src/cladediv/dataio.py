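"""Phylogeny, community-matrix and clade-map I/O.

Trees are :class:`dendropy.Tree` objects (rooted, branch lengths required,
polytomies allowed). Community matrices are pandas DataFrames with sites in
rows and species in columns; values are raw covers/abundances — normalization
to proportions happens inside the metric and index functions, never at read
time. Clade maps are plain ``dict`` objects mapping species name to clade
label.

Depths and heights are measured from the tips (height 0 at the tips); trees
need not be ultrametric unless an operation states so.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "read_newick",
    "tree_from_string",
    "write_newick",
    "prune_to_taxa",
    "pairwise_distances",
    "read_community",
    "read_clade_map",
    "tip_labels",
    "tree_height",
    "TreeDataError",
]


class TreeDataError(ValueError):
    """Raised for malformed or inconsistent tree/community/clade-map input."""


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    leaves = [lf for lf in tree.leaf_node_iter()]
    if not leaves:
        raise TreeDataError("tree has no tips")
    labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
    if any(lab is None for lab in labels):
        raise TreeDataError("tree contains an unlabeled tip")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TreeDataError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue  # root stem length is optional and ignored
        if nd.edge.length is None:
            where = nd.taxon.label if nd.taxon is not None else "an internal node"
            raise TreeDataError(f"missing branch length above {where}")
        if nd.edge.length < 0:
            where = nd.taxon.label if nd.taxon is not None else "an internal node"
            raise TreeDataError(f"negative branch length above {where}")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read one rooted Newick tree with branch lengths.

    Polytomies are retained; duplicate tip labels or missing branch lengths
    raise :class:`TreeDataError` naming the offender.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeDataError(f"could not parse Newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def tree_from_string(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeDataError(f"could not parse Newick string: {exc}") from exc
    return _validate_tree(tree)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in tree (leaf-iteration) order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum tip depth (root-to-tip path length)."""
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Restrict a tree to ``taxa``.

    Unary nodes introduced by pruning are suppressed with their path lengths
    summed; the returned tree is rooted at the most recent common ancestor of
    ``taxa`` with no stem edge above it. Pairwise patristic distances among
    the retained taxa are unchanged.
    """
    taxa = set(taxa)
    present = set(tip_labels(tree))
    missing = sorted(taxa - present)
    if missing:
        raise TreeDataError(f"taxa not in tree: {', '.join(missing)}")
    if len(taxa) < 2:
        raise TreeDataError("need at least 2 taxa to prune to")
    sub = tree.extract_tree_with_taxa_labels(
        labels=taxa, suppress_unifurcations=True
    )
    # drop any residual stem above the MRCA of the retained taxa
    while len(sub.seed_node.child_nodes()) == 1:
        child = sub.seed_node.child_nodes()[0]
        sub.seed_node.remove_child(child)
        sub.seed_node = child
    sub.seed_node.edge.length = None
    sub.seed_node.parent_node = None
    return sub


def pairwise_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix.

    Entry (j, k) is the sum of branch lengths along the tree path between
    tips j and k; on an ultrametric tree this is twice the divergence time.
    """
    labels = tip_labels(tree)
    if len(labels) < 2:
        raise TreeDataError("pairwise distances need at least 2 tips")
    M = _tip_edge_matrix(tree)  # tips x edges, entries sqrt(edge length)
    shared = np.asarray((M @ M.T).todense())  # root-to-MRCA path lengths
    depth = np.diag(shared)
    d = depth[:, None] + depth[None, :] - 2.0 * shared
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0  # numerical dust from the sqrt factorization
    return pd.DataFrame(d, index=labels, columns=labels)


def _tip_edge_matrix(tree: dendropy.Tree) -> sp.csr_matrix:
    """Sparse tips × edges matrix with sqrt(edge length) where the edge lies
    on the tip's root path. ``M @ M.T`` then gives shared root-path lengths."""
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    lengths = np.zeros(len(nodes))
    for nd in nodes[1:]:
        lengths[index[id(nd)]] = nd.edge.length or 0.0
    rows, cols, vals = [], [], []
    tip_i = 0
    sqrt_len = np.sqrt(lengths)
    for lf in tree.leaf_node_iter():
        nd = lf
        while nd is not None:
            j = index[id(nd)]
            if sqrt_len[j] > 0 or nd is not tree.seed_node:
                rows.append(tip_i)
                cols.append(j)
                vals.append(sqrt_len[j])
            nd = nd.parent_node
        tip_i += 1
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(tip_i, len(nodes)), dtype=float
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype_backend="numpy_nullable")


def read_community(path: str | Path) -> pd.DataFrame:
    """Read a sites × species abundance/cover table (TSV or CSV).

    First column is the site id; remaining columns are species. Blank/NA
    cells become 0. Negative values, duplicate species columns and duplicate
    site ids are rejected.
    """
    # inspect the raw header: pandas silently mangles duplicate column names
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    species_header = header[1:]
    dup = {s for s in species_header if species_header.count(s) > 1}
    if dup:
        raise TreeDataError(f"duplicate species columns: {', '.join(sorted(dup))}")
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise TreeDataError("community table needs a site-id column and at least one species")
    site_col = raw.columns[0]
    comm = raw.set_index(site_col)
    if comm.index.duplicated().any():
        dups = comm.index[comm.index.duplicated()].unique().tolist()
        raise TreeDataError(f"duplicate site ids: {dups}")
    comm = comm.astype(float).fillna(0.0)
    if (comm.values < 0).any():
        ii, jj = np.argwhere(comm.values < 0)[0]
        raise TreeDataError(
            f"negative abundance for species {comm.columns[jj]!r} at site {comm.index[ii]!r}"
        )
    empty = comm.index[(comm.values > 0).sum(axis=1) == 0].tolist()
    if empty:
        raise TreeDataError(f"sites with no positive abundance: {empty}")
    comm.index = comm.index.astype(str)
    comm.index.name = "site"
    return comm


def read_clade_map(path: str | Path) -> dict[str, str]:
    """Read a two-column species→clade table (header ``species<TAB>clade``)."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise TreeDataError("clade map needs two columns: species, clade")
    mapping: dict[str, str] = {}
    for sp_name, clade in zip(raw.iloc[:, 0].astype(str), raw.iloc[:, 1].astype(str)):
        if sp_name in mapping and mapping[sp_name] != clade:
            raise TreeDataError(
                f"species {sp_name!r} mapped to conflicting clades "
                f"{mapping[sp_name]!r} and {clade!r}"
            )
        mapping[sp_name] = clade
    return mapping


def check_species_coverage(
    comm: pd.DataFrame,
    known: Iterable[str],
    *,
    allow_drop: bool = False,
    what: str = "reference",
) -> pd.DataFrame:
    """Ensure every species with positive abundance is in ``known``.

    Unknown species raise :class:`TreeDataError` unless ``allow_drop`` is
    set, in which case their columns are removed (names reported through
    the module logger).
    """
    known = set(known)
    present = [s for s in comm.columns if comm[s].gt(0).any()]
    unknown = sorted(set(present) - known)
    if not unknown:
        return comm
    if not allow_drop:
        raise TreeDataError(
            f"species missing from {what}: {', '.join(unknown)}"
        )
    import logging

    logging.getLogger(__name__).warning(
        "dropping %d species missing from %s: %s", len(unknown), what, ", ".join(unknown)
    )
    return comm.drop(columns=unknown)
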