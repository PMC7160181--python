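"""Simulation workflow: random communities on phylogenies.

Reproduces the factorial simulation design used to evaluate the clade
indices: species pools sampled at random from a phylogeny at several
"phylogenetic scales" (trees of increasing inclusiveness), random community
matrices across species-richness ranges, per-matrix metric and index tables,
and per-matrix fit accuracies (R²).

Self-contained generators are included so everything runs without external
trees: Yule (pure-birth) trees, nested monophyletic subclades of one tree as
phylogenetic scales, and clade maps obtained by cutting an ultrametric tree
at a fixed height above the tips (a synthetic analogue of family-level
assignment).

Seed discipline: a master seed is combined with each design-cell label
(scale / pool size / richness range / replicate) through a stable hash, so
any cell can be regenerated in isolation and runs are reproducible
end-to-end.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .clade_indices import clade_index_table, summarize_pool
from .dataio import (
    TreeDataError,
    pairwise_distances,
    prune_to_taxa,
    tip_labels,
    tree_height,
)
from .evaluation import DegenerateFitError, fit_linear
from .phylo_metrics import diversity_table

__all__ = [
    "simulate_yule_tree",
    "rescale_tree_height",
    "nested_scale_trees",
    "sample_species_pool",
    "generate_community_matrix",
    "clade_map_from_tree",
    "SimulationConfig",
    "run_factorial",
    "derive_seed",
]


def derive_seed(master_seed: int, *labels) -> int:
    """Stable per-cell seed below 2^31 from a master seed and cell labels."""
    key = "|".join([str(master_seed), *map(str, labels)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_yule_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with uniquely labeled tips."""
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(int(seed)),
    )
    tree.seed_node.edge.length = None
    return tree


def rescale_tree_height(tree: dendropy.Tree, height: float) -> dendropy.Tree:
    """Rescale all branch lengths in place so the tree height equals ``height``.

    Used to set the depth of a phylogenetic scale. Rescaling by itself leaves
    all fits invariant; depth matters only relative to a fixed clade cut
    height, which is exactly how a fixed-age taxonomic cut (e.g. families)
    sits in clades of very different crown ages.
    """
    if height <= 0:
        raise ValueError("target height must be positive")
    factor = height / tree_height(tree)
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= factor
    return tree


def nested_scale_trees(
    tree: dendropy.Tree, target_sizes: Sequence[int]
) -> dict[str, dendropy.Tree]:
    """Nested monophyletic subtrees approximating the requested tip counts.

    Walks from the root along the chain of largest children and, for each
    target size (descending), extracts the smallest chain clade with at
    least that many tips, so a scale never undershoots its target. Emulates
    nested phylogenetic scales (e.g. vascular plants ⊃ angiosperms ⊃
    superasterids): deeper scales keep more basal structure. Returned dict
    maps "scale_1" (largest) … to trees, largest first.
    """
    targets = sorted(set(int(t) for t in target_sizes), reverse=True)
    if any(t < 2 for t in targets):
        raise ValueError("scale sizes must be >= 2")
    n_total = len(tree.leaf_node_iter_count()) if hasattr(tree, "leaf_node_iter_count") else sum(
        1 for _ in tree.leaf_node_iter()
    )
    if targets[0] > n_total:
        raise ValueError(
            f"largest scale size {targets[0]} exceeds tree size {n_total}"
        )
    # chain of nested clades from the root, descending into the largest child
    chain: list[tuple[int, dendropy.Node]] = []
    node = tree.seed_node
    while True:
        size = sum(1 for _ in node.leaf_iter())
        chain.append((size, node))
        children = node.child_nodes()
        if not children:
            break
        node = max(children, key=lambda c: sum(1 for _ in c.leaf_iter()))
    out: dict[str, dendropy.Tree] = {}
    used: set[int] = set()
    for i, target in enumerate(targets, start=1):
        candidates = [c for c in chain if id(c[1]) not in used and c[0] >= target]
        if not candidates:  # only smaller clades left; take the largest unused
            candidates = [c for c in chain if id(c[1]) not in used and c[0] >= 2]
        best = min(candidates, key=lambda c: abs(c[0] - target))
        used.add(id(best[1]))
        labels = [lf.taxon.label for lf in best[1].leaf_iter()]
        out[f"scale_{i}"] = prune_to_taxa(tree, labels)
    return out


def sample_species_pool(
    tree: dendropy.Tree, size: int, seed: int | np.random.Generator
) -> tuple[list[str], dendropy.Tree]:
    """Uniform random species pool (without replacement) plus its pruned tree."""
    labels = sorted(tip_labels(tree))
    if not 2 <= size <= len(labels):
        raise ValueError(
            f"pool size must be between 2 and the number of tips ({len(labels)}); got {size}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool = sorted(rng.choice(labels, size=size, replace=False).tolist())
    return pool, prune_to_taxa(tree, pool)


def generate_community_matrix(
    pool: Sequence[str],
    richness_range: tuple[int, int],
    n_sites: int,
    seed: int | np.random.Generator,
    *,
    proportion_model: str = "dirichlet",
) -> pd.DataFrame:
    """Random community matrix over a species pool.

    Per site: richness S drawn uniformly from the inclusive integer range,
    S species drawn uniformly without replacement, proportions over those
    species drawn from a flat Dirichlet (uniform on the simplex; the
    "uniform" model instead normalizes iid U(0,1) draws). Rows sum to 1.
    """
    lo, hi = int(richness_range[0]), int(richness_range[1])
    if not 1 <= lo <= hi <= len(pool):
        raise ValueError(
            f"richness range ({lo}, {hi}) invalid for pool of {len(pool)} species"
        )
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if proportion_model not in {"dirichlet", "uniform"}:
        raise ValueError(f"unknown proportion model: {proportion_model!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool = list(pool)
    values = np.zeros((n_sites, len(pool)))
    for i in range(n_sites):
        s = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(pool), size=s, replace=False)
        if proportion_model == "dirichlet":
            props = rng.dirichlet(np.ones(s))
        else:
            draws = rng.uniform(size=s)
            props = draws / draws.sum()
        values[i, chosen] = props
    width = len(str(n_sites))
    idx = pd.Index([f"site_{i + 1:0{width}d}" for i in range(n_sites)], name="site")
    return pd.DataFrame(values, index=idx, columns=pool)


def clade_map_from_tree(tree: dendropy.Tree, cut_depth: float) -> dict[str, str]:
    """Clades from cutting an ultrametric tree at a height above the tips.

    Clades are the tip sets of the lineages crossing height ``cut_depth``
    (tips at height 0): a monophyletic partition of all tips. A cut just
    above 0 makes every tip its own clade; just below the tree height, one
    clade.
    """
    height = tree_height(tree)
    if not 0 < cut_depth < height:
        raise ValueError(
            f"cut depth must lie strictly between 0 and the tree height ({height:.6g})"
        )
    depths = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depths[id(nd)] = depths[id(nd.parent_node)] + (nd.edge.length or 0.0)
    tip_depths = [depths[id(lf)] for lf in tree.leaf_node_iter()]
    if max(tip_depths) - min(tip_depths) > 1e-6 * max(height, 1.0):
        raise TreeDataError("clade cutting requires an ultrametric tree")
    # node height above tips = tree height - depth from root
    mapping: dict[str, str] = {}
    counter = 0
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            h_node = height
            h_parent = np.inf
        else:
            h_node = height - depths[id(nd)]
            h_parent = height - depths[id(nd.parent_node)]
        if h_node <= cut_depth < h_parent:
            counter += 1
            label = f"clade_{counter:04d}"
            for lf in nd.leaf_iter():
                mapping[lf.taxon.label] = label
    return mapping


@dataclass
class SimulationConfig:
    """Factorial design for the simulation workflow.

    pool_sizes and richness_ranges are fully crossed within every
    phylogenetic scale; each cell gets ``n_matrices_per_cell`` replicate
    (pool, community-matrix) pairs of ``n_sites`` sites. ``clade_cut_depth``
    is the absolute height above the tips at which each scale tree is cut to
    define clades.
    """

    pool_sizes: list[int]
    richness_ranges: list[tuple[int, int]]
    n_matrices_per_cell: int = 50
    n_sites: int = 240
    clade_cut_depth: float = 1.0
    master_seed: int = 0
    proportion_model: str = "dirichlet"

    def validate(self, trees: Mapping[str, dendropy.Tree]) -> None:
        if not trees:
            raise ValueError("at least one phylogenetic scale tree is required")
        if self.n_matrices_per_cell < 1 or self.n_sites < 1:
            raise ValueError("replicate and site counts must be >= 1")
        n_tips = {name: sum(1 for _ in t.leaf_node_iter()) for name, t in trees.items()}
        for ps in self.pool_sizes:
            for name, n in n_tips.items():
                if ps > n:
                    raise ValueError(
                        f"pool size {ps} exceeds the {n} tips of scale {name!r}"
                    )
        for lo, hi in self.richness_ranges:
            if not 1 <= lo <= hi:
                raise ValueError(f"invalid richness range ({lo}, {hi})")
            if hi > min(self.pool_sizes):
                raise ValueError(
                    f"richness range ({lo}, {hi}) exceeds smallest pool size "
                    f"{min(self.pool_sizes)}"
                )
        for name, t in trees.items():
            if not 0 < self.clade_cut_depth < tree_height(t):
                raise ValueError(
                    f"clade cut depth {self.clade_cut_depth} outside (0, height) "
                    f"for scale {name!r}"
                )

    @classmethod
    def paper_design(cls, **overrides) -> "SimulationConfig":
        """The published factorial: pools 2000/500/250, six richness ranges,
        50 matrices of 240 sites per cell."""
        base = dict(
            pool_sizes=[2000, 500, 250],
            richness_ranges=[(10, 160), (10, 80), (10, 40), (10, 20), (5, 10), (2, 5)],
            n_matrices_per_cell=50,
            n_sites=240,
        )
        base.update(overrides)
        return cls(**base)


def _range_label(rng_pair: tuple[int, int]) -> str:
    return f"{rng_pair[0]}-{rng_pair[1]}"


def run_factorial(
    trees: Mapping[str, dendropy.Tree],
    config: SimulationConfig,
    *,
    compute: str = "full",
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the factorial simulation.

    For every (scale × pool size × richness range × replicate) cell a fresh
    species pool and community matrix are generated. With ``compute="full"``
    the phylogeny-based metrics, clade indices and the three fit accuracies
    are computed per matrix (sqrt-PD ~ CRI, MPD ~ CDI, log-VPD ~ CRG);
    ``compute="generate"`` only generates and counts. Degenerate fits are
    recorded as NA with the reason in the ``note`` column.

    Returns the results table with one row per cell (columns scale,
    pool_size, richness_range, replicate, n_sites, r2_richness,
    r2_divergence, r2_regularity, note). With ``out_dir`` set, per-matrix
    metric+index tables and the master ``results_r2.tsv`` are written there.
    """
    if compute not in {"full", "generate"}:
        raise ValueError("compute must be 'full' or 'generate'")
    config.validate(trees)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    scale_maps: dict[str, dict[str, str]] = {}
    if compute == "full":
        for name, t in trees.items():
            scale_maps[name] = clade_map_from_tree(t, config.clade_cut_depth)

    rows = []
    for scale_name, scale_tree in trees.items():
        for pool_size in config.pool_sizes:
            for rng_pair in config.richness_ranges:
                for rep in range(1, config.n_matrices_per_cell + 1):
                    label = (scale_name, pool_size, _range_label(rng_pair), rep)
                    seed = derive_seed(config.master_seed, *label)
                    rng = np.random.default_rng(seed)
                    pool_labels = sorted(
                        rng.choice(
                            sorted(tip_labels(scale_tree)),
                            size=pool_size,
                            replace=False,
                        ).tolist()
                    )
                    comm = generate_community_matrix(
                        pool_labels,
                        rng_pair,
                        config.n_sites,
                        rng,
                        proportion_model=config.proportion_model,
                    )
                    row = dict(
                        scale=scale_name,
                        pool_size=pool_size,
                        richness_range=_range_label(rng_pair),
                        replicate=rep,
                        n_sites=len(comm),
                        seed=seed,
                        r2_richness=np.nan,
                        r2_divergence=np.nan,
                        r2_regularity=np.nan,
                        note="",
                    )
                    if compute == "full":
                        pool_tree = prune_to_taxa(scale_tree, pool_labels)
                        clade_map = {
                            s: scale_maps[scale_name][s] for s in pool_labels
                        }
                        div = diversity_table(pool_tree, comm)
                        pool_summary = summarize_pool(clade_map, pool_labels)
                        idx = clade_index_table(comm, clade_map, pool=pool_summary)
                        notes = []
                        for key, resp, transform, pred in (
                            ("r2_richness", "PD", "sqrt", "clade_richness_index"),
                            ("r2_divergence", "MPD", "none", "clade_divergence_index"),
                            ("r2_regularity", "VPD", "log", "clade_regularity_index"),
                        ):
                            try:
                                fit = fit_linear(
                                    idx[pred], div[resp], transform=transform
                                )
                                row[key] = fit.r_squared
                            except DegenerateFitError as exc:
                                notes.append(f"{key}: {exc}")
                        row["note"] = "; ".join(notes)
                        if out_dir is not None:
                            tab = div.join(idx.drop(columns="S"))
                            fname = (
                                f"{scale_name}_pool{pool_size}_"
                                f"rng{_range_label(rng_pair)}_rep{rep:03d}.tsv"
                            )
                            tab.to_csv(
                                out_dir / fname, sep="\t", na_rep="NA",
                                index_label="site",
                            )
                    rows.append(row)
    results = pd.DataFrame(rows)
    if out_dir is not None:
        results.to_csv(out_dir / "results_r2.tsv", sep="\t", na_rep="NA", index=False)
    return results
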