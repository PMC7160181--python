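"""Clade indices: phylogeny-free surrogates for phylogenetic diversity.

The three indices summarize the clade composition of a plot relative to a
species pool. They need only a species→clade map (e.g. family membership)
and per-plot abundances — no tree:

* clade richness index   CRI = log(S) + 3 * sum_i(p_i / CR_i)
* clade divergence index CDI = 1 - sum_i((p_i - 1/CR_SP)^2)
* clade regularity index CRG = 1 - sum_i((p_i - CR_i/S_SP)^2)

with S the plot species richness, p_i the relative abundance of clade i in
the plot, CR_i the species richness of clade i in the pool, CR_SP the number
of pool clades, and S_SP the pool species richness. Logs are natural.

CRI rewards cover of species-poor clades (whose members tend to be distant
relatives of the rest of the plot) and grows with S. CDI peaks at 1 when all
pool clades are present in equal proportions and is always in (0, 1]. CRG
peaks at 1 when clade proportions match relative clade richness in the pool;
it can go negative for extreme proportions and is never clipped.

Sums run over all pool clades by default, absent clades contributing
(0 - optimum)^2; ``include_absent=False`` restricts to clades present in the
plot for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PoolSummary",
    "summarize_pool",
    "clade_proportions",
    "clade_richness_index",
    "clade_divergence_index",
    "clade_regularity_index",
    "clade_index_table",
]


@dataclass(frozen=True)
class PoolSummary:
    """Clade richness bookkeeping for a species pool.

    clade_richness maps clade -> CR_i (number of pool species in the clade);
    cr_sp is the number of pool clades and s_sp the pool species richness.
    """

    clade_richness: dict[str, int]

    @property
    def cr_sp(self) -> int:
        return len(self.clade_richness)

    @property
    def s_sp(self) -> int:
        return sum(self.clade_richness.values())

    @property
    def clades(self) -> list[str]:
        return list(self.clade_richness)


def summarize_pool(
    clade_map: Mapping[str, str], pool_species: Iterable[str]
) -> PoolSummary:
    """Count pool species per clade.

    Every pool species must be mapped; unmapped species are reported in the
    error. The conventional pool is every species appearing in the dataset.
    """
    pool = sorted(set(pool_species))
    if not pool:
        raise ValueError("empty species pool")
    unmapped = [s for s in pool if s not in clade_map]
    if unmapped:
        raise ValueError(f"species missing from clade map: {', '.join(unmapped)}")
    counts: dict[str, int] = {}
    for s in pool:
        counts[clade_map[s]] = counts.get(clade_map[s], 0) + 1
    return PoolSummary(clade_richness=counts)


def clade_proportions(
    site_abundances: Mapping[str, float],
    clade_map: Mapping[str, str],
    pool: PoolSummary,
) -> dict[str, float]:
    """Relative abundance p_i of each pool clade in one plot.

    Clades in the pool but absent from the plot get p_i = 0; proportions sum
    to 1. Raises on zero total abundance or an unmapped plot species.
    """
    p = {c: 0.0 for c in pool.clade_richness}
    total = 0.0
    for s, a in site_abundances.items():
        if a < 0:
            raise ValueError(f"negative abundance for {s!r}")
        if a == 0:
            continue
        if s not in clade_map:
            raise ValueError(f"species missing from clade map: {s}")
        clade = clade_map[s]
        if clade not in p:
            raise ValueError(f"clade {clade!r} of species {s!r} not in pool")
        p[clade] += float(a)
        total += float(a)
    if total == 0:
        raise ValueError("site has zero total abundance")
    return {c: v / total for c, v in p.items()}


def clade_richness_index(
    S: int, p: Mapping[str, float], pool: PoolSummary
) -> float:
    """log(S) + 3 * sum_i(p_i / CR_i). Surrogate for (sqrt-)Faith's PD."""
    if S < 1:
        raise ValueError("site species richness must be >= 1")
    acc = sum(p.get(c, 0.0) / cr for c, cr in pool.clade_richness.items())
    return math.log(S) + 3.0 * acc


def clade_divergence_index(
    p: Mapping[str, float], pool: PoolSummary, *, include_absent: bool = True
) -> float:
    """1 - sum_i((p_i - 1/CR_SP)^2). Surrogate for MPD; in (0, 1]."""
    opt = 1.0 / pool.cr_sp
    clades = pool.clades if include_absent else [c for c in pool.clades if p.get(c, 0.0) > 0]
    return 1.0 - sum((p.get(c, 0.0) - opt) ** 2 for c in clades)


def clade_regularity_index(
    p: Mapping[str, float], pool: PoolSummary, *, include_absent: bool = True
) -> float:
    """1 - sum_i((p_i - CR_i/S_SP)^2). Surrogate for (log-)VPD; <= 1, can be
    negative for extreme proportions (returned unclipped)."""
    s_sp = pool.s_sp
    clades = pool.clades if include_absent else [c for c in pool.clades if p.get(c, 0.0) > 0]
    return 1.0 - sum(
        (p.get(c, 0.0) - pool.clade_richness[c] / s_sp) ** 2 for c in clades
    )


def clade_index_table(
    comm: pd.DataFrame,
    clade_map: Mapping[str, str],
    *,
    pool: PoolSummary | None = None,
    include_absent: bool = True,
) -> pd.DataFrame:
    """Per-site S and the three clade indices for a community matrix.

    The pool defaults to all species with positive abundance anywhere in
    ``comm``. Computing indices at a different clade resolution means
    swapping ``clade_map`` only.
    """
    values = comm.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundance in community matrix")
    species = list(comm.columns)
    if pool is None:
        present = [s for s in species if comm[s].gt(0).any()]
        pool = summarize_pool(clade_map, present)

    unmapped = sorted(
        {s for s in species if comm[s].gt(0).any() and s not in clade_map}
    )
    if unmapped:
        raise ValueError(f"species missing from clade map: {', '.join(unmapped)}")

    # species -> clade column aggregation, vectorized over sites
    clades = pool.clades
    clade_pos = {c: i for i, c in enumerate(clades)}
    agg = np.zeros((len(species), len(clades)))
    for j, s in enumerate(species):
        c = clade_map.get(s)
        if c in clade_pos:
            agg[j, clade_pos[c]] = 1.0
    clade_abund = values @ agg
    totals = values.sum(axis=1)
    if (totals == 0).any():
        bad = comm.index[totals == 0].tolist()
        raise ValueError(f"sites with zero total abundance: {bad}")
    stray = values @ (1.0 - agg.sum(axis=1))
    if (stray > 0).any():
        bad = comm.index[stray > 0].tolist()
        raise ValueError(f"sites with species outside the pool clades: {bad}")
    P = clade_abund / totals[:, None]
    S = (values > 0).sum(axis=1)

    cr = np.array([pool.clade_richness[c] for c in clades], dtype=float)
    cri = np.log(S) + 3.0 * (P / cr).sum(axis=1)
    present_mask = (P > 0) if not include_absent else np.ones_like(P, dtype=bool)
    cdi = 1.0 - (present_mask * (P - 1.0 / pool.cr_sp) ** 2).sum(axis=1)
    crg = 1.0 - (present_mask * (P - cr / pool.s_sp) ** 2).sum(axis=1)

    return pd.DataFrame(
        {
            "S": S.astype(int),
            "clade_richness_index": cri,
            "clade_divergence_index": cdi,
            "clade_regularity_index": crg,
        },
        index=comm.index.copy(),
    )


def write_clade_index_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", na_rep="NA", index_label="site")
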