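import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladediv import (
    PoolSummary,
    clade_divergence_index,
    clade_index_table,
    clade_proportions,
    clade_regularity_index,
    clade_richness_index,
    summarize_pool,
)


class TestPoolSummary:
    def test_counts(self):
        cm = {f"s{i}": c for i, c in enumerate("aaaabbbccd")}
        pool = summarize_pool(cm, cm.keys())
        assert pool.cr_sp == 4
        assert pool.s_sp == 10
        assert sorted(pool.clade_richness.values(), reverse=True) == [4, 3, 2, 1]

    def test_single_clade(self):
        pool = summarize_pool({"x": "c", "y": "c"}, ["x", "y"])
        assert pool.cr_sp == 1

    def test_unmapped_species_listed(self):
        with pytest.raises(ValueError, match="q1"):
            summarize_pool({"x": "c"}, ["x", "q1"])


class TestCladeProportions:
    def test_worked_example(self):
        cm = {"A": "f1", "B": "f1", "C": "f2"}
        pool = summarize_pool(cm, ["A", "B", "C"])
        p = clade_proportions({"A": 30, "B": 30, "C": 40}, cm, pool)
        assert p == {"f1": pytest.approx(0.6), "f2": pytest.approx(0.4)}

    def test_single_species_site(self):
        cm = {"A": "f1", "B": "f2"}
        pool = summarize_pool(cm, ["A", "B"])
        p = clade_proportions({"A": 5.0}, cm, pool)
        assert p == {"f1": 1.0, "f2": 0.0}

    def test_proportions_sum_to_one(self, rng):
        cm = {f"s{i}": f"c{i % 3}" for i in range(9)}
        pool = summarize_pool(cm, cm.keys())
        for _ in range(10):
            ab = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0, 2, 9))}
            p = clade_proportions(ab, cm, pool)
            assert sum(p.values()) == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        cm = {"A": "f1"}
        pool = summarize_pool(cm, ["A"])
        with pytest.raises(ValueError, match="zero total"):
            clade_proportions({"A": 0.0}, cm, pool)


class TestWorkedArithmetic:
    def test_richness_singleton_case(self):
        pool = PoolSummary({"c": 1})
        assert clade_richness_index(1, {"c": 1.0}, pool) == pytest.approx(3.0)

    def test_richness_two_clade_case(self):
        pool = PoolSummary({"c1": 10, "c2": 2})
        v = clade_richness_index(4, {"c1": 0.6, "c2": 0.4}, pool)
        assert v == pytest.approx(2.166294, abs=1e-6)

    def test_richness_rises_when_cover_moves_to_poor_clade(self):
        pool = PoolSummary({"rich": 50, "poor": 5})
        skewed = clade_richness_index(10, {"rich": 0.9, "poor": 0.1}, pool)
        even = clade_richness_index(10, {"rich": 0.5, "poor": 0.5}, pool)
        assert skewed == pytest.approx(2.416585, abs=1e-6)
        assert even == pytest.approx(2.632585, abs=1e-6)
        assert even > skewed

    @pytest.mark.parametrize(
        "p, expected",
        [
            ({"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25}, 1.0),
            ({"a": 1.0}, 0.25),
            ({"a": 0.5, "b": 0.5}, 0.75),
        ],
    )
    def test_divergence_four_clades(self, p, expected):
        pool = PoolSummary({"a": 1, "b": 1, "c": 1, "d": 1})
        assert clade_divergence_index(p, pool) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p, expected",
        [
            ({"a": 0.4, "b": 0.3, "c": 0.2, "d": 0.1}, 1.0),
            ({"a": 0.4, "b": 0.3, "c": 0.3}, 0.98),
            ({"d": 1.0}, -0.10),
        ],
    )
    def test_regularity_including_negative_values(self, p, expected):
        pool = PoolSummary({"a": 4, "b": 3, "c": 2, "d": 1})
        assert clade_regularity_index(p, pool) == pytest.approx(expected)

    def test_singleton_site_chain(self):
        # one species, in the 1-species clade of a 2-clade pool CR = (9, 1)
        pool = PoolSummary({"big": 9, "solo": 1})
        p = {"big": 0.0, "solo": 1.0}
        assert clade_richness_index(1, p, pool) == pytest.approx(3.0)
        assert clade_divergence_index(p, pool) == pytest.approx(0.5)
        assert clade_regularity_index(p, pool) == pytest.approx(-0.62)


def _random_pool_and_simplex(rng, k=None):
    k = k or int(rng.integers(2, 8))
    cr = {f"c{i}": int(rng.integers(1, 20)) for i in range(k)}
    pool = PoolSummary(cr)
    p = rng.dirichlet(np.ones(k))
    return pool, {f"c{i}": float(p[i]) for i in range(k)}


class TestIndexProperties:
    def test_divergence_bounds_on_random_simplex(self, rng):
        """CDI in (0, 1] for any proportions: the squared deviation from the
        uniform optimum is at most 1 - 1/CR_SP < 1."""
        for _ in range(200):
            pool, p = _random_pool_and_simplex(rng)
            v = clade_divergence_index(p, pool)
            assert 0.0 < v <= 1.0 + 1e-12

    def test_divergence_is_one_iff_uniform(self, rng):
        pool, p = _random_pool_and_simplex(rng, k=5)
        uniform = {c: 1 / 5 for c in pool.clades}
        assert clade_divergence_index(uniform, pool) == pytest.approx(1.0, abs=1e-15)
        skew = dict(uniform, c0=0.3, c1=0.1)
        assert clade_divergence_index(skew, pool) < 1.0

    def test_regularity_is_one_iff_richness_proportional(self):
        pool = PoolSummary({"a": 7, "b": 2, "c": 1})
        match = {c: n / 10 for c, n in pool.clade_richness.items()}
        assert clade_regularity_index(match, pool) == pytest.approx(1.0, abs=1e-15)
        assert clade_regularity_index({"a": 1.0}, pool) < 1.0

    def test_richness_index_increasing_in_s(self, rng):
        pool, p = _random_pool_and_simplex(rng)
        vals = [clade_richness_index(s, p, pool) for s in (1, 2, 5, 17)]
        assert vals == sorted(vals)
        assert len(set(vals)) == 4

    def test_richness_index_rewards_poor_clades(self, rng):
        """Moving cover from a species-richer to a species-poorer clade
        increases the richness index."""
        for _ in range(50):
            pool, p = _random_pool_and_simplex(rng, k=4)
            cr = pool.clade_richness
            rich = max(cr, key=cr.get)
            poor = min(cr, key=cr.get)
            if cr[rich] == cr[poor] or p[rich] < 0.05:
                continue
            shifted = dict(p)
            shifted[rich] -= 0.05
            shifted[poor] += 0.05
            assert clade_richness_index(8, shifted, pool) > clade_richness_index(
                8, p, pool
            )

    @given(st.floats(min_value=0.01, max_value=1000.0))
    @settings(max_examples=25, deadline=None)
    def test_indices_depend_only_on_proportions(self, c):
        comm = pd.DataFrame(
            {"A": [3.0], "B": [1.0], "C": [2.0]}, index=["s1"]
        )
        cm = {"A": "f1", "B": "f1", "C": "f2"}
        base = clade_index_table(comm, cm)
        scaled = clade_index_table(comm * c, cm)
        pd.testing.assert_frame_equal(base, scaled, check_exact=False, atol=1e-12)


class TestCladeIndexTable:
    def test_row_per_site_and_duplicates_identical(self):
        rng = np.random.default_rng(1)
        species = [f"s{i}" for i in range(12)]
        cm = {s: f"c{i % 4}" for i, s in enumerate(species)}
        values = rng.uniform(0, 1, size=(20, 12))
        values[10] = values[0]  # duplicate site
        comm = pd.DataFrame(values, columns=species,
                            index=[f"p{i}" for i in range(20)])
        tab = clade_index_table(comm, cm)
        assert len(tab) == 20
        pd.testing.assert_series_equal(
            tab.loc["p0"], tab.loc["p10"], check_names=False
        )

    def test_matches_scalar_functions(self):
        rng = np.random.default_rng(2)
        species = [f"s{i}" for i in range(10)]
        cm = {s: f"c{i % 3}" for i, s in enumerate(species)}
        comm = pd.DataFrame(
            rng.uniform(0, 1, size=(5, 10)), columns=species,
            index=[f"p{i}" for i in range(5)],
        )
        pool = summarize_pool(cm, species)
        tab = clade_index_table(comm, cm, pool=pool)
        for site in comm.index:
            ab = comm.loc[site].to_dict()
            p = clade_proportions(ab, cm, pool)
            s = int((comm.loc[site] > 0).sum())
            assert tab.loc[site, "clade_richness_index"] == pytest.approx(
                clade_richness_index(s, p, pool)
            )
            assert tab.loc[site, "clade_divergence_index"] == pytest.approx(
                clade_divergence_index(p, pool)
            )
            assert tab.loc[site, "clade_regularity_index"] == pytest.approx(
                clade_regularity_index(p, pool)
            )

    def test_finer_resolution_swaps_in_by_map_only(self):
        """Re-running with a finer clade map is the whole resolution switch."""
        rng = np.random.default_rng(3)
        species = [f"s{i}" for i in range(12)]
        coarse = {s: f"order{i % 2}" for i, s in enumerate(species)}
        fine = {s: f"family{i % 6}" for i, s in enumerate(species)}
        comm = pd.DataFrame(
            rng.uniform(0, 1, size=(6, 12)), columns=species,
            index=[f"p{i}" for i in range(6)],
        )
        t_coarse = clade_index_table(comm, coarse)
        t_fine = clade_index_table(comm, fine)
        assert (t_coarse["S"] == t_fine["S"]).all()
        assert not np.allclose(
            t_coarse["clade_divergence_index"], t_fine["clade_divergence_index"]
        )

    def test_unmapped_species_rejected(self):
        comm = pd.DataFrame({"A": [1.0], "B": [1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="B"):
            clade_index_table(comm, {"A": "f1"})
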