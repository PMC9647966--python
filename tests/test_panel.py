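"""Discernibility scoring and randomized panel-selection simulation."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

import snpanel as sp
from snpanel.model import Call
from snpanel.panel import (
    SimulationConfig,
    discernibility,
    efficiency_curve,
    exhaustive_best,
    genotype_string,
    minimal_panel_size,
    simulate_combinations,
)

from conftest import build_matrix, random_matrix


def oracle_n_unique(matrix, panel):
    """Independent recount: distinct call tuples over the panel columns."""
    cols = [matrix.column(m) for m in panel]
    return len({tuple(int(c[i]) for c in cols) for i in range(matrix.n_samples)})


class TestGenotypeString:
    def test_token_encoding(self):
        m = build_matrix([[Call.HOM_REF, Call.HET]],
                         ref_alts=[("A", "G"), ("C", "T")])
        gs = genotype_string(m, "s1", ["m1", "m2"])
        assert gs.tokens == ("AA", "CT")
        assert gs.joined == "AA|CT"

    def test_missing_token(self):
        m = build_matrix([[Call.HOM_REF, Call.MISSING]],
                         ref_alts=[("A", "G"), ("C", "T")])
        assert genotype_string(m, "s1", ["m1", "m2"]).joined == "AA|NN"

    def test_het_token_is_allele_order_invariant(self):
        # ref G / alt A and ref A / alt G give the same het token
        m1 = build_matrix([[Call.HET]], ref_alts=[("G", "A")])
        m2 = build_matrix([[Call.HET]], ref_alts=[("A", "G")])
        t1 = genotype_string(m1, "s1", ["m1"]).tokens[0]
        t2 = genotype_string(m2, "s1", ["m1"]).tokens[0]
        assert t1 == t2 == "AG"

    def test_unknown_marker_raises(self):
        m = build_matrix([[0]])
        with pytest.raises(KeyError):
            genotype_string(m, "s1", ["nope"])


class TestDiscernibility:
    def test_all_distinct_is_one(self):
        m = build_matrix([[0], [1], [2], [3]])
        res = discernibility(m, ["m1"])
        assert res.discernibility == 1.0
        assert res.discernibility_exact == Fraction(1)

    def test_identical_samples_hit_floor(self):
        m = build_matrix([[1, 1]] * 5)
        res = discernibility(m, ["m1", "m2"])
        assert res.n_unique == 1
        assert res.discernibility_exact == Fraction(1, 5)

    def test_hand_built_collision_example(self):
        """Samples 1 and 2 collide on markers {1,2} but are separated
        once marker 3 replaces marker 2."""
        calls = [
            [0, 0, 0],
            [0, 0, 2],
            [1, 0, 0],
            [2, 1, 0],
            [0, 2, 1],
        ]
        m = build_matrix(calls)
        assert discernibility(m, ["m1", "m2"]).discernibility_exact == Fraction(4, 5)
        assert discernibility(m, ["m1", "m3"]).discernibility == 1.0

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError):
            discernibility(build_matrix([[0]]), [])

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 20, 5)
        perm = rng.permutation(m.samples).tolist()
        shuffled = m.select_samples(perm)
        for panel in (["m1"], ["m2", "m4"], m.marker_ids):
            assert (
                discernibility(m, panel).n_unique
                == discernibility(shuffled, panel).n_unique
            )

    def test_matches_independent_recount(self):
        rng = np.random.default_rng(21)
        m = random_matrix(rng, 30, 8)
        for panel in (["m1", "m5"], m.marker_ids[:4], m.marker_ids):
            assert discernibility(m, panel).n_unique == oracle_n_unique(m, panel)


class TestMonotonicity:
    def test_nested_subsets_never_lose_resolution(self):
        rng = np.random.default_rng(17)
        m = random_matrix(rng, 25, 10)
        ids = m.marker_ids
        for _ in range(200):
            k_small = rng.integers(1, len(ids))
            small = list(rng.choice(ids, size=k_small, replace=False))
            extra = [i for i in ids if i not in small]
            k_extra = rng.integers(1, len(extra) + 1)
            big = small + list(rng.choice(extra, size=k_extra, replace=False))
            assert (
                discernibility(m, big).n_unique
                >= discernibility(m, small).n_unique
            )


class TestSimulation:
    def test_simulated_best_equals_exhaustive_optimum(self):
        """On small instances the randomized search must find the true
        per-size optimum computed by full enumeration."""
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            m = random_matrix(rng, 12, 8)
            cfg = SimulationConfig(
                panel_sizes=tuple(range(1, 9)), reps_per_size=1500, seed=seed
            )
            sim = simulate_combinations(m, cfg)
            for k in range(1, 9):
                exact = exhaustive_best(m, k)
                assert sim[k].best_n_unique == exact.best_n_unique, (seed, k)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 15, 10)
        cfg = SimulationConfig(panel_sizes=(2, 4), reps_per_size=200, seed=42)
        a = simulate_combinations(m, cfg)
        b = simulate_combinations(m, cfg)
        assert {k: (v.best_n_unique, v.best_subsets) for k, v in a.items()} == {
            k: (v.best_n_unique, v.best_subsets) for k, v in b.items()
        }

    def test_full_size_panel_is_the_single_subset(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 10, 5)
        cfg = SimulationConfig(panel_sizes=(5,), reps_per_size=50, seed=0)
        res = simulate_combinations(m, cfg)[5]
        assert res.best_subsets == [tuple(sorted(m.marker_ids))]
        assert res.best_n_unique == discernibility(m, m.marker_ids).n_unique

    def test_known_separating_pair_is_found(self):
        # markers m1+m2 jointly separate all 6 samples; alone they do not
        calls = [
            [0, 0, 1],
            [0, 1, 1],
            [0, 2, 1],
            [1, 0, 1],
            [1, 1, 1],
            [1, 2, 1],
        ]
        m = build_matrix(calls)
        brute = {
            combo: oracle_n_unique(m, combo)
            for combo in itertools.combinations(m.marker_ids, 2)
        }
        assert max(brute.values()) == 6 and brute[("m1", "m2")] == 6
        cfg = SimulationConfig(panel_sizes=(2,), reps_per_size=200, seed=1)
        res = simulate_combinations(m, cfg)[2]
        assert res.best_n_unique == 6
        assert ("m1", "m2") in res.best_subsets

    def test_oversized_panel_raises(self):
        m = build_matrix([[0, 1]])
        with pytest.raises(ValueError):
            simulate_combinations(
                m, SimulationConfig(panel_sizes=(3,), reps_per_size=1, seed=0)
            )


class TestMinimalPanel:
    def test_single_separating_marker_gives_k1(self):
        m = build_matrix([[0, 0], [1, 0], [2, 0], [3, 0]])
        k, best = minimal_panel_size(m, exhaustive=True)
        assert k == 1
        assert ("m1",) in best.best_subsets

    def test_planted_k3_instance(self):
        """No 2-subset reaches full discernibility but the full triple
        does; verified by brute force over all 2- and 3-subsets."""
        calls = [
            [0, 0, 0],
            [0, 0, 2],
            [0, 2, 0],
            [2, 0, 0],
        ]
        m = build_matrix(calls)
        full = oracle_n_unique(m, m.marker_ids)
        assert full == 4
        for combo in itertools.combinations(m.marker_ids, 2):
            assert oracle_n_unique(m, list(combo)) < full
        k, _ = minimal_panel_size(m, exhaustive=True)
        assert k == 3

    def test_all_identical_samples_gives_k1(self):
        m = build_matrix([[1, 2]] * 4)
        k, best = minimal_panel_size(m, exhaustive=True)
        assert k == 1
        assert best.best_n_unique == 1


class TestEfficiencyCurve:
    def test_running_maximum_is_monotone_and_ends_at_full_panel(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 20, 8)
        cfg = SimulationConfig(
            panel_sizes=tuple(range(1, 9)), reps_per_size=300, seed=3
        )
        rows = efficiency_curve(m, cfg)
        run = [r["running_max"] for r in rows]
        assert all(b >= a for a, b in zip(run, run[1:]))
        assert rows[-1]["best_discernibility"] == pytest.approx(
            discernibility(m, m.marker_ids).discernibility
        )


class TestMissingModes:
    def test_wildcard_mode_merges_compatible_samples(self):
        calls = [
            [0, Call.MISSING],
            [0, 2],
            [1, 1],
        ]
        m = build_matrix(calls)
        strict = discernibility(m, m.marker_ids, missing_mode="distinct")
        loose = discernibility(m, m.marker_ids, missing_mode="wildcard")
        assert strict.n_unique == 3
        assert loose.n_unique == 2  # s1 compatible with s2

    def test_two_missing_samples_match_in_distinct_mode(self):
        calls = [[Call.MISSING], [Call.MISSING]]
        m = build_matrix(calls)
        assert discernibility(m, ["m1"]).n_unique == 1
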