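import numpy as np
import pytest

from mosaicalign import (
    Query,
    ScoringScheme,
    align_no_recombination,
    align_with_recombination,
    backward_matrix,
    build_displacement_table,
    canonicalize,
    displacement,
    enforce_distinct_paths,
    forward_matrix,
    load_gfa,
    rescore_alignment,
    spell_path,
)
from mosaicalign.oracle import brute_force_recombination, naive_alpha_beta_displacement
from mosaicalign.recombination_dp import breakpoint_window_bounds

from conftest import random_fixture, random_query


@pytest.fixture
def two_branch(two_branch_gfa):
    return canonicalize(load_gfa(two_branch_gfa))


class TestDisplacement:
    def test_disjoint_branches_balanced_junction(self, two_branch):
        # rho = 2nd A, psi = 3rd C: |a1|=3, |a2|=4, |b1|=3, |b2|=2 -> d_r = 0
        tab = build_displacement_table(two_branch)
        rho = two_branch.paths["p1"][2]
        psi = two_branch.paths["p2"][3]
        alpha, beta, dr = displacement(tab, "p1", "p2", rho, psi)
        assert (alpha, beta) == (two_branch.source, two_branch.sink)
        assert dr == 0

    def test_mirror_positions_cost_two(self, two_branch):
        # symmetric junction (|a1|=|a2|, |b1|=|b2|) forces |+1| + |-1| = 2
        tab = build_displacement_table(two_branch)
        rho = two_branch.paths["p1"][2]
        psi = two_branch.paths["p2"][2]
        assert displacement(tab, "p1", "p2", rho, psi)[2] == 2

    def test_identical_paths_share_every_vertex(self):
        doc = "S\t1\tACG\nP\ta\t1+\t*\nP\tb\t1+\t*\n"
        cg = canonicalize(load_gfa(doc))
        tab = build_displacement_table(cg)
        px = tab.pair("a", "b")
        assert px.shared == cg.paths["a"]

    def test_domain_errors(self, two_branch):
        tab = build_displacement_table(two_branch)
        off_p1 = two_branch.paths["p2"][1]
        with pytest.raises(ValueError, match="not on path"):
            displacement(tab, "p1", "p2", off_p1, off_p1)
        with pytest.raises(ValueError, match="different paths"):
            displacement(tab, "p1", "p1", off_p1, off_p1)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_naive_scan_oracle(self, seed):
        g, cg = random_fixture(seed, max_paths=4, max_sites=5, min_len=15, max_len=30)
        tab = build_displacement_table(cg)
        rng = np.random.default_rng(seed)
        names = sorted(cg.paths)
        for _ in range(30):
            i1, i2 = rng.choice(len(names), size=2, replace=False)
            n1, n2 = names[i1], names[i2]
            rho = cg.paths[n1][int(rng.integers(len(cg.paths[n1])))]
            psi = cg.paths[n2][int(rng.integers(len(cg.paths[n2])))]
            assert displacement(tab, n1, n2, rho, psi) == naive_alpha_beta_displacement(
                cg, n1, n2, rho, psi
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_agrees_with_point_queries(self, seed):
        g, cg = random_fixture(seed, max_paths=3, max_sites=4, min_len=12, max_len=20)
        tab = build_displacement_table(cg)
        names = sorted(cg.paths)
        n1, n2 = names[0], names[1]
        D = tab.displacement_matrix(n1, n2)
        for a, rho in enumerate(cg.paths[n1]):
            for b, psi in enumerate(cg.paths[n2]):
                assert D[a, b] == displacement(tab, n1, n2, rho, psi)[2]


class TestAlignWithRecombination:
    def test_mosaic_beats_single_paths(self, two_branch, scoring):
        rec = align_with_recombination(two_branch, Query("q", "AAC"), scoring)
        ev = rec.recombination
        assert rec.score == 2.0
        assert (ev.p1, ev.p2) == ("p1", "p2")
        assert ev.breakpoint == 2
        assert ev.displacement == 0
        assert rescore_alignment(rec, two_branch, rec.query, scoring) == rec.score

    def test_on_path_query_reports_no_recombination(self, two_branch, scoring):
        rec = align_with_recombination(two_branch, Query("q", "AAA"), scoring)
        assert rec.recombination is None
        assert rec.score == 6.0

    def test_walk_has_single_virtual_junction(self, two_branch, scoring):
        rec = align_with_recombination(two_branch, Query("q", "AAC"), scoring)
        idx = rec.walk.virtual_arc_index
        assert idx is not None
        u, v = rec.walk.vertices[idx], rec.walk.vertices[idx + 1]
        assert (u, v) == (rec.recombination.rho, rec.recombination.psi)
        rec.walk.validate(two_branch)

    def test_huge_open_penalty_degenerates_to_no_recombination(self, scoring):
        sc_inf = ScoringScheme(2, 4, 4, 1e9, 0.1, 1.0)
        for seed in range(8):
            g, cg = random_fixture(seed)
            q, _ = random_query(g, cg, seed)
            with_rec = align_with_recombination(cg, q, sc_inf)
            without = align_no_recombination(cg, q, sc_inf)
            assert with_rec.recombination is None
            assert with_rec.score == without.score

    def test_open_penalty_monotonicity(self):
        fixtures = []
        for seed in range(10):
            g, cg = random_fixture(seed, min_len=40, max_len=70)
            q, _ = random_query(g, cg, seed, mutation_rates=(0.03,))
            fixtures.append((cg, q))
        counts = []
        for d_o in (4, 28, 48):
            sc = ScoringScheme(2, 4, 4, d_o, 0.1, 0.95)
            counts.append(
                sum(
                    align_with_recombination(cg, q, sc).recombination is not None
                    for cg, q in fixtures
                )
            )
        assert counts[0] >= counts[1] >= counts[2]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed, scoring):
        g, cg = random_fixture(seed, max_paths=5, max_sites=6, min_len=25, max_len=55)
        q, _ = random_query(g, cg, seed)
        rec = align_with_recombination(cg, q, scoring)
        score_o, ties = brute_force_recombination(cg, q, scoring)
        assert rec.score == score_o
        if rec.recombination is None:
            assert not ties
        else:
            ev = rec.recombination
            assert (ev.p1, ev.p2, ev.breakpoint) in ties
        assert rescore_alignment(rec, cg, q, scoring) == rec.score

    def test_shared_junction_vertex_label_used_by_both_halves(self, scoring):
        # paths share the middle G; a switch there duplicates it in the walk
        doc = (
            "S\t1\tAA\nS\t2\tG\nS\t3\tTT\nS\t4\tCC\nS\t5\tAG\n"
            "L\t1\t+\t2\t+\t0M\nL\t2\t+\t3\t+\t0M\n"
            "L\t4\t+\t2\t+\t0M\nL\t2\t+\t5\t+\t0M\n"
            "P\tp1\t1+,2+,3+\t*\nP\tp2\t4+,2+,5+\t*\n"
        )
        cg = canonicalize(load_gfa(doc))
        q = Query("q", "AAGGAG")  # AA G + G AG: junction uses G twice
        rec = align_with_recombination(cg, q, scoring)
        ev = rec.recombination
        assert ev is not None and ev.rho == ev.psi
        assert rec.score == 12.0 - scoring.rec_open_penalty - scoring.rec_ext_penalty * ev.displacement
        counts = {}
        for v in rec.walk.vertices:
            counts[v] = counts.get(v, 0) + 1
        assert counts[ev.rho] == 2
        assert rescore_alignment(rec, cg, q, scoring) == rec.score


class TestEnforceDistinctPaths:
    def _state(self, cg, q, sc):
        st = forward_matrix(cg, q, sc)
        backward_matrix(cg, q, sc, st)
        return st

    def test_distinct_bests_returned_directly(self, two_branch, scoring):
        st = self._state(two_branch, Query("q", "AACC"), scoring)
        p, q_, s = enforce_distinct_paths(st, two_branch.source, two_branch.sink, 2)
        assert p != q_
        assert s == st.bestM[two_branch.source][2] + st.bestR[two_branch.sink][2]

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_pair_maximum(self, seed, scoring):
        g, cg = random_fixture(seed, max_paths=5)
        q, _ = random_query(g, cg, seed)
        st = self._state(cg, q, scoring)
        rng = np.random.default_rng(seed)
        vids = sorted(cg.vertices)
        names = list(cg.paths)
        for _ in range(20):
            v = vids[int(rng.integers(len(vids)))]
            w = vids[int(rng.integers(len(vids)))]
            j = int(rng.integers(len(q) + 1))
            best = float("-inf")
            for a in names:
                for b in names:
                    if a == b:
                        continue
                    s = st.m_cell(v, j, a) + st.r_cell(w, j, b)
                    best = max(best, s)
            got = enforce_distinct_paths(st, v, w, j)[2]
            if best == float("-inf"):
                assert got == float("-inf")
            else:
                assert got == best


def test_breakpoint_window_bounds():
    assert breakpoint_window_bounds(100, 1.0) == (0, 100)
    lo, hi = breakpoint_window_bounds(100, 0.95)
    assert (lo, hi) == (3, 97)
    lo, hi = breakpoint_window_bounds(10, 0.5)
    assert (lo, hi) == (3, 7)
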