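import numpy as np
import pytest

from mosaicalign import Query, canonicalize, spell_path
from mosaicalign import evalmetrics, simgen


def tiny_levenshtein(a: str, b: str) -> int:
    """Independent quadratic edit-distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestJaccard:
    def test_identical_sets(self):
        assert evalmetrics.jaccard_nodes({1, 2}, {1, 2}) == 1.0

    def test_disjoint_sets(self):
        assert evalmetrics.jaccard_nodes({1}, {2}) == 0.0

    def test_half_overlap(self):
        assert evalmetrics.jaccard_nodes({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_symmetry_and_identity_characterisation(self):
        a, b = {1, 2, 5}, {2, 5, 9}
        assert evalmetrics.jaccard_nodes(a, b) == evalmetrics.jaccard_nodes(b, a)
        assert evalmetrics.jaccard_nodes(a, a) == 1.0
        assert evalmetrics.jaccard_nodes(a, b) < 1.0

    def test_empty_sets_undefined(self):
        with pytest.raises(ValueError):
            evalmetrics.jaccard_nodes(set(), set())


class TestEditDistance:
    def test_identical_and_single_sub(self):
        g = simgen.make_graph(2, 2, 20, seed=1)
        cg = canonicalize(g)
        walk = cg.paths["strain00"]
        s = spell_path(cg, walk)
        assert evalmetrics.edit_distance_to_path(Query("q", s), cg, walk) == 0
        mutated = "T" + s[1:] if s[0] != "T" else "A" + s[1:]
        assert evalmetrics.edit_distance_to_path(Query("q", mutated), cg, walk) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracle(self, seed):
        g = simgen.make_graph(3, 5, 40, seed=seed)
        cg = canonicalize(g)
        walk = cg.paths["strain01"]
        q, _ = simgen.mutate(Query("q", spell_path(cg, cg.paths["strain02"])), 0.1, seed)
        assert evalmetrics.edit_distance_to_path(q, cg, walk) == tiny_levenshtein(
            q.sequence, spell_path(cg, walk)
        )


def exhaustive_min_switches(vids, g):
    """Brute-force partition search over all block decompositions."""
    pos = {name: {v: i for i, v in enumerate(p)} for name, p in g.paths.items()}

    def contiguous(block):
        for name in g.paths:
            if all(v in pos[name] for v in block) and all(
                pos[name][b] == pos[name][a] + 1 for a, b in zip(block, block[1:])
            ):
                return True
        return False

    best = [len(vids)]

    def rec(i, nblocks):
        if i == len(vids):
            best[0] = min(best[0], nblocks - 1)
            return
        if nblocks > best[0]:  # any completion adds >= 1 more block
            return
        for j in range(i + 1, len(vids) + 1):
            if contiguous(vids[i:j]):
                rec(j, nblocks + 1)

    rec(0, 0)
    return best[0]


class TestMinSwitches:
    def test_single_path_walk_needs_no_switch(self):
        g = simgen.make_graph(3, 4, 30, seed=2)
        cg = canonicalize(g)
        assert evalmetrics.min_switches(cg.paths["strain00"], cg) == 0

    def test_true_mosaic_needs_one(self):
        for seed in range(10):
            g = simgen.make_graph(3, 6, 40, 0.0, seed=seed)
            cg = canonicalize(g)
            q, truth = simgen.simulate_recombinant(g, "strain00", "strain01", (0.2, 0.8), seed, cg=cg)
            seq1, seq2 = cg.paths["strain00"], cg.paths["strain01"]
            cut1 = seq1.index(truth.junction_vertex)
            cut2 = seq2.index(truth.junction_vertex)
            walk = seq1[1 : cut1 + 1] + seq2[cut2 + 1 : -1]
            got = evalmetrics.min_switches(walk, cg)
            assert got <= 1
            if spell_path(cg, walk) not in {spell_path(cg, p) for p in cg.paths.values()}:
                only_single = all(
                    evalmetrics.min_switches(p[1:-1], cg) == 0 for p in cg.paths.values()
                )
                assert got == 1 or not only_single

    def test_vertex_on_no_path_is_an_error(self):
        g = simgen.make_graph(2, 2, 20, seed=3)
        cg = canonicalize(g)
        with pytest.raises(ValueError, match="no distinguished path"):
            evalmetrics.min_switches([10**6], cg)

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_exhaustive_partition_search(self, seed):
        g = simgen.make_graph(4, 5, 18, 0.3, seed)
        cg = canonicalize(g)
        rng = np.random.default_rng(seed)
        names = sorted(cg.paths)
        # stitch k short path segments into a walk of <= 20 vertices
        walk = []
        name = names[int(rng.integers(len(names)))]
        i = 1
        while len(walk) < 18:
            p = cg.paths[name]
            if i >= len(p) - 1:
                break
            j = min(i + int(rng.integers(2, 6)), len(p) - 1)
            seg = p[i:j]
            if walk and seg and seg[0] in walk:
                break
            walk.extend(seg)
            # jump to another path sharing the boundary vertex, if any
            i = j
            name2 = names[int(rng.integers(len(names)))]
            if walk and walk[-1] in cg.paths[name2]:
                i = cg.paths[name2].index(walk[-1]) + 1
                name = name2
        if not walk:
            walk = cg.paths[names[0]][1:5]
        assert evalmetrics.min_switches(walk, cg) == exhaustive_min_switches(walk, cg)


class TestBreakpointError:
    def test_exact_and_offset(self):
        g = simgen.make_graph(2, 3, 30, seed=1)
        _q, truth = simgen.simulate_recombinant(g, "strain00", "strain01", seed=1)
        assert evalmetrics.breakpoint_error(truth.breakpoint, truth) == 0
        assert evalmetrics.breakpoint_error(truth.breakpoint + 3, truth) == 3

    def test_missing_report_is_a_miss(self):
        g = simgen.make_graph(2, 3, 30, seed=1)
        _q, truth = simgen.simulate_recombinant(g, "strain00", "strain01", seed=1)
        assert evalmetrics.breakpoint_error(None, truth) is None


def test_report_table_shape():
    rows = [{"query": "q1", "jaccard": "1.0", "n_switches": "1"}]
    tsv = evalmetrics.report_table(rows)
    lines = tsv.strip().splitlines()
    assert lines[0].split("\t") == ["query", "jaccard", "edit_distance", "n_switches", "breakpoint_error"]
    assert lines[1].startswith("q1\t1.0")
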