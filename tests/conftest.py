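import numpy as np
import pytest

from mosaicalign import ScoringScheme, canonicalize
from mosaicalign import simgen

TINY_GFA = """S\t1\tAC
S\t2\tG
L\t1\t+\t2\t+\t0M
P\tx\t1+,2+\t*
"""

TWO_BRANCH_GFA = """S\t1\tAAA
S\t2\tCCC
P\tp1\t1+\t*
P\tp2\t2+\t*
"""


@pytest.fixture
def scoring():
    """Match 2, mismatch 4, gap 4, rec-open 4, rec-ext 0.1, full window."""
    return ScoringScheme(2, 4, 4, 4, 0.1, 1.0)


@pytest.fixture
def tiny_gfa():
    return TINY_GFA


@pytest.fixture
def two_branch_gfa():
    return TWO_BRANCH_GFA


def random_fixture(seed, max_paths=6, max_sites=7, min_len=25, max_len=60, indel_fraction=0.3):
    """A random bubble graph plus its canonical form."""
    rng = np.random.default_rng(seed)
    n_paths = int(rng.integers(2, max_paths + 1))
    n_sites = int(rng.integers(1, max_sites + 1))
    length = int(rng.integers(min_len, max_len + 1))
    g = simgen.make_graph(n_paths, n_sites, length, indel_fraction, seed)
    return g, canonicalize(g)


def random_query(g, cg, seed, mutation_rates=(0.0, 0.02, 0.05, 0.1), window=(0.1, 0.9)):
    """A recombinant (or plain-path) query with optional point mutations."""
    rng = np.random.default_rng(seed + 10_000)
    names = sorted(g.paths)
    if rng.random() < 0.25 or len(names) < 2:
        p = names[int(rng.integers(len(names)))]
        q, truth = simgen.simulate_recombinant(g, p, p, window, seed, cg=cg)
    else:
        i1, i2 = rng.choice(len(names), size=2, replace=False)
        q, truth = simgen.simulate_recombinant(g, names[i1], names[i2], window, seed, cg=cg)
    rate = float(rng.choice(mutation_rates))
    if rate > 0:
        q, _ = simgen.mutate(q, rate, seed)
    return q, truth
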