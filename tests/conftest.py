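"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive expected values from first
principles (exact rational arithmetic, brute-force reachability, literal
step-up definitions) so they share no code with the implementation paths
they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from gssa.annotation import AnnotationMap
from gssa.rates import RankedList


# ---------------------------------------------------------------- oracles


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Exact Fraction arithmetic; includes every table with the same margins
    whose point probability is <= the observed table's.
    """
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(n, K)
    den = comb(N, n)
    pmf = {k: Fraction(comb(K, k) * comb(N - K, n - k), den) for k in range(lo, hi + 1)}
    return float(sum(p for p in pmf.values() if p <= pmf[a]))


def naive_bh(p_values) -> np.ndarray:
    """Literal quadratic Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_i, i in enumerate(order, start=1):
        candidates = [
            m * p[j] / rank_j
            for rank_j, j in enumerate(order, start=1)
            if rank_j >= rank_i
        ]
        q[i] = min(1.0, min(candidates))
    return np.asarray(q)


def brute_force_ancestors(edges, node) -> set:
    """All ancestors of ``node`` by naive repeated edge expansion."""
    parents = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    out = set()
    frontier = {node}
    while frontier:
        nxt = set()
        for n in frontier:
            for p in parents.get(n, ()):
                if p not in out:
                    out.add(p)
                    nxt.add(p)
        frontier = nxt
    return out


# ---------------------------------------------------------------- builders


def make_ranked(n: int, variable: str = "omega", seed: int = 0) -> RankedList:
    """A ranked list of n genes with strictly decreasing synthetic values."""
    rng = np.random.default_rng(seed)
    values = np.sort(rng.gamma(2.0, 0.1, size=n))[::-1]
    width = len(str(n))
    return RankedList(
        variable=variable,
        gene_ids=tuple(f"g{i:0{width}d}" for i in range(n)),
        values=values,
    )


def map_from_positions(ranked: RankedList, positions_by_term) -> AnnotationMap:
    """Annotation map assigning the genes at the given 0-based ranks."""
    assignments = {
        term: {ranked.gene_ids[i] for i in positions}
        for term, positions in positions_by_term.items()
    }
    return AnnotationMap.from_sets(assignments, universe=ranked.gene_ids)


def random_map(ranked: RankedList, sizes, seed: int = 0) -> AnnotationMap:
    rng = np.random.default_rng(seed)
    n = len(ranked)
    positions = {
        f"t{i:03d}": rng.choice(n, size=int(s), replace=False)
        for i, s in enumerate(sizes)
    }
    return map_from_positions(ranked, positions)


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def toy_rate_file(tmp_path):
    path = tmp_path / "rates.tsv"
    path.write_text(
        "gene_id\tbranch_id\tdS\tdN\taln_length_bp\n"
        "geneA\tb1\t0.10\t0.02\t500\n"
        "geneB\tb1\t0.30\t0.03\t900\n"
        "geneC\tb1\t0.20\t0.01\t1500\n"
    )
    return path


@pytest.fixture
def toy_gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "set1\tfirst set\tg1\tg2\tg3\n"
        "set2\tsecond set\tg2\tg4\n"
    )
    return path
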