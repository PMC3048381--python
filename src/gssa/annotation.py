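"""Gene-set annotations: GMT / table input, DAG propagation, level and size filters."""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "Term",
    "AnnotationMap",
    "read_gmt",
    "write_gmt",
    "read_gene_term_table",
    "read_edges",
    "propagate_to_ancestors",
    "assign_levels",
    "filter_terms",
]

logger = logging.getLogger(__name__)

#: Default minimum genes per retained term.
DEFAULT_MIN_SIZE = 15


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str = ""
    source: str = "custom"  # {GO, KEGG, custom}
    level: int | None = None  # DAG depth, root = 1; None for flat sources

    def __post_init__(self) -> None:
        if self.level is not None and self.level < 1:
            raise ValidationError(f"term {self.term_id!r} has level {self.level} < 1")


@dataclass
class AnnotationMap:
    """Term -> gene-set assignments over a gene universe."""

    terms: dict[str, Term]
    assignments: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, genes in self.assignments.items():
            if term_id not in self.terms:
                self.terms[term_id] = Term(term_id)
            if not genes <= self.universe:
                extra = sorted(genes - self.universe)[:3]
                raise ValidationError(
                    f"term {term_id!r} assigns genes outside the universe, e.g. {extra}"
                )

    @classmethod
    def from_sets(
        cls,
        assignments: Mapping[str, Iterable[str]],
        terms: Mapping[str, Term] | None = None,
        universe: Iterable[str] | None = None,
    ) -> "AnnotationMap":
        frozen = {t: frozenset(genes) for t, genes in assignments.items()}
        if universe is None:
            universe = frozenset().union(*frozen.values()) if frozen else frozenset()
        return cls(dict(terms or {}), frozen, frozenset(universe))

    def __len__(self) -> int:
        return len(self.assignments)

    def sizes(self) -> dict[str, int]:
        return {t: len(g) for t, g in self.assignments.items()}


def read_gmt(path) -> AnnotationMap:
    """Read gene sets from a GMT file (term, description, member genes...).

    Duplicate genes within a line are deduplicated; the universe is the union
    of all member genes.
    """
    terms: dict[str, Term] = {}
    assignments: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            term_id, name, *genes = fields
            genes = [g for g in genes if g]
            terms[term_id] = Term(term_id, name=name)
            assignments[term_id] = frozenset(genes)
    return AnnotationMap.from_sets(assignments, terms)


def write_gmt(amap: AnnotationMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(amap.assignments):
            name = amap.terms[term_id].name or term_id
            genes = "\t".join(sorted(amap.assignments[term_id]))
            fh.write(f"{term_id}\t{name}\t{genes}\n")


def read_gene_term_table(path) -> AnnotationMap:
    """Read a two-column (gene_id, term_id) TSV as an alternative to GMT."""
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns (gene, term)")
    assignments: dict[str, set[str]] = {}
    for gene, term in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        assignments.setdefault(term, set()).add(gene)
    return AnnotationMap.from_sets(assignments)


def read_edges(path) -> list[tuple[str, str]]:
    """Read child -> parent term edges from a two-column TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns (child, parent)")
    return list(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def _parent_index(edges: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    return parents


def _check_acyclic(parents: Mapping[str, set[str]]) -> None:
    # Kahn's algorithm on the child->parent graph; leftovers form a cycle.
    out_degree = {node: len(ps) for node, ps in parents.items()}
    children: dict[str, list[str]] = {node: [] for node in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].append(child)
    queue = deque(node for node, deg in out_degree.items() if deg == 0)
    seen = 0
    while queue:
        node = queue.popleft()
        seen += 1
        for child in children[node]:
            out_degree[child] -= 1
            if out_degree[child] == 0:
                queue.append(child)
    if seen != len(parents):
        member = sorted(node for node, deg in out_degree.items() if deg > 0)[0]
        raise ValidationError(f"term graph contains a cycle through {member!r}")


def _ancestors(parents: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """All reachable ancestors (excluding self) per node, memoised DFS."""
    cache: dict[str, set[str]] = {}
    # iterative DFS to dodge recursion limits on deep chains
    for start in parents:
        stack = [start]
        while stack:
            node = stack[-1]
            if node in cache:
                stack.pop()
                continue
            pending = [p for p in parents.get(node, ()) if p not in cache]
            if pending:
                stack.extend(pending)
            else:
                acc: set[str] = set()
                for p in parents.get(node, ()):
                    acc |= {p} | cache[p]
                cache[node] = acc
                stack.pop()
    return cache


def propagate_to_ancestors(
    amap: AnnotationMap, edges: Iterable[tuple[str, str]]
) -> AnnotationMap:
    """Extend annotations upward: a gene on a term joins every ancestor term.

    Never removes an annotation, and applying it twice is a no-op.  Raises
    :class:`ValidationError` if the child->parent edges contain a cycle.
    """
    parents = _parent_index(edges)
    _check_acyclic(parents)
    ancestors = _ancestors(parents)
    new_assignments: dict[str, set[str]] = {
        t: set(g) for t, g in amap.assignments.items()
    }
    for term_id, genes in amap.assignments.items():
        for anc in ancestors.get(term_id, ()):
            new_assignments.setdefault(anc, set()).update(genes)
    new_terms = dict(amap.terms)
    for term_id in new_assignments:
        new_terms.setdefault(term_id, Term(term_id))
    return AnnotationMap.from_sets(new_assignments, new_terms, amap.universe)


def assign_levels(
    edges: Iterable[tuple[str, str]], roots: Iterable[str]
) -> dict[str, int]:
    """Shortest-path depth from a root for every term; roots are level 1.

    ``level(t) = 1 + min(level(parent))`` over the parents of ``t``.  A
    non-root term that reaches no root raises :class:`ValidationError`.
    """
    parents = _parent_index(edges)
    _check_acyclic(parents)
    roots = set(roots)
    for r in roots:
        parents.setdefault(r, set())
    levels: dict[str, int] = {r: 1 for r in roots}
    # BFS downward from the roots over the parent->child direction
    children: dict[str, list[str]] = {node: [] for node in parents}
    for child, ps in parents.items():
        for p in ps:
            children.setdefault(p, []).append(child)
    queue = deque(roots)
    while queue:
        node = queue.popleft()
        for child in children.get(node, ()):
            candidate = levels[node] + 1
            if child not in levels or candidate < levels[child]:
                levels[child] = candidate
                queue.append(child)
    orphans = sorted(set(parents) - set(levels))
    if orphans:
        raise ValidationError(
            f"terms unreachable from any root, e.g. {orphans[:3]}"
        )
    return levels


def filter_terms(
    amap: AnnotationMap,
    min_size: int = DEFAULT_MIN_SIZE,
    level_window: tuple[int, int] | None = None,
    ranked_universe: Iterable[str] | None = None,
) -> AnnotationMap:
    """Drop undersized terms and terms outside the level window.

    Sizes are counted against ``ranked_universe`` when given (genes absent
    from the ranked list do not count toward the minimum).  Terms without a
    level (flat sources such as KEGG) are exempt from the level rule.
    """
    if min_size < 1:
        raise ConfigurationError(f"min_size must be >= 1, got {min_size}")
    if level_window is not None:
        lo, hi = level_window
        if lo > hi:
            raise ConfigurationError(f"level window lower bound {lo} exceeds upper bound {hi}")
    counted = frozenset(ranked_universe) if ranked_universe is not None else amap.universe
    kept: dict[str, frozenset[str]] = {}
    for term_id, genes in amap.assignments.items():
        if len(genes & counted) < min_size:
            continue
        level = amap.terms[term_id].level
        if level_window is not None and level is not None:
            if not (level_window[0] <= level <= level_window[1]):
                continue
        kept[term_id] = genes
    logger.info("filter_terms: retained %d of %d terms", len(kept), len(amap.assignments))
    terms = {t: amap.terms[t] for t in kept}
    return AnnotationMap(terms, kept, amap.universe)


def with_levels(amap: AnnotationMap, levels: Mapping[str, int]) -> AnnotationMap:
    """Return a copy whose terms carry the given DAG levels."""
    terms = {
        t: replace(term, level=levels.get(t, term.level))
        for t, term in amap.terms.items()
    }
    return AnnotationMap(terms, dict(amap.assignments), amap.universe)
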