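"""The segmentation test: partitions, two-tailed Fisher tests, FDR, verdicts.

For one ranked gene list and one annotation map the test places a fixed
number of cuts along the ranking, builds the 2x2 table (term membership x
list side) at every cut for every term, computes a two-tailed Fisher exact
p-value per table, corrects the full terms-x-partitions family with
Benjamini-Hochberg, and calls each term SH (skewed toward high values),
SL (toward low values) or NS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .annotation import AnnotationMap
from .errors import ValidationError
from .rates import RankedList

__all__ = [
    "Partition",
    "PartitionResult",
    "TermCall",
    "PsgComparison",
    "make_partitions",
    "fisher_two_tailed",
    "segmentation_test",
    "adjust_fdr",
    "classify_terms",
    "run_gssa",
    "compare_psg_counts",
]

logger = logging.getLogger(__name__)

DEFAULT_N_PARTITIONS = 30
DEFAULT_ALPHA_TIERS = (0.001, 0.05)

# Relative tolerance when deciding which tables are "as extreme" as the
# observed one; matches the convention of mainstream implementations.
_TIE_EPS = 1e-7


class Partition(NamedTuple):
    """One cut of the ranked list: genes 1..position form side A."""

    index: int  # 1-based partition number
    position: int  # cut index in [1, N-1]


@dataclass
class PartitionResult:
    """One 2x2 Fisher test of one term at one partition."""

    term_id: str
    partition_index: int
    cut_index: int
    a: int  # term genes on side A (top of the list)
    b: int  # non-term genes on side A
    c: int  # term genes on side B
    d: int  # non-term genes on side B
    odds_ratio: float
    p_value: float
    q_value: float | None = None

    @property
    def n_genes(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def term_size(self) -> int:
        return self.a + self.c

    @property
    def expected_a(self) -> float:
        """Expected top-side term count under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n_genes


@dataclass
class TermCall:
    """Per-term verdict after FDR over the whole family."""

    term_id: str
    verdict: str  # {"SH", "SL", "NS"}
    tier: str  # {"FDR_0.1pct", "FDR_5pct", "none"}
    q_min: float
    best_partition: PartitionResult
    first_significant_partition: PartitionResult | None
    pct_contributing: float | None
    n_genes: int


@dataclass(frozen=True)
class PsgComparison:
    """Welch t-test of per-module positively-selected-gene counts, SH vs SL."""

    computable: bool
    mean_sh: float = math.nan
    mean_sl: float = math.nan
    t_statistic: float = math.nan
    p_value: float = math.nan
    n_sh: int = 0
    n_sl: int = 0


def make_partitions(n_genes: int, n_partitions: int = DEFAULT_N_PARTITIONS) -> list[Partition]:
    """Evenly spaced cut positions along a ranked list of ``n_genes``.

    ``position(k) = floor(k * N / (P + 1))`` clamped to ``[1, N-1]`` for
    ``k = 1..P``.  Duplicate positions (tiny N) are collapsed, keeping the
    first partition index at each position.
    """
    if n_genes <= n_partitions:
        raise ValidationError(
            f"cannot place {n_partitions} partitions on {n_genes} genes; "
            "use fewer partitions"
        )
    out: list[Partition] = []
    last = None
    for k in range(1, n_partitions + 1):
        pos = (k * n_genes) // (n_partitions + 1)
        pos = min(max(pos, 1), n_genes - 1)
        if pos != last:
            out.append(Partition(index=k, position=pos))
            last = pos
    if len(out) < n_partitions:
        logger.info(
            "make_partitions: collapsed %d duplicate cuts (N=%d, P=%d)",
            n_partitions - len(out), n_genes, n_partitions,
        )
    return out


def _two_sided_pvalue_table(
    n_genes: int, term_size: int, cuts: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed Fisher p-values for every possible table of one term.

    Returns ``(ptab, valid)`` of shape ``(len(cuts), term_size + 1)`` where
    ``ptab[j, a]`` is the minimum-likelihood two-sided p-value of observing
    ``a`` term genes above cut ``cuts[j]``, and ``valid`` marks the ``a``
    values inside the hypergeometric support.

    The p-value sums the point hypergeometric probabilities of every table
    (same margins) no more likely than the observed one.
    """
    N, K = n_genes, term_size
    lf = gammaln(np.arange(N + 1, dtype=np.float64) + 1.0)  # lf[i] = log(i!)
    k = np.arange(K + 1)
    n = np.asarray(cuts, dtype=np.int64)[:, None]
    valid = (k >= np.maximum(0, n - (N - K))) & (k <= np.minimum(n, K))
    ks = np.where(valid, k, 0)
    ns_minus_k = np.clip(n - ks, 0, N)
    lp = (
        (lf[K] - lf[ks] - lf[K - ks])
        + (lf[N - K] - lf[ns_minus_k] - lf[np.clip(N - K - ns_minus_k, 0, N)])
        - (lf[N] - lf[n] - lf[N - n])
    )
    pmf = np.where(valid, np.exp(lp), 0.0)

    order = np.argsort(pmf, axis=1, kind="stable")
    sorted_pmf = np.take_along_axis(pmf, order, axis=1)
    csum = np.cumsum(sorted_pmf, axis=1)
    ptab = np.empty_like(pmf)
    for j in range(pmf.shape[0]):
        thr = pmf[j] * (1.0 + _TIE_EPS)
        idx = np.searchsorted(sorted_pmf[j], thr, side="right") - 1
        ptab[j] = np.minimum(csum[j, np.maximum(idx, 0)], 1.0)
    ptab[~valid] = np.nan
    return ptab, valid


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    num, den = a * d, b * c
    if den == 0:
        return 1.0 if num == 0 else math.inf
    return num / den


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-tailed Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p_value)``.  The p-value follows the
    minimum-likelihood convention: the sum over all tables with the same
    margins whose point hypergeometric probability does not exceed that of
    the observed table.  The odds ratio is the sample ratio ``(a*d)/(b*c)``
    with ``0/0 -> 1`` and ``x/0 -> +inf``.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or v != int(v):
            raise ValidationError(f"count {name}={v} must be a non-negative integer")
    N = a + b + c + d
    if N == 0:
        raise ValidationError("all four counts are zero")
    ptab, _ = _two_sided_pvalue_table(N, a + c, [a + b])
    return _odds_ratio(a, b, c, d), float(ptab[0, a])


def _term_positions(ranked: RankedList, genes: Iterable[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(ranked.gene_ids)}
    pos = sorted(index[g] for g in genes if g in index)
    return np.asarray(pos, dtype=np.int64)


def segmentation_test(
    ranked: RankedList,
    amap: AnnotationMap,
    n_partitions: int = DEFAULT_N_PARTITIONS,
) -> list[PartitionResult]:
    """Fisher-test every term at every partition of the ranked list.

    Produces one :class:`PartitionResult` per (term, unique cut);
    ``q_value`` stays unset until :func:`adjust_fdr` runs on the family.
    Term genes absent from the ranking are ignored.
    """
    if len(amap) == 0:
        raise ValidationError("annotation map is empty after filtering")
    N = len(ranked)
    partitions = make_partitions(N, n_partitions)
    cuts = [p.position for p in partitions]
    results: list[PartitionResult] = []
    for term_id in sorted(amap.assignments):
        positions = _term_positions(ranked, amap.assignments[term_id])
        K = len(positions)
        ptab, _ = _two_sided_pvalue_table(N, K, cuts)
        a_at_cut = np.searchsorted(positions, cuts, side="left")
        for j, part in enumerate(partitions):
            a = int(a_at_cut[j])
            b = part.position - a
            c = K - a
            d = (N - part.position) - c
            results.append(
                PartitionResult(
                    term_id=term_id,
                    partition_index=part.index,
                    cut_index=part.position,
                    a=a, b=b, c=c, d=d,
                    odds_ratio=_odds_ratio(a, b, c, d),
                    p_value=float(ptab[j, a]),
                )
            )
    return results


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests.

    ``q_(i) = min_{j >= i} m * p_(j) / j``, capped at 1; order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def apply_fdr(results: Sequence[PartitionResult]) -> int:
    """Attach BH q-values across the whole terms-x-partitions family.

    Returns the family size used (the reproducibility-critical C x P count).
    """
    q = adjust_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    logger.info("apply_fdr: corrected a family of %d tests", len(results))
    return len(results)


def _direction(result: PartitionResult) -> str:
    """SH when the term is over-represented on side A (top), else SL."""
    return "SH" if result.a > result.expected_a else "SL"


def classify_terms(
    results: Sequence[PartitionResult],
    alpha_tiers: tuple[float, float] = DEFAULT_ALPHA_TIERS,
) -> list[TermCall]:
    """Collapse per-partition results into one verdict per term.

    The best partition is the one with minimal q (ties: lowest partition
    index).  A term is NS when its minimal q exceeds the loose tier.  The
    contributing-gene percentage counts term genes on the enriched side of
    the first significant partition.
    """
    strict, loose = sorted(alpha_tiers)
    if any(r.q_value is None for r in results):
        raise ValidationError("q-values unset; run apply_fdr first")
    by_term: dict[str, list[PartitionResult]] = {}
    for r in results:
        by_term.setdefault(r.term_id, []).append(r)

    calls: list[TermCall] = []
    for term_id in sorted(by_term):
        rs = sorted(by_term[term_id], key=lambda r: r.partition_index)
        best = min(rs, key=lambda r: (r.q_value, r.partition_index))
        q_min = best.q_value
        first_sig = next((r for r in rs if r.q_value <= loose), None)
        if first_sig is None:
            verdict, tier, pct = "NS", "none", None
        else:
            verdict = _direction(best)
            tier = "FDR_0.1pct" if q_min <= strict else "FDR_5pct"
            on_side = first_sig.a if _direction(first_sig) == "SH" else first_sig.c
            pct = 100.0 * on_side / first_sig.term_size
        calls.append(
            TermCall(
                term_id=term_id,
                verdict=verdict,
                tier=tier,
                q_min=float(q_min),
                best_partition=best,
                first_significant_partition=first_sig,
                pct_contributing=pct,
                n_genes=best.term_size,
            )
        )
    return calls


def run_gssa(
    ranked: RankedList,
    amap: AnnotationMap,
    n_partitions: int = DEFAULT_N_PARTITIONS,
    alpha_tiers: tuple[float, float] = DEFAULT_ALPHA_TIERS,
) -> tuple[list[PartitionResult], list[TermCall], int]:
    """Full test for one (ranking, annotation) pair.

    Returns ``(partition_results, term_calls, fdr_family_size)``.
    """
    results = segmentation_test(ranked, amap, n_partitions)
    family = apply_fdr(results)
    calls = classify_terms(results, alpha_tiers)
    return results, calls, family


def compare_psg_counts(
    calls: Sequence[TermCall],
    amap: AnnotationMap,
    psg_flags: Mapping[str, int],
) -> PsgComparison:
    """Welch t-test comparing positively-selected-gene counts, SH vs SL modules.

    Each module's count is the number of its genes flagged as positively
    selected.  With fewer than two modules in either group the comparison is
    reported as not computable rather than raising.
    """
    def counts(verdict: str) -> list[int]:
        return [
            sum(int(bool(psg_flags.get(g, 0))) for g in amap.assignments[c.term_id])
            for c in calls
            if c.verdict == verdict and c.term_id in amap.assignments
        ]

    sh, sl = counts("SH"), counts("SL")
    if len(sh) < 2 or len(sl) < 2:
        return PsgComparison(computable=False, n_sh=len(sh), n_sl=len(sl))
    sh_a, sl_a = np.asarray(sh, float), np.asarray(sl, float)
    if sh_a.var(ddof=1) == 0 and sl_a.var(ddof=1) == 0:
        # degenerate zero-variance groups: identical means -> no effect
        equal = sh_a.mean() == sl_a.mean()
        t, p = (0.0, 1.0) if equal else (math.inf, 0.0)
    else:
        t, p = stats.ttest_ind(sh_a, sl_a, equal_var=False)
    return PsgComparison(
        computable=True,
        mean_sh=float(sh_a.mean()),
        mean_sl=float(sl_a.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_sh=len(sh),
        n_sl=len(sl),
    )
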