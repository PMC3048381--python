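"""Reading, validating, filtering and ranking per-gene evolutionary-rate tables.

A rate table holds one row per (gene, branch) with synonymous (dS) and
nonsynonymous (dN) substitution rates, the selective pressure ``omega = dN/dS``
and, when an ancestral estimate is available, the change in selective pressure
``delta_omega = omega - omega_ancestral``.  Tables of this shape are what a
free-ratio branch codon model produces; producing them is out of scope here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "RATE_VARIABLES",
    "CLADE_RULES",
    "CladeRule",
    "RateTable",
    "RankedList",
    "read_rate_table",
    "compute_delta_omega",
    "saturation_filter",
    "length_filter",
    "apply_filters",
    "rank_genes",
]

logger = logging.getLogger(__name__)

#: Ranking variables accepted throughout the package.
RATE_VARIABLES = ("dS", "dN", "omega", "delta_omega")

#: Values treated as missing when parsing TSV input.
MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A"}

#: Canonical column names; ``read_rate_table`` maps input headers onto these.
_CANONICAL_COLUMNS = (
    "gene_id",
    "branch_id",
    "dS",
    "dN",
    "omega",
    "omega_ancestral",
    "delta_omega",
    "aln_length_bp",
)

_NUMERIC_COLUMNS = _CANONICAL_COLUMNS[2:]


@dataclass(frozen=True)
class CladeRule:
    """Exclusive upper bounds on dS and dN for saturation screening.

    A record is excluded when either ``dS >= dS_max`` or ``dN >= dN_max``.
    """

    name: str
    dS_max: float
    dN_max: float


#: Saturation rule sets shipped as named defaults.  Bounds are exclusive
#: upper limits: a record at the bound is excluded.
CLADE_RULES: Mapping[str, CladeRule] = {
    "primates-rodents": CladeRule("primates-rodents", dS_max=1.0, dN_max=0.5),
    "rodents": CladeRule("rodents", dS_max=0.256, dN_max=0.122),
    "primates": CladeRule("primates", dS_max=0.064, dN_max=0.030),
}


@dataclass
class RateTable:
    """Per-gene, per-branch rate records backed by a :class:`pandas.DataFrame`.

    The frame always carries the canonical columns ``gene_id, branch_id, dS,
    dN, omega, omega_ancestral, delta_omega, aln_length_bp``; numeric columns
    use ``NaN`` for missing values.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CANONICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"rate table missing required columns: {missing}")
        dup = self.frame.duplicated(subset=["gene_id", "branch_id"])
        if dup.any():
            pair = self.frame.loc[dup.idxmax(), ["gene_id", "branch_id"]]
            raise ValidationError(
                f"duplicate (gene_id, branch_id) pair: ({pair.gene_id!r}, {pair.branch_id!r})"
            )
        for col in ("dS", "dN"):
            vals = self.frame[col]
            if (vals.dropna() < 0).any():
                raise ValidationError(f"negative values in column {col!r}")

    @property
    def universe(self) -> tuple[str, ...]:
        """Ordered set of gene ids present in the table."""
        return tuple(dict.fromkeys(self.frame["gene_id"]))

    @property
    def branches(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["branch_id"]))

    def __len__(self) -> int:
        return len(self.frame)

    def for_branch(self, branch_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["branch_id"] == branch_id]
        if sub.empty:
            raise ValidationError(f"no records for branch {branch_id!r}")
        return sub


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by one rate variable, highest value first."""

    variable: str
    gene_ids: tuple[str, ...]
    values: np.ndarray
    tie_policy: str = "stable-descending, lexicographic gene_id tie-break"
    n_missing_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.values):
            raise ValidationError("gene_ids and values must be parallel")
        if np.any(np.diff(self.values) > 0):
            raise ValidationError("ranked values must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def reversed(self) -> "RankedList":
        """Mirror the ranking (used for SH/SL symmetry checks)."""
        return RankedList(
            variable=self.variable,
            gene_ids=self.gene_ids[::-1],
            values=self.values[::-1] * -1.0,
            tie_policy=self.tie_policy + " (reversed)",
            n_missing_dropped=self.n_missing_dropped,
        )


def read_rate_table(path, dialect: Mapping[str, str] | None = None) -> RateTable:
    """Read a tab-separated rate table into a validated :class:`RateTable`.

    Parameters
    ----------
    path:
        TSV file with a header row.  Must provide a gene id column and at
        least one of dS / dN / omega.
    dialect:
        Optional mapping from canonical column names (``gene_id``, ``dS``,
        ``dN``, ...) to the column names actually used in the file.

    Unparseable numeric cells and the tokens ``NA``/empty are recorded as
    missing.  ``omega`` is derived as dN/dS where absent (missing when
    dS == 0) and ``delta_omega`` as omega - omega_ancestral.
    """
    dialect = dict(dialect or {})
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty rate table file: {path}") from None
    rename = {dialect.get(canon, canon): canon for canon in _CANONICAL_COLUMNS}
    raw = raw.rename(columns={src: dst for src, dst in rename.items() if src in raw.columns})

    if "gene_id" not in raw.columns:
        raise FormatError("rate table is missing mandatory column 'gene_id'")
    if not any(c in raw.columns for c in ("dS", "dN", "omega")):
        raise FormatError("rate table must contain at least one of columns 'dS', 'dN', 'omega'")
    if "branch_id" not in raw.columns:
        raw["branch_id"] = "branch0"

    frame = pd.DataFrame({"gene_id": raw["gene_id"], "branch_id": raw["branch_id"]})
    n_bad = 0
    for col in _NUMERIC_COLUMNS:
        if col in raw.columns:
            cleaned = raw[col].where(~raw[col].isin(MISSING_TOKENS), other=np.nan)
            parsed = pd.to_numeric(cleaned, errors="coerce")
            n_bad += int((parsed.isna() & cleaned.notna()).sum())
            frame[col] = parsed
        else:
            frame[col] = np.nan
    if n_bad:
        logger.info("read_rate_table: %d unparseable numeric cells recorded as missing", n_bad)

    # derive omega and delta_omega where the inputs allow it
    derivable = frame["omega"].isna() & frame["dS"].gt(0) & frame["dN"].notna()
    frame.loc[derivable, "omega"] = frame.loc[derivable, "dN"] / frame.loc[derivable, "dS"]
    # dS == 0 leaves omega undefined; treat as missing rather than infinity
    zero_ds = frame["dS"].eq(0) & frame["omega"].notna()
    if zero_ds.any():
        logger.info("read_rate_table: %d records with dS=0 set to missing omega", int(zero_ds.sum()))
        frame.loc[zero_ds, "omega"] = np.nan
    d_derivable = (
        frame["delta_omega"].isna() & frame["omega"].notna() & frame["omega_ancestral"].notna()
    )
    frame.loc[d_derivable, "delta_omega"] = (
        frame.loc[d_derivable, "omega"] - frame.loc[d_derivable, "omega_ancestral"]
    )
    return RateTable(frame)


def compute_delta_omega(omega_descendant: float, omega_ancestral: float) -> float:
    """Change in selective pressure, descendant minus ancestor.

    Positive values indicate relaxation / increased omega relative to the
    ancestor.  Returns ``nan`` when either argument is missing.
    """
    if omega_descendant is None or omega_ancestral is None:
        return math.nan
    if math.isnan(omega_descendant) or math.isnan(omega_ancestral):
        return math.nan
    return omega_descendant - omega_ancestral


def saturation_filter(dS: float, dN: float, clade_rule: str | CladeRule) -> bool:
    """Return True (keep) unless either rate reaches its saturation bound.

    The bound is exclusive: ``dS >= dS_max`` or ``dN >= dN_max`` excludes.
    """
    if isinstance(clade_rule, str):
        try:
            clade_rule = CLADE_RULES[clade_rule]
        except KeyError:
            raise ConfigurationError(
                f"unknown clade rule {clade_rule!r}; known: {sorted(CLADE_RULES)}"
            ) from None
    if dS is not None and not math.isnan(dS) and dS >= clade_rule.dS_max:
        return False
    if dN is not None and not math.isnan(dN) and dN >= clade_rule.dN_max:
        return False
    return True


def length_filter(aln_length_bp: int, min_length: int = 100) -> bool:
    """Return True (keep) iff the alignment is at least ``min_length`` bp."""
    if aln_length_bp < 0:
        raise ValidationError(f"negative alignment length: {aln_length_bp}")
    return aln_length_bp >= min_length


def apply_filters(
    table: RateTable,
    clade_rule: str | CladeRule | None = None,
    min_length: int = 100,
) -> RateTable:
    """Drop saturated records and short alignments, logging counts.

    Records with a missing alignment length pass the length filter.
    """
    frame = table.frame
    keep = pd.Series(True, index=frame.index)
    if clade_rule is not None:
        keep &= frame.apply(
            lambda row: saturation_filter(row["dS"], row["dN"], clade_rule), axis=1
        )
    has_len = frame["aln_length_bp"].notna()
    neg = has_len & frame["aln_length_bp"].lt(0)
    if neg.any():
        raise ValidationError("negative alignment length in rate table")
    keep &= ~(has_len & frame["aln_length_bp"].lt(min_length))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("apply_filters: excluded %d of %d records", n_dropped, len(frame))
    return RateTable(frame[keep].reset_index(drop=True))


def rank_genes(table: RateTable, variable: str, branch_id: str | None = None) -> RankedList:
    """Rank the genes of one branch by a rate variable, highest value first.

    Genes with a missing value for ``variable`` are excluded and counted in
    ``n_missing_dropped``.  Ties are broken lexicographically by gene id so
    rankings are reproducible across platforms.
    """
    if variable not in RATE_VARIABLES:
        raise ConfigurationError(
            f"unknown ranking variable {variable!r}; expected one of {RATE_VARIABLES}"
        )
    if branch_id is None:
        branches = table.branches
        if len(branches) != 1:
            raise ValidationError(
                f"table has {len(branches)} branches; branch_id is required"
            )
        branch_id = branches[0]
    sub = table.for_branch(branch_id)
    usable = sub[sub[variable].notna()]
    n_missing = len(sub) - len(usable)
    if len(usable) < 2:
        raise ValidationError(
            f"fewer than 2 genes with {variable!r} on branch {branch_id!r}"
        )
    ordered = usable.sort_values(
        by=[variable, "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return RankedList(
        variable=variable,
        gene_ids=tuple(ordered["gene_id"]),
        values=ordered[variable].to_numpy(dtype=float),
        n_missing_dropped=n_missing,
    )
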