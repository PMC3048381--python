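"""Synthetic genome-scale rate tables and annotation maps with known truth.

Backgrounds use right-skewed positive distributions for dS and dN (gamma by
default), with omega = dN/dS and an independently drawn ancestral omega so
delta_omega is exercised.  Modules are planted by an additive location shift
on the ranking variable, which is the minimal mechanism producing the rank
skew the segmentation test detects; dependent columns are re-derived so the
table's internal invariants (omega = dN/dS, delta = omega - ancestral) hold
after planting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationMap, Term
from .core import TermCall
from .errors import ConfigurationError, ValidationError
from .rates import RATE_VARIABLES, RateTable

__all__ = [
    "DistributionSpec",
    "BackgroundSpec",
    "PlantedModule",
    "SyntheticTruth",
    "RecoveryReport",
    "simulate_rates",
    "plant_modules",
    "recovery_report",
]

logger = logging.getLogger(__name__)

#: Floor applied to rate columns after a downward shift; rates stay positive.
_RATE_FLOOR = 1e-9


@dataclass(frozen=True)
class DistributionSpec:
    """A named positive distribution with parameters."""

    name: str  # {"gamma", "lognormal", "uniform"}
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.name == "gamma":
            shape, scale = self.params
            if shape <= 0 or scale <= 0:
                raise ConfigurationError("gamma parameters must be positive")
            return rng.gamma(shape, scale, size=size)
        if self.name == "lognormal":
            mean, sigma = self.params
            if sigma <= 0:
                raise ConfigurationError("lognormal sigma must be positive")
            return rng.lognormal(mean, sigma, size=size)
        if self.name == "uniform":
            low, high = self.params
            if not (0 <= low < high):
                raise ConfigurationError("uniform bounds must satisfy 0 <= low < high")
            return rng.uniform(low, high, size=size)
        raise ConfigurationError(f"unknown distribution {self.name!r}")

    @property
    def mean(self) -> float:
        if self.name == "gamma":
            return self.params[0] * self.params[1]
        if self.name == "lognormal":
            return float(np.exp(self.params[0] + self.params[1] ** 2 / 2))
        if self.name == "uniform":
            return (self.params[0] + self.params[1]) / 2
        raise ConfigurationError(f"unknown distribution {self.name!r}")


@dataclass(frozen=True)
class BackgroundSpec:
    """Distributions for the background dS and dN draws.

    The dS shape must exceed 2 for omega = dN/dS to have finite variance;
    the defaults give omega a mean near 0.33 and standard deviation near
    0.37, in the range free-ratio branch estimates typically span.
    """

    dS: DistributionSpec = DistributionSpec("gamma", (4.0, 0.05))
    dN: DistributionSpec = DistributionSpec("gamma", (2.0, 0.025))


DEFAULT_BACKGROUND = BackgroundSpec()


@dataclass(frozen=True)
class PlantedModule:
    direction: str  # {"SH", "SL"}
    effect_size: float  # rank shift, in background standard deviations
    size: int  # genes

    def __post_init__(self) -> None:
        if self.direction not in ("SH", "SL"):
            raise ValidationError(f"direction must be SH or SL, got {self.direction!r}")
        if self.size < 1:
            raise ValidationError("planted module size must be >= 1")
        if not np.isfinite(self.effect_size):
            raise ValidationError("effect size must be finite")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a planted-module experiment."""

    planted: Mapping[str, PlantedModule]  # term_id -> module
    background_spec: BackgroundSpec
    seed: int


@dataclass(frozen=True)
class RecoveryReport:
    """How well a set of term calls recovered the planted truth."""

    sensitivity: Mapping[str, float]  # per direction ("SH", "SL"); nan if none planted
    false_discovery_proportion: float | None  # None when nothing was called
    n_planted: int
    n_detected_planted: int
    n_called: int
    direction_errors: int  # planted terms called with the wrong direction


def simulate_rates(
    n_genes: int,
    spec: BackgroundSpec = DEFAULT_BACKGROUND,
    seed: int = 0,
    branch_id: str = "branch0",
) -> RateTable:
    """Draw a genome-scale rate table from the background distributions.

    dS and dN are right-skewed positive draws; omega = dN/dS; an ancestral
    omega is drawn the same way so delta_omega is populated.  Deterministic
    for a given seed.
    """
    if n_genes < 100:
        raise ValidationError(f"n_genes must be >= 100, got {n_genes}")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    dS = spec.dS.sample(rng, n_genes)
    dN = spec.dN.sample(rng, n_genes)
    dS_anc = spec.dS.sample(rng, n_genes)
    dN_anc = spec.dN.sample(rng, n_genes)
    omega = dN / dS
    omega_anc = dN_anc / dS_anc
    frame = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "branch_id": branch_id,
            "dS": dS,
            "dN": dN,
            "omega": omega,
            "omega_ancestral": omega_anc,
            "delta_omega": omega - omega_anc,
            "aln_length_bp": rng.integers(120, 3000, size=n_genes),
        }
    )
    return RateTable(frame)


def _rederive(frame: pd.DataFrame, variable: str) -> None:
    """Re-derive dependent columns after shifting ``variable`` in place."""
    if variable in ("omega", "delta_omega"):
        frame["dN"] = frame["omega"] * frame["dS"]
    elif variable in ("dS", "dN"):
        frame["omega"] = frame["dN"] / frame["dS"]
    frame["delta_omega"] = frame["omega"] - frame["omega_ancestral"]


def plant_modules(
    table: RateTable,
    truth: SyntheticTruth,
    variable: str,
    n_controls: int | None = None,
) -> tuple[RateTable, AnnotationMap]:
    """Shift planted modules along ``variable`` and build the annotation map.

    SH modules are shifted upward, SL downward, by ``effect_size`` times the
    background standard deviation of ``variable``.  Planted members are
    drawn disjointly; the map is padded with negative-control terms of
    random membership whose sizes are resampled from the planted sizes so
    size is not a confound.  Returns the shifted table and the map.
    """
    if variable not in RATE_VARIABLES:
        raise ConfigurationError(f"unknown ranking variable {variable!r}")
    genes = list(table.universe)
    n_genes = len(genes)
    total_planted = sum(m.size for m in truth.planted.values())
    if total_planted > n_genes:
        raise ValidationError(
            f"planted modules need {total_planted} genes but the table has {n_genes}"
        )
    rng = np.random.default_rng(truth.seed)
    frame = table.frame.copy()
    sd = float(frame[variable].std(ddof=1))

    # disjoint planted membership, one draw across all modules
    chosen = rng.choice(n_genes, size=total_planted, replace=False)
    assignments: dict[str, set[str]] = {}
    offset = 0
    idx = frame.set_index("gene_id").index
    for term_id in sorted(truth.planted):
        module = truth.planted[term_id]
        member_idx = chosen[offset : offset + module.size]
        offset += module.size
        members = [genes[i] for i in member_idx]
        assignments[term_id] = set(members)
        shift = module.effect_size * sd * (1.0 if module.direction == "SH" else -1.0)
        rows = frame["gene_id"].isin(members)
        shifted = frame.loc[rows, variable] + shift
        if variable != "delta_omega":  # rates and omega must stay positive
            shifted = shifted.clip(lower=_RATE_FLOOR)
        frame.loc[rows, variable] = shifted
        if variable == "delta_omega":
            # realise the delta shift through the descendant omega
            frame.loc[rows, "omega"] = (
                frame.loc[rows, "omega_ancestral"] + frame.loc[rows, "delta_omega"]
            ).clip(lower=_RATE_FLOOR)
            frame.loc[rows, "delta_omega"] = (
                frame.loc[rows, "omega"] - frame.loc[rows, "omega_ancestral"]
            )
    _rederive(frame, variable)

    # negative controls: random membership over the whole universe, sizes
    # matched to the planted-size distribution so size is not a confound.
    # Controls may touch planted genes by chance, exactly as a biologically
    # unrelated term would; keep the total planted mass small relative to
    # the genome when clean negatives matter.
    planted_sizes = [m.size for m in truth.planted.values()] or [50]
    if n_controls is None:
        n_controls = max(len(truth.planted), 5)
    width = len(str(n_controls)) if n_controls else 1
    for j in range(n_controls):
        size = int(planted_sizes[int(rng.integers(len(planted_sizes)))])
        member_idx = rng.choice(n_genes, size=size, replace=False)
        assignments[f"control{j:0{width}d}"] = {genes[i] for i in member_idx}

    terms = {t: Term(t, name=t) for t in assignments}
    amap = AnnotationMap.from_sets(assignments, terms, universe=genes)
    return RateTable(frame), amap


def recovery_report(calls: Sequence[TermCall], truth: SyntheticTruth) -> RecoveryReport:
    """Sensitivity per direction and false-discovery proportion vs the truth.

    Sensitivity is the fraction of planted terms whose verdict matches the
    planted direction.  FDP is (non-planted terms called non-NS) / (all
    terms called non-NS); with no non-NS calls it is ``None``.
    """
    by_term = {c.term_id: c for c in calls}
    detected = 0
    wrong_direction = 0
    per_direction_hits = {"SH": 0, "SL": 0}
    per_direction_total = {"SH": 0, "SL": 0}
    for term_id, module in truth.planted.items():
        per_direction_total[module.direction] += 1
        call = by_term.get(term_id)
        if call is None or call.verdict == "NS":
            continue
        if call.verdict == module.direction:
            detected += 1
            per_direction_hits[module.direction] += 1
        else:
            wrong_direction += 1
    called = [c for c in calls if c.verdict != "NS"]
    false_calls = sum(1 for c in called if c.term_id not in truth.planted)
    fdp = (false_calls / len(called)) if called else None
    sensitivity = {
        d: (per_direction_hits[d] / per_direction_total[d])
        if per_direction_total[d]
        else float("nan")
        for d in ("SH", "SL")
    }
    return RecoveryReport(
        sensitivity=sensitivity,
        false_discovery_proportion=fdp,
        n_planted=len(truth.planted),
        n_detected_planted=detected,
        n_called=len(called),
        direction_errors=wrong_direction,
    )
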