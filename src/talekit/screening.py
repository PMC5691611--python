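"""Replicate screening statistics, genotype clustering and clone selection.

Implements the decision layer of an evolution campaign: replicate-level
growth metrics with percent relative standard deviation (%RSD), grouping of
resequenced isolates into genetically-identical / genetically-similar
clusters, the %RSD-gated best-clone decision rule (fastest growth rate and
highest final OD with least variability), and per-condition aggregation of
evolution endpoints (mean end concentration, flask counts, fold increase in
tolerated stressor concentration).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .growth import GrowthMetrics

__all__ = [
    "CloneMetrics",
    "ClusterAssignment",
    "PopulationOutcome",
    "ConditionSummary",
    "rsd",
    "cluster_genotypes",
    "select_best_clone",
    "aggregate_condition",
    "fold_increase_report",
    "resequencing_plan",
]

RSD_GATE_PCT = 20.0


def _round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero at a fixed decimal precision.

    Goes through the shortest decimal representation so that e.g. a mean of
    6.05 rounds to 6.1 rather than being a hair below the midpoint in
    binary.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rsd(values: Sequence[float]) -> float:
    """Percent relative standard deviation: 100 * sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicates for %RSD")
    mean = float(arr.mean())
    if mean == 0:
        raise ValueError("%RSD undefined for zero mean")
    return 100.0 * float(arr.std(ddof=1)) / mean


@dataclass(frozen=True)
class CloneMetrics:
    """Replicate-averaged growth metrics for one isolate."""

    isolate: str
    replicates: tuple[GrowthMetrics, ...]
    mean_rate: float
    mean_final_od: float
    mean_lag: float
    rsd_rate: float
    rsd_final_od: float

    @classmethod
    def from_replicates(
        cls, isolate: str, replicates: Sequence[GrowthMetrics]
    ) -> "CloneMetrics":
        if not replicates:
            raise ValueError("need at least one replicate")
        rates = [m.rate for m in replicates]
        finals = [m.final_od for m in replicates]
        lags = [m.lag for m in replicates]
        n = len(replicates)
        return cls(
            isolate=isolate,
            replicates=tuple(replicates),
            mean_rate=float(np.mean(rates)),
            mean_final_od=float(np.mean(finals)),
            mean_lag=float(np.mean(lags)),
            rsd_rate=rsd(rates) if n >= 2 else 0.0,
            rsd_final_od=rsd(finals) if n >= 2 else 0.0,
        )


@dataclass(frozen=True)
class ClusterAssignment:
    isolate: str
    cluster_id: str
    relation: str  # identical | similar | singleton


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def cluster_genotypes(
    genotypes: Mapping[str, set],
    jaccard_min: float = 0.5,
) -> list[ClusterAssignment]:
    """Cluster isolates by genotype (hypermutators assumed pre-excluded).

    Isolates with exactly equal mutation sets form "identical" clusters.
    The remaining isolates are joined by single linkage wherever the
    pairwise Jaccard similarity of their mutation sets is at least
    ``jaccard_min``; linked groups of two or more are "similar", the rest
    are singletons.  Cluster labels are deterministic, derived from sorted
    member names.
    """
    items = {name: frozenset(s) for name, s in genotypes.items()}
    for name, s in items.items():
        if not s:
            warnings.warn(f"isolate {name!r} has an empty genotype; kept as singleton",
                          stacklevel=2)

    by_set: dict[frozenset, list[str]] = defaultdict(list)
    for name in sorted(items):
        by_set[items[name]].append(name)
    clusters: list[tuple[str, list[str]]] = []  # (relation, members)
    leftovers: list[str] = []
    for members in by_set.values():
        if len(members) >= 2:
            clusters.append(("identical", members))
        else:
            leftovers.append(members[0])

    # Single-linkage over the remaining isolates.
    parent = {name: name for name in leftovers}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(leftovers):
        for b in leftovers[i + 1 :]:
            if items[a] and _jaccard(items[a], items[b]) >= jaccard_min:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[str, list[str]] = defaultdict(list)
    for name in leftovers:
        groups[find(name)].append(name)
    for members in groups.values():
        relation = "similar" if len(members) >= 2 else "singleton"
        clusters.append((relation, sorted(members)))

    clusters.sort(key=lambda c: c[1][0])
    out = []
    for i, (relation, members) in enumerate(clusters, start=1):
        cid = f"C{i}"
        for name in members:
            out.append(ClusterAssignment(isolate=name, cluster_id=cid, relation=relation))
    out.sort(key=lambda a: a.isolate)
    return out


def select_best_clone(cluster: Sequence[CloneMetrics]) -> str:
    """Pick the representative clone of a genotype cluster.

    If every member reproduces well (%RSD of rate and final OD both within
    the 20% gate) the ranking is (mean rate desc, mean final OD desc, rate
    %RSD asc); otherwise variability is not trusted as a tie-break and the
    ranking is (mean rate desc, mean final OD desc).  Residual ties go to
    the lexicographically first isolate label.
    """
    if not cluster:
        raise ValueError("cluster must be non-empty")
    all_reproducible = all(
        m.rsd_rate <= RSD_GATE_PCT and m.rsd_final_od <= RSD_GATE_PCT for m in cluster
    )
    if all_reproducible:
        key = lambda m: (-m.mean_rate, -m.mean_final_od, m.rsd_rate, m.isolate)
    else:
        key = lambda m: (-m.mean_rate, -m.mean_final_od, m.isolate)
    return min(cluster, key=key).isolate


@dataclass(frozen=True)
class PopulationOutcome:
    """Endpoint of one independent evolution population."""

    strain: str
    il: str
    start_conc: float
    end_conc: float
    n_flasks: int


@dataclass(frozen=True)
class ConditionSummary:
    """Aggregate of replicate populations evolved under one condition.

    ``mean_end`` and ``sd_end`` are rounded half-away-from-zero to one
    decimal (display precision); ``mean_end_raw`` keeps the unrounded value
    and is what fold-increase comparisons use.  ``start_conc`` and
    ``fold_increase`` are None when the aggregated rows mix starting
    concentrations (e.g. flask-count aggregation across strains).
    """

    strain: str
    il: str
    start_conc: float | None
    end_concs: tuple[float, ...]
    mean_end: float
    sd_end: float | None
    mean_end_raw: float
    flask_counts: tuple[int, ...]
    mean_flasks: int
    fold_increase: float | None


def aggregate_condition(rows: Sequence[PopulationOutcome]) -> ConditionSummary:
    """Aggregate per-population endpoints sharing one ionic liquid.

    Raises a grouping error when rows mix ionic liquids.  Rows may mix
    strains (the summary then carries a joined strain label), which is how
    per-liquid flask-count averages across both strain backgrounds are
    formed.
    """
    if not rows:
        raise ValueError("need at least one population row")
    ils = {r.il for r in rows}
    if len(ils) > 1:
        raise ValueError(f"inconsistent ionic-liquid labels in group: {sorted(ils)}")
    strains = sorted({r.strain for r in rows})
    starts = {r.start_conc for r in rows}
    ends = np.array([r.end_conc for r in rows], dtype=float)
    flasks = tuple(int(r.n_flasks) for r in rows)
    mean_raw = float(ends.mean())
    sd = float(ends.std(ddof=1)) if len(rows) >= 2 else None
    start = starts.pop() if len(starts) == 1 else None
    return ConditionSummary(
        strain="+".join(strains),
        il=rows[0].il,
        start_conc=start,
        end_concs=tuple(float(e) for e in ends),
        mean_end=_round_half_away(mean_raw, 1),
        sd_end=None if sd is None else _round_half_away(sd, 1),
        mean_end_raw=mean_raw,
        flask_counts=flasks,
        mean_flasks=int(_round_half_away(float(np.mean(flasks)), 0)),
        fold_increase=None if start in (None, 0) else mean_raw / start,
    )


def fold_increase_report(summaries: Sequence[ConditionSummary]) -> float:
    """Minimum fold increase in tolerated concentration across conditions."""
    if not summaries:
        raise ValueError("need at least one condition summary")
    folds = [s.fold_increase for s in summaries if s.fold_increase is not None]
    if not folds:
        raise ValueError("no summary carries a defined fold increase")
    return min(folds)


def resequencing_plan(
    n_populations: int,
    n_dropped: int = 0,
    isolates_per_population: int = 3,
) -> int:
    """Number of isolates entering whole-genome resequencing."""
    if n_dropped > n_populations:
        raise ValueError("cannot drop more populations than exist")
    return (n_populations - n_dropped) * isolates_per_population
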