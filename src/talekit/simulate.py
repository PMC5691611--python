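"""Stochastic serial-passage evolution simulator.

Emulates the population dynamics of a tolerance evolution experiment:
parallel batch cultures grow exponentially under a stressor that depresses
growth in a dose-dependent way, beneficial and neutral mutations arrive
during cell divisions, and 1:100 bottlenecks at each passage impose genetic
drift.  Bookkeeping is at the lineage level (a lineage is the clonal
descendance of one mutational event), which keeps cultures of 10^9-10^10
cells tractable: growth within a flask is deterministic per lineage, while
mutation arrivals and bottleneck survival are stochastic.

The dose-response of growth rate on stressor concentration is

    r(C) = r_max * max(0, 1 - (C / tolerance)**hill)

so a lineage stops growing at or above its tolerance concentration, and
beneficial mutations raise tolerance multiplicatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .growth import ODSeries, PLATE_TO_BENCHTOP

__all__ = [
    "GeneMenu",
    "SimConfig",
    "Mutation",
    "Lineage",
    "FlaskResult",
    "default_gene_menu",
    "child_rng",
    "growth_rate_of",
    "simulate_flask",
    "bottleneck",
    "sample_isolates",
    "write_od_csv",
    "write_mutation_table",
]

_MUTATION_TYPES = ("SNP", "DEL", "INS", "MOB")
_TYPE_WEIGHTS = (0.5, 0.25, 0.15, 0.10)


@dataclass(frozen=True)
class GeneMenu:
    """Region labels partitioned into causal (tolerance) and neutral sets."""

    causal: tuple[str, ...]
    neutral: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.causal or not self.neutral:
            raise ValueError("causal and neutral gene sets must be non-empty")
        if set(self.causal) & set(self.neutral):
            raise ValueError("causal and neutral gene sets must be disjoint")


def default_gene_menu(n_causal: int = 5, n_neutral: int = 45) -> GeneMenu:
    """Default menu: 5 causal loci named after recurrently hit tolerance
    genes, plus 45 neutral decoy regions."""
    causal_names = ("yhdP", "mdtJ/tqsA", "rpoC", "rho", "fhuA")
    if n_causal <= len(causal_names):
        causal = causal_names[:n_causal]
    else:
        causal = causal_names + tuple(
            f"cau{i:02d}" for i in range(1, n_causal - len(causal_names) + 1)
        )
    neutral = tuple(f"neu{i:02d}" for i in range(1, n_neutral + 1))
    return GeneMenu(causal=causal, neutral=neutral)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic evolution experiment.

    Attributes
    ----------
    r_max : float
        Maximal (zero-stress) growth rate, h^-1.
    ic50_wt : float
        Wild-type zero-growth stressor concentration, % w/v.
    hill : float
        Shape exponent of the dose-response.
    mu_b, mu_n : float
        Beneficial / neutral mutation rates per cell division.  These are
        effective rates of mutations that would be called by resequencing,
        not genome-wide rates.
    effect_mean : float
        Mean multiplicative tolerance gain per beneficial mutation (> 1).
    gene_menu : GeneMenu
        Causal and neutral region labels.
    cells_per_od : float
        Cells per mL per benchtop OD600 unit.
    volume_ml : float
        Culture working volume, mL.
    plate_ratio : float
        Benchtop-to-plate OD600 ratio.
    seed : int
        Root RNG seed; per-flask streams are derived from it by counter.
    """

    r_max: float = 0.7
    ic50_wt: float = 2.5
    hill: float = 1.0
    mu_b: float = 1e-10
    mu_n: float = 1e-10
    effect_mean: float = 1.1
    gene_menu: GeneMenu = field(default_factory=default_gene_menu)
    cells_per_od: float = 1e9
    volume_ml: float = 15.0
    plate_ratio: float = PLATE_TO_BENCHTOP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.ic50_wt <= 0:
            raise ValueError("ic50_wt must be positive")
        if not (0 <= self.mu_b < 1 and 0 <= self.mu_n < 1):
            raise ValueError("mutation rates must be in [0, 1)")
        if self.effect_mean <= 1:
            raise ValueError("effect_mean must exceed 1")
        if self.cells_per_od <= 0 or self.volume_ml <= 0:
            raise ValueError("cells_per_od and volume_ml must be positive")


@dataclass(frozen=True)
class Mutation:
    """One labeled allele carried by a lineage."""

    region: str
    allele: str
    mutation_type: str
    position: int
    causal: bool


@dataclass(frozen=True)
class Lineage:
    """A clonal lineage: its mutation set, tolerance, and cell count."""

    id: str
    mutations: tuple[Mutation, ...]
    tolerance: float
    size: float

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("lineage size must be non-negative")


@dataclass(frozen=True)
class FlaskResult:
    """Outcome of one batch flask: OD trace and lineage state at passage."""

    flask_index: int
    concentration: float
    od_series: ODSeries
    lineage_snapshot: tuple[Lineage, ...]
    crashed: bool
    duration_h: float


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Derive a reproducible child RNG stream from a root seed and counters.

    The stream depends only on (seed, key), never on call order, so flasks
    and populations can be simulated in any order with identical results.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def growth_rate_of(lineage: Lineage, concentration: float, config: SimConfig) -> float:
    """Dose-dependent growth rate of a lineage at a stressor concentration."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    frac = (concentration / lineage.tolerance) ** config.hill
    return config.r_max * max(0.0, 1.0 - frac)


def _plate_od(total_cells: float, config: SimConfig) -> float:
    return total_cells / (config.cells_per_od * config.volume_ml * config.plate_ratio)


def simulate_flask(
    lineages: Sequence[Lineage],
    concentration: float,
    config: SimConfig,
    passage_od: float = 0.3,
    timeout_h: float = 72.0,
    *,
    rng: np.random.Generator | None = None,
    flask_index: int = 0,
    allele_prefix: str = "",
    sample_dt: float = 0.5,
) -> FlaskResult:
    """Simulate one exponential batch between passages.

    Each lineage grows deterministically at its dose-dependent rate until the
    culture reaches ``passage_od`` (plate-reader units) or ``timeout_h``
    elapses, in which case the flask is marked crashed.  Beneficial and
    neutral mutations arrive as Poisson processes over the divisions in each
    lineage; every arrival founds a child lineage carrying a new unique
    allele, with a multiplicative tolerance gain for beneficial arrivals.
    """
    if not lineages:
        raise ValueError("lineage list must be non-empty")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    sizes = np.array([lin.size for lin in lineages], dtype=float)
    if sizes.sum() <= 0:
        raise ValueError("total initial cell count must be positive")
    if rng is None:
        rng = child_rng(config.seed, flask_index)

    rates = np.array([growth_rate_of(lin, concentration, config) for lin in lineages])
    n_target = passage_od * config.plate_ratio * config.cells_per_od * config.volume_ml

    def total_at(t: float) -> float:
        return float(np.dot(sizes, np.exp(rates * t)))

    if total_at(0.0) >= n_target:
        duration, crashed = 0.0, False
    elif total_at(timeout_h) >= n_target:
        duration = float(brentq(lambda t: total_at(t) - n_target, 0.0, timeout_h))
        crashed = False
    else:
        duration, crashed = timeout_h, True

    # OD trace on the sampling grid plus the passage/timeout instant.
    grid = np.arange(0.0, duration, sample_dt)
    if grid.size == 0 or grid[-1] < duration:
        grid = np.append(grid, duration)
    ods = np.array([_plate_od(total_at(t), config) for t in grid])
    series = ODSeries(times=grid, ods=ods, unit="plate")

    growth_factors = np.exp(rates * duration)
    end_sizes = sizes * growth_factors
    divisions = end_sizes - sizes  # net new cells ~ divisions

    survivors: list[Lineage] = [
        replace(lin, size=float(end_sizes[i])) for i, lin in enumerate(lineages)
    ]
    children: list[Lineage] = []
    allele_counter = 0
    menu = config.gene_menu
    for i, parent in enumerate(lineages):
        if divisions[i] <= 0 or rates[i] <= 0:
            continue
        for causal, mu, regions in (
            (True, config.mu_b, menu.causal),
            (False, config.mu_n, menu.neutral),
        ):
            if mu <= 0:
                continue
            k = int(rng.poisson(mu * divisions[i]))
            for _ in range(k):
                region = regions[int(rng.integers(len(regions)))]
                allele_counter += 1
                allele = f"{allele_prefix}{flask_index}.{allele_counter}"
                mut = Mutation(
                    region=region,
                    allele=allele,
                    mutation_type=str(rng.choice(_MUTATION_TYPES, p=_TYPE_WEIGHTS)),
                    position=int(rng.integers(1, 3001)),
                    causal=causal,
                )
                tol = parent.tolerance
                if causal:
                    tol *= 1.0 + float(rng.exponential(config.effect_mean - 1.0))
                # Arrival time: division density in the parent is n*r*e^{rt},
                # so e^{r t_a} is uniform on (1, e^{r T}).
                u = rng.uniform(1.0, growth_factors[i])
                t_arr = math.log(u) / rates[i]
                child = Lineage(id=allele, mutations=parent.mutations + (mut,), tolerance=tol, size=1.0)
                r_child = growth_rate_of(child, concentration, config)
                child = replace(child, size=max(1.0, math.exp(r_child * (duration - t_arr))))
                children.append(child)

    return FlaskResult(
        flask_index=flask_index,
        concentration=concentration,
        od_series=series,
        lineage_snapshot=tuple(survivors + children),
        crashed=crashed,
        duration_h=duration,
    )


def bottleneck(
    lineages: Sequence[Lineage],
    dilution: float,
    config: SimConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> list[Lineage]:
    """Pass a culture fraction into fresh medium.

    Each lineage's transferred count is binomial with success probability
    ``dilution``; lineages with zero transferred cells are dropped.
    """
    if not (0 < dilution <= 1):
        raise ValueError("dilution must be in (0, 1]")
    if dilution == 1.0:
        return [replace(lin) for lin in lineages]
    if rng is None:
        seed = config.seed if config is not None else 0
        rng = child_rng(seed, 1)
    out: list[Lineage] = []
    for lin in lineages:
        n = int(round(lin.size))
        if n <= 0:
            continue
        k = int(rng.binomial(n, dilution))
        if k > 0:
            out.append(replace(lin, size=float(k)))
    return out


def sample_isolates(
    final_lineages: Sequence[Lineage],
    n: int,
    seed: int,
    *,
    strain: str = "SIM",
    population: str = "pop1",
) -> list[pd.DataFrame]:
    """Sample endpoint clonal isolates, frequency-weighted by lineage size.

    Emulates plating an endpoint population and picking colonies: each of
    the ``n`` isolates is one lineage drawn with probability proportional to
    its cell count.  Returns one mutation table per isolate with columns
    matching the analysis module's expected input (strain, population,
    isolate, region, position, mutation_type, description).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sizes = np.array([lin.size for lin in final_lineages], dtype=float)
    total = sizes.sum()
    if total <= 0:
        raise ValueError("all lineage sizes are zero")
    rng = child_rng(seed, 2)
    idx = rng.choice(len(final_lineages), size=n, replace=True, p=sizes / total)
    tables = []
    for k, i in enumerate(idx, start=1):
        lin = final_lineages[int(i)]
        rows = [
            {
                "strain": strain,
                "population": population,
                "isolate": f"{population}.{k}",
                "region": m.region,
                "position": m.position,
                "mutation_type": m.mutation_type,
                "description": f"allele:{m.allele}",
            }
            for m in lin.mutations
        ]
        tables.append(
            pd.DataFrame(
                rows,
                columns=[
                    "strain",
                    "population",
                    "isolate",
                    "region",
                    "position",
                    "mutation_type",
                    "description",
                ],
            )
        )
    return tables


def write_od_csv(results: Iterable[FlaskResult], path) -> None:
    """Write flask OD traces as CSV (flask_index, time_h, od_plate, concentration_pct)."""
    frames = []
    for fr in results:
        frames.append(
            pd.DataFrame(
                {
                    "flask_index": fr.flask_index,
                    "time_h": fr.od_series.times,
                    "od_plate": fr.od_series.ods,
                    "concentration_pct": fr.concentration,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_mutation_table(tables: Iterable[pd.DataFrame], path) -> None:
    """Write isolate mutation tables as one tab-separated file."""
    df = pd.concat(list(tables), ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
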