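"""Convergent-mutation analysis of resequenced evolution isolates.

Starting from per-isolate mutation calls (tab-separated tables or a minimal
GenomeDiff-style dialect, i.e. downstream of breseq), this module

* normalizes region names so that the same intergenic region is grouped
  regardless of gene order ("tqsA/mdtJ" == "mdtJ/tqsA"),
* flags hypermutator isolates by their outlying genome-wide mutation count,
* identifies *key mutations*: genes or intergenic regions carrying multiple
  unique alleles, or mutated in isolates from independent populations --
  the classic signature of convergent (parallel) evolution, and
* categorizes key regions as "combined" (observed in two or more strain
  backgrounds) versus "strain-specific".
"""

from __future__ import annotations

import io
import os
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MUTATION_TYPES",
    "MutationRecord",
    "KeyMutationSummary",
    "HypermutatorCall",
    "ParseResult",
    "MutationTableFormatError",
    "parse_mutation_table",
    "canonical_region",
    "flag_hypermutators",
    "exclude_hypermutators",
    "identify_key_mutations",
    "summarize_counts",
]

MUTATION_TYPES = frozenset({"SNP", "DEL", "INS", "MOB"})

_REQUIRED_COLUMNS = (
    "strain",
    "population",
    "isolate",
    "region",
    "position",
    "mutation_type",
    "description",
)

_CATEGORY_ORDER = {"combined": 0, "strain-specific": 1, "not-key": 2}


class MutationTableFormatError(ValueError):
    """Raised when a mutation table is structurally unusable."""


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation in one isolate.

    ``(region, position, description)`` identifies a unique allele;
    coordinates follow the 1-based inclusive breseq/GenomeDiff convention
    (kept as text, since spans and amino-acid labels also occur).
    """

    strain: str
    population: str
    isolate: str
    region: str
    position: str
    mutation_type: str
    description: str
    coding: str = ""

    def __post_init__(self) -> None:
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mutation_type!r}")
        if not self.strain or not self.population:
            raise ValueError("strain and population labels must be non-empty")

    @property
    def allele(self) -> tuple[str, str, str]:
        return (self.position, self.description, self.mutation_type)

    @property
    def isolate_key(self) -> tuple[str, str, str]:
        return (self.strain, self.population, self.isolate)


@dataclass(frozen=True)
class KeyMutationSummary:
    """Per-region recurrence evidence and key-mutation category."""

    region: str
    unique_alleles: int
    isolate_count: int
    populations: frozenset[tuple[str, str]]
    strains: frozenset[str]
    category: str


@dataclass(frozen=True)
class HypermutatorCall:
    isolate: str
    n_mutations: int
    flagged: bool
    cohort_median: float
    threshold_used: float


@dataclass(frozen=True)
class ParseResult:
    """Parsed records plus an error report of malformed rows (never silently
    dropped)."""

    records: tuple[MutationRecord, ...]
    errors: tuple[tuple[int, str, str], ...]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def canonical_region(region: str) -> str:
    """Canonical name for a gene or intergenic region.

    Intergenic regions written "a/b" are returned with the gene pair sorted
    lexicographically; gene names pass through unchanged.  Idempotent.
    """
    if not region:
        raise ValueError("region name must be non-empty")
    if "/" in region:
        parts = [p.strip() for p in region.split("/")]
        return "/".join(sorted(parts))
    return region


def _normalize_type(raw: str) -> str:
    t = raw.strip().upper()
    aliases = {"SNP": "SNP", "SUB": "SNP", "DEL": "DEL", "INS": "INS", "MOB": "MOB"}
    if t not in aliases:
        raise ValueError(f"unknown mutation type {raw!r}")
    return aliases[t]


def _lines_from_source(source) -> list[str]:
    if isinstance(source, (str, os.PathLike)) and not (
        isinstance(source, str) and ("\n" in source or "\t" in source)
    ):
        with open(source, "r", encoding="utf-8") as fh:
            return fh.read().splitlines()
    if isinstance(source, str):
        return source.splitlines()
    if isinstance(source, io.IOBase):
        return source.read().splitlines()
    return [str(line).rstrip("\n") for line in source]


def _parse_gd_lines(
    lines: list[str], strain: str, population: str, isolate: str
) -> tuple[list[MutationRecord], list[tuple[int, str, str]]]:
    """Minimal GenomeDiff dialect: SNP/DEL/INS/MOB entry lines, with an
    optional ``gene_name=`` key-value field supplying the region."""
    records: list[MutationRecord] = []
    errors: list[tuple[int, str, str]] = []
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0].strip().upper()
        if kind not in MUTATION_TYPES:
            errors.append((i, f"unknown entry type {fields[0]!r}", line))
            continue
        if len(fields) < 5:
            errors.append((i, "too few fields for a mutation entry", line))
            continue
        kv = dict(
            f.split("=", 1) for f in fields[5:] if "=" in f
        )
        region = kv.get("gene_name", fields[3]).strip()
        desc = kv.get("description") or " ".join(
            f for f in fields[5:] if "=" not in f
        ) or kind
        try:
            records.append(
                MutationRecord(
                    strain=strain,
                    population=population,
                    isolate=isolate,
                    region=region,
                    position=fields[4].strip(),
                    mutation_type=kind,
                    description=desc.strip(),
                )
            )
        except ValueError as exc:
            errors.append((i, str(exc), line))
    return records, errors


def parse_mutation_table(
    source,
    *,
    strain: str = "unknown",
    population: str = "unknown",
    isolate: str = "unknown",
) -> ParseResult:
    """Parse per-isolate mutation calls into :class:`MutationRecord` rows.

    Accepts a path, raw text, an iterable of lines, or a DataFrame.  Two
    dialects are recognized: a tab-separated table with a header naming the
    columns strain, population, isolate, region, position, mutation_type,
    description; or GenomeDiff-style entry lines (SNP/DEL/INS/MOB), in which
    case the strain/population/isolate labels are taken from the keyword
    arguments.  Malformed rows are collected in the error report.
    """
    if isinstance(source, pd.DataFrame):
        df = source
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise MutationTableFormatError(f"missing required column {missing[0]!r}")
        records, errors = [], []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                records.append(
                    MutationRecord(
                        strain=str(row.strain),
                        population=str(row.population),
                        isolate=str(row.isolate),
                        region=str(row.region),
                        position=str(row.position),
                        mutation_type=_normalize_type(str(row.mutation_type)),
                        description=str(row.description),
                        coding=str(getattr(row, "coding", "")),
                    )
                )
            except ValueError as exc:
                errors.append((i, str(exc), str(tuple(row))))
        return ParseResult(tuple(records), tuple(errors))

    lines = _lines_from_source(source)
    body = [l for l in lines if l.strip() and not l.startswith("#")]
    if body and body[0].split("\t")[0].strip().upper() in MUTATION_TYPES:
        records, errors = _parse_gd_lines(lines, strain, population, isolate)
        return ParseResult(tuple(records), tuple(errors))

    if not body:
        raise MutationTableFormatError("no header found in mutation table")
    header = [h.strip() for h in body[0].split("\t")]
    col_index = {name: i for i, name in enumerate(header)}
    missing = [c for c in _REQUIRED_COLUMNS if c not in col_index]
    if missing:
        raise MutationTableFormatError(f"missing required column {missing[0]!r}")
    records, errors = [], []
    for lineno, line in enumerate(body[1:], start=2):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < len(header):
            errors.append((lineno, "row has fewer fields than header", line))
            continue
        get = lambda c: fields[col_index[c]]
        try:
            records.append(
                MutationRecord(
                    strain=get("strain"),
                    population=get("population"),
                    isolate=get("isolate"),
                    region=get("region"),
                    position=get("position"),
                    mutation_type=_normalize_type(get("mutation_type")),
                    description=get("description"),
                    coding=fields[col_index["coding"]] if "coding" in col_index else "",
                )
            )
        except ValueError as exc:
            errors.append((lineno, str(exc), line))
    return ParseResult(tuple(records), tuple(errors))


def flag_hypermutators(
    records: Sequence[MutationRecord],
    multiplier: float = 4.0,
    min_threshold: int = 20,
) -> list[HypermutatorCall]:
    """Flag isolates whose mutation count is an outlier in the cohort.

    The threshold is ``max(min_threshold, multiplier * cohort median)``; an
    isolate is flagged iff its count strictly exceeds it.  This is a
    heuristic stand-in for inspection-based hypermutator identification and
    both knobs are configurable.
    """
    if not records:
        raise ValueError("need at least one record (one isolate)")
    counts: dict[tuple[str, str, str], int] = defaultdict(int)
    for rec in records:
        counts[rec.isolate_key] += 1
    values = sorted(counts.values())
    mid = len(values) // 2
    median = (
        float(values[mid])
        if len(values) % 2
        else (values[mid - 1] + values[mid]) / 2.0
    )
    threshold = max(float(min_threshold), multiplier * median)
    calls = []
    for key in sorted(counts):
        n = counts[key]
        calls.append(
            HypermutatorCall(
                isolate=":".join(key),
                n_mutations=n,
                flagged=n > threshold,
                cohort_median=median,
                threshold_used=threshold,
            )
        )
    return calls


def exclude_hypermutators(
    records: Sequence[MutationRecord],
    multiplier: float = 4.0,
    min_threshold: int = 20,
) -> tuple[list[MutationRecord], list[HypermutatorCall]]:
    """Drop all records of flagged hypermutator isolates."""
    calls = flag_hypermutators(records, multiplier, min_threshold)
    flagged = {c.isolate for c in calls if c.flagged}
    kept = [r for r in records if ":".join(r.isolate_key) not in flagged]
    return kept, calls


def identify_key_mutations(
    records: Sequence[MutationRecord],
) -> list[KeyMutationSummary]:
    """Find convergently mutated regions (hypermutators assumed excluded).

    Records are grouped by canonical region.  A region is *key* iff it
    carries >= 2 unique alleles -- distinct (position, description, type)
    triples -- or is mutated in isolates from >= 2 independent populations
    (distinct (strain, population) labels; isolates from one population
    share ancestry and do not count as independent evidence).  Key regions
    observed in >= 2 strain backgrounds are "combined", otherwise
    "strain-specific"; non-key regions are still summarized as "not-key".
    """
    by_region: dict[str, list[MutationRecord]] = defaultdict(list)
    for rec in records:
        by_region[canonical_region(rec.region)].append(rec)
    summaries = []
    for region, recs in by_region.items():
        alleles = {r.allele for r in recs}
        isolates = {r.isolate_key for r in recs}
        populations = frozenset((r.strain, r.population) for r in recs)
        strains = frozenset(r.strain for r in recs)
        is_key = len(alleles) >= 2 or len(populations) >= 2
        if not is_key:
            category = "not-key"
        elif len(strains) >= 2:
            category = "combined"
        else:
            category = "strain-specific"
        summaries.append(
            KeyMutationSummary(
                region=region,
                unique_alleles=len(alleles),
                isolate_count=len(isolates),
                populations=populations,
                strains=strains,
                category=category,
            )
        )
    summaries.sort(key=lambda s: (_CATEGORY_ORDER[s.category], -s.isolate_count, s.region))
    return summaries


def summarize_counts(
    summaries: Sequence[KeyMutationSummary],
    records: Sequence[MutationRecord],
) -> pd.DataFrame:
    """Per-allele isolate counts with per-region totals.

    Returns one row per (region, allele) restricted to the summarized
    regions, with columns region, position, mutation_type, description,
    isolate_count and region_total; region totals equal the sum of that
    region's allele counts.
    """
    wanted = {s.region for s in summaries}
    per_allele: dict[tuple, set] = defaultdict(set)
    for rec in records:
        region = canonical_region(rec.region)
        if region in wanted:
            per_allele[(region, *rec.allele)].add(rec.isolate_key)
    rows = [
        {
            "region": key[0],
            "position": key[1],
            "description": key[2],
            "mutation_type": key[3],
            "isolate_count": len(isolates),
        }
        for key, isolates in per_allele.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=["region", "position", "description", "mutation_type", "isolate_count"],
    )
    if df.empty:
        df["region_total"] = pd.Series(dtype=int)
        return df
    df["region_total"] = df.groupby("region")["isolate_count"].transform("sum")
    order = {s.region: i for i, s in enumerate(summaries)}
    df["_order"] = df["region"].map(lambda r: order.get(r, len(order)))
    df = df.sort_values(["_order", "isolate_count"], ascending=[True, False])
    return df.drop(columns="_order").reset_index(drop=True)
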