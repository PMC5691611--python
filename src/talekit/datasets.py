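"""Packaged worked-example datasets.

Two small fixtures transcribe the published summary tables of an ionic-liquid
tolerance evolution campaign in *E. coli* K-12 MG1655 and DH1:

* ``load_endpoint_table`` -- per-population evolution endpoints (starting and final
  stressor concentrations, growth rates, flask counts) for 16 independent
  populations across two strains and two ionic liquids,
  1-butyl-3-methylimidazolium chloride ("B", [C4C1Im]Cl) and
  1-ethyl-3-methylimidazolium acetate ("E", [C2C1Im][OAc]).
* ``load_key_mutation_catalog`` -- the key-mutation catalogue: recurrently mutated genes
  and intergenic regions with allele descriptions, mutation types and
  per-allele isolate counts.

``catalog_mutation_records`` expands the allele-level catalogue into
synthetic per-isolate records so the convergence pipeline can run on it:
each allele row becomes ``count`` isolates, distributed round-robin over
four population labels per strain/liquid (the real population assignments
are not part of the published table).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mutations import MutationRecord
from .screening import PopulationOutcome

__all__ = [
    "load_endpoint_table",
    "load_key_mutation_catalog",
    "endpoint_outcomes",
    "catalog_mutation_records",
]

_POPS_PER_CONDITION = 4


def _data_path(name: str):
    return resources.files("talekit.data").joinpath(name)


def load_endpoint_table() -> pd.DataFrame:
    """Evolution-endpoint table: one row per independent population."""
    with resources.as_file(_data_path("evolution_endpoints.csv")) as p:
        return pd.read_csv(p)


def load_key_mutation_catalog() -> pd.DataFrame:
    """Key-mutation catalogue: one row per unique allele."""
    with resources.as_file(_data_path("key_mutation_catalog.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def endpoint_outcomes() -> list[PopulationOutcome]:
    """Endpoint-table rows as :class:`PopulationOutcome` objects."""
    df = load_endpoint_table()
    return [
        PopulationOutcome(
            strain=row.strain,
            il=row.il,
            start_conc=float(row.start_conc_pct),
            end_conc=float(row.end_conc_pct),
            n_flasks=int(row.n_flasks),
        )
        for row in df.itertuples(index=False)
    ]


def catalog_mutation_records() -> list[MutationRecord]:
    """Expand the allele catalogue into synthetic per-isolate records.

    Each allele row yields ``count`` isolate records.  Isolate labels are
    synthetic (unique per row) and population labels cycle through four
    populations per strain/ionic-liquid combination, mirroring the four
    replicate populations evolved per condition; allele identities
    (region, position, description, type) are transcribed verbatim.
    """
    df = load_key_mutation_catalog()
    records: list[MutationRecord] = []
    for ridx, row in df.iterrows():
        il = str(row["il"]).split(",")[0]
        for k in range(int(row["count"])):
            pop = f"{row['strain']}-{il}-p{(k % _POPS_PER_CONDITION) + 1}"
            records.append(
                MutationRecord(
                    strain=str(row["strain"]),
                    population=pop,
                    isolate=f"{pop}-r{ridx:02d}i{k + 1}",
                    region=str(row["region"]),
                    position=str(row["position"]),
                    mutation_type=str(row["mutation_type"]),
                    description=str(row["description"]),
                )
            )
    return records
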