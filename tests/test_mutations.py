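"""Mutation-table parsing, hypermutator flagging, key-mutation convergence."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from talekit.datasets import load_key_mutation_catalog, catalog_mutation_records
from talekit.mutations import (
    MutationRecord,
    MutationTableFormatError,
    canonical_region,
    exclude_hypermutators,
    flag_hypermutators,
    identify_key_mutations,
    parse_mutation_table,
    summarize_counts,
)


def record(
    region,
    isolate="i1",
    population="p1",
    strain="MG",
    position="1",
    mutation_type="SNP",
    description="x",
):
    return MutationRecord(
        strain=strain,
        population=population,
        isolate=isolate,
        region=region,
        position=position,
        mutation_type=mutation_type,
        description=description,
    )


class TestParse:
    HEADER = "strain\tpopulation\tisolate\tregion\tposition\tmutation_type\tdescription"

    def test_parses_insertion_row(self):
        text = (
            self.HEADER
            + "\nMG\tALE1\tMG4.7\tyhdP\t647\tINS\t(TGGAGCC)1→2"
        )
        result = parse_mutation_table(text)
        assert len(result) == 1
        rec = result.records[0]
        assert rec.mutation_type == "INS"
        assert rec.region == "yhdP"
        assert not result.errors

    def test_empty_file_with_header(self):
        result = parse_mutation_table(self.HEADER)
        assert len(result) == 0
        assert not result.errors

    def test_unknown_type_routed_to_error_report(self):
        text = self.HEADER + "\nMG\tALE1\tMG4.7\tyhdP\t647\tAMP\tdup"
        result = parse_mutation_table(text)
        assert len(result) == 0
        assert len(result.errors) == 1
        assert "AMP" in result.errors[0][1]

    def test_missing_column_names_the_column(self):
        bad = "strain\tpopulation\tisolate\tregion\tposition\tdescription\nMG\tp\ti\tg\t1\td"
        with pytest.raises(MutationTableFormatError, match="mutation_type"):
            parse_mutation_table(bad)

    def test_genomediff_dialect(self):
        gd = "\n".join(
            [
                "#=GENOME_DIFF 1.0",
                "SNP\t1\t10\tNC_000913\t3815859\tA\tgene_name=rho",
                "DEL\t2\t11\tNC_000913\t1000\t120",
            ]
        )
        result = parse_mutation_table(
            gd, strain="DH1", population="ALE13", isolate="DH13.10"
        )
        assert [r.mutation_type for r in result.records] == ["SNP", "DEL"]
        assert result.records[0].region == "rho"
        assert result.records[0].isolate == "DH13.10"


class TestCanonicalRegion:
    @pytest.mark.parametrize(
        "raw,canonical",
        [
            ("tqsA/mdtJ", "mdtJ/tqsA"),
            ("mdtJ/tqsA", "mdtJ/tqsA"),
            ("yhdP", "yhdP"),
            ("pyrE/rph", "pyrE/rph"),
        ],
    )
    def test_examples(self, raw, canonical):
        assert canonical_region(raw) == canonical

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.text(
                alphabet=st.characters(whitelist_categories=("Ll", "Lu")),
                min_size=1,
                max_size=6,
            ),
            min_size=1,
            max_size=3,
        )
    )
    def test_idempotent(self, parts):
        name = "/".join(parts)
        once = canonical_region(name)
        assert canonical_region(once) == once


class TestHypermutators:
    def _records_with_counts(self, counts):
        recs = []
        for isolate, n in counts.items():
            for j in range(n):
                recs.append(
                    record("g%d" % j, isolate=isolate, position=str(j),
                           description=f"{isolate}-{j}")
                )
        return recs

    def test_extreme_outlier_flagged(self):
        recs = self._records_with_counts({"a": 5, "b": 6, "c": 267})
        calls = {c.isolate.split(":")[-1]: c for c in flag_hypermutators(recs)}
        assert calls["c"].flagged
        assert not calls["a"].flagged and not calls["b"].flagged

    def test_homogeneous_cohort_unflagged(self):
        recs = self._records_with_counts({"a": 5, "b": 5, "c": 5})
        assert not any(c.flagged for c in flag_hypermutators(recs))

    def test_threshold_is_multiplier_times_median(self):
        recs = self._records_with_counts({"a": 4, "b": 6, "c": 39})
        calls = {c.isolate.split(":")[-1]: c for c in flag_hypermutators(recs)}
        assert calls["c"].threshold_used == pytest.approx(24.0)
        assert calls["c"].flagged
        assert not calls["a"].flagged

    def test_exclusion_removes_all_flagged_records(self):
        recs = self._records_with_counts({"a": 5, "b": 6, "c": 267})
        kept, calls = exclude_hypermutators(recs)
        isolates = {r.isolate for r in kept}
        assert "c" not in isolates
        assert {"a", "b"} <= isolates


@pytest.fixture(scope="module")
def catalog_records():
    return catalog_mutation_records()


class TestKeyMutations:
    def test_yhdp_has_five_unique_alleles(self, catalog_records):
        summ = identify_key_mutations(catalog_records)
        yhdp = next(s for s in summ if s.region == "yhdP")
        assert yhdp.unique_alleles == 5
        assert yhdp.category == "combined"

    def test_exactly_two_combined_regions(self, catalog_records):
        summ = identify_key_mutations(catalog_records)
        combined = {s.region for s in summ if s.category == "combined"}
        assert combined == {"mdtJ/tqsA", "yhdP"}

    def test_private_single_mutation_is_not_key(self):
        recs = [record("geneX")]
        summ = identify_key_mutations(recs)
        assert summ[0].category == "not-key"

    def test_two_populations_single_allele_each_is_key(self):
        recs = [
            record("geneX", isolate="i1", population="p1", description="d1"),
            record("geneX", isolate="i2", population="p2", description="d1"),
        ]
        assert identify_key_mutations(recs)[0].category == "strain-specific"

    def test_order_and_relabeling_invariance(self, catalog_records):
        base = identify_key_mutations(catalog_records)
        shuffled = list(catalog_records)
        random.Random(123).shuffle(shuffled)
        relabeled = [
            MutationRecord(
                strain=r.strain,
                population=r.population,
                isolate="iso-" + r.isolate,
                region=r.region,
                position=r.position,
                mutation_type=r.mutation_type,
                description=r.description,
            )
            for r in shuffled
        ]
        again = identify_key_mutations(relabeled)
        assert [(s.region, s.category, s.unique_alleles) for s in base] == [
            (s.region, s.category, s.unique_alleles) for s in again
        ]


class TestSummarizeCounts:
    def test_rho_region_total_is_13(self, catalog_records):
        summ = identify_key_mutations(catalog_records)
        counts = summarize_counts(summ, catalog_records)
        rho = counts[counts.region == "rho"]
        assert len(rho) == 4  # four coding SNP alleles
        assert rho.region_total.iloc[0] == 13

    def test_region_totals_conserve_allele_counts(self, catalog_records):
        summ = identify_key_mutations(catalog_records)
        counts = summarize_counts(summ, catalog_records)
        for region, grp in counts.groupby("region"):
            assert (grp.region_total == grp.isolate_count.sum()).all()

    def test_empty_inputs_give_empty_report(self):
        df = summarize_counts([], [])
        assert df.empty

    def test_single_allele_three_isolates(self):
        recs = [
            record("geneX", isolate=f"i{k}", population=f"p{k}") for k in range(3)
        ]
        summ = identify_key_mutations(recs)
        counts = summarize_counts(summ, recs)
        assert counts.region_total.iloc[0] == 3


class TestCatalogFixture:
    def test_catalogue_shape(self):
        df = load_key_mutation_catalog()
        assert len(df) == 32
        assert set(df.mutation_type) <= {"SNP", "DEL", "INS", "MOB"}

    def test_expansion_matches_counts(self, catalog_records):
        df = load_key_mutation_catalog()
        assert len(catalog_records) == int(df["count"].sum())
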