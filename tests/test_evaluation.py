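"""Consistency rate, identification rate, overlaps, protein support,
operon detection and collection arithmetic."""

import random

import pytest

from hapid import (
    GeneLocus,
    collection_summary,
    consistency_rate,
    detect_expressed_operons,
    genome_support_summary,
    identification_rate,
    il_canonical,
    peptide_overlap,
    protein_support,
)
from hapid.evaluation import read_loci_tsv
from hapid.search_engine import PSM


def psm(sid, peptide, proteins=("p1",)):
    return PSM(sid, peptide, 10.0, False, frozenset(proteins))


class TestConsistencyRate:
    def test_nine_of_ten_shared(self):
        small = [psm(f"s{i}", "AAAK") for i in range(10)]
        big = [psm(f"s{i}", "AAAK") for i in range(9)] + [psm("s9", "CCCK")]
        rate, n_same, n_shared = consistency_rate(small, big)
        assert (rate, n_same, n_shared) == (0.9, 9, 10)

    def test_identical_runs_give_one(self):
        psms = [psm("s1", "AAAK"), psm("s2", "MMMK")]
        assert consistency_rate(psms, psms)[0] == 1.0

    def test_leucine_isoleucine_swap_counts_as_same(self):
        assert consistency_rate([psm("s1", "NIK")], [psm("s1", "NLK")])[0] == 1.0

    def test_spectra_only_in_one_run_ignored(self):
        small = [psm("s1", "AAAK"), psm("s2", "CCCK")]
        big = [psm("s1", "AAAK"), psm("s3", "DDDK")]
        assert consistency_rate(small, big) == (1.0, 1, 1)

    def test_disjoint_runs_rejected(self):
        with pytest.raises(ValueError, match="both runs"):
            consistency_rate([psm("s1", "AAAK")], [psm("s2", "AAAK")])

    def test_il_canonicalization_idempotent(self):
        for pep in ("NIK", "NLK", "ILLIL", "PEPTIDE"):
            assert il_canonical(il_canonical(pep)) == il_canonical(pep)


class TestIdentificationRate:
    @pytest.mark.parametrize(
        "n_id,n_total,expected",
        [(39, 100, 39.0), (0, 100, 0.0), (22000, 57835, 38.04)],
    )
    def test_arithmetic(self, n_id, n_total, expected):
        assert identification_rate(n_id, n_total) == pytest.approx(expected, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            identification_rate(1, 0)
        with pytest.raises(ValueError):
            identification_rate(5, 4)


class TestPeptideOverlap:
    def test_non_il_difference_is_disjoint(self):
        assert peptide_overlap({"PEPTIDEK"}, {"PEPTVDEK"}) == (1, 0, 1)

    def test_il_swap_is_shared(self):
        assert peptide_overlap({"NIK"}, {"NLK"}) == (0, 1, 0)

    def test_identical_sets(self):
        assert peptide_overlap({"AAK", "CCK"}, {"AAK", "CCK"}) == (0, 2, 0)


class TestProteinSupport:
    def test_distinct_spectra_per_protein(self):
        psms = [psm(f"s{i}", "AAAK", proteins=("p1",)) for i in range(3)]
        assert protein_support(psms) == {"p1": 3}

    def test_shared_peptide_credits_every_protein(self):
        psms = [psm("s1", "AAAK", proteins=("p1", "p2"))]
        assert protein_support(psms) == {"p1": 1, "p2": 1}

    def test_genome_summary_percentages(self):
        psms = [psm(f"s{i}", "AAAK", proteins=(f"p{i}",)) for i in range(19)]
        registry = {f"p{i}": "g1" for i in range(19)}
        df = genome_support_summary(psms, {"g1": 100}, registry, min_spectra=1)
        assert df.loc[0, "n_supported"] == 19
        assert df.loc[0, "percent_supported"] == pytest.approx(19.0)

    def test_min_spectra_threshold(self):
        psms = [psm(f"s{i}", "AAAK", proteins=("p1",)) for i in range(3)]
        psms += [psm("s9", "CCCK", proteins=("p2",))]
        registry = {"p1": "g1", "p2": "g1"}
        df = genome_support_summary(psms, {"g1": 10}, registry, min_spectra=3)
        assert df.loc[0, "n_supported"] == 1


def locus(gid, start, end, strand="+", count=12, contig="c1"):
    return GeneLocus(gid, f"prot_{gid}", contig, start, end, strand, count)


class TestOperons:
    def test_two_gene_cluster_within_gap(self):
        clusters = detect_expressed_operons(
            [locus("a", 1, 300, count=12), locus("b", 350, 600, count=15)]
        )
        assert len(clusters) == 1
        assert [g.gene_id for g in clusters[0]] == ["a", "b"]

    def test_opposite_strand_breaks_cluster(self):
        clusters = detect_expressed_operons(
            [locus("a", 1, 300), locus("b", 350, 600, strand="-")]
        )
        assert clusters == []

    def test_gap_boundary_inclusive_at_100(self):
        # end 300, next start 401 -> gap exactly 100
        assert detect_expressed_operons([locus("a", 1, 300), locus("b", 401, 600)])
        # gap 101 -> broken
        assert not detect_expressed_operons([locus("a", 1, 300), locus("b", 402, 600)])

    def test_mean_exactly_ten_rejected(self):
        clusters = detect_expressed_operons(
            [locus("a", 1, 300, count=10), locus("b", 350, 600, count=10)]
        )
        assert clusters == []

    def test_overlapping_genes_treated_as_gap_zero(self):
        clusters = detect_expressed_operons(
            [locus("a", 1, 300), locus("b", 250, 500)]
        )
        assert len(clusters) == 1

    def test_clusters_partition_genes_and_ignore_input_order(self):
        loci = [
            locus("a", 1, 300), locus("b", 350, 600), locus("c", 2000, 2300),
            locus("d", 2320, 2500), locus("e", 5000, 5100, count=1),
            locus("f", 100, 400, contig="c2"), locus("g", 450, 700, contig="c2"),
        ]
        shuffled = loci[:]
        random.Random(5).shuffle(shuffled)
        ref = detect_expressed_operons(loci)
        alt = detect_expressed_operons(shuffled)
        assert [[g.gene_id for g in c] for c in ref] == [
            [g.gene_id for g in c] for c in alt
        ]
        seen = [g.gene_id for c in ref for g in c]
        assert len(seen) == len(set(seen))

    def test_loci_tsv_reader(self, tmp_path):
        path = tmp_path / "loci.tsv"
        path.write_text(
            "gene_id\tprotein_id\tcontig_id\tstart\tend\tstrand\tspectra_count\n"
            "a\tpa\tc1\t1\t300\t+\t12\n"
        )
        loci = read_loci_tsv(path)
        assert loci[0].end == 300 and loci[0].spectra_count == 12
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene_id\tprotein_id\n")
        with pytest.raises(ValueError, match="contig_id"):
            read_loci_tsv(bad)


class TestCollectionSummary:
    def test_database_reduction_arithmetic(self):
        summary = collection_summary(
            genome_counts={"refseq": 612, "hbc": 737, "umgs": 1952, "archaea": 56},
            protein_counts={"hbc": 2_602_889, "umgs": 4_001_749, "refseq": 2_017_525},
            n_hapdb=110_103,
            n_searchable_proteins=8_512_249,
        )
        assert summary["n_genomes"] == 3357
        assert summary["n_proteins"] == 8_622_163
        assert summary["hapdb_percent"] == pytest.approx(1.2934, abs=1e-3)
        assert summary["hapdb_percent"] <= 1.3

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            collection_summary({"a": 1}, {"a": 0}, 5)
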