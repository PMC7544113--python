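"""MSA consensus building, SNP/InDel calling and annotation."""

import dataclasses

import pytest

from plastotype import (
    AlignerUnavailableError,
    Msa,
    PlastomeIOError,
    QuadripartiteStructure,
    align,
    annotate_variants,
    build_consensus,
    call_indels,
    call_snps,
    generate_plastome,
)
from plastotype.io import Feature, FeatureTable
from plastotype.variants import distinct_events


def msa_of(*rows):
    return Msa(tuple(f"r{i}" for i in range(len(rows))), tuple(rows))


class TestMsa:
    def test_ragged_rows_rejected_naming_the_row(self):
        with pytest.raises(PlastomeIOError, match="r1"):
            msa_of("ACGT", "ACG")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(Exception, match="duplicate"):
            Msa(("a", "a"), ("AC", "AC"))

    def test_from_fasta(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nAC-T\n>b\nACGT\n")
        msa = Msa.from_fasta(p)
        assert msa.n_rows == 2 and msa.n_cols == 4
        assert msa.row("a") == "AC-T"


class TestConsensus:
    def test_majority_column(self):
        rows = ["A"] * 7 + ["C"] * 6
        msa = msa_of(*rows)
        cons = build_consensus(msa)
        assert cons.symbols == "A" and cons.flags == ("majority",)

    def test_exact_half_tie_lexicographic(self):
        msa = msa_of("A", "A", "C", "C")
        cons = build_consensus(msa)
        assert cons.symbols == "A" and cons.flags == ("tie",)

    def test_gap_counts_as_a_symbol(self):
        msa = msa_of("-", "-", "-", "A", "C")
        cons = build_consensus(msa)
        assert cons.symbols == "-" and cons.flags == ("majority",)

    def test_hand_built_toy_matches_hand_computation(self):
        rows = (
            "ACGTAC-TAG",
            "ACGTACGTAG",
            "ACTTACGAAG",
            "ACGTACGT-G",
        )
        # hand-derived per column: every column has a >50% symbol here
        cons = build_consensus(msa_of(*rows))
        assert cons.symbols == "ACGTACGTAG"
        assert cons.flags == ("majority",) * 10


class TestCallSnps:
    def test_identical_msa_has_no_sites(self):
        msa = msa_of("ACGT", "ACGT", "ACGT")
        sites, counts = call_snps(msa, build_consensus(msa))
        assert sites == [] and all(v == 0 for v in counts.values())

    def test_hand_enumerated_toy(self):
        msa = msa_of("AAA", "AAA", "AAC", "ATC")
        sites, counts = call_snps(msa, build_consensus(msa))
        assert [s.column for s in sites] == [2, 3]
        by_col = {s.column: s for s in sites}
        assert by_col[2].site_class == "singleton-2"
        assert by_col[2].alleles == {"A": 3, "T": 1}
        assert by_col[3].site_class == "parsimony-informative-2"
        assert by_col[3].alleles == {"A": 2, "C": 2}
        assert counts == {"r0": 0, "r1": 0, "r2": 1, "r3": 2}

    def test_three_allele_classes(self):
        singleton3 = msa_of("A", "A", "A", "C", "G")
        (site,) = call_snps(singleton3, build_consensus(singleton3))[0]
        assert site.site_class == "singleton-3"
        pi3 = msa_of("A", "A", "A", "C", "C", "G")
        (site,) = call_snps(pi3, build_consensus(pi3))[0]
        assert site.site_class == "parsimony-informative-3"

    def test_gaps_and_n_are_missing_data_not_alleles(self):
        msa = msa_of("A-", "AN", "A-", "AA")
        sites, _ = call_snps(msa, build_consensus(msa))
        assert sites == []

    def test_every_site_has_one_class_and_a_minor_row(self):
        seqs = msa_of("ACGTTA", "ACCTTA", "AGGTAA", "ACGTAC")
        sites, counts = call_snps(seqs, build_consensus(seqs))
        for s in sites:
            kind, k = s.site_class.rsplit("-", 1)
            assert kind in ("singleton", "parsimony-informative")
            assert int(k) == len(s.alleles) >= 2
        assert sum(counts.values()) >= len(sites)


class TestCallIndels:
    def test_gap_free_msa_has_no_events(self):
        msa = msa_of("ACGT", "ACGT", "ACGT")
        events, counts = call_indels(msa, build_consensus(msa))
        assert events == [] and all(v == 0 for v in counts.values())

    def test_single_gap_run_is_one_deletion(self):
        msa = msa_of("AC---GT", "ACTTAGT", "ACTTAGT")
        events, counts = call_indels(msa, build_consensus(msa))
        (e,) = events
        assert e.kind == "deletion" and e.length == 3
        assert (e.col_start, e.col_end) == (3, 5)
        assert counts["r0"] == 1

    def test_shared_gap_counts_once_per_genome(self):
        rows = ["AA----TT"] * 2 + ["AACCGGTT"] * 3
        msa = msa_of(*rows)
        events, counts = call_indels(msa, build_consensus(msa))
        assert len(events) == 2
        assert all(e.kind == "deletion" and e.length == 4 for e in events)
        assert len(distinct_events(events)) == 1

    def test_insertion_when_consensus_is_gapped(self):
        rows = ["AAGGTT"] + ["AA--TT"] * 3
        msa = msa_of(*rows)
        events, _ = call_indels(msa, build_consensus(msa))
        (e,) = events
        assert e.kind == "insertion" and e.length == 2 and e.genome_id == "r0"

    def test_insertion_deletion_symmetry(self):
        # one row gapped among many: deletion; flip the majority: insertion
        del_rows = ["AC--GT"] + ["ACTTGT"] * 3
        ins_rows = ["ACTTGT"] + ["AC--GT"] * 3
        del_events, _ = call_indels(msa_of(*del_rows),
                                    build_consensus(msa_of(*del_rows)))
        ins_events, _ = call_indels(msa_of(*ins_rows),
                                    build_consensus(msa_of(*ins_rows)))
        assert del_events[0].kind == "deletion"
        assert ins_events[0].kind == "insertion"
        assert del_events[0].length == ins_events[0].length == 2


class TestAlign:
    def test_identical_sequences_align_gap_free(self):
        seq, _, _ = generate_plastome("W", 3, "toy")
        a = dataclasses.replace(seq, id="a")
        b = dataclasses.replace(seq, id="b")
        msa = align([a, b])
        assert "-" not in msa.rows[0] and "-" not in msa.rows[1]
        assert msa.rows[0] == msa.rows[1]

    def test_missing_engine_error_is_instructive(self):
        seq, _, _ = generate_plastome("W", 3, "toy")
        with pytest.raises(AlignerUnavailableError, match="from_fasta"):
            align([seq, seq], engine="no_such_aligner_binary")

    def test_implanted_48bp_deletion_appears_as_gap_run(self):
        from plastotype.synthetic import _ANCHORS
        seq, _, _ = generate_plastome("C", 6, "toy")
        s = seq.residues
        cut = s.index(_ANCHORS["del48_5"]) + len(_ANCHORS["del48_5"])
        deleted = s[:cut] + s[cut + 48:]
        rows = [
            dataclasses.replace(seq, id="c1"),
            dataclasses.replace(seq, id="c2"),
            dataclasses.replace(seq, id="s1", residues=deleted),
        ]
        msa = align(rows)
        row = msa.row("s1")
        runs = []
        i = 0
        while i < len(row):
            if row[i] == "-":
                j = i
                while j < len(row) and row[j] == "-":
                    j += 1
                runs.append(j - i)
                i = j
            else:
                i += 1
        assert runs == [48]
        assert "-" not in msa.row("c1")


class TestAnnotate:
    @staticmethod
    def toy_setup():
        # 60 bp "genome": LSC 1-30, IRb 31-40, SSC 41-50, IRa 51-60
        structure = QuadripartiteStructure((1, 30), (31, 40), (41, 50), (51, 60), 60)
        features = FeatureTable(
            [
                Feature("geneX", "CDS", 5, 10, "+"),
                Feature("geneX", "intron", 12, 14, "+"),
                Feature("sscGene", "gene", 42, 48, "+"),
            ]
        )
        return structure, features

    def test_labels_follow_hand_projection(self):
        structure, features = self.toy_setup()
        ref = "ACGT" + "-" * 3 + "A" * 56  # gap shifts columns 8+ back by 3
        other = "ACGT" + "TTT" + "A" * 8 + "C" + "A" * 47
        msa = Msa(("ref", "other"), (ref, other))
        cons = build_consensus(msa)
        sites, _ = call_snps(msa, cons)
        (site,) = [s for s in sites if s.column == 16]
        annotate_variants(sites, [], features, structure, msa, "ref")
        # column 16 -> reference position 13 (3-column gap) -> geneX intron
        assert site.gene == "geneX" and site.context == "intron"
        assert site.region == "LSC"

    def test_region_partition_and_intergenic(self):
        structure, features = self.toy_setup()
        rows = (
            "A" * 60,
            "A" * 19 + "C" + "A" * 24 + "G" + "A" * 15,  # SNPs at cols 20, 45
        )
        msa = Msa(("ref", "alt"), rows)
        sites, _ = call_snps(msa, build_consensus(msa))
        annotate_variants(sites, [], features, structure, msa, "ref")
        by_col = {s.column: s for s in sites}
        assert by_col[20].region == "LSC" and by_col[20].context == "intergenic"
        assert by_col[45].region == "SSC" and by_col[45].context == "CDS"
        assert by_col[45].gene == "sscGene"

    def test_unplaced_before_reference_span(self):
        structure, features = self.toy_setup()
        rows = ("---" + "A" * 60, "GGG" + "A" * 60, "GGC" + "A" * 60)
        msa = Msa(("ref", "alt1", "alt2"), rows)
        sites, _ = call_snps(msa, build_consensus(msa))
        annotate_variants(sites, [], features, structure, msa, "ref")
        (site,) = [s for s in sites if s.column == 3]
        assert site.region == "unplaced" and site.gene == "-"

    def test_per_gene_tally_aggregates(self):
        structure, features = self.toy_setup()
        rows = ("A" * 60, "A" * 5 + "C" + "A" * 54)  # SNP at col 6 inside geneX
        msa = Msa(("ref", "alt"), rows)
        sites, _ = call_snps(msa, build_consensus(msa))
        _, _, tally = annotate_variants(sites, [], features, structure, msa, "ref")
        row = tally[(tally.gene == "geneX") & (tally.variant_kind == "SNP")]
        assert row["count"].tolist() == [1]
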