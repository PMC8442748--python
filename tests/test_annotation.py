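import textwrap

import pandas as pd
import pytest
from pyfaidx import Fasta

from bsamap.annotation import (
    GeneModel,
    annotate_variants,
    classify_codon_change,
    classify_table,
    collapse_effect,
    count_effects,
    load_candidate_gene_snps,
    load_gene_models,
    nonsynonymous_gene_tally,
    parse_codon_change,
)
from _oracles import all_single_base_codon_changes, codon_effect_oracle


class TestClassifier:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("aTc", "aGc", "non_synonymous"),  # Ile -> Ser
            ("ctA", "ctG", "synonymous"),  # Leu -> Leu
            ("Ggt", "Agt", "non_synonymous"),  # Gly -> Ser
            ("TAC", "TAA", "stop_gained"),
            ("TGA", "CGA", "stop_lost"),
            ("TAA", "TGA", "synonymous"),  # stop -> stop
        ],
    )
    def test_known_changes(self, ref, alt, expected):
        assert classify_codon_change(ref, alt) == expected

    def test_start_codon_flag(self):
        assert classify_codon_change("ATG", "ACG", is_start=True) == "start_lost"
        assert classify_codon_change("ATG", "ACG", is_start=False) == "non_synonymous"

    def test_case_insensitive(self):
        assert classify_codon_change("atc", "agc") == classify_codon_change("ATC", "AGC")

    def test_agrees_with_brute_force_translation_everywhere(self):
        """All 576 single-base codon substitutions against direct translation."""
        n = 0
        for ref, alt in all_single_base_codon_changes():
            assert classify_codon_change(ref, alt) == codon_effect_oracle(ref, alt)
            n += 1
        assert n == 576

    @pytest.mark.parametrize(
        "ref, alt", [("AT", "AG"), ("ATCG", "ATCC"), ("ATC", "ATC"), ("ATC", "GGC"), ("ANC", "AGC")]
    )
    def test_invalid_inputs_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            classify_codon_change(ref, alt)


class TestNotation:
    def test_uppercase_marks_mutated_base(self):
        assert parse_codon_change("aTc/aGc") == ("aTc", "aGc", 1)

    def test_uniform_case_falls_back_to_positional_diff(self):
        assert parse_codon_change("atc/agc") == ("atc", "agc", 1)

    def test_malformed_notation_rejected(self):
        with pytest.raises(ValueError):
            parse_codon_change("aTcaGc")
        with pytest.raises(ValueError):
            parse_codon_change("atcc/agcc")


class TestCandidateGeneTable:
    def test_effect_labels_reproduced_row_by_row(self):
        table = classify_table(load_candidate_gene_snps())
        assert len(table) == 16
        assert (table["effect_called"] == table["effect"]).all()

    def test_nine_nonsynonymous_seven_synonymous(self):
        table = classify_table(load_candidate_gene_snps())
        n_syn, n_nonsyn, other = count_effects(
            table["effect_raw"].map(collapse_effect)
        )
        assert (n_nonsyn, n_syn, other) == (9, 7, 0)


class TestCounts:
    def test_empty(self):
        assert count_effects([]) == (0, 0, 0)

    def test_additivity(self):
        a = ["synonymous", "non_synonymous"]
        b = ["non_synonymous", "non_coding"]
        summed = tuple(
            x + y for x, y in zip(count_effects(a), count_effects(b))
        )
        assert count_effects(a + b) == summed


@pytest.fixture()
def toy_genome(tmp_path):
    """Two 2-codon genes on opposite strands encoding the same peptide.

    Plus-strand gene at 11..16: ATG GGA (Met-Gly). Minus-strand gene at
    31..36 whose reverse complement is also ATG GGA.
    """
    seq = "A" * 10 + "ATGGGA" + "A" * 14 + "TCCCAT" + "A" * 14
    fasta = tmp_path / "toy.fa"
    fasta.write_text(f">c1\n{seq}\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        textwrap.dedent(
            """\
            ##gff-version 3
            c1\ttoy\tgene\t11\t16\t.\t+\t.\tID=gplus
            c1\ttoy\tmRNA\t11\t16\t.\t+\t.\tID=gplus.t1;Parent=gplus
            c1\ttoy\tCDS\t11\t16\t.\t+\t0\tID=gplus.c1;Parent=gplus.t1
            c1\ttoy\tgene\t31\t36\t.\t-\t.\tID=gminus
            c1\ttoy\tmRNA\t31\t36\t.\t-\t.\tID=gminus.t1;Parent=gminus
            c1\ttoy\tCDS\t31\t36\t.\t-\t0\tID=gminus.c1;Parent=gminus.t1
            """
        )
    )
    return fasta, gff


class TestGeneAnnotation:
    def test_gff3_gene_models_load(self, toy_genome):
        _, gff = toy_genome
        models = {g.gene_id: g for g in load_gene_models(gff)}
        assert set(models) == {"gplus", "gminus"}
        assert models["gminus"].strand == "-"
        assert models["gplus"].frame_ok

    def test_planted_effects_and_gene_tally(self, toy_genome):
        fasta_path, gff = toy_genome
        fasta = Fasta(str(fasta_path))
        models = load_gene_models(gff)
        variants = pd.DataFrame(
            [
                # GGA -> AGA: Gly -> Arg, non-synonymous
                {"chrom": "c1", "pos": 14, "ref": "G", "alt": "A"},
                # GGA -> GGG: synonymous
                {"chrom": "c1", "pos": 16, "ref": "A", "alt": "G"},
                # intergenic
                {"chrom": "c1", "pos": 25, "ref": "A", "alt": "T"},
            ]
        )
        out = annotate_variants(variants, models, fasta)
        assert list(out["effect"]) == ["non_synonymous", "synonymous", "non_coding"]
        tally = nonsynonymous_gene_tally(out)
        assert tally.to_dict() == {"gplus": 1}

    def test_strand_symmetry(self, toy_genome):
        """The same biological codon change on the minus strand gets the
        same effect call as its plus-strand twin."""
        fasta_path, gff = toy_genome
        fasta = Fasta(str(fasta_path))
        models = load_gene_models(gff)
        variants = pd.DataFrame(
            [
                # plus gene codon 2 GGA->AGA at genomic 14 (G>A)
                {"chrom": "c1", "pos": 14, "ref": "G", "alt": "A"},
                # minus gene codon 2 GGA->AGA: genomic 33 on the minus strand
                # (CDS base C>T on the plus strand)
                {"chrom": "c1", "pos": 33, "ref": "C", "alt": "T"},
            ]
        )
        out = annotate_variants(variants, models, fasta)
        assert out["effect"].iloc[0] == out["effect"].iloc[1] == "non_synonymous"
        assert out["ref_codon"].iloc[0] == out["ref_codon"].iloc[1]

    def test_reference_mismatch_raises(self, toy_genome):
        fasta_path, gff = toy_genome
        fasta = Fasta(str(fasta_path))
        models = load_gene_models(gff)
        variants = pd.DataFrame([{"chrom": "c1", "pos": 14, "ref": "T", "alt": "A"}])
        with pytest.raises(ValueError, match="reference mismatch"):
            annotate_variants(variants, models, fasta)

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            GeneModel("g", "c1", "+", [(1, 10), (5, 20)])
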