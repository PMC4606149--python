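"""Flat-file parsing, sentence extraction, and the TSV file formats."""

import io
import random

import pytest

from metsp.synthetic import gen_flatfile
from metsp.uniprot_io import (
    FieldFlag,
    KnownTSP,
    LabeledInstance,
    UniProtEntry,
    extract_sentences,
    format_flatfile,
    merge_known_tsps,
    parse_flatfile,
    read_known_tsps,
    read_training_file,
    split_sentences,
    write_training_file,
)

TWO_ENTRY_STREAM = """\
ID   S12A8_HUMAN             Reviewed;         714 AA.
AC   A0AV02; Q8IUN1;
DE   RecName: Full=Solute carrier family 12 member 8;
DE   AltName: Full=Cation-chloride cotransporter 9;
GN   Name=SLC12A8;
CC   -!- FUNCTION: May transport potassium and chloride ions across the
CC       membrane in an electroneutral manner and play a role in cell
CC       volume regulation in many tissues.
CC   -!- SUBCELLULAR LOCATION: Membrane.
DR   GO; GO:0006813; P:potassium ion transport; IEA:UniProtKB-KW.
DR   EMBL; AK097060; BAC04950.1; -; mRNA.
SQ   SEQUENCE   714 AA;  78787 MW;  0A6F
     MADSPT
//
AC   Q4U2R8;
DE   RecName: Full=Solute carrier family 22 member 6;
CC   -!- FUNCTION: Involved in the renal elimination of endogenous and
CC       exogenous organic anions. Mediates the uptake of indoleacetate.
DR   GO; GO:0015711; P:organic anion transport; IEA:Ensembl.
//
"""


class TestParseFlatfile:
    def test_multiline_function_block_joined(self):
        entries = parse_flatfile(io.StringIO(TWO_ENTRY_STREAM))
        assert len(entries) == 2
        e = entries[0]
        assert e.accession == "A0AV02"
        assert e.secondary_accessions == ["Q8IUN1"]
        assert len(e.cc_function_texts) == 1
        assert e.cc_function_texts[0] == (
            "May transport potassium and chloride ions across the membrane "
            "in an electroneutral manner and play a role in cell volume "
            "regulation in many tissues."
        )

    def test_only_retained_fields_survive(self):
        entries = parse_flatfile(io.StringIO(TWO_ENTRY_STREAM))
        e = entries[0]
        assert e.de_lines == [
            "Solute carrier family 12 member 8",
            "Cation-chloride cotransporter 9",
        ]
        # only the GO cross-reference, with the aspect prefix stripped
        assert e.dr_go_terms == ["potassium ion transport"]

    def test_entry_with_no_annotation_fields(self):
        text = "ID   X\nAC   P12345;\nSQ   SEQUENCE\n     MAD\n//\n"
        (e,) = parse_flatfile(io.StringIO(text))
        assert e.accession == "P12345"
        assert e.de_lines == []
        assert e.cc_function_texts == []
        assert e.dr_go_terms == []

    def test_record_without_ac_rejected_with_warning(self, caplog):
        text = "DE   RecName: Full=Orphan;\n//\nAC   P12345;\n//\n"
        with caplog.at_level("WARNING"):
            entries = parse_flatfile(io.StringIO(text))
        assert [e.accession for e in entries] == ["P12345"]
        assert any("no AC line" in r.message for r in caplog.records)

    def test_truncated_final_record_kept_and_flagged(self, caplog):
        text = "AC   P12345;\nDE   RecName: Full=Orphan;\n"
        with caplog.at_level("WARNING"):
            (e,) = parse_flatfile(io.StringIO(text))
        assert e.accession == "P12345"
        assert any("terminator" in r.message for r in caplog.records)

    def test_synthetic_roundtrip_is_idempotent(self):
        """parse -> serialize retained fields -> parse is a fixpoint."""
        text, _ = gen_flatfile(10, seed=21)
        first = parse_flatfile(io.StringIO(text))
        assert len(first) == 10
        second = parse_flatfile(io.StringIO(format_flatfile(first)))
        assert first == second


class TestSplitSentences:
    def test_splits_on_period_capital(self):
        assert split_sentences(
            "May transport potassium and chloride. Its function is unclear."
        ) == [
            "May transport potassium and chloride.",
            "Its function is unclear.",
        ]

    @pytest.mark.parametrize(
        "text",
        [
            "Transports D-glucose (i.e. dextrose) efficiently.",
            "Expressed in E. coli and yeast.",
            "Described by Smith et al. In both tissues.",
            "Active at pH 7.5 in vitro.",
        ],
    )
    def test_protected_tokens_do_not_split(self, text):
        # hand-segmented: each fixture is exactly one sentence except the
        # 'et al.' case which the guard also keeps whole
        assert len(split_sentences(text)) == 1

    def test_decimal_and_digit_boundaries(self):
        out = split_sentences("Km is 7.5 mM. 2-oxoglutarate is exchanged.")
        assert out == ["Km is 7.5 mM.", "2-oxoglutarate is exchanged."]


class TestExtractSentences:
    def test_cc_block_split(self):
        e = UniProtEntry(
            accession="P00001",
            cc_function_texts=[
                "May transport potassium and chloride. Its function is unclear."
            ],
        )
        out = extract_sentences(e)
        assert [s.text for s in out] == [
            "May transport potassium and chloride.",
            "Its function is unclear.",
        ]
        assert all(s.field_flag is FieldFlag.CC for s in out)

    def test_de_and_dr_emitted_whole(self):
        e = UniProtEntry(
            accession="A0AV02",
            de_lines=["Solute carrier family 12 member 8"],
            dr_go_terms=["potassium ion transport"],
        )
        out = extract_sentences(e)
        assert len(out) == 2
        assert [s.field_flag for s in out] == [FieldFlag.DE, FieldFlag.DR]
        assert [s.index for s in out] == [0, 1]

    def test_empty_entry_empty_list(self):
        assert extract_sentences(UniProtEntry(accession="P00001")) == []

    def test_indices_are_permutation_and_counts_add_up(self):
        text, _ = gen_flatfile(15, seed=33)
        for e in parse_flatfile(io.StringIO(text)):
            out = extract_sentences(e)
            assert [s.index for s in out] == list(range(len(out)))
            per_field = sum(
                sum(1 for s in out if s.field_flag is f) for f in FieldFlag
            )
            assert per_field == len(out)
            # every sentence is entry text up to whitespace normalization
            blob = " ".join(
                e.de_lines + e.cc_function_texts + e.dr_go_terms
            )
            blob = " ".join(blob.split())
            for s in out:
                assert s.text in blob


class TestTrainingFile:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "train.tsv"
        p.write_text("positive\tA0AV02\tCC\tMay transport potassium.\n")
        (inst,) = read_training_file(p)
        assert inst == LabeledInstance(
            "positive", "A0AV02", FieldFlag.CC, "May transport potassium."
        )

    def test_empty_file(self, tmp_path):
        p = tmp_path / "train.tsv"
        p.write_text("")
        assert read_training_file(p) == []

    def test_wrong_column_count_skipped_and_counted(self, tmp_path, caplog):
        p = tmp_path / "train.tsv"
        p.write_text(
            "positive\tA0AV02\tCC\tMay transport potassium.\n"
            "positive\tonly-two-columns\n"
            "unlabeled\tP12345\tDE\tUncharacterized protein\n"
        )
        with caplog.at_level("WARNING"):
            out = read_training_file(p)
        assert len(out) == 2
        assert any("skipped 1" in r.message for r in caplog.records)

    def test_unknown_label_is_an_error_naming_the_line(self, tmp_path):
        p = tmp_path / "train.tsv"
        p.write_text("positive\tA\tCC\tok\nnegative\tB\tCC\tbad label\n")
        with pytest.raises(ValueError, match=":2"):
            read_training_file(p)

    def test_roundtrip_lossless(self, tmp_path):
        instances = [
            LabeledInstance("positive", "A0AV02", FieldFlag.CC,
                            "May transport potassium."),
            LabeledInstance("unlabeled", "P12345", FieldFlag.DR,
                            "chromatin binding"),
        ]
        p = tmp_path / "train.tsv"
        write_training_file(instances, p)
        assert read_training_file(p) == instances


class TestKnownTSPs:
    def test_duplicates_collapse(self, tmp_path):
        p = tmp_path / "k.tsv"
        p.write_text("A0AV02\tC00238\nA0AV02\tC00238\n")
        assert read_known_tsps(p) == {KnownTSP("A0AV02", "C00238")}

    def test_single_pair_row_parses(self, tmp_path):
        p = tmp_path / "k.tsv"
        p.write_text("Q4U2R8\tC00954\n")
        assert read_known_tsps(p) == {KnownTSP("Q4U2R8", "C00954")}

    def test_malformed_row_skipped_with_warning(self, tmp_path, caplog):
        rows = ["P%05d\tC%05d" % (i, i) for i in range(9)]
        rows.insert(4, "P99999\tnot-a-compound")
        p = tmp_path / "k.tsv"
        p.write_text("\n".join(rows) + "\n")
        with caplog.at_level("WARNING"):
            pairs = read_known_tsps(p)
        assert len(pairs) == 9
        assert sum("malformed" in r.message for r in caplog.records) == 1


class TestMergeKnownTSPs:
    def test_toy_sets(self):
        a = KnownTSP("A00001", "C00001")
        b = KnownTSP("B00001", "C00002")
        c = KnownTSP("C00001x", "C00003")
        d = KnownTSP("D00001", "C00004")
        assert merge_known_tsps({a, b}, {b, c}, {d}) == {b, d}

    def test_all_empty(self):
        assert merge_known_tsps(set(), set(), set()) == set()

    def test_brute_force_membership_oracle(self):
        rng = random.Random(17)

        def rand_set():
            return {
                KnownTSP("P%05d" % rng.randrange(50), "C%05d" % rng.randrange(50))
                for _ in range(100)
            }

        u, t, c = rand_set(), rand_set(), rand_set()
        merged = merge_known_tsps(u, t, c)
        universe = u | t | c
        expected = {
            p for p in universe if (p in u and p in t) or p in c
        }
        assert merged == expected
        assert merged <= universe
        assert merged >= c
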