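import numpy as np
import pytest

from seedseq.classify import OffTargetRecord
from seedseq.seedscan import SeedSite
from seedseq.seedseq_io import (
    Feature,
    ParseError,
    SeedSeqRecord,
    annotate_transcript,
    read_record,
    read_records,
    write_record,
    write_records,
)
from seedseq.seqcore import NucSeq, Transcript, base_count


def random_record(rng: np.random.Generator) -> SeedSeqRecord:
    length = int(rng.integers(30, 400))
    seq = NucSeq("".join(rng.choice(list("ACGU"), size=length)))
    features = []
    for i in range(int(rng.integers(0, 4))):
        lo = int(rng.integers(1, length - 6))
        features.append(
            Feature(
                key="target_siRNAs",
                location=(lo, lo + 6),
                qualifiers=(
                    ("sirna_id", f"s{i}"),
                    ("supplier", "synthetic"),
                    ("categories", "mirna_like"),
                    ("seed_occurrences", int(rng.integers(1, 5))),
                ),
            )
        )
    return SeedSeqRecord(
        locus_name=f"NM_{int(rng.integers(1, 10**6))}",
        sequence=seq,
        molecule=str(rng.choice(["DNA", "RNA"])),
        definition=f"sym=G{int(rng.integers(1, 99))}|len={length}",
        accession=f"NM_{int(rng.integers(1, 10**6))}",
        features=tuple(features),
    )


class TestPrintedRecord:
    def test_fields(self, printed_record_path):
        rec = read_record(printed_record_path)
        assert rec.locus_name == "GXP_170357"
        assert rec.accession == "GXP_170357"
        assert rec.length == 743
        assert rec.molecule == "DNA"

    def test_base_counts(self, printed_record_path):
        rec = read_record(printed_record_path)
        assert rec.base_counts() == {"a": 216, "c": 180, "g": 147, "t": 200}

    def test_definition_metadata_parsed(self, printed_record_path):
        fields = read_record(printed_record_path).definition_fields
        assert fields["sym"] == "TPH2"
        assert fields["spec"] == "Homo sapiens"
        assert fields["len"] == "743"

    def test_reparse_after_write_is_idempotent(self, printed_record_path):
        first = read_record(printed_record_path)
        again = read_record(write_record(first))
        assert again == first

    def test_origin_layout_of_written_record(self, printed_record_path):
        text = write_record(read_record(printed_record_path))
        origin_lines = text[text.index("ORIGIN") :].splitlines()[1:-1]
        assert len(origin_lines) == 13  # ceil(743/60)
        assert origin_lines[-1].split()[0] == "721"
        assert sum(len(g) for g in origin_lines[-1].split()[1:]) == 23
        assert text.rstrip().endswith("//")


class TestRoundTrip:
    def test_read_write_identity_on_generated_records(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            rec = random_record(rng)
            assert read_record(write_record(rec)) == rec

    def test_base_count_line_always_recomputed(self):
        rng = np.random.default_rng(23)
        rec = random_record(rng)
        text = write_record(rec)
        counts = base_count(rec.sequence)
        line = next(l for l in text.splitlines() if l.startswith("BASE COUNT"))
        for b, key in (("A", "a"), ("C", "c"), ("G", "g")):
            assert f"{counts[b]:>6} {key}" in line

    def test_multi_record_file(self):
        rng = np.random.default_rng(29)
        recs = [random_record(rng) for _ in range(3)]
        assert read_records(write_records(recs)) == recs

    def test_feature_block_cardinality(self):
        rng = np.random.default_rng(31)
        rec = random_record(rng)
        two = SeedSeqRecord(
            locus_name=rec.locus_name,
            sequence=rec.sequence,
            molecule=rec.molecule,
            features=(
                Feature("target_siRNAs", (1, 7), (("sirna_id", "a"),)),
                Feature("target_siRNAs", (8, 14), (("sirna_id", "b"),)),
            ),
        )
        assert write_record(two).count("target_siRNAs") == 2


class TestTolerantReader:
    MINIMAL = "LOCUS NM_1 8 bp RNA\nORIGIN\n1 ACGUACGU\n"

    def test_minimal_record_without_features_or_terminator(self):
        rec = read_record(self.MINIMAL)
        assert rec.length == 8 and rec.features == ()
        assert read_record(write_record(rec)) == rec

    def test_case_and_grouping_insensitive_origin(self):
        rec = read_record("LOCUS NM_1 8 bp RNA\nORIGIN\n1 acg uAC\n7 gu\n")
        assert str(rec.sequence) == "ACGUACGU"

    def test_missing_locus_rejected(self):
        with pytest.raises(ParseError, match="LOCUS"):
            read_record("ORIGIN\n1 ACGU\n")

    def test_missing_origin_rejected(self):
        with pytest.raises(ParseError, match="ORIGIN"):
            read_record("LOCUS NM_1 4 bp RNA\n")

    def test_inconsistent_base_count_warns_by_default(self):
        text = "LOCUS NM_1 8 bp RNA\nBASE COUNT 5 a 1 c 1 g 1 u\nORIGIN\n1 ACGUACGU\n"
        with pytest.warns(UserWarning, match="BASE COUNT"):
            rec = read_record(text)
        assert rec.length == 8

    def test_inconsistent_base_count_strict_raises(self):
        text = "LOCUS NM_1 8 bp RNA\nBASE COUNT 5 a 1 c 1 g 1 u\nORIGIN\n1 ACGUACGU\n"
        with pytest.raises(ParseError):
            read_record(text, strict=True)


class TestAnnotateTranscript:
    def _transcript(self, n=60):
        return Transcript(
            accession="NM_T", sequence=NucSeq("ACGU" * (n // 4)), gene_symbol="TGT", utr3_start=8
        )

    def _record(self, sid, sites=()):
        return OffTargetRecord(
            sirna_id=sid,
            transcript_accession="NM_T",
            supplier="synthetic",
            categories=frozenset({"mirna_like"}),
            seed_occurrences=1,
            sites=tuple(sites),
        )

    def test_no_offtargets_no_features(self):
        rec = annotate_transcript(self._transcript(), [])
        assert rec.features == ()

    def test_seven_sirnas_seven_features(self):
        records = [self._record(f"s{i}") for i in range(7)]
        rec = annotate_transcript(self._transcript(), records)
        assert len(rec.features) == 7
        assert [f.qualifier("sirna_id") for f in rec.features] == sorted(
            f"s{i}" for i in range(7)
        )

    def test_duplicates_deduplicated(self):
        records = [self._record("s1"), self._record("s1")]
        assert len(annotate_transcript(self._transcript(), records).features) == 1

    def test_site_backed_feature_located_at_site(self):
        site = SeedSite("NM_T", 10, 17)
        rec = annotate_transcript(self._transcript(), [self._record("s1", sites=[site])])
        assert rec.features[0].location == (11, 17)

    def test_siteless_evidence_spans_full_record(self):
        t = self._transcript()
        rec = annotate_transcript(t, [self._record("s1")])
        assert rec.features[0].location == (1, len(t.sequence))

    def test_accession_mismatch_rejected(self):
        bad = OffTargetRecord(sirna_id="s1", transcript_accession="NM_OTHER")
        with pytest.raises(ValueError, match="NM_OTHER"):
            annotate_transcript(self._transcript(), [bad])

    def test_annotation_round_trips(self):
        records = [self._record("s1", sites=[SeedSite("NM_T", 10, 17)])]
        rec = annotate_transcript(self._transcript(), records)
        assert read_record(write_record(rec)) == rec
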