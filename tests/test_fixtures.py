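import numpy as np
import pytest

from seedseq.align import align_duplex
from seedseq.classify import ClassifierConfig, classify_alignment
from seedseq.conserve import load_conserved, is_conserved
from seedseq.fixtures import (
    FixtureSpec,
    generate_conservation,
    generate_expression,
    generate_library,
    generate_transcriptome,
    manifest_frame,
    write_fixture_files,
)
from seedseq.seedscan import ScanConfig, SeedSite, extract_window, find_seed_sites
from seedseq.seqcore import read_fasta, read_sirna_library


class TestDeterminism:
    def test_identical_builds_for_identical_seed(self, spec, library, transcriptome):
        transcripts, manifest = transcriptome
        t2, m2 = generate_transcriptome(spec, library)
        assert [str(t.sequence) for t in t2] == [str(t.sequence) for t in transcripts]
        assert m2 == manifest

    def test_different_seeds_differ(self, spec, transcriptome):
        other = FixtureSpec(rng_seed=43)
        t2, _ = generate_transcriptome(other, generate_library(other))
        assert [str(t.sequence) for t in t2] != [
            str(t.sequence) for t in transcriptome[0]
        ]

    def test_library_streams_independent(self, spec, library):
        # regenerating the library never changes it
        assert [str(s.antisense) for s in generate_library(spec)] == [
            str(s.antisense) for s in library
        ]


class TestLibrary:
    def test_strand_lengths(self, library):
        assert all(len(s.antisense) == 21 for s in library)

    def test_seeds_pairwise_distinct(self, library):
        seeds = [str(s.antisense[1:8]) for s in library]
        assert len(set(seeds)) == len(seeds)


class TestManifestClosedLoop:
    def test_planted_seed_sites_all_recovered(self, library, transcriptome):
        """Recall 1.0 on planted exact seed sites."""
        transcripts, manifest = transcriptome
        by_acc = {t.accession: t for t in transcripts}
        lib = {s.sirna_id: s for s in library}
        planted = [m for m in manifest if m.seed_start is not None]
        assert planted
        for m in planted:
            sites = find_seed_sites(by_acc[m.accession], lib[m.sirna_id])
            assert any(s.start == m.seed_start for s in sites)

    def test_no_off_manifest_exact_sites(self, library, transcriptome):
        """Zero false positives by construction of the rejection-sampled background."""
        transcripts, manifest = transcriptome
        expected = {
            (m.sirna_id, m.accession, m.seed_start)
            for m in manifest
            if m.seed_start is not None
        }
        found = set()
        for sirna in library:
            for t in transcripts:
                for s in find_seed_sites(t, sirna):
                    found.add((sirna.sirna_id, t.accession, s.start))
        assert found == expected

    def test_planted_near_exact_pairs_at_least_17(self, library, transcriptome):
        transcripts, manifest = transcriptome
        by_acc = {t.accession: t for t in transcripts}
        lib = {s.sirna_id: s for s in library}
        for m in (x for x in manifest if x.cls == "near_exact"):
            t = by_acc[m.accession]
            window = t.sequence[m.start : m.end]
            aln = align_duplex(lib[m.sirna_id], window)
            assert aln.paired_positions >= 17

    @pytest.mark.parametrize("cls,check", [
        ("partial_contiguous11", lambda a: a.longest_contiguous_run >= 11),
        ("partial_total15", lambda a: a.paired_positions >= 15),
    ])
    def test_planted_partial_classes_trigger_their_rule(
        self, library, transcriptome, cls, check
    ):
        transcripts, manifest = transcriptome
        by_acc = {t.accession: t for t in transcripts}
        lib = {s.sirna_id: s for s in library}
        hits = [m for m in manifest if m.cls == cls]
        assert hits
        for m in hits:
            t = by_acc[m.accession]
            site = SeedSite(t.accession, m.start, m.end, seed_len=m.end - m.start)
            (lo, hi), window = extract_window(t, site, ScanConfig(window_width=60))
            aln = align_duplex(lib[m.sirna_id], window)
            assert check(aln)
            assert "partial" in classify_alignment(aln, ClassifierConfig())

    def test_planted_total15_is_not_near_exact_at_site(self, library, transcriptome):
        transcripts, manifest = transcriptome
        by_acc = {t.accession: t for t in transcripts}
        lib = {s.sirna_id: s for s in library}
        for m in (x for x in manifest if x.cls == "partial_total15"):
            t = by_acc[m.accession]
            aln = align_duplex(lib[m.sirna_id], t.sequence[m.start : m.end])
            assert aln.paired_positions == 15
            assert aln.longest_contiguous_run < 11


class TestConservationTrack:
    def test_nondecoy_sites_conserved_decoys_not(self, spec, library, transcriptome, conservation):
        transcripts, manifest = transcriptome
        cset = load_conserved(conservation)
        for m in manifest:
            if m.seed_start is None:
                continue
            site = SeedSite(m.accession, m.seed_start, m.seed_end)
            if m.cls == "m8_seed":
                assert is_conserved(site, cset)
            elif m.cls == "decoy_nonconserved":
                assert not is_conserved(site, cset)


class TestExpression:
    def test_all_accessions_present(self, spec):
        preds = ["NM_1", "NM_2"]
        df = generate_expression(spec, preds, all_accessions=["NM_1", "NM_2", "NM_3"])
        assert sorted(df.accession) == ["NM_1", "NM_2", "NM_3"]

    def test_deterministic(self, spec):
        a = generate_expression(spec, ["NM_1", "NM_2"])
        b = generate_expression(spec, ["NM_2", "NM_1"])
        assert a.equals(b)


class TestFileEmission:
    def test_written_fixtures_round_trip_through_readers(self, tmp_path, spec):
        paths = write_fixture_files(spec, tmp_path)
        transcripts = read_fasta(paths["fasta"])
        library = read_sirna_library(paths["library"])
        assert len(transcripts) == spec.n_transcripts
        assert len(library) == spec.library_size
        assert all(t.utr3_start is not None for t in transcripts)
        manifest = manifest_frame
        cset = load_conserved(paths["conserved"])
        assert len(cset) > 0

    def test_byte_identical_across_runs(self, tmp_path, spec):
        p1 = write_fixture_files(spec, tmp_path / "a")
        p2 = write_fixture_files(spec, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
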