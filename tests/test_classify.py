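import pytest

from seedseq.align import MATCH, ScoringScheme, align_duplex, DuplexAlignment
from seedseq.classify import (
    MIRNA_LIKE,
    NEAR_EXACT,
    PARTIAL,
    ClassifierConfig,
    call_offtargets,
    classify_alignment,
    classify_mirna_like,
    cleavage_competent,
    site_pairing,
)
from seedseq.seedscan import ConfigurationError, SeedSite, find_seed_sites
from seedseq.seqcore import NucSeq, SiRNA, Transcript, reverse_complement

SIRNA = SiRNA(sirna_id="s1", antisense=NucSeq("AAAUACUGACAAACGUGAGGC"), on_target_gene="WNK3")


def _aln(paired, run):
    return DuplexAlignment(0.0, (0, 19), (0, 19), "", paired, run)


class TestClassifyAlignment:
    @pytest.mark.parametrize(
        "paired,run,expected",
        [
            (17, 9, {NEAR_EXACT, PARTIAL}),   # near-exact also satisfies total>=15
            (16, 9, {PARTIAL}),               # one below the near-exact bound
            (14, 11, {PARTIAL}),              # contiguous-run rule alone
            (14, 10, set()),                  # both partial clauses just missed
            (15, 4, {PARTIAL}),               # total rule alone
            (10, 8, set()),
            (19, 19, {NEAR_EXACT, PARTIAL}),
        ],
    )
    def test_thresholds(self, paired, run, expected):
        assert classify_alignment(_aln(paired, run)) == expected

    def test_near_exact_implies_partial_under_defaults(self):
        cfg = ClassifierConfig()
        for paired in range(20):
            for run in range(paired + 1):
                cats = classify_alignment(_aln(paired, run), cfg)
                if NEAR_EXACT in cats:
                    assert PARTIAL in cats

    def test_raising_thresholds_never_adds_categories(self):
        base = ClassifierConfig()
        stricter = ClassifierConfig(
            near_exact_min_paired=18, partial_min_contiguous=12, partial_min_total=16
        )
        for paired in range(20):
            for run in range(paired + 1):
                assert classify_alignment(_aln(paired, run), stricter) <= classify_alignment(
                    _aln(paired, run), base
                )


def _transcript_with_site(construct: str, utr3: bool = True):
    """Background-free transcript: 40 nt of C (pairs nothing in this siRNA),
    the construct, then 10 nt of C."""
    pad5, pad3 = "C" * 40, "C" * 10
    seq = pad5 + construct + pad3
    return Transcript(
        accession="NM_T",
        sequence=NucSeq(seq),
        gene_symbol="TGT",
        utr3_start=10 if utr3 else len(seq) - 2,
    )


def _mutate(site: str, antisense_pos: int, base: str) -> str:
    i = 19 - antisense_pos
    return site[:i] + base + site[i + 1 :]


PERFECT = str(SIRNA.expected_target_site())


class TestMirnaLike:
    def _site(self, t):
        sites = find_seed_sites(t, SIRNA)
        assert sites, "constructed site not found"
        return sites[0]

    def test_perfect_seed_in_utr3(self):
        t = _transcript_with_site(PERFECT)
        assert classify_mirna_like(SIRNA, t, self._site(t)) is True

    def test_compensatory_rescue(self):
        # one seed mismatch (antisense 5), 13-19 untouched
        construct = _mutate(PERFECT, 5, str(SIRNA.antisense[4]))
        t = _transcript_with_site(construct)
        from seedseq.seedscan import find_seed_sites_with_mismatches

        site = [
            s for s in find_seed_sites_with_mismatches(t, SIRNA) if s.seed_mismatches == 1
        ][0]
        assert classify_mirna_like(SIRNA, t, site) is True

    def test_compensatory_broken_fails(self):
        construct = _mutate(PERFECT, 5, str(SIRNA.antisense[4]))
        construct = _mutate(construct, 15, str(SIRNA.antisense[14]))
        t = _transcript_with_site(construct)
        from seedseq.seedscan import find_seed_sites_with_mismatches

        site = [
            s for s in find_seed_sites_with_mismatches(t, SIRNA) if s.seed_mismatches == 1
        ][0]
        assert classify_mirna_like(SIRNA, t, site) is False

    def test_site_outside_utr3_rejected_by_default(self):
        t = _transcript_with_site(PERFECT, utr3=False)
        assert classify_mirna_like(SIRNA, t, self._site(t)) is False

    def test_whole_transcript_mode_accepts_cds_site(self):
        t = _transcript_with_site(PERFECT, utr3=False)
        cfg = ClassifierConfig(require_utr3_for_mirna_like=False)
        assert classify_mirna_like(SIRNA, t, self._site(t), cfg) is True

    def test_unknown_utr3_offset_is_config_error(self):
        t = Transcript(accession="NM_U", sequence=NucSeq("C" * 40 + PERFECT))
        site = find_seed_sites(t, SIRNA)[0]
        with pytest.raises(ConfigurationError):
            classify_mirna_like(SIRNA, t, site)


class TestCleavage:
    def test_fully_paired_duplex_cleaves(self):
        aln = align_duplex(SIRNA, PERFECT)
        assert cleavage_competent(aln) is True

    def test_center_mismatch_blocks_cleavage(self):
        target = _mutate(PERFECT, 9, str(SIRNA.antisense[8]))
        aln = align_duplex(SIRNA, target)
        assert cleavage_competent(aln) is False

    def test_center_wobble_tolerated_when_scheme_allows(self):
        # antisense position 9 is A in this strand; pick a strand with U at 9
        sirna = SiRNA(sirna_id="w", antisense=NucSeq("AAAUACUGUCAAACGUGAGGC"))
        target = _mutate(str(sirna.expected_target_site()), 9, "G")  # U:G wobble
        tolerant = align_duplex(sirna, target, ScoringScheme(wobble_as_match=True))
        strict = align_duplex(sirna, target, ScoringScheme(wobble_as_match=False))
        assert cleavage_competent(tolerant, s=ScoringScheme(wobble_as_match=True)) is True
        assert cleavage_competent(strict, s=ScoringScheme(wobble_as_match=False)) is False


class TestSitePairing:
    def test_anchored_pairing_of_perfect_site(self):
        t = _transcript_with_site(PERFECT)
        site = find_seed_sites(t, SIRNA)[0]
        status = site_pairing(SIRNA, t, site)
        assert all(status[p] == MATCH for p in range(1, 20))


class TestCallOfftargets:
    def test_on_target_gene_excluded(self):
        t = _transcript_with_site(PERFECT)
        own = Transcript(
            accession="NM_OWN", sequence=t.sequence, gene_symbol="WNK3", utr3_start=t.utr3_start
        )
        records = call_offtargets(SIRNA, [own], mode="mirna_like")
        assert records == []

    def test_planted_m8_site_called_mirna_like(self):
        t = _transcript_with_site(PERFECT)
        records = call_offtargets(SIRNA, [t], mode="mirna_like")
        assert len(records) == 1
        assert MIRNA_LIKE in records[0].categories
        assert records[0].seed_occurrences >= 1

    def test_planted_full_complement_near_exact(self):
        t = _transcript_with_site(PERFECT)
        records = call_offtargets(SIRNA, [t], mode="full_sw")
        assert len(records) == 1
        assert {NEAR_EXACT, PARTIAL} <= records[0].categories
        assert records[0].cleavage_competent is True

    def test_empty_transcriptome(self):
        assert call_offtargets(SIRNA, [], mode="full_sw") == []
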