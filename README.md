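# seedseq

Prediction of siRNA **off-target transcripts** — the mRNAs an siRNA is
liable to silence besides its intended target — and a GenBank-dialect
record format ("SeedSeq") for storing those predictions as transcript
annotations.

Large-scale RNAi screens depend on siRNA specificity, but partial
complementarity is enough for silencing: ~90% complementarity (17 of the
19 duplex-core nucleotides), as few as 11 contiguous paired nucleotides or
15 in total, or mere complementarity between the siRNA **seed region**
(antisense-strand positions 2–8) and a transcript's 3′UTR can all
down-regulate an unintended transcript. G:U wobble pairs are read by RISC
like Watson–Crick pairs, further widening the target space. This package
implements that rule set end to end, for library designers and screen
analysts who need to know which transcripts are sensitive.

## Method

All numbering is fixed on the antisense (guide) strand, 5′→3′, 1-based;
the duplex core is positions 1–19 (3′ overhangs never score).

1. **Seed scan** — every occurrence of the seed-match motif
   (reverse complement of antisense 2–8, the 7mer-m8 register; a 6-mer
   register 2–7 is available) is located in each transcript, and a ~50-nt
   window is cut around each site.
2. **Duplex alignment** — Smith–Waterman local alignment (linear gaps,
   defaults +2/−1/−2) of the expected target site against the window or,
   in `full_sw` mode, the whole transcript. Wobble-equivalent
   substitutions count as matches under `wobble_as_match`. Pairing is
   reported over the 19 core positions.
3. **Classification** —
   `near_exact` (≥17/19 paired), `partial` (≥11 contiguous or ≥15 total),
   `mirna_like` (seed perfectly paired, or exactly one seed mismatch
   rescued by perfect pairing of positions 13–19 — the 3′ compensatory
   rule — in the 3′UTR by default). Cleavage competence additionally
   requires the center region (8–10, opposite the mRNA cleavage site)
   fully paired.
4. **Conservation filter** (optional) — miRNA-like support restricted to
   seed sites fully contained in precomputed conserved intervals
   (transcript coordinates; merged, length ≥ 8).
5. **Validation** — predictions scored against expression-change tables:
   transcripts with log-ratio < 0 and p < 0.01 after transfection count as
   true off-targets; the pooled true-positive rate is the headline number.
6. **Annotation** — each off-targeted transcript is written as a SeedSeq
   record whose `target_siRNAs` features carry the siRNAs that hit it.

## Worked example

```python
>>> import seedseq as ss
>>> s = {x.sirna_id: x for x in ss.table2_library()}["s35278"]   # WNK3 siRNA
>>> str(ss.extract_seed(s)), str(ss.seed_site_motif(s))
('AAUACUG', 'CAGUAUU')
>>> t = ss.Transcript("NM_DEMO",
...     ss.NucSeq("GGGC"*10 + str(s.expected_target_site()) + "AGGC"*3),
...     gene_symbol="ZEB1", utr3_start=20)
>>> ss.find_seed_sites(t, s)[0]
SeedSite(transcript_accession='NM_DEMO', start=51, end=58, seed_len=7,
         in_utr3=True, conserved=None, seed_mismatches=0)
>>> aln = ss.align_duplex(s, t.sequence)
>>> aln.score, aln.paired_positions, aln.longest_contiguous_run
(38.0, 19, 19)
>>> rec = ss.call_offtargets(s, [t], mode="mirna_like")[0]
>>> sorted(rec.categories), rec.cleavage_competent, rec.seed_occurrences
(['mirna_like'], True, 1)
```

The seed of s35278 is `AAUACUG` (shared with hsa-miR-200b), so the scanner
looks for `CAGUAUU` on the mRNA; here the planted site is fully
complementary (19/19 paired, run 19), lies in the 3′UTR, and is called a
cleavage-competent miRNA-like off-target. `ss.annotate_transcript(t, [rec])`
turns this into a SeedSeq record with one `target_siRNAs` feature at
`52..58`.

From the shell, on a synthetic dataset:

```sh
$ seedseq simulate --seed 5 --out demo/data
$ seedseq predict --transcriptome demo/data/transcriptome.fasta \
      --library demo/data/library.tsv --mode mirna_like \
      --conserved demo/data/conserved.bed --use-conservation --out demo/run
8 off-target call(s) -> demo/run/offtargets.tsv
SeedSeq records -> demo/run/offtargets.seedseq
$ seedseq validate --offtargets demo/run/offtargets.tsv \
      --expression-dir demo/data --out demo/validation.tsv
pooled: tp=4 fp=4 tp_rate=0.5000 -> demo/validation.tsv
```

`offtargets.tsv` traces every call to its evidence (categories, paired
positions, longest run, seed occurrences, cleavage competence, conserved
site count); `offtargets.seedseq` holds the annotated records.

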