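# Methods

## Sequence model and numbering

All sequences are normalized to the RNA alphabet {A,C,G,U} on input (T is
mapped to U); output formats restore the source alphabet via the record's
molecule type. siRNA coordinates are fixed on the antisense (guide)
strand, 5′→3′, 1-based. The seed region is positions 2–8 (the 7mer-m8
register), the center/cleavage region 8–10, and the duplex core 1–19; the
2-nt 3′ overhangs of a 21-mer never participate in scoring. When a sense
strand is not supplied it is derived as the reverse complement of the
core.

Two numbering conventions appear in the off-targeting literature — seed
positions counted from the antisense 5′ end versus from the 3′ end of the
sense strand. These coincide only for a 19-nt core; this package commits
to antisense numbering everywhere and maps the 3′-compensatory region
("13–19 from the sense 3′ end") onto antisense core positions 13–19. The
mapping is configurable (`ClassifierConfig.compensatory_region`). Likewise
the seed register: 2–8 is the default; a 1–7 register can be set per siRNA
(`seed_def`) but is never chosen silently. The 6-mer register trims the
7-mer motif on its 5′ (mRNA) side, i.e. antisense positions 2–7.

## Seed scanning and windows

Seed-match sites are exact string matches of the motif (reverse complement
of the seed); overlapping occurrences are all reported because the
seed-frequency evidence downstream needs true counts. G:U wobble inside
the seed motif is opt-in (`allow_wobble_in_seed`) — wobble is normally
honored during alignment and pairing evaluation, not during candidate
scanning; wobble-carrying seed sites still enter through the one-mismatch
near-miss scan used by the compensatory rule. The "~50 nt" alignment
window is fixed at exactly `window_width` = 50 with the left flank
`floor((width − seed_len)/2)` and the remainder on the right; flanks clip
independently at transcript ends, so a clipped window is shorter but
always contains the full site. Fixed asymmetric flanks were chosen over
any centering heuristic for determinism.

## Alignment

The local aligner is a plain Smith–Waterman dynamic program with a linear
gap model (no open/extend distinction), chosen deliberately: the pipeline
only aligns a 19-nt query against ≤ ~50-nt windows or single transcripts,
and a linear-gap DP can be verified against an exhaustive
alignment-enumeration oracle, which the test suite does. Defaults
+2 match / −1 mismatch / −2 per gapped position make a 7-nt exact seed
outscore scattered matches; all three are configuration. Tie-breaking is
deterministic (first best cell in row-major order; traceback prefers
diagonal, then query-consuming gap, then target-consuming gap).

Duplex alignment aligns the *expected target site* (reverse complement of
the core) against the mRNA under identity scoring, with the two
wobble-equivalent substitutions (expected C→U, expected A→G on the mRNA
side) classified as wobble and scored as matches iff `wobble_as_match`
(default true). Pairing statistics are recomputed over the 19 core
positions — unaligned or gapped core positions count unpaired — so
"17 of 19" has a fixed denominator. Note that with wobble counted as
pairing, the expected per-position pairing probability against random
background is 5/16, and the best local alignment against a 500-nt random
transcript frequently reaches 15–16 paired core positions; the permissive
behavior of the full-transcript search mode on random sequence is a
property of the published thresholds, not of the implementation.

## Classification rules

* `near_exact`: paired core positions ≥ 17.
* `partial`: longest contiguous paired run ≥ 11, or total paired ≥ 15.
  Under the defaults `near_exact` implies `partial`; the categories are
  computed independently and may co-occur.
* `mirna_like`: evaluated at a seed site by gapless anchored pairing
  (antisense position p faces transcript position `site.start + 8 − p`):
  the seed is perfectly paired, or has *exactly one* mismatch while
  positions 13–19 are perfectly paired. "Exactly one" (not at-most-one)
  keeps the two clauses disjoint. By default the site must lie in the
  3′UTR (canonical miRNA biology); whole-transcript evaluation is a
  configuration switch.
* Cleavage competence: center positions 8–10 all paired. It is tracked as
  a flag, never as a category, since miRNA-like repression does not
  require cleavage.
* Seed G/C content is reported (`seed_gc_fraction`) but never used as a
  filter: no defensible threshold exists for it.

On-target transcripts are excluded by gene-symbol match. Search modes:
`full_sw` (whole transcripts; refused above 200 transcripts unless
overridden, as a cost guardrail, not a semantic limit), `seed_window_sw`
(windows around exact seed sites) and `mirna_like` (rule evaluation at
seed sites with ≤ 1 seed mismatch). The mode is always an explicit user
choice.

## Conservation

Conserved intervals arrive precomputed in transcript coordinates (0-based
half-open, 3-column BED-like); extraction from genomic multiple alignments
is out of scope by design. Intervals are merged (overlapping or adjacent)
and only merged intervals ≥ 8 nt survive. A seed site counts as conserved
only when *fully contained* in a retained interval — containment is the
strictest deterministic reading of "conserved site". Filtering restricts
miRNA-like support to conserved sites and drops records left without
support; alignment-wide (near-exact/partial) evidence is not site-bound
and passes through. Whether conservation must hold in all five reference
species or a subset is delegated to whoever produced the interval set.

## Validation

True off-targets are transcripts with log-ratio < 0 and p < alpha
(default 0.01, a raw threshold — no multiple-testing correction, matching
how such expression cut-offs are conventionally applied in this setting).
The pooled true-positive rate (counts summed over siRNAs) is primary; the
unweighted mean of per-siRNA rates is reported alongside because the
pooling choice is genuinely ambiguous and changes the number. An siRNA
with predictions but no expression table is flagged, never dropped.

## Synthetic data

The fixture generator builds the closed-loop test bed:

* **Library**: random 21-nt antisense strands with pairwise-distinct
  seeds (default 4 strands). The published 13-row siRNA/miRNA
  seed-overlap table also ships as a packaged static fixture.
* **Transcriptome**: default 24 transcripts of 400–700 nt, the final 40%
  of each being 3′UTR. Background is rejection-sampled per transcript so
  that, for every library siRNA, it contains no exact seed motif and no
  3′UTR window the miRNA-like rule would call (wobble-rescued seeds occur
  in random background at ~one per few hundred nt per siRNA, so post-hoc
  masking would be unreliable; rejection makes false positives zero by
  construction). Planted constructs, one per manifest entry, each trigger
  exactly one rule: an exact seed 7-mer (3′UTR), a one-seed-mismatch
  19-mer with intact 13–19 (3′UTR), a non-conserved decoy seed site
  (3′UTR), a perfect 19-mer, an 11-mer covering antisense 5–15, and a
  19-mer with mismatches at positions 3/8/13/18 (15 paired, longest run
  4). Mismatches substitute the antisense base itself, which can never
  pair Watson–Crick or wobble. CDS-only classes sit upstream of the UTR
  so the miRNA-like scan cannot see them. After planting, the whole build
  is verified detector-clean and redrawn on junction artifacts. Each
  generator draws from its own child RNG stream, so outputs are
  byte-stable under extension.
* **Conservation track**: wraps every non-decoy miRNA-like site, plus
  ~30% random coverage that never contains a decoy site.
* **Expression tables**: each predicted accession is a true off-target
  with probability `tp_rate` (default 0.65, the ballpark of published
  validation rates); null rows have uniform p and symmetric log-ratios,
  nudged positive when p < alpha so the planted rate is exactly binomial.

What passing these tests does *not* show: real transcriptomes are not
motif-free backgrounds — repeats, composition bias and shared seed
families produce far denser candidate sets; expression changes after
transfection include concentration and immune effects no sequence rule
captures; and conservation tracks derived from real multiple alignments
carry alignment error. The closed loop certifies the machinery, not
biological accuracy.

## Problem sizes and numerics

Default test/acceptance scales — 24 transcripts × 4 siRNAs, 200 random
oracle transcripts, 500 oracle alignment pairs, 100 round-trip records,
2000 validation predictions — were chosen so the whole suite completes in
seconds while leaving each statistical check comfortably powered (the
binomial check on 2000 predictions has σ ≈ 1.1 points against a ±3-point
band). Alignment scores are floats but all default scores are integers,
so oracle comparisons are exact; empty local alignments return score 0
with empty intervals. Degenerate inputs (empty transcriptome, empty
prediction set, unknown accessions) return empty results rather than
errors; genuinely inconsistent configuration (a 3′UTR-only scan on a
transcript without a UTR offset, conservation filtering without a track)
raises a configuration error.

## Format dialect

The record layout is documented in `seedseq_io`'s module docstring: LOCUS
carries name/length/molecule only; DEFINITION is verbatim pipe-joined
`key=value` metadata; features use 1-based inclusive `a..b` locations with
the fixed v1 qualifier vocabulary (`sirna_id`, `supplier`, `categories`,
`seed_occurrences`), stamped in the COMMENT line of records the annotator
writes. The reader tolerates missing FEATURES and missing terminal `//`
(the published example record has neither), arbitrary ORIGIN grouping and
case; the writer always emits the full layout, lowercase ORIGIN by
convention (configurable), with BASE COUNT recomputed from the sequence.
A declared LOCUS length or BASE COUNT that contradicts the sequence warns
by default and raises in strict mode.
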