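"""Smith-Waterman local alignment and siRNA:mRNA duplex evaluation.

The aligner is a plain dynamic-programming implementation with linear gap
costs, written for exactness and oracle-testability rather than speed: the
pipeline only ever aligns a short siRNA-derived query (19 nt) against a
~50-nt window or a single transcript, so striped/SIMD variants buy nothing.

Two pairing vocabularies coexist:

* plain :func:`smith_waterman` treats "match" as sequence identity — used
  when aligning the expected target-site sequence against the mRNA;
* :func:`align_duplex` honors G:U wobble, which RISC reads as an authentic
  Watson-Crick pair, by treating wobble-equivalent substitutions in the
  expected site (C->U, A->G on the mRNA side) as matches when the scoring
  scheme says so.

All duplex bookkeeping is reported over the antisense duplex core
(positions 1-19, 5'->3'), so statements like "17 paired out of 19" have a
fixed denominator regardless of strand length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .seqcore import NucSeq, SiRNA, complement_base

__all__ = [
    "MATCH",
    "WOBBLE",
    "MISMATCH",
    "GAP",
    "ScoringScheme",
    "DuplexAlignment",
    "pair_bases",
    "smith_waterman",
    "align_duplex",
]

MATCH = "|"
WOBBLE = ":"
MISMATCH = "."
GAP = "-"

CORE_LEN = 19


@dataclass(frozen=True)
class ScoringScheme:
    """Local-alignment scoring parameters.

    Defaults (+2 match / -1 mismatch / -2 per gapped position, linear) are
    chosen so that a 7-nt exact seed outscores scattered matches.
    ``wobble_as_match`` makes G:U pairs score (and count) as matches.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0
    wobble_as_match: bool = True

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap scores must be <= 0")

    def column_score(self, kind: str) -> float:
        if kind == MATCH or (kind == WOBBLE and self.wobble_as_match):
            return self.match
        if kind in (WOBBLE, MISMATCH):
            return self.mismatch
        raise ValueError(f"unknown column kind {kind!r}")

    def counts_paired(self, kind: str) -> bool:
        return kind == MATCH or (kind == WOBBLE and self.wobble_as_match)


@dataclass(frozen=True)
class DuplexAlignment:
    """Outcome of a local alignment, with duplex pairing bookkeeping.

    ``pairing_string`` has one symbol per alignment column: '|' match,
    ':' wobble, '.' mismatch, '-' gap; ``ops`` is the parallel column type
    string over {M: both consumed, I: query consumed/target gap, D: target
    consumed/query gap}.  ``paired_positions`` and
    ``longest_contiguous_run`` are counted over antisense core positions
    for duplex alignments and over alignment columns for plain ones.
    ``core_status`` (duplex alignments only) maps antisense position
    (1-based, 1..19) to its column symbol, '-' when unaligned or gapped.
    """

    score: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    pairing_string: str
    paired_positions: int
    longest_contiguous_run: int
    ops: str = ""
    core_status: Optional[dict[int, str]] = None

    @property
    def is_empty(self) -> bool:
        return self.query_interval[0] == self.query_interval[1]

    def __post_init__(self) -> None:
        if self.longest_contiguous_run > self.paired_positions:
            raise ValueError("contiguous run cannot exceed paired positions")


def pair_bases(antisense_base: str, mrna_base: str, s: ScoringScheme = ScoringScheme()) -> str:
    """Classify an antisense:mRNA base pair as match, wobble or mismatch.

    Watson-Crick pairs (A:U, U:A, G:C, C:G) are matches; G:U and U:G are
    wobbles (scored as matches iff ``s.wobble_as_match``); anything else
    mismatches.
    """
    if complement_base(antisense_base) == mrna_base:
        return MATCH
    if (antisense_base, mrna_base) in (("G", "U"), ("U", "G")):
        return WOBBLE
    return MISMATCH


def _identity_kind(a: str, b: str) -> str:
    return MATCH if a == b else MISMATCH


def _duplex_kind(expected: str, actual: str) -> str:
    """Pair kind for identity alignment of the expected target site.

    The expected-site base is the complement of the antisense base, so a
    G:U wobble in the duplex shows up as expected C / actual U (antisense
    G : mRNA U) or expected A / actual G (antisense U : mRNA G).
    """
    if expected == actual:
        return MATCH
    if (expected, actual) in (("C", "U"), ("A", "G")):
        return WOBBLE
    return MISMATCH


def smith_waterman(
    a: NucSeq | str,
    b: NucSeq | str,
    s: ScoringScheme = ScoringScheme(),
    pair_kind: Callable[[str, str], str] = _identity_kind,
) -> DuplexAlignment:
    """Optimal local alignment of ``a`` (query) against ``b`` (target).

    Linear gap model; score >= 0, with the empty alignment (score 0)
    returned when no positive-scoring pair of substrings exists.
    Tie-breaks are deterministic: the first best cell in row-major order
    is chosen, and traceback prefers diagonal over up over left.
    """
    a, b = str(NucSeq(a)), str(NucSeq(b))
    if not a or not b:
        raise ValueError("smith_waterman requires nonempty sequences")
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, n + 1):
            diag = prev[j - 1] + s.column_score(pair_kind(ai, b[j - 1]))
            up = prev[j] + s.gap
            left = row[j - 1] + s.gap
            h = max(0.0, diag, up, left)
            row[j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return DuplexAlignment(0.0, (0, 0), (0, 0), "", 0, 0, "")

    # traceback from the (unique, row-major-first) best cell
    symbols: list[str] = []
    ops: list[str] = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        kind = pair_kind(a[i - 1], b[j - 1])
        if h == H[i - 1][j - 1] + s.column_score(kind):
            symbols.append(kind)
            ops.append("M")
            i, j = i - 1, j - 1
        elif h == H[i - 1][j] + s.gap:
            symbols.append(GAP)
            ops.append("I")
            i -= 1
        else:
            symbols.append(GAP)
            ops.append("D")
            j -= 1
    symbols.reverse()
    ops.reverse()
    pairing = "".join(symbols)
    paired = sum(1 for k in symbols if s.counts_paired(k))
    run = best_run = 0
    for k in symbols:
        run = run + 1 if s.counts_paired(k) else 0
        best_run = max(best_run, run)
    return DuplexAlignment(
        score=best,
        query_interval=(i, bi),
        target_interval=(j, bj),
        pairing_string=pairing,
        paired_positions=paired,
        longest_contiguous_run=best_run,
        ops="".join(ops),
    )


def align_duplex(
    sirna: SiRNA, window: NucSeq | str, s: ScoringScheme = ScoringScheme()
) -> DuplexAlignment:
    """Align an siRNA against an mRNA window and score the duplex core.

    The expected target site (reverse complement of antisense positions
    1-19) is locally aligned against the window with wobble-equivalent
    substitutions honored.  ``paired_positions`` and
    ``longest_contiguous_run`` are then recomputed over the 19 antisense
    core positions: a core position is paired iff its alignment column is a
    match (or a wobble under ``wobble_as_match``); unaligned or gapped core
    positions are unpaired.  Expected-site index ``i`` (0-based) pairs with
    antisense position ``19 - i`` (1-based).
    """
    site = sirna.expected_target_site()
    aln = smith_waterman(site, window, s, pair_kind=_duplex_kind)

    status = {p: GAP for p in range(1, CORE_LEN + 1)}
    q = aln.query_interval[0]
    for sym, op in zip(aln.pairing_string, aln.ops):
        if op == "M":
            status[CORE_LEN - q] = sym
            q += 1
        elif op == "I":  # query consumed against a target gap: unpaired
            status[CORE_LEN - q] = GAP
            q += 1
        # op == "D": target-only column, no core position consumed

    paired = sum(1 for sym in status.values() if s.counts_paired(sym))
    run = best_run = 0
    for p in range(1, CORE_LEN + 1):
        run = run + 1 if s.counts_paired(status[p]) else 0
        best_run = max(best_run, run)
    return DuplexAlignment(
        score=aln.score,
        query_interval=aln.query_interval,
        target_interval=aln.target_interval,
        pairing_string=aln.pairing_string,
        paired_positions=paired,
        longest_contiguous_run=best_run,
        ops=aln.ops,
        core_status=status,
    )
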