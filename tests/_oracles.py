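"""Independent reference computations used by the test suite.

These deliberately avoid the package's own dynamic-programming local
aligner: the enumeration oracle scores every complete alignment of every
substring pair, and the memoized oracle phrases the problem as global
alignment maximized over substring pairs.  Both agree with Smith-Waterman
by definition of a local alignment.
"""

from functools import lru_cache


def enumerate_local_best(a: str, b: str, match=2.0, mismatch=-1.0, gap=-2.0) -> float:
    """Best local score by explicit enumeration of all alignments of all
    substring pairs.  Exponential; only for very short sequences."""

    def all_global_scores(x: str, y: str):
        if not x and not y:
            yield 0.0
            return
        if x and y:
            sub = match if x[0] == y[0] else mismatch
            for s in all_global_scores(x[1:], y[1:]):
                yield sub + s
        if x:
            for s in all_global_scores(x[1:], y):
                yield gap + s
        if y:
            for s in all_global_scores(x, y[1:]):
                yield gap + s

    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1, len(b) + 1):
                    if i1 == i2 and j1 == j2:
                        continue
                    best = max(best, max(all_global_scores(a[i1:i2], b[j1:j2])))
    return best


def global_over_substrings_best(a: str, b: str, match=2.0, mismatch=-1.0, gap=-2.0) -> float:
    """Best local score as max over substring pairs of the global
    (end-to-end) alignment score, computed by memoized recursion."""

    @lru_cache(maxsize=None)
    def g(x: str, y: str) -> float:
        if not x:
            return gap * len(y)
        if not y:
            return gap * len(x)
        sub = match if x[0] == y[0] else mismatch
        return max(sub + g(x[1:], y[1:]), gap + g(x[1:], y), gap + g(x, y[1:]))

    best = 0.0
    for i1 in range(len(a) + 1):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b) + 1):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, g(a[i1:i2], b[j1:j2]))
    g.cache_clear()
    return best


def naive_seed_scan(sequence: str, motif: str, start_from: int = 0) -> list[int]:
    """Position-by-position substring comparison (seed-scan oracle)."""
    hits = []
    for i in range(start_from, len(sequence) - len(motif) + 1):
        if all(sequence[i + k] == motif[k] for k in range(len(motif))):
            hits.append(i)
    return hits


def biopython_local_score(a: str, b: str, match=2.0, mismatch=-1.0, gap=-2.0) -> float:
    """Cross-check via Biopython's C pairwise aligner (linear gaps)."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap,
        extend_gap_score=gap,
    )
    return float(aligner.score(a, b))
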