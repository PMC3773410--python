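"""Conservation filtering of seed-match sites.

Seed sites conserved across closely related species (human, chimp, mouse,
rat, dog by convention) are more likely to be functional; restricting the
miRNA-like search to conserved sites cuts the candidate list sharply.
Conserved intervals are consumed pre-computed, in transcript coordinates
(0-based half-open, BED-like 3 columns: accession, start, end) — the
genomic multiple-alignment extraction that produces them is out of scope.
Intervals are merged when overlapping or adjacent, and only merged
intervals of at least ``min_length`` bases (default 8) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .classify import MIRNA_LIKE, OffTargetRecord
from .seedscan import SeedSite

__all__ = ["ConservedIntervalSet", "load_conserved", "is_conserved", "filter_conserved"]

DEFAULT_SPECIES = "human,chimp,mouse,rat,dog"
DEFAULT_MIN_LENGTH = 8


@dataclass
class ConservedIntervalSet:
    """Per-transcript conserved intervals, normalized and length-filtered."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)
    species_set: str = DEFAULT_SPECIES
    min_length: int = DEFAULT_MIN_LENGTH

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[tuple[str, int, int]],
        species_set: str = DEFAULT_SPECIES,
        min_length: int = DEFAULT_MIN_LENGTH,
    ) -> "ConservedIntervalSet":
        trees: dict[str, IntervalTree] = {}
        for i, (acc, start, end) in enumerate(rows):
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(
                    f"malformed conserved interval row {i} ({acc}, {start}, {end}): start >= end"
                )
            trees.setdefault(acc, IntervalTree()).addi(start, end)
        for acc, tree in trees.items():
            tree.merge_overlaps(strict=False)  # adjacent intervals merge too
            for iv in [iv for iv in tree if iv.end - iv.begin < min_length]:
                tree.remove(iv)
        return cls(trees={a: t for a, t in trees.items() if t}, species_set=species_set,
                   min_length=min_length)

    def intervals(self, accession: str) -> list[tuple[int, int]]:
        tree = self.trees.get(accession)
        return sorted((iv.begin, iv.end) for iv in tree) if tree else []

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def load_conserved(
    source: str | Path | pd.DataFrame,
    species_set: str = DEFAULT_SPECIES,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> ConservedIntervalSet:
    """Load a BED-like 3-column table (accession, start, end; 0-based half-open)."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(
            source, sep=r"\s+", header=None, names=["accession", "start", "end"],
            comment="#", dtype={"accession": str},
        )
    return ConservedIntervalSet.from_rows(
        ((r.accession, r.start, r.end) for r in df.itertuples(index=False)),
        species_set=species_set,
        min_length=min_length,
    )


def is_conserved(site: SeedSite, cset: ConservedIntervalSet) -> bool:
    """True iff the site interval is fully contained in a retained interval.

    Containment, not mere overlap: a site half inside a conserved block is
    not a conserved site.  Unknown accessions are simply not conserved.
    """
    tree = cset.trees.get(site.transcript_accession)
    if tree is None:
        return False
    return any(iv.begin <= site.start and site.end <= iv.end for iv in tree.overlap(site.start, site.end))


def filter_conserved(
    records: Sequence[OffTargetRecord], cset: ConservedIntervalSet
) -> list[OffTargetRecord]:
    """Restrict miRNA-like support to conserved sites.

    Each record's supporting sites are filtered to conserved ones and
    ``conserved_site_count`` is set.  A record whose only support was
    non-conserved miRNA-like sites is dropped; near-exact/partial calls
    are untouched (their evidence is alignment-wide, not site-bound).
    Output is always a subset of the input.
    """
    out = []
    for rec in records:
        kept = tuple(
            replace(s, conserved=True) for s in rec.sites if is_conserved(s, cset)
        )
        if MIRNA_LIKE in rec.categories:
            cats = set(rec.categories)
            if not kept:
                cats.discard(MIRNA_LIKE)
            if not cats:
                continue
            out.append(
                replace(rec, sites=kept, categories=frozenset(cats), conserved_site_count=len(kept))
            )
        else:
            out.append(replace(rec, sites=kept, conserved_site_count=len(kept)))
    return out
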