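"""Nucleotide sequence model, strand arithmetic and seed extraction.

All sequences are held internally in a canonical RNA alphabet {A,C,G,U};
DNA input (T) is accepted and mapped to U on construction.  Numbering of
siRNA strands is fixed on the antisense (guide) strand, 5'->3', 1-based:
the seed region is positions 2-8 and the cleavage-site center region is
positions 8-10.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

try:  # Python >= 3.9 importlib.resources files API
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

__all__ = [
    "AlphabetError",
    "NucSeq",
    "Transcript",
    "SiRNA",
    "reverse_complement",
    "complement_base",
    "extract_seed",
    "seed_site_motif",
    "seed_gc_fraction",
    "base_count",
    "to_dna",
    "read_fasta",
    "read_sirna_library",
    "table2_library",
]

_CANONICAL = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_RC_TABLE = str.maketrans("ACGU", "UGCA")


class AlphabetError(ValueError):
    """A sequence contains a residue outside {A,C,G,U,T} (case-insensitive)."""


class NucSeq(str):
    """An RNA sequence over {A,C,G,U}.

    Subclasses :class:`str`: slicing, iteration and comparison behave as for
    plain strings (slices degrade to ``str``).  Construction normalizes case
    and maps T->U; any other residue raises :class:`AlphabetError`.
    """

    def __new__(cls, residues: str = "") -> "NucSeq":
        s = str(residues).upper().replace("T", "U")
        bad = set(s) - _CANONICAL
        if bad:
            raise AlphabetError(
                f"non-canonical residue(s) {sorted(bad)} in sequence {residues[:30]!r}"
            )
        return super().__new__(cls, s)

    def reverse_complement(self) -> "NucSeq":
        return reverse_complement(self)


def complement_base(b: str) -> str:
    """Watson-Crick complement of a single canonical RNA residue."""
    try:
        return _COMPLEMENT[b]
    except KeyError:
        raise AlphabetError(f"non-canonical residue {b!r}") from None


def reverse_complement(s: NucSeq | str) -> NucSeq:
    """Reverse complement (A<->U, C<->G) of a normalized RNA sequence."""
    if not isinstance(s, NucSeq):
        s = NucSeq(s)
    return NucSeq(str(s).translate(_RC_TABLE)[::-1])


def base_count(s: NucSeq | str) -> dict[str, int]:
    """Residue counts over the canonical alphabet; counts sum to ``len(s)``."""
    if not isinstance(s, NucSeq):
        s = NucSeq(s)
    return {b: s.count(b) for b in "ACGU"}


def to_dna(s: NucSeq | str) -> str:
    """Render a canonical RNA sequence in the DNA alphabet (U -> T)."""
    return str(NucSeq(s)).replace("U", "T")


@dataclass(frozen=True)
class Transcript:
    """An mRNA/ncRNA transcript (NM_/NR_/XM_/XR_-style accession).

    ``utr3_start`` is the 0-based offset of the first 3'UTR base, when known.
    """

    accession: str
    sequence: NucSeq
    gene_symbol: str = ""
    utr3_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("transcript accession must be nonempty")
        if not isinstance(self.sequence, NucSeq):
            object.__setattr__(self, "sequence", NucSeq(self.sequence))
        if self.utr3_start is not None and not (
            0 <= self.utr3_start < len(self.sequence)
        ):
            raise ValueError(
                f"utr3_start {self.utr3_start} outside transcript "
                f"{self.accession} of length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiRNA:
    """An siRNA duplex, held by its antisense (guide) strand 5'->3'.

    The seed is antisense positions ``seed_def`` (1-based inclusive,
    default 2-8, the 7mer-m8 register).  ``center_def`` marks the cleavage
    site opposite antisense bases 8-10.  When the sense strand is absent it
    is derived as the reverse complement of antisense positions 1-19 (the
    duplex core); 3' overhangs never participate in scoring.
    """

    sirna_id: str
    antisense: NucSeq
    on_target_gene: str = ""
    sense: Optional[NucSeq] = None
    supplier: str = ""
    seed_def: tuple[int, int] = (2, 8)
    center_def: tuple[int, int] = (8, 10)

    CORE_LEN = 19

    def __post_init__(self) -> None:
        if not isinstance(self.antisense, NucSeq):
            object.__setattr__(self, "antisense", NucSeq(self.antisense))
        if self.sense is not None and not isinstance(self.sense, NucSeq):
            object.__setattr__(self, "sense", NucSeq(self.sense))
        if not 19 <= len(self.antisense) <= 23:
            raise ValueError(
                f"antisense strand of {self.sirna_id!r} has length "
                f"{len(self.antisense)}; expected 19-23 nt"
            )
        lo, hi = self.seed_def
        if not (1 <= lo <= hi <= len(self.antisense)):
            raise ValueError(f"seed_def {self.seed_def} outside antisense bounds")

    @property
    def core(self) -> NucSeq:
        """Antisense positions 1-19, the region base-paired in the duplex."""
        return NucSeq(self.antisense[: self.CORE_LEN])

    def derived_sense(self) -> NucSeq:
        """Sense strand: given, or reverse complement of the duplex core."""
        return self.sense if self.sense is not None else reverse_complement(self.core)

    def expected_target_site(self) -> NucSeq:
        """The mRNA sequence a fully complementary target site would have.

        Reverse complement of the duplex core, 5'->3' in mRNA orientation;
        its index ``i`` pairs with antisense position ``19 - i`` (1-based).
        """
        return reverse_complement(self.core)


def extract_seed(sirna: SiRNA) -> NucSeq:
    """Seed region of the antisense strand (1-based positions 2-8 by default)."""
    lo, hi = sirna.seed_def
    if len(sirna.antisense) < hi:
        raise ValueError(
            f"antisense strand shorter than seed bound {hi} for {sirna.sirna_id!r}"
        )
    return NucSeq(sirna.antisense[lo - 1 : hi])


def seed_site_motif(sirna: SiRNA) -> NucSeq:
    """The mRNA-side seed-match motif: reverse complement of the seed."""
    return reverse_complement(extract_seed(sirna))


def seed_gc_fraction(sirna: SiRNA) -> float:
    """G+C fraction of the seed region, in [0, 1]."""
    seed = extract_seed(sirna)
    return (seed.count("G") + seed.count("C")) / len(seed)


# ---------------------------------------------------------------------------
# readers

_GENE_KEY = re.compile(r"\bgene=(\S+)")


def read_fasta(path: str | Path | Iterable[str]) -> list[Transcript]:
    """Read a transcriptome FASTA (RNA or DNA alphabet).

    The accession is the first whitespace-delimited header token; a gene
    symbol is taken from an optional ``gene=SYMBOL`` key, and a 3'UTR offset
    from an optional ``utr3_start=N`` key (0-based).
    """
    from Bio import SeqIO

    transcripts = []
    for rec in SeqIO.parse(str(path) if isinstance(path, (str, Path)) else path, "fasta"):
        m = _GENE_KEY.search(rec.description)
        u = re.search(r"\butr3_start=(\d+)", rec.description)
        transcripts.append(
            Transcript(
                accession=rec.id,
                sequence=NucSeq(str(rec.seq)),
                gene_symbol=m.group(1) if m else "",
                utr3_start=int(u.group(1)) if u else None,
            )
        )
    return transcripts


def read_sirna_library(path: str | Path, sep: str = "\t") -> list[SiRNA]:
    """Read an siRNA library table with columns sirna_id, gene, antisense[, sense]."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sirna_id", "gene", "antisense"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"siRNA library missing column(s): {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SiRNA(
                sirna_id=row.sirna_id,
                on_target_gene=row.gene,
                antisense=NucSeq(row.antisense.replace(" ", "")),
                sense=NucSeq(row.sense) if "sense" in df.columns and isinstance(row.sense, str) else None,
                supplier=getattr(row, "supplier", "") or "",
            )
        )
    return out


def table2_library(unique: bool = True) -> list[SiRNA]:
    """The packaged 13-row published siRNA/miRNA seed-overlap table.

    With ``unique=True`` (default) rows are deduplicated by sirna_id,
    preserving first occurrence (the table repeats siRNAs with several
    off-target genes).
    """
    path = _pkg_files("seedseq").joinpath("data/table2_sirnas.tsv")
    lib = read_sirna_library(str(path))
    if not unique:
        return lib
    seen: dict[str, SiRNA] = {}
    for s in lib:
        seen.setdefault(s.sirna_id, s)
    return list(seen.values())
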