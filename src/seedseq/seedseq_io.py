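"""Reader/writer for the SeedSeq flat-file dialect.

SeedSeq records look like RefSeq/GenBank flat files: LOCUS, DEFINITION,
ACCESSION, an optional COMMENT, a FEATURES table, a BASE COUNT line and an
ORIGIN sequence block, optionally terminated by ``//``.  The dialect
departs from canonical GenBank in a few deliberate ways:

* the LOCUS line carries only name, length and molecule (no division or
  date fields);
* DEFINITION holds pipe-joined ``key=value`` metadata, preserved verbatim
  (a parsed key->value view is available; unknown keys survive
  round-trips);
* off-target annotations live in FEATURES under the key ``target_siRNAs``
  with the fixed qualifier vocabulary sirna_id, supplier, categories,
  seed_occurrences (dialect v1, stamped in the COMMENT line by
  :func:`annotate_transcript`).

The reader is tolerant: ORIGIN position labels, 10-base grouping,
whitespace and case are all optional, and both FEATURES and the trailing
``//`` may be absent (the published example record has neither).  The
writer always emits the full canonical layout: BASE COUNT recomputed from
the sequence, ORIGIN with 1-based labels, 60 residues per line in
10-residue groups, lowercase by default, terminated by ``//``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .classify import OffTargetRecord
from .seqcore import NucSeq, Transcript, base_count, to_dna

__all__ = [
    "Feature",
    "SeedSeqRecord",
    "ParseError",
    "read_record",
    "read_records",
    "write_record",
    "write_records",
    "annotate_transcript",
]

DIALECT_COMMENT = (
    "seedseq dialect v1; target_siRNAs qualifiers: sirna_id, supplier, "
    "categories, seed_occurrences"
)

_KEYWORDS = ("LOCUS", "DEFINITION", "ACCESSION", "COMMENT", "FEATURES", "BASE", "ORIGIN")


class ParseError(ValueError):
    """Malformed SeedSeq/GenBank-dialect input; message carries a line number."""


@dataclass(frozen=True)
class Feature:
    """A feature-table entry: key, 1-based inclusive location, qualifiers."""

    key: str
    location: tuple[int, int]
    qualifiers: tuple[tuple[str, str | int], ...] = ()

    def qualifier(self, name: str, default=None):
        for k, v in self.qualifiers:
            if k == name:
                return v
        return default


@dataclass(frozen=True)
class SeedSeqRecord:
    """One SeedSeq flat-file record (data model; layout lives in the writer)."""

    locus_name: str
    sequence: NucSeq
    molecule: str = "RNA"
    definition: str = ""
    accession: str = ""
    comment: str = ""
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.sequence, NucSeq):
            object.__setattr__(self, "sequence", NucSeq(self.sequence))
        if self.molecule not in ("DNA", "RNA"):
            raise ValueError(f"molecule must be DNA or RNA, not {self.molecule!r}")
        if not self.accession:  # accession defaults to the locus name
            object.__setattr__(self, "accession", self.locus_name)
        for f in self.features:
            lo, hi = f.location
            if not 1 <= lo <= hi <= len(self.sequence):
                raise ValueError(
                    f"feature {f.key} location {f.location} outside record of "
                    f"length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def definition_fields(self) -> dict[str, str]:
        """Parsed view of pipe-joined key=value DEFINITION metadata."""
        out: dict[str, str] = {}
        for part in self.definition.split("|"):
            part = part.strip()
            if "=" in part:
                k, v = part.split("=", 1)
                out[k.strip()] = v.strip()
        return out

    def base_counts(self) -> dict[str, int]:
        """Counts keyed by the record's output alphabet (t for DNA, u for RNA)."""
        counts = base_count(self.sequence)
        last = "t" if self.molecule == "DNA" else "u"
        return {"a": counts["A"], "c": counts["C"], "g": counts["G"], last: counts["U"]}


# ---------------------------------------------------------------------------
# reading


def _is_keyword_line(line: str) -> bool:
    head = line.split(maxsplit=1)
    return bool(head) and not line[:1].isspace() and head[0].upper() in _KEYWORDS


def read_records(source: str | Path, strict: bool = False) -> list[SeedSeqRecord]:
    """Read a (possibly multi-record, ``//``-separated) SeedSeq file or text."""
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "\n" not in text:
            try:
                if Path(text).exists():
                    text = Path(text).read_text()
            except OSError:
                pass
    records = []
    block: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.strip() == "//":
            if any(l.strip() for _, l in block):
                records.append(_parse_block(block, strict))
            block = []
        else:
            block.append((lineno, line))
    if any(l.strip() for _, l in block):
        records.append(_parse_block(block, strict))
    return records


def read_record(source: str | Path, strict: bool = False) -> SeedSeqRecord:
    """Read a single SeedSeq record (the terminal ``//`` may be absent)."""
    records = read_records(source, strict=strict)
    if len(records) != 1:
        raise ParseError(f"expected exactly one record, found {len(records)}")
    return records[0]


def _parse_block(lines: list[tuple[int, str]], strict: bool) -> SeedSeqRecord:
    locus_name = molecule = accession = ""
    length_declared: Optional[int] = None
    definition_parts: list[str] = []
    comment_parts: list[str] = []
    declared_counts: Optional[dict[str, int]] = None
    feature_lines: list[tuple[int, str]] = []
    seq_chars: list[str] = []
    section = None
    saw_locus = saw_origin = False

    for lineno, raw in lines:
        if not raw.strip():
            continue
        if _is_keyword_line(raw):
            tokens = raw.split()
            kw = tokens[0].upper()
            if kw == "LOCUS":
                saw_locus = True
                section = None
                if len(tokens) < 2:
                    raise ParseError(f"line {lineno}: LOCUS line has no name")
                locus_name = tokens[1]
                m = re.search(r"(\d+)\s*bp\b", raw, re.I)
                if m:
                    length_declared = int(m.group(1))
                mm = re.search(r"\b(DNA|RNA)\b", raw, re.I)
                molecule = mm.group(1).upper() if mm else "DNA"
            elif kw == "DEFINITION":
                section = "DEFINITION"
                definition_parts.append(raw.split(maxsplit=1)[1] if len(tokens) > 1 else "")
            elif kw == "ACCESSION":
                section = None
                accession = tokens[1] if len(tokens) > 1 else ""
            elif kw == "COMMENT":
                section = "COMMENT"
                comment_parts.append(raw.split(maxsplit=1)[1] if len(tokens) > 1 else "")
            elif kw == "FEATURES":
                section = "FEATURES"
            elif kw == "BASE":
                section = None
                declared_counts = _parse_base_count(raw, lineno)
            elif kw == "ORIGIN":
                saw_origin = True
                section = "ORIGIN"
        else:
            if section == "DEFINITION":
                definition_parts.append(raw.strip())
            elif section == "COMMENT":
                comment_parts.append(raw.strip())
            elif section == "FEATURES":
                feature_lines.append((lineno, raw))
            elif section == "ORIGIN":
                seq_chars.append(re.sub(r"[\d\s.]", "", raw))
            # stray lines outside any section are ignored

    if not saw_locus:
        raise ParseError(f"line {lines[0][0] if lines else 0}: record has no LOCUS line")
    if not saw_origin:
        raise ParseError(f"line {lines[-1][0] if lines else 0}: record has no ORIGIN block")

    sequence = NucSeq("".join(seq_chars))
    record = SeedSeqRecord(
        locus_name=locus_name,
        sequence=sequence,
        molecule=molecule,
        definition=" ".join(p for p in definition_parts if p),
        accession=accession or locus_name,
        comment=" ".join(p for p in comment_parts if p),
        features=tuple(_parse_features(feature_lines, len(sequence))),
    )

    if length_declared is not None and length_declared != len(sequence):
        msg = (
            f"LOCUS declares {length_declared} bp but ORIGIN holds "
            f"{len(sequence)} for {locus_name}"
        )
        if strict:
            raise ParseError(msg)
        warnings.warn(msg, stacklevel=2)
    if declared_counts is not None and declared_counts != record.base_counts():
        msg = f"BASE COUNT line inconsistent with sequence of {locus_name}"
        if strict:
            raise ParseError(msg)
        warnings.warn(msg, stacklevel=2)
    return record


def _parse_base_count(line: str, lineno: int) -> dict[str, int]:
    tokens = line.split()[2:]  # drop "BASE COUNT"
    if len(tokens) % 2:
        raise ParseError(f"line {lineno}: malformed BASE COUNT line")
    counts = {}
    for n, letter in zip(tokens[::2], tokens[1::2]):
        try:
            counts[letter.lower()] = int(n)
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric BASE COUNT entry {n!r}") from None
    return counts


_LOCATION = re.compile(r"^(\d+)\.\.(\d+)$")


def _parse_features(lines: list[tuple[int, str]], seq_len: int) -> list[Feature]:
    features: list[Feature] = []
    key = None
    location = None
    quals: list[tuple[str, str | int]] = []

    def flush():
        nonlocal key, location, quals
        if key is not None:
            features.append(Feature(key=key, location=location, qualifiers=tuple(quals)))
        key, location, quals = None, None, []

    for lineno, raw in lines:
        stripped = raw.strip()
        if not stripped or stripped.lower().startswith("location/qualifiers"):
            continue
        if stripped.startswith("/"):
            body = stripped[1:]
            if "=" in body:
                qk, qv = body.split("=", 1)
                qv = qv.strip()
                if qv.startswith('"') and qv.endswith('"'):
                    val: str | int = qv[1:-1]
                else:
                    try:
                        val = int(qv)
                    except ValueError:
                        val = qv
                quals.append((qk.strip(), val))
            else:
                quals.append((body.strip(), ""))
        else:
            flush()
            parts = stripped.split()
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: feature line lacks a location: {stripped!r}")
            key = parts[0]
            m = _LOCATION.match(parts[1])
            if not m:
                raise ParseError(f"line {lineno}: unsupported feature location {parts[1]!r}")
            location = (int(m.group(1)), int(m.group(2)))
    flush()
    return features


# ---------------------------------------------------------------------------
# writing


def write_record(r: SeedSeqRecord, case: str = "lower") -> str:
    """Render one record in the canonical dialect layout.

    ORIGIN is written 60 residues per line in 10-residue groups with
    1-based position labels right-aligned in a 9-column field; the sequence
    is emitted in the record's molecule alphabet (T for DNA, U for RNA),
    lowercase by default.  BASE COUNT is always recomputed from the
    sequence.  Sequence comparisons on read are case-insensitive.
    """
    if case not in ("lower", "upper"):
        raise ValueError("case must be 'lower' or 'upper'")
    seq = to_dna(r.sequence) if r.molecule == "DNA" else str(r.sequence)
    seq = seq.lower() if case == "lower" else seq.upper()

    out = [f"LOCUS       {r.locus_name:<16} {r.length:>7} bp    {r.molecule}"]
    if r.definition:
        out.append(f"DEFINITION  {r.definition}")
    out.append(f"ACCESSION   {r.accession or r.locus_name}")
    if r.comment:
        out.append(f"COMMENT     {r.comment}")
    out.append("FEATURES             Location/Qualifiers")
    for f in r.features:
        out.append(f"     {f.key:<15} {f.location[0]}..{f.location[1]}")
        for qk, qv in f.qualifiers:
            rendered = str(qv) if isinstance(qv, int) else f'"{qv}"'
            out.append(f"                     /{qk}={rendered}")
    counts = r.base_counts()
    out.append("BASE COUNT  " + "  ".join(f"{n:>6} {b}" for b, n in counts.items()))
    out.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        out.append(f"{i + 1:>9} {groups}")
    out.append("//")
    return "\n".join(out) + "\n"


def write_records(records: Iterable[SeedSeqRecord], case: str = "lower") -> str:
    return "".join(write_record(r, case=case) for r in records)


def annotate_transcript(
    t: Transcript,
    records: Sequence[OffTargetRecord],
    molecule: str = "RNA",
) -> SeedSeqRecord:
    """Build a SeedSeq record annotating a transcript with its off-targeting siRNAs.

    One ``target_siRNAs`` feature per distinct siRNA (deduplicated and
    ordered by sirna_id), located at its first supporting seed site, or
    spanning the full record for site-less (near-exact/partial alignment)
    evidence.  All records must reference the transcript's accession.
    """
    by_sirna: dict[str, OffTargetRecord] = {}
    for rec in records:
        if rec.transcript_accession != t.accession:
            raise ValueError(
                f"off-target record for {rec.transcript_accession} cannot annotate "
                f"transcript {t.accession}"
            )
        by_sirna.setdefault(rec.sirna_id, rec)

    features = []
    for sirna_id in sorted(by_sirna):
        rec = by_sirna[sirna_id]
        if rec.sites:
            site = rec.sites[0]
            location = (site.start + 1, site.end)
        else:
            location = (1, len(t.sequence))
        features.append(
            Feature(
                key="target_siRNAs",
                location=location,
                qualifiers=(
                    ("sirna_id", rec.sirna_id),
                    ("supplier", rec.supplier),
                    ("categories", ",".join(sorted(rec.categories))),
                    ("seed_occurrences", rec.seed_occurrences),
                ),
            )
        )
    definition = f"acc={t.accession}|len={len(t.sequence)}"
    if t.gene_symbol:
        definition = f"sym={t.gene_symbol}|" + definition
    return SeedSeqRecord(
        locus_name=t.accession,
        sequence=t.sequence,
        molecule=molecule,
        definition=definition,
        accession=t.accession,
        comment=DIALECT_COMMENT,
        features=tuple(features),
    )
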