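"""Seed-match site scanning and window extraction.

The first stage of the windowed search: every occurrence of an siRNA's
seed-match motif (the reverse complement of its seed region) is located in
each transcript, and a ~50-nt window around each occurrence is cut out for
local alignment.  Restricting alignment to these windows is what makes
Smith-Waterman affordable at transcriptome scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .seqcore import NucSeq, SiRNA, Transcript, seed_site_motif

__all__ = [
    "SeedSite",
    "ScanConfig",
    "ConfigurationError",
    "find_seed_sites",
    "find_seed_sites_with_mismatches",
    "count_seed_occurrences",
    "extract_window",
]

_WOBBLE_EQUIV = {"C": "U", "A": "G"}  # expected motif base -> wobble-tolerated mRNA base


class ConfigurationError(ValueError):
    """A scan/pipeline configuration is inconsistent with its inputs."""


@dataclass(frozen=True)
class SeedSite:
    """A seed-match occurrence on a transcript, 0-based half-open."""

    transcript_accession: str
    start: int
    end: int
    seed_len: int = 7
    in_utr3: bool = False
    conserved: Optional[bool] = None
    seed_mismatches: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad site interval [{self.start},{self.end})")
        if self.end - self.start != self.seed_len:
            raise ValueError("site interval length must equal seed_len")


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the seed scan.

    seed_len: 7 (m8 register, antisense 2-8) or 6 (antisense 2-7).
    window_width: total width of the alignment window cut around a site.
    region: 'whole_transcript' or 'utr3_only' (miRNA-like mode).
    allow_wobble_in_seed: tolerate G:U-wobble-equivalent substitutions
        inside the seed motif itself (off by default; wobble is normally
        honored only during alignment scoring).
    """

    seed_len: int = 7
    window_width: int = 50
    region: str = "whole_transcript"
    allow_wobble_in_seed: bool = False

    def __post_init__(self) -> None:
        if self.seed_len not in (6, 7):
            raise ValueError("seed_len must be 6 or 7")
        if self.window_width < self.seed_len:
            raise ValueError("window_width must be >= seed_len")
        if self.region not in ("whole_transcript", "utr3_only"):
            raise ValueError(f"unknown region {self.region!r}")


def _scan_motif(sirna: SiRNA, cfg: ScanConfig) -> str:
    """mRNA-side motif to scan for; the 6-mer keeps the motif's 3'-most
    6 residues (antisense positions 2-7)."""
    motif = str(seed_site_motif(sirna))
    if cfg.seed_len == 6:
        motif = motif[-6:]
    return motif


def _positions_match(motif: str, window: str, allow_wobble: bool) -> int:
    """Number of mismatching positions, with optional wobble tolerance."""
    mm = 0
    for e, o in zip(motif, window):
        if e == o:
            continue
        if allow_wobble and _WOBBLE_EQUIV.get(e) == o:
            continue
        mm += 1
    return mm


def find_seed_sites(t: Transcript, sirna: SiRNA, cfg: ScanConfig = ScanConfig()) -> list[SeedSite]:
    """All exact seed-motif occurrences of ``sirna`` in ``t``, sorted by start.

    Overlapping occurrences are all reported.  With ``region='utr3_only'``
    only sites starting at or after the transcript's 3'UTR offset are
    returned (a missing offset is a :class:`ConfigurationError`).
    """
    return find_seed_sites_with_mismatches(t, sirna, cfg, max_mismatches=0)


def find_seed_sites_with_mismatches(
    t: Transcript,
    sirna: SiRNA,
    cfg: ScanConfig = ScanConfig(),
    max_mismatches: int = 1,
) -> list[SeedSite]:
    """Seed-motif occurrences allowing up to ``max_mismatches`` substitutions.

    Used by the 3'-compensatory rule, which admits sites with exactly one
    seed mismatch.  Exact occurrences are reported with seed_mismatches=0.
    """
    motif = _scan_motif(sirna, cfg)
    seq = str(t.sequence)
    k = len(motif)
    if cfg.region == "utr3_only":
        if t.utr3_start is None:
            raise ConfigurationError(
                f"utr3_only scan requested but transcript {t.accession} has no utr3_start"
            )
        lo = t.utr3_start
    else:
        lo = 0
    sites = []
    for start in range(lo, len(seq) - k + 1):
        mm = _positions_match(motif, seq[start : start + k], cfg.allow_wobble_in_seed)
        if mm <= max_mismatches:
            sites.append(
                SeedSite(
                    transcript_accession=t.accession,
                    start=start,
                    end=start + k,
                    seed_len=k,
                    in_utr3=t.utr3_start is not None and start >= t.utr3_start,
                    seed_mismatches=mm,
                )
            )
    return sites


def count_seed_occurrences(t: Transcript, sirna: SiRNA, cfg: ScanConfig = ScanConfig()) -> int:
    """Seed complementation frequency: number of exact seed-match sites."""
    return len(find_seed_sites(t, sirna, cfg))


def extract_window(
    t: Transcript, site: SeedSite, cfg: ScanConfig = ScanConfig()
) -> tuple[tuple[int, int], NucSeq]:
    """Cut the alignment window around a seed site.

    The window has total width ``cfg.window_width`` centered on the site:
    left flank ``floor((width - seed_len) / 2)``, remainder on the right,
    clipped at transcript boundaries (clipped windows are shorter but always
    contain the full site).  Returns the 0-based half-open interval and the
    corresponding slice.
    """
    n = len(t.sequence)
    if not (0 <= site.start and site.end <= n):
        raise ValueError(
            f"site [{site.start},{site.end}) outside transcript {t.accession} of length {n}"
        )
    flank_total = cfg.window_width - site.seed_len
    left = flank_total // 2
    # flanks clip independently; a window near a transcript end is shorter
    start = max(0, site.start - left)
    end = min(n, site.end + (flank_total - left))
    return (start, end), NucSeq(t.sequence[start:end])
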