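"""Rule-based off-target classification.

Evidence from seed scanning and duplex alignment is turned into per-
(siRNA, transcript) off-target calls in three categories:

* ``near_exact`` — near-full complementarity: at least 17 of the 19 duplex
  core positions paired (~90% complementarity);
* ``partial`` — partial complementarity still competent to silence: a run
  of at least 11 contiguous paired positions, or at least 15 paired in
  total;
* ``mirna_like`` — a seed-match site (antisense positions 2-8 perfectly
  paired with the mRNA), or a site with exactly one seed mismatch rescued
  by perfect pairing of the siRNA 3' region (positions 13-19; the 3'
  compensatory rule), by default required to lie in the 3'UTR.

Cleavage competence is tracked separately: slicer-mediated cleavage needs
the center region (antisense positions 8-10, opposite the mRNA cleavage
site) fully paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .align import (
    CORE_LEN,
    GAP,
    DuplexAlignment,
    ScoringScheme,
    align_duplex,
    pair_bases,
)
from .seedscan import (
    ConfigurationError,
    ScanConfig,
    SeedSite,
    count_seed_occurrences,
    extract_window,
    find_seed_sites,
    find_seed_sites_with_mismatches,
)
from .seqcore import SiRNA, Transcript

__all__ = [
    "NEAR_EXACT",
    "PARTIAL",
    "MIRNA_LIKE",
    "ClassifierConfig",
    "OffTargetRecord",
    "classify_alignment",
    "classify_mirna_like",
    "cleavage_competent",
    "site_pairing",
    "call_offtargets",
    "records_to_frame",
]

NEAR_EXACT = "near_exact"
PARTIAL = "partial"
MIRNA_LIKE = "mirna_like"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and region definitions for off-target calling.

    ``compensatory_region`` is the siRNA 3' region of the compensatory
    rule.  The published rule numbers it 13-19 from the 3' end of the sense
    strand; on the fixed antisense 5'->3' numbering used throughout this
    package that maps onto antisense core positions 13-19, which is the
    default here and configurable.
    """

    near_exact_min_paired: int = 17
    partial_min_contiguous: int = 11
    partial_min_total: int = 15
    seed_region: tuple[int, int] = (2, 8)
    compensatory_region: tuple[int, int] = (13, 19)
    center_region: tuple[int, int] = (8, 10)
    require_utr3_for_mirna_like: bool = True

    def __post_init__(self) -> None:
        for v in (self.near_exact_min_paired, self.partial_min_contiguous, self.partial_min_total):
            if v <= 0:
                raise ValueError("classifier thresholds must be positive")
        for lo, hi in (self.seed_region, self.compensatory_region, self.center_region):
            if not 1 <= lo <= hi <= CORE_LEN:
                raise ValueError("classifier regions must lie within the duplex core 1-19")


@dataclass(frozen=True)
class OffTargetRecord:
    """One off-target call for a (siRNA, transcript) pair."""

    sirna_id: str
    transcript_accession: str
    gene_symbol: str = ""
    supplier: str = ""
    categories: frozenset[str] = frozenset()
    cleavage_competent: bool = False
    seed_occurrences: int = 0
    best_alignment: Optional[DuplexAlignment] = None
    sites: tuple[SeedSite, ...] = ()
    conserved_site_count: Optional[int] = None


def classify_alignment(aln: DuplexAlignment, cfg: ClassifierConfig = ClassifierConfig()) -> set[str]:
    """Complementarity categories supported by one duplex alignment.

    ``near_exact`` iff paired positions >= cfg.near_exact_min_paired;
    ``partial`` iff the longest contiguous run >= cfg.partial_min_contiguous
    or total paired >= cfg.partial_min_total.  The categories may co-occur
    and the empty set is a valid outcome.
    """
    cats = set()
    if aln.paired_positions >= cfg.near_exact_min_paired:
        cats.add(NEAR_EXACT)
    if (
        aln.longest_contiguous_run >= cfg.partial_min_contiguous
        or aln.paired_positions >= cfg.partial_min_total
    ):
        cats.add(PARTIAL)
    return cats


def site_pairing(
    sirna: SiRNA,
    t: Transcript,
    site: SeedSite,
    s: ScoringScheme = ScoringScheme(),
) -> dict[int, str]:
    """Gapless duplex pairing anchored at a seed site.

    With the seed site's m8 end fixed, antisense position ``p`` (1-based)
    faces transcript position ``site.start + m8 - p`` where ``m8`` is the
    seed's 3' bound (8 for the 7-mer register, 7 for the 6-mer).  Positions
    falling outside the transcript are unpaired ('-').
    """
    m8 = site.seed_len + 1
    status: dict[int, str] = {}
    for p in range(1, CORE_LEN + 1):
        tpos = site.start + m8 - p
        if 0 <= tpos < len(t.sequence):
            status[p] = pair_bases(sirna.antisense[p - 1], t.sequence[tpos], s)
        else:
            status[p] = GAP
    return status


def _region_all_paired(
    status: dict[int, str], region: tuple[int, int], s: ScoringScheme
) -> bool:
    return all(s.counts_paired(status[p]) for p in range(region[0], region[1] + 1))


def _region_mismatches(
    status: dict[int, str], region: tuple[int, int], s: ScoringScheme
) -> int:
    return sum(1 for p in range(region[0], region[1] + 1) if not s.counts_paired(status[p]))


def classify_mirna_like(
    sirna: SiRNA,
    t: Transcript,
    site: SeedSite,
    cfg: ClassifierConfig = ClassifierConfig(),
    s: ScoringScheme = ScoringScheme(),
) -> bool:
    """Does a seed site support a miRNA-like off-target call?

    True iff the seed region is perfectly paired at the site, or the seed
    has exactly one mismatch and the 3' compensatory region is perfectly
    paired.  Wobbles count as paired when the scoring scheme says so.  With
    ``require_utr3_for_mirna_like`` the site must lie in the 3'UTR (a
    transcript without a known 3'UTR offset is a configuration error).
    """
    if cfg.require_utr3_for_mirna_like:
        if t.utr3_start is None:
            raise ConfigurationError(
                f"miRNA-like call requires utr3_start on transcript {t.accession}"
            )
        if not site.in_utr3:
            return False
    status = site_pairing(sirna, t, site, s)
    seed_mm = _region_mismatches(status, cfg.seed_region, s)
    if seed_mm == 0:
        return True
    return seed_mm == 1 and _region_all_paired(status, cfg.compensatory_region, s)


def cleavage_competent(
    aln: DuplexAlignment,
    cfg: ClassifierConfig = ClassifierConfig(),
    s: ScoringScheme = ScoringScheme(),
) -> bool:
    """True iff the center region (antisense 8-10) is fully paired.

    Mismatches opposite the cleavage site abolish slicer cleavage; wobbles
    count as paired under ``wobble_as_match``.
    """
    if aln.core_status is None:
        raise ValueError("cleavage competence needs a duplex alignment with core_status")
    return _region_all_paired(aln.core_status, cfg.center_region, s)


def _status_cleavage(status: dict[int, str], cfg: ClassifierConfig, s: ScoringScheme) -> bool:
    return _region_all_paired(status, cfg.center_region, s)


def call_offtargets(
    sirna: SiRNA,
    transcriptome: Sequence[Transcript],
    mode: str = "mirna_like",
    scan_cfg: ScanConfig = ScanConfig(),
    scheme: ScoringScheme = ScoringScheme(),
    cls_cfg: ClassifierConfig = ClassifierConfig(),
) -> list[OffTargetRecord]:
    """Off-target calls of one siRNA over a transcriptome.

    Transcripts of the siRNA's own on-target gene are excluded.  Three
    search variants:

    * ``full_sw`` — duplex Smith-Waterman against each whole transcript;
    * ``seed_window_sw`` — duplex Smith-Waterman restricted to ~50-nt
      windows around exact seed-match sites;
    * ``mirna_like`` — seed sites (up to one seed mismatch) evaluated by
      the perfect-seed / 3'-compensatory rules, in the 3'UTR by default.

    Only records with a nonempty category set are emitted, ordered by
    transcript accession.
    """
    if mode not in ("full_sw", "seed_window_sw", "mirna_like"):
        raise ConfigurationError(f"unknown search mode {mode!r}")
    records = []
    for t in sorted(transcriptome, key=lambda t: t.accession):
        if sirna.on_target_gene and t.gene_symbol == sirna.on_target_gene:
            continue
        rec = _call_one(sirna, t, mode, scan_cfg, scheme, cls_cfg)
        if rec is not None:
            records.append(rec)
    return records


def _call_one(
    sirna: SiRNA,
    t: Transcript,
    mode: str,
    scan_cfg: ScanConfig,
    scheme: ScoringScheme,
    cls_cfg: ClassifierConfig,
) -> Optional[OffTargetRecord]:
    categories: set[str] = set()
    best: Optional[DuplexAlignment] = None
    support: list[SeedSite] = []
    cleaves = False

    if mode == "full_sw":
        best = align_duplex(sirna, t.sequence, scheme)
        categories = classify_alignment(best, cls_cfg)
        cleaves = cleavage_competent(best, cls_cfg, scheme)
    elif mode == "seed_window_sw":
        for site in find_seed_sites(t, sirna, scan_cfg):
            _, window = extract_window(t, site, scan_cfg)
            aln = align_duplex(sirna, window, scheme)
            if best is None or aln.score > best.score:
                best = aln
        if best is not None:
            categories = classify_alignment(best, cls_cfg)
            cleaves = cleavage_competent(best, cls_cfg, scheme)
    else:  # mirna_like
        region_cfg = scan_cfg
        if cls_cfg.require_utr3_for_mirna_like and scan_cfg.region != "utr3_only":
            region_cfg = replace(scan_cfg, region="utr3_only")
        for site in find_seed_sites_with_mismatches(t, sirna, region_cfg, max_mismatches=1):
            if classify_mirna_like(sirna, t, site, cls_cfg, scheme):
                support.append(site)
        if support:
            categories = {MIRNA_LIKE}
            # window alignment at the first supporting site as alignment evidence
            _, window = extract_window(t, support[0], region_cfg)
            best = align_duplex(sirna, window, scheme)
            cleaves = _status_cleavage(site_pairing(sirna, t, support[0], scheme), cls_cfg, scheme)

    if not categories:
        return None
    return OffTargetRecord(
        sirna_id=sirna.sirna_id,
        transcript_accession=t.accession,
        gene_symbol=t.gene_symbol,
        supplier=sirna.supplier,
        categories=frozenset(categories),
        cleavage_competent=cleaves,
        seed_occurrences=count_seed_occurrences(t, sirna, scan_cfg),
        best_alignment=best,
        sites=tuple(support),
    )


def records_to_frame(records: Sequence[OffTargetRecord]):
    """Flatten off-target records into a pandas DataFrame for export."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "sirna_id": r.sirna_id,
                "accession": r.transcript_accession,
                "gene": r.gene_symbol,
                "categories": ",".join(sorted(r.categories)),
                "seed_occurrences": r.seed_occurrences,
                "paired_positions": r.best_alignment.paired_positions if r.best_alignment else 0,
                "contiguous_run": r.best_alignment.longest_contiguous_run if r.best_alignment else 0,
                "cleavage_competent": r.cleavage_competent,
                "conserved_site_count": (
                    r.conserved_site_count if r.conserved_site_count is not None else ""
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sirna_id",
            "accession",
            "gene",
            "categories",
            "seed_occurrences",
            "paired_positions",
            "contiguous_run",
            "cleavage_competent",
            "conserved_site_count",
        ],
    )
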