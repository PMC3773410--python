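"""Deterministic synthetic data: transcriptomes with planted off-target
sites, siRNA libraries, conservation tracks and expression tables.

The generator exists so every pipeline stage can be tested closed-loop
without downloads: each planted site class is constructed to trigger
exactly one classification rule, the random background is rejection-
sampled so that no unplanted site of any library siRNA exists (the
manifest is exhaustive ground truth), and every generator draws from its
own seeded RNG stream so adding one generator never shifts another's
output.

Planted site classes
--------------------
``m8_seed``              exact 7-mer seed-match site in the 3'UTR
``compensatory``         19-nt site, one seed mismatch, perfect 13-19 pairing (3'UTR)
``decoy_nonconserved``   exact seed site in the 3'UTR, outside conservation
``near_exact``           perfect 19-nt complementary region (CDS)
``partial_contiguous11`` 11 contiguous paired positions (antisense 5-15, CDS)
``partial_total15``      15 of 19 paired, mismatches at positions 3/8/13/18,
                         longest run 4 (CDS)

RNG streams (children of ``rng_seed``): 0 library, 1 transcriptome,
2 conservation, 3 expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .seqcore import NucSeq, SiRNA, Transcript
from .seedscan import ScanConfig, find_seed_sites, find_seed_sites_with_mismatches
from .classify import ClassifierConfig, classify_mirna_like
from .align import ScoringScheme

__all__ = [
    "FixtureSpec",
    "PlantedSite",
    "generate_library",
    "generate_transcriptome",
    "generate_conservation",
    "generate_expression",
    "write_fixture_files",
    "manifest_frame",
]

_BASES = np.array(list("ACGU"))

UTR3_CLASSES = ("m8_seed", "compensatory", "decoy_nonconserved")
CDS_CLASSES = ("near_exact", "partial_contiguous11", "partial_total15")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Transcript lengths and counts are sized for desk-scale runs; planted
    counts give each rule a handful of positive examples.  ``tp_rate`` is
    the per-prediction probability that a predicted off-target shows a
    significant negative expression change (the published validation is in
    the two-thirds range, hence 0.65).
    """

    rng_seed: int = 0
    n_transcripts: int = 24
    length_range: tuple[int, int] = (400, 700)
    utr3_fraction: float = 0.4
    planted: tuple[tuple[str, int], ...] = (
        ("m8_seed", 5),
        ("compensatory", 3),
        ("decoy_nonconserved", 3),
        ("near_exact", 3),
        ("partial_contiguous11", 3),
        ("partial_total15", 3),
    )
    library_size: int = 4
    tp_rate: float = 0.65
    conservation_coverage: float = 0.3
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if any(n < 0 for _, n in self.planted):
            raise ValueError("planted counts must be >= 0")
        for frac in (self.utr3_fraction, self.tp_rate, self.conservation_coverage):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        bad = {c for c, _ in self.planted} - set(UTR3_CLASSES) - set(CDS_CLASSES)
        if bad:
            raise ValueError(f"unknown planted classes: {sorted(bad)}")


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth manifest entry for one planted construct.

    ``start``/``end`` bound the written construct; ``seed_start``/
    ``seed_end`` bound the exact seed-match 7-mer it embeds, when it
    embeds one.
    """

    cls: str
    sirna_id: str
    accession: str
    start: int
    end: int
    seed_start: Optional[int] = None
    seed_end: Optional[int] = None


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.rng_seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_library(spec: FixtureSpec) -> list[SiRNA]:
    """Random 21-nt siRNA library with pairwise-distinct seed regions."""
    rng = _rng(spec, 0)
    seen_seeds: set[str] = set()
    lib: list[SiRNA] = []
    while len(lib) < spec.library_size:
        anti = _random_seq(rng, 21)
        if anti[1:8] in seen_seeds:
            continue
        seen_seeds.add(anti[1:8])
        i = len(lib) + 1
        lib.append(
            SiRNA(
                sirna_id=f"syn{i:03d}",
                antisense=NucSeq(anti),
                on_target_gene=f"GENE{i:03d}",
                supplier="synthetic",
            )
        )
    return lib


def _construct(sirna: SiRNA, cls: str) -> tuple[str, Optional[int]]:
    """Planted construct sequence and the offset of its exact seed 7-mer.

    Constructs are written 5'->3' in mRNA orientation; expected-site index
    ``i`` pairs with antisense position ``19 - i``, so the seed-match
    7-mer (antisense 2-8) occupies expected-site indices 11-17.
    """
    site = str(sirna.expected_target_site())  # 19 nt, perfect complement

    def mutate(s: str, site_idx: int) -> str:
        # replace with the antisense base itself: never Watson-Crick, never wobble
        p = 19 - site_idx  # antisense position
        return s[:site_idx] + str(sirna.antisense[p - 1]) + s[site_idx + 1 :]

    if cls in ("m8_seed", "decoy_nonconserved"):
        return site[11:18], 0
    if cls == "near_exact":
        return site, 11
    if cls == "compensatory":
        # one seed mismatch (antisense position 5 -> site index 14), 13-19 intact
        return mutate(site, 14), None
    if cls == "partial_contiguous11":
        return site[4:15], None  # antisense 5-15 paired, no full seed
    if cls == "partial_total15":
        s = site
        for p in (3, 8, 13, 18):  # antisense positions; runs of <= 4
            s = mutate(s, 19 - p)
        return s, None
    raise ValueError(f"unknown planted class {cls!r}")


def _background_clean(t: Transcript, library: Sequence[SiRNA]) -> bool:
    """No exact seed motif anywhere, and no 3'UTR window the miRNA-like
    rule would call (wobble-rescued seeds and compensatory rescues occur in
    random background at a rate that makes post-hoc masking unreliable, so
    they are rejected at draw time)."""
    whole = ScanConfig()
    utr = ScanConfig(region="utr3_only")
    for s in library:
        if find_seed_sites(t, s, whole):
            return False
        for site in find_seed_sites_with_mismatches(t, s, utr, max_mismatches=1):
            if classify_mirna_like(s, t, site):
                return False
    return True


def _scan_clean(
    transcripts: Sequence[Transcript],
    library: Sequence[SiRNA],
    manifest: Sequence[PlantedSite],
) -> bool:
    """True iff detectors see exactly the planted sites and nothing else."""
    whole = ScanConfig(region="whole_transcript")
    cls_cfg = ClassifierConfig()
    scheme = ScoringScheme()
    expected_exact = {
        (m.sirna_id, m.accession, m.seed_start)
        for m in manifest
        if m.seed_start is not None
    }
    for sirna in library:
        for t in transcripts:
            found = {
                (sirna.sirna_id, t.accession, s.start)
                for s in find_seed_sites(t, sirna, whole)
            }
            want = {e for e in expected_exact if e[0] == sirna.sirna_id and e[1] == t.accession}
            if found != want:
                return False
            # miRNA-like rule over the 3'UTR must fire only at planted sites
            utr = ScanConfig(region="utr3_only")
            hits = {
                s.start
                for s in find_seed_sites_with_mismatches(t, sirna, utr, max_mismatches=1)
                if classify_mirna_like(sirna, t, s, cls_cfg, scheme)
            }
            want_m = set()
            for m in manifest:
                if m.sirna_id != sirna.sirna_id or m.accession != t.accession:
                    continue
                if m.cls in ("m8_seed", "decoy_nonconserved"):
                    want_m.add(m.seed_start)
                elif m.cls == "compensatory":
                    want_m.add(m.start + 11)  # seed 7-mer offset within the 19-mer
            if hits != want_m:
                return False
    return True


def generate_transcriptome(
    spec: FixtureSpec, library: Optional[Sequence[SiRNA]] = None
) -> tuple[list[Transcript], list[PlantedSite]]:
    """Random-background transcriptome with planted sites and its manifest.

    Background transcripts are rejection-sampled so no unplanted exact
    seed motif of any library siRNA occurs, and the finished transcriptome
    is verified detector-clean (exact scan and miRNA-like rule recover the
    manifest and nothing else); on a junction artifact the build is
    redrawn.  Fully deterministic for a fixed spec.
    """
    if library is None:
        library = generate_library(spec)
    rng = _rng(spec, 1)
    min_len, max_len = spec.length_range
    if min_len < 30:
        raise ValueError("transcripts must be at least 30 nt for planting")

    for _attempt in range(60):
        transcripts: list[Transcript] = []
        for i in range(spec.n_transcripts):
            length = int(rng.integers(min_len, max_len + 1))
            for _ in range(200):
                t = Transcript(
                    accession=f"NM_{900000 + i}",
                    sequence=NucSeq(_random_seq(rng, length)),
                    gene_symbol=f"BG{i:03d}",
                    utr3_start=int(length * (1 - spec.utr3_fraction)),
                )
                if _background_clean(t, library):
                    break
            else:  # pragma: no cover - clean draws have probability ~0.5 each
                raise RuntimeError("could not draw a detector-clean background")
            transcripts.append(t)

        seqs = {t.accession: list(str(t.sequence)) for t in transcripts}
        occupied: dict[str, list[tuple[int, int]]] = {t.accession: [] for t in transcripts}
        manifest: list[PlantedSite] = []
        ok = True
        for cls, count in spec.planted:
            for _ in range(count):
                sirna = library[int(rng.integers(len(library)))]
                construct, seed_off = _construct(sirna, cls)
                placed = False
                for _try in range(200):
                    t = transcripts[int(rng.integers(len(transcripts)))]
                    L = len(t.sequence)
                    if cls in UTR3_CLASSES:
                        lo = t.utr3_start
                        if cls == "compensatory":
                            # the 19-mer's seed 7-mer sits at offset 11; only
                            # that part must lie inside the UTR
                            lo = max(t.utr3_start - 11, 0)
                        hi = L - len(construct)
                    else:
                        lo, hi = 0, t.utr3_start - len(construct)
                    if hi <= lo:
                        continue
                    start = int(rng.integers(lo, hi))
                    if cls == "compensatory" and start + 11 < t.utr3_start:
                        continue
                    end = start + len(construct)
                    # 8-nt margin keeps junction k-mers from abutting constructs
                    if any(s - 8 < end and start < e + 8 for s, e in occupied[t.accession]):
                        continue
                    seqs[t.accession][start:end] = list(construct)
                    occupied[t.accession].append((start, end))
                    manifest.append(
                        PlantedSite(
                            cls=cls,
                            sirna_id=sirna.sirna_id,
                            accession=t.accession,
                            start=start,
                            end=end,
                            seed_start=start + seed_off if seed_off is not None else None,
                            seed_end=start + seed_off + 7 if seed_off is not None else None,
                        )
                    )
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue

        final = [
            Transcript(
                accession=t.accession,
                sequence=NucSeq("".join(seqs[t.accession])),
                gene_symbol=t.gene_symbol,
                utr3_start=t.utr3_start,
            )
            for t in transcripts
        ]
        if _scan_clean(final, library, manifest):
            return final, manifest
    raise RuntimeError("could not build a detector-clean transcriptome in 60 attempts")


def generate_conservation(
    spec: FixtureSpec,
    transcripts: Sequence[Transcript],
    manifest: Sequence[PlantedSite],
) -> pd.DataFrame:
    """Conservation track (accession, start, end) in transcript coordinates.

    Every planted miRNA-like site except the ``decoy_nonconserved`` class
    is wrapped in a conserved interval; random background intervals cover
    roughly ``conservation_coverage`` of each transcript but never contain
    a decoy site.
    """
    rng = _rng(spec, 2)
    decoys = [
        (m.accession, m.seed_start, m.seed_end)
        for m in manifest
        if m.cls == "decoy_nonconserved"
    ]
    rows: list[tuple[str, int, int]] = []
    for m in manifest:
        if m.cls == "m8_seed":
            rows.append((m.accession, max(0, m.seed_start - 2), m.seed_end + 2))
        elif m.cls == "compensatory":
            # seed 7-mer sits at construct offset 11
            rows.append((m.accession, max(0, m.start + 9), m.end + 1))
    for t in transcripts:
        L = len(t.sequence)
        target = spec.conservation_coverage * L
        covered = 0.0
        for _ in range(50):
            if covered >= target:
                break
            length = int(rng.integers(10, 40))
            start = int(rng.integers(0, max(1, L - length)))
            end = min(L, start + length)
            if any(
                acc == t.accession and start <= ds and de <= end for acc, ds, de in decoys
            ):
                continue
            rows.append((t.accession, start, end))
            covered += length
    df = pd.DataFrame(rows, columns=["accession", "start", "end"])
    return df.sort_values(["accession", "start"], kind="stable").reset_index(drop=True)


def generate_expression(
    spec: FixtureSpec,
    predictions: Iterable[str],
    all_accessions: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Expression-change table with a planted per-prediction truth rate.

    Each predicted accession is a true off-target (negative log-ratio,
    p < alpha) with probability ``tp_rate``; all other rows are null draws
    (p uniform, log-ratio symmetric) that are nudged positive when their p
    falls below alpha, so the planted rate is exactly binomial.
    """
    rng = _rng(spec, 3)
    predicted = sorted(set(predictions))
    others = sorted(set(all_accessions or []) - set(predicted))
    rows = []
    for acc in predicted:
        if rng.random() < spec.tp_rate:
            rows.append((acc, -abs(rng.normal(1.0, 0.3)), spec.alpha * rng.random()))
        else:
            lr = rng.normal(0.0, 0.5)
            p = rng.random()
            if p < spec.alpha:
                lr = abs(lr)
            rows.append((acc, lr, p))
    for acc in others:
        lr = rng.normal(0.0, 0.5)
        p = rng.random()
        if p < spec.alpha:
            lr = abs(lr)
        rows.append((acc, lr, p))
    return pd.DataFrame(rows, columns=["accession", "log_ratio", "p_value"])


def manifest_frame(manifest: Sequence[PlantedSite]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in manifest])


def write_fixture_files(
    spec: FixtureSpec, outdir: str | Path
) -> dict[str, Path]:
    """Materialize one synthetic dataset in the formats the pipeline reads.

    Writes transcriptome FASTA, siRNA library TSV, conservation BED,
    manifest TSV and (for the planted miRNA-like off-target accessions) an
    expression TSV per library siRNA.  Returns the path of each artifact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = generate_library(spec)
    transcripts, manifest = generate_transcriptome(spec, library)
    conservation = generate_conservation(spec, transcripts, manifest)

    fasta = outdir / "transcriptome.fasta"
    with fasta.open("w") as fh:
        for t in transcripts:
            fh.write(f">{t.accession} gene={t.gene_symbol} utr3_start={t.utr3_start}\n")
            s = str(t.sequence)
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")

    lib_path = outdir / "library.tsv"
    pd.DataFrame(
        [
            {"sirna_id": s.sirna_id, "gene": s.on_target_gene, "antisense": str(s.antisense),
             "supplier": s.supplier}
            for s in library
        ]
    ).to_csv(lib_path, sep="\t", index=False)

    bed_path = outdir / "conserved.bed"
    conservation.to_csv(bed_path, sep="\t", index=False, header=False)

    man_path = outdir / "manifest.tsv"
    manifest_frame(manifest).to_csv(man_path, sep="\t", index=False)

    expr_paths = {}
    accs = [t.accession for t in transcripts]
    for s in library:
        planted = [m.accession for m in manifest if m.sirna_id == s.sirna_id]
        expr = generate_expression(spec, planted, all_accessions=accs)
        p = outdir / f"expression_{s.sirna_id}.tsv"
        expr.to_csv(p, sep="\t", index=False)
        expr_paths[s.sirna_id] = p

    return {"fasta": fasta, "library": lib_path, "conserved": bed_path,
            "manifest": man_path, **{f"expression_{k}": v for k, v in expr_paths.items()}}
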