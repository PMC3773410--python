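"""End-to-end orchestration: scan -> align -> classify -> filter -> annotate.

Three search variants are exposed, mirroring how the cost of local
alignment is traded against sensitivity:

* ``full_sw``       — duplex Smith-Waterman against every whole transcript;
                      refused above ``max_full_sw_targets`` transcripts
                      (default 200) unless explicitly overridden, since
                      whole-transcriptome local alignment is impractical;
* ``seed_window_sw`` — alignment restricted to ~50-nt windows around exact
                      seed-match sites;
* ``mirna_like``    — seed sites judged by the perfect-seed/3'-compensatory
                      rules, optionally restricted to conserved sites.

The variant is always a user choice; prediction itself is deterministic
for fixed inputs and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .align import ScoringScheme
from .classify import (
    ClassifierConfig,
    OffTargetRecord,
    call_offtargets,
    records_to_frame,
)
from .conserve import ConservedIntervalSet, filter_conserved
from .seedscan import ConfigurationError, ScanConfig
from .seedseq_io import annotate_transcript, write_record
from .seqcore import SiRNA, Transcript
from .validate import ExpressionTable, ValidationConfig, validation_report

__all__ = ["PipelineConfig", "PipelineResult", "run"]

MODES = ("full_sw", "seed_window_sw", "mirna_like")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs besides its inputs."""

    mode: str = "mirna_like"
    max_full_sw_targets: int = 200
    allow_large_full_sw: bool = False
    use_conservation: bool = False
    emit_all: bool = False
    scan: ScanConfig = field(default_factory=ScanConfig)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; choose from {MODES}")


@dataclass
class PipelineResult:
    """Outputs of one run; every call is traceable through ``table``."""

    records: list[OffTargetRecord]
    table: pd.DataFrame
    seedseq_text: str
    report: Optional[pd.DataFrame] = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["offtargets"] = outdir / "offtargets.tsv"
        self.table.to_csv(paths["offtargets"], sep="\t", index=False)
        paths["seedseq"] = outdir / "offtargets.seedseq"
        paths["seedseq"].write_text(self.seedseq_text)
        if self.report is not None:
            paths["validation"] = outdir / "validation.tsv"
            self.report.to_csv(paths["validation"], sep="\t", index=False)
        return paths


def run(
    config: PipelineConfig,
    transcriptome: Sequence[Transcript],
    library: Sequence[SiRNA],
    conserved: Optional[ConservedIntervalSet] = None,
    expression: Optional[Mapping[str, ExpressionTable]] = None,
) -> PipelineResult:
    """Predict off-targets for a library, annotate and optionally validate.

    Returns deterministic outputs for fixed inputs/config: records sorted
    by (sirna_id, accession), one SeedSeq record per transcript with at
    least one call (all transcripts under ``emit_all``), and a validation
    report when expression tables are supplied.  Filtering steps only ever
    shrink the record list.
    """
    if config.mode == "full_sw" and len(transcriptome) > config.max_full_sw_targets:
        if not config.allow_large_full_sw:
            raise ConfigurationError(
                f"full_sw refused for {len(transcriptome)} transcripts "
                f"(> max_full_sw_targets={config.max_full_sw_targets}); "
                "use seed_window_sw/mirna_like or set allow_large_full_sw"
            )
    if config.use_conservation and conserved is None:
        raise ConfigurationError("use_conservation requires a conserved-interval set")

    records: list[OffTargetRecord] = []
    for sirna in sorted(library, key=lambda s: s.sirna_id):
        records.extend(
            call_offtargets(
                sirna,
                transcriptome,
                mode=config.mode,
                scan_cfg=config.scan,
                scheme=config.scheme,
                cls_cfg=config.classifier,
            )
        )
    records.sort(key=lambda r: (r.sirna_id, r.transcript_accession))

    if config.use_conservation and conserved is not None:
        records = filter_conserved(records, conserved)

    table = records_to_frame(records)

    by_transcript: dict[str, list[OffTargetRecord]] = {}
    for r in records:
        by_transcript.setdefault(r.transcript_accession, []).append(r)
    chunks = []
    for t in sorted(transcriptome, key=lambda t: t.accession):
        recs = by_transcript.get(t.accession, [])
        if recs or config.emit_all:
            chunks.append(write_record(annotate_transcript(t, recs)))
    seedseq_text = "".join(chunks)

    report = None
    if expression is not None:
        predictions = {
            sid: {r.transcript_accession for r in records if r.sirna_id == sid}
            for sid in sorted({s.sirna_id for s in library})
        }
        report = validation_report(predictions, expression, config.validation)

    return PipelineResult(records=records, table=table, seedseq_text=seedseq_text, report=report)
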