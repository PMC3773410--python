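"""Validation of off-target predictions against expression-change data.

After transfecting an siRNA, transcripts showing a significant negative
expression change relative to mock control (log-ratio < 0, p < alpha,
default alpha 0.01, raw threshold — no multiple-testing correction) are
taken as the experimentally supported ("true") off-targets.  Predictions
are then scored as true/false positives against that set; the headline
statistic is the pooled true-positive rate over all predictions across
siRNAs (per-siRNA rates and a mean-of-rates view are reported alongside,
since pooling choices genuinely change the number).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ExpressionTable",
    "ValidationConfig",
    "true_offtargets",
    "tp_fp",
    "validation_report",
    "read_expression_table",
]


@dataclass(frozen=True)
class ValidationConfig:
    """Truth definition: negative log-ratio with p below ``alpha``."""

    alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly between 0 and 1")


class ExpressionTable:
    """Per-transcript expression change after siRNA transfection.

    Wraps a DataFrame with columns (accession, log_ratio, p_value); one row
    per accession (duplicates rejected), p-values in [0, 1].
    """

    REQUIRED = ("accession", "log_ratio", "p_value")

    def __init__(self, df: pd.DataFrame, timepoint_label: str = "24h") -> None:
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"expression table missing column(s): {sorted(missing)}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        if df["accession"].duplicated().any():
            dups = df.loc[df["accession"].duplicated(), "accession"].tolist()
            raise ValueError(f"duplicate accession(s) in expression table: {dups[:5]}")
        if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
            raise ValueError("p_value outside [0, 1]")
        self.df = df.reset_index(drop=True)
        self.timepoint_label = timepoint_label

    def __len__(self) -> int:
        return len(self.df)


def read_expression_table(
    path: str | Path,
    sep: str = "\t",
    timepoint_label: str = "24h",
    column_map: Optional[Mapping[str, str]] = None,
) -> ExpressionTable:
    """Read a delimited expression table.

    ``column_map`` maps source column names onto the required (accession,
    log_ratio, p_value) vocabulary, so arbitrarily labelled tables can be
    ingested without editing the file.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return ExpressionTable(df, timepoint_label=timepoint_label)


def true_offtargets(tab: ExpressionTable, cfg: ValidationConfig = ValidationConfig()) -> set[str]:
    """Accessions significantly down-regulated: log_ratio < 0 and p < alpha."""
    df = tab.df
    mask = (df["log_ratio"] < 0) & (df["p_value"] < cfg.alpha)
    return set(df.loc[mask, "accession"])


def tp_fp(predicted: set[str], truth: set[str]) -> tuple[int, int, float]:
    """True/false positive counts and rate of a prediction set.

    tp = |predicted & truth|, fp = |predicted - truth|,
    tp_rate = tp / |predicted| (0.0 for an empty prediction set).
    """
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    fp = len(predicted) - tp
    rate = tp / len(predicted) if predicted else 0.0
    return tp, fp, rate


def validation_report(
    predictions: Mapping[str, set[str]],
    tables: Mapping[str, ExpressionTable],
    cfg: ValidationConfig = ValidationConfig(),
    conserved_predictions: Optional[Mapping[str, set[str]]] = None,
) -> pd.DataFrame:
    """Per-siRNA and pooled true-positive summary.

    One row per siRNA plus a ``pooled`` row (counts summed over siRNAs,
    the primary rate) and a ``mean_of_rates`` row (unweighted mean of
    per-siRNA rates, for comparison).  When ``conserved_predictions`` is
    given, with-conservation columns are filled from it; an siRNA with
    predictions but no expression table is flagged in the ``status``
    column rather than silently dropped.
    """
    rows = []
    pooled = {"tp": 0, "fp": 0, "tp_c": 0, "fp_c": 0}
    rates, rates_c = [], []
    for sid in sorted(predictions):
        pred = predictions[sid]
        row: dict = {"sirna_id": sid, "n_predicted": len(pred)}
        if sid not in tables:
            row.update(status="missing_expression_table", tp=0, fp=0, tp_rate=float("nan"))
            rows.append(row)
            continue
        truth = true_offtargets(tables[sid], cfg)
        tp, fp, rate = tp_fp(pred, truth)
        row.update(status="ok", tp=tp, fp=fp, tp_rate=rate)
        pooled["tp"] += tp
        pooled["fp"] += fp
        rates.append(rate)
        if conserved_predictions is not None:
            tp_c, fp_c, rate_c = tp_fp(conserved_predictions.get(sid, set()), truth)
            row.update(tp_conserved=tp_c, fp_conserved=fp_c, tp_rate_conserved=rate_c)
            pooled["tp_c"] += tp_c
            pooled["fp_c"] += fp_c
            rates_c.append(rate_c)
        rows.append(row)

    n_pooled = pooled["tp"] + pooled["fp"]
    summary = {
        "sirna_id": "pooled",
        "n_predicted": n_pooled,
        "status": "ok",
        "tp": pooled["tp"],
        "fp": pooled["fp"],
        "tp_rate": pooled["tp"] / n_pooled if n_pooled else 0.0,
    }
    mean_row = {
        "sirna_id": "mean_of_rates",
        "n_predicted": n_pooled,
        "status": "ok",
        "tp": pooled["tp"],
        "fp": pooled["fp"],
        "tp_rate": sum(rates) / len(rates) if rates else 0.0,
    }
    if conserved_predictions is not None:
        n_c = pooled["tp_c"] + pooled["fp_c"]
        summary.update(
            tp_conserved=pooled["tp_c"],
            fp_conserved=pooled["fp_c"],
            tp_rate_conserved=pooled["tp_c"] / n_c if n_c else 0.0,
        )
        mean_row.update(
            tp_conserved=pooled["tp_c"],
            fp_conserved=pooled["fp_c"],
            tp_rate_conserved=sum(rates_c) / len(rates_c) if rates_c else 0.0,
        )
    rows.extend([summary, mean_row])
    return pd.DataFrame(rows)
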