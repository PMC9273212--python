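"""Per-sample quality gating for cfRNA sequencing libraries.

A plasma cfRNA library passes quality control only if all of the following
hold (strict inequalities): more than 10 million raw reads; more than 5
million clean reads after trimming; more than 0.5 million deduplicated reads
aligned to the human genome and circRNA junctions; spike-in fraction and rRNA
fraction of the clean reads each below 0.5; mRNA+lncRNA ratio of the aligned
reads above 0.2; unclassified-read ratio below 0.3; and more than 100,000
intron-spanning read pairs.  The decision is per sample and independent of
the rest of the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import pandas as pd


class QCValidationError(ValueError):
    """A QC metric is missing or malformed; the offending field is named."""


@dataclass(frozen=True)
class SampleQCMetrics:
    raw_reads: int
    clean_reads: int
    dedup_aligned_reads: int
    spikein_fraction: float
    rrna_fraction: float
    mrna_lncrna_ratio: float
    unclassified_ratio: float
    intron_spanning_pairs: int


@dataclass(frozen=True)
class QCDecision:
    passed: bool
    failed_rules: tuple[str, ...]


# rule id -> (metric, threshold, direction); pass requires metric OP threshold
# with OP strict ">" for "gt" and strict "<" for "lt"
QC_RULES: dict[str, tuple[str, float, str]] = {
    "r1": ("raw_reads", 10_000_000, "gt"),
    "r2": ("clean_reads", 5_000_000, "gt"),
    "r3": ("dedup_aligned_reads", 500_000, "gt"),
    "r4_spikein": ("spikein_fraction", 0.5, "lt"),
    "r4_rrna": ("rrna_fraction", 0.5, "lt"),
    "r5_mrna_lncrna": ("mrna_lncrna_ratio", 0.2, "gt"),
    "r5_unclassified": ("unclassified_ratio", 0.3, "lt"),
    "r5_introns": ("intron_spanning_pairs", 100_000, "gt"),
}

_FRACTION_FIELDS = ("spikein_fraction", "rrna_fraction",
                    "mrna_lncrna_ratio", "unclassified_ratio")


def _validate(metrics: SampleQCMetrics) -> None:
    for f in fields(SampleQCMetrics):
        value = getattr(metrics, f.name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise QCValidationError(f"QC metric {f.name!r} is missing")
        if value < 0:
            raise QCValidationError(f"QC metric {f.name!r} is negative: {value}")
        if f.name in _FRACTION_FIELDS and value > 1:
            raise QCValidationError(
                f"QC metric {f.name!r} must be in [0, 1], got {value}"
            )


def apply_qc(metrics: SampleQCMetrics) -> QCDecision:
    """Evaluate all eight QC rules; the sample passes iff none is violated.

    Every rule is always evaluated and every violation reported — the rules
    are independent thresholds, so application order cannot change the
    decision.
    """
    _validate(metrics)
    failed = []
    for rule_id, (metric, threshold, direction) in QC_RULES.items():
        value = getattr(metrics, metric)
        ok = value > threshold if direction == "gt" else value < threshold
        if not ok:
            failed.append(rule_id)
    return QCDecision(passed=not failed, failed_rules=tuple(failed))


def apply_qc_table(sample_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the QC gate to every row of a sample table.

    The table must contain one column per metric of
    :class:`SampleQCMetrics`; missing columns raise
    :class:`QCValidationError`.  Returns a frame indexed like the input with
    ``passed`` (bool) and ``failed_rules`` (semicolon-joined rule ids).
    """
    metric_names = [f.name for f in fields(SampleQCMetrics)]
    missing = [m for m in metric_names if m not in sample_table.columns]
    if missing:
        raise QCValidationError(f"sample table lacks QC metric columns: {missing}")
    out = {}
    for sid, row in sample_table.iterrows():
        decision = apply_qc(SampleQCMetrics(**{m: row[m] for m in metric_names}))
        out[sid] = {"passed": decision.passed,
                    "failed_rules": ";".join(decision.failed_rules)}
    return pd.DataFrame.from_dict(out, orient="index").loc[sample_table.index]
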