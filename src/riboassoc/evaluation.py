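"""Recovery metrics for simulated studies with known ground truth."""

from __future__ import annotations

from typing import Mapping

from .pipeline import PipelineResult
from .simulate import TranscriptTruth


def study_recovery_metrics(
    result: PipelineResult,
    truth: Mapping[str, TranscriptTruth],
) -> dict:
    """Compare a pipeline run against simulator ground truth.

    Returns per-study summary statistics: the fraction of expressed mRNAs
    classified ribosome-associated (pooled over datasets), balanced accuracy
    of lncRNA association recovery, the fraction of translated lncRNAs whose
    best per-dataset translation level is A3, and the identity/purity of the
    trans class.
    """
    tp = fp = tn = fn = 0
    mrna_assoc = mrna_total = 0
    for res in result.per_dataset.values():
        for tid, s in res.stats.items():
            if not s.expressed:
                continue
            info = truth[tid]
            if info.is_mrna:
                mrna_total += 1
                mrna_assoc += bool(s.associated)
            elif info.is_associated:
                tp += bool(s.associated)
                fn += not s.associated
            else:
                tn += not s.associated
                fp += bool(s.associated)

    best_level: dict[str, int] = {}
    for res in result.per_dataset.values():
        for tid, level in res.levels.items():
            best_level[tid] = max(best_level.get(tid, 0), level)
    translated = [
        tid for tid, info in truth.items() if info.is_translated and not info.is_mrna
    ]
    trans_ids = [e.transcript_id for e in result.entries if e.cls == "trans"]

    tpr = tp / (tp + fn) if tp + fn else float("nan")
    tnr = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "mrna_associated_fraction": mrna_assoc / mrna_total if mrna_total else float("nan"),
        "lnc_tpr": tpr,
        "lnc_tnr": tnr,
        "balanced_accuracy": 0.5 * (tpr + tnr),
        "translated_a3_fraction": (
            sum(best_level.get(tid, 0) == 3 for tid in translated) / len(translated)
            if translated
            else float("nan")
        ),
        "n_trans": len(trans_ids),
        "trans_ids": trans_ids,
        "trans_all_translated": all(truth[tid].is_translated for tid in trans_ids),
        "n_expressed_pairs": tp + fp + tn + fn,
    }
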