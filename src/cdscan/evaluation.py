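"""Nucleotide-level accuracy measures and per-sequence threshold optimization.

Sn = TP/(TP+FN), Sp = TN/(TN+FP), BA = (Sn+Sp)/2, PPV = TP/(TP+FP),
MSP = (Sn+PPV)/2 and F1 = 2TP/(2TP+FP+FN).  Ratios with zero denominators
are reported as 0 and flagged so that batch summaries never propagate NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .consensus import ConsensusConfig, _enumerate_arrays, adjust_predictions
from .sequence_io import PredictionTrack


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    sn: float
    sp: float
    ba: float
    ppv: float
    msp: float
    f1: float
    counts: ConfusionCounts
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sn": self.sn, "sp": self.sp, "ba": self.ba, "ppv": self.ppv,
            "msp": self.msp, "f1": self.f1,
            "counts": self.counts.__dict__,
            "degenerate": self.degenerate,
        }


def confusion(pred: PredictionTrack, truth: PredictionTrack) -> ConfusionCounts:
    """Count TP/FP/TN/FN over the intersection of the two valid ranges."""
    if len(pred.labels) != len(truth.labels):
        raise ValueError(
            f"track length mismatch: {len(pred.labels)} vs {len(truth.labels)}"
        )
    s = max(pred.valid_start, truth.valid_start)
    e = min(pred.valid_end, truth.valid_end)
    p = pred.labels[s:e].astype(bool)
    t = truth.labels[s:e].astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: int, den: int, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    degenerate: list[str] = []
    sn = _ratio(counts.tp, counts.tp + counts.fn, "sn", degenerate)
    sp = _ratio(counts.tn, counts.tn + counts.fp, "sp", degenerate)
    ppv = _ratio(counts.tp, counts.tp + counts.fp, "ppv", degenerate)
    f1 = _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn,
                "f1", degenerate)
    return MetricsReport(
        sn=sn, sp=sp, ba=(sn + sp) / 2.0, ppv=ppv, msp=(sn + ppv) / 2.0,
        f1=f1, counts=counts, degenerate=degenerate,
    )


def best_threshold(
    seq: str,
    initial: PredictionTrack,
    truth: PredictionTrack,
    grid: list[float],
    objective: str = "msp",
    config: ConsensusConfig | None = None,
) -> tuple[float, MetricsReport]:
    """Pick the grid threshold maximizing the objective against the truth.

    objective "msp"/"f1" maximize the respective measure; "sn_eq_sp"
    minimizes |Sn - Sp|.  Ties go to the smallest threshold.
    """
    if not grid:
        raise ValueError("threshold grid is empty")
    if objective not in ("msp", "f1", "sn_eq_sp"):
        raise ValueError(f"unknown objective {objective!r}")
    if config is None:
        config = ConsensusConfig()
    arrays = _enumerate_arrays(seq, config)
    best: tuple[float, MetricsReport] | None = None
    best_score = -np.inf
    for th in grid:
        adjusted, _ = adjust_predictions(
            seq, initial, replace(config, threshold=th), arrays)
        report = metrics(confusion(adjusted, truth))
        if objective == "msp":
            score = report.msp
        elif objective == "f1":
            score = report.f1
        else:
            score = -abs(report.sn - report.sp)
        if score > best_score:  # strict: ties keep the smallest threshold
            best_score = score
            best = (th, report)
    return best
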