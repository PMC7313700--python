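"""End-to-end orchestration and evaluation metrics.

Chains descriptor extraction and the MLP forward pass under a single
mode switch (float or fixed applied uniformly to both stages), and
computes the standard screening metrics from a confusion matrix with
melanoma as the positive class:

* accuracy     = (TP + TN) / total
* specificity  = TN / (TN + FP)   — non-melanomas correctly identified
* sensitivity  = TP / (TP + FN)   — melanomas correctly identified

Internal metric values are exact count ratios; rounding to one decimal in
percent happens only at display.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annm import MELANOMA, ClassificationResult, MlpModel, classify, mlp_forward
from .dpim import NormalizationGains, extract_descriptors

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "PipelineStageError",
    "run_pipeline",
    "evaluate",
    "metrics_from_counts",
]


class PipelineStageError(RuntimeError):
    """An error raised by a pipeline stage, wrapped with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; melanoma is the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    specificity: float
    sensitivity: float

    def percent(self, digits: int = 1) -> dict:
        """Display values in percent, rounded (default one decimal)."""
        return {
            "accuracy": round(100 * self.accuracy, digits),
            "specificity": round(100 * self.specificity, digits),
            "sensitivity": round(100 * self.sensitivity, digits),
        }


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    if c.total == 0:
        raise ValueError("no evaluated items")
    return MetricSet(
        accuracy=(c.tp + c.tn) / c.total,
        specificity=c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan"),
        sensitivity=c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan"),
    )


def evaluate(predictions, truth_labels) -> tuple[ConfusionCounts, MetricSet]:
    """Confusion counts and metrics from parallel label lists."""
    predictions = list(predictions)
    truth_labels = list(truth_labels)
    if len(predictions) != len(truth_labels):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(truth_labels)} truth labels"
        )
    tp = fn = fp = tn = 0
    for pred, true in zip(predictions, truth_labels):
        if true == MELANOMA:
            if pred == MELANOMA:
                tp += 1
            else:
                fn += 1
        else:
            if pred == MELANOMA:
                fp += 1
            else:
                tn += 1
    counts = ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)
    return counts, metrics_from_counts(counts)


def run_pipeline(
    image,
    mask,
    gains: NormalizationGains,
    model: MlpModel,
    mode: str = "float",
) -> ClassificationResult:
    """image + mask -> descriptors -> MLP -> label, in one mode throughout."""
    try:
        d = extract_descriptors(image, mask, gains, mode=mode)
    except Exception as exc:
        raise PipelineStageError("dpim", exc) from exc
    try:
        u0, u1 = mlp_forward(d, model, mode=mode)
    except Exception as exc:
        raise PipelineStageError("annm", exc) from exc
    return ClassificationResult(u0=u0, u1=u1, label=classify(u0, u1))
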