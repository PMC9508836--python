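"""Scoring of de novo call sets against truth sets.

A call set and a truth set are both mappings from a variant key
(contig, position, ref, alt) to a binary label: ``True`` for a de novo
mutation (DNM, the positive class) and ``False`` for an inherited variant
or artifact (IV, the negative class).  The 2x2 confusion table drives all
reported metrics: sensitivity (recall), specificity, precision, accuracy
and F1.

Percentages are rounded half-up to two decimals, the convention used in
published variant-caller comparison tables; metrics with a zero
denominator are reported as ``None`` (absent), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional

__all__ = ["ConfusionTable", "MetricSet", "confusion", "metrics", "per_type_breakdown"]


@dataclass(frozen=True)
class ConfusionTable:
    """True/false positive/negative counts with DNM as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def calls(self) -> int:
        """Number of positive (DNM) calls made: tp + fp."""
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Performance metrics; percentages to 2 decimals, ``None`` when undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    accuracy: Optional[float]
    f1: Optional[float]
    calls: int


def _pct(numerator: int, denominator: int) -> Optional[float]:
    if denominator == 0:
        return None
    frac = Decimal(numerator) / Decimal(denominator)
    return float((frac * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion(
    truth: Mapping[object, bool], predicted: Mapping[object, bool]
) -> ConfusionTable:
    """Count the 2x2 table of predicted vs truth labels over a shared key set.

    Raises ``ValueError`` if the two mappings do not cover the same keys, so
    that silently dropped candidates cannot inflate a metric.
    """
    if set(truth) != set(predicted):
        missing = set(truth) ^ set(predicted)
        raise ValueError(f"truth/prediction key mismatch on {len(missing)} keys")
    tp = fp = tn = fn = 0
    for key, is_dnm in truth.items():
        called = predicted[key]
        if is_dnm and called:
            tp += 1
        elif is_dnm and not called:
            fn += 1
        elif not is_dnm and called:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(table: ConfusionTable) -> MetricSet:
    """Compute sensitivity/specificity/precision/accuracy (percent) and F1.

    sensitivity = tp/(tp+fn); specificity = tn/(tn+fp);
    precision = tp/(tp+fp); accuracy = (tp+tn)/total;
    f1 = 2*precision*sensitivity/(precision+sensitivity) as a fraction.
    """
    if table.total == 0:
        raise ValueError("cannot compute metrics on an all-zero confusion table")
    sens = _pct(table.tp, table.tp + table.fn)
    spec = _pct(table.tn, table.tn + table.fp)
    prec = _pct(table.tp, table.tp + table.fp)
    acc = _pct(table.tp + table.tn, table.total)
    f1: Optional[float] = None
    if sens is not None and prec is not None and (sens + prec) > 0:
        p = table.tp / (table.tp + table.fp)
        s = table.tp / (table.tp + table.fn)
        f1 = 2 * p * s / (p + s) if (p + s) > 0 else None
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        accuracy=acc,
        f1=f1,
        calls=table.calls,
    )


def per_type_breakdown(
    truth: Mapping[object, bool],
    predicted: Mapping[object, bool],
    variant_types: Mapping[object, str],
) -> dict:
    """Metrics within each variant-type partition plus the overall set.

    ``variant_types`` maps each candidate key to one of
    ``substitution`` / ``insertion`` / ``deletion``.  Partition counts sum
    to the total by construction.
    """
    result: dict = {}
    types = sorted(set(variant_types.values()))
    for vt in types:
        keys = [k for k in truth if variant_types[k] == vt]
        if not keys:
            continue
        sub_truth = {k: truth[k] for k in keys}
        sub_pred = {k: predicted[k] for k in keys}
        table = confusion(sub_truth, sub_pred)
        result[vt] = (table, metrics(table))
    overall = confusion(truth, predicted)
    result["all"] = (overall, metrics(overall))
    return result
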