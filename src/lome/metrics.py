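"""Screening classification metrics.

Sensitivity, specificity, PPV and NPV are reported as percentages with
half-up rounding to two decimals (the convention of clinical screening
tables); full precision is retained internally.  Ratios with a zero
denominator are reported as not-available (``None``), never as 0.  Groups
excluded from training get their own specificity, since a screening tool's
false-positive behavior on unseen disease groups is a separate claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["ClassMetrics", "evaluate", "round_half_up"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero upward, as printed clinical tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


@dataclass(frozen=True)
class ClassMetrics:
    """Confusion counts plus the four screening percentages.

    ``sensitivity``/``specificity``/``ppv``/``npv`` are full-precision
    percentages (``None`` when undefined); use :meth:`reported` for the
    2-decimal half-up presentation values.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _pct(self.tn, self.tn + self.fn)

    def reported(self) -> dict:
        """Counts plus percentages rounded half-up to 2 decimals ('NA' if undefined)."""
        out = {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = "NA" if v is None else round_half_up(v)
        return out


def evaluate(
    predictions,
    is_target,
    group_labels=None,
    excluded_groups=(),
) -> tuple[ClassMetrics, dict[str, float | None]]:
    """Confusion counts and screening metrics for one evaluation set.

    ``predictions`` and ``is_target`` are equal-length boolean sequences
    (True = screen-positive / target class).  If ``group_labels`` is given,
    a per-group specificity is computed for each label in
    ``excluded_groups`` (groups that were not part of training).
    """
    predictions = np.asarray(predictions, dtype=bool)
    is_target = np.asarray(is_target, dtype=bool)
    if predictions.size != is_target.size:
        raise ValueError(
            f"{predictions.size} predictions for {is_target.size} labels"
        )
    tp = int(np.sum(predictions & is_target))
    fp = int(np.sum(predictions & ~is_target))
    tn = int(np.sum(~predictions & ~is_target))
    fn = int(np.sum(~predictions & is_target))
    per_group: dict[str, float | None] = {}
    if group_labels is not None:
        group_labels = np.asarray(group_labels)
        if group_labels.size != predictions.size:
            raise ValueError("group label length mismatch")
        for g in excluded_groups:
            mask = (group_labels == g) & ~is_target
            per_group[str(g)] = _pct(
                int(np.sum(~predictions & mask)), int(np.sum(mask))
            )
    return ClassMetrics(tp, fp, tn, fn), per_group
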