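"""Accuracy assessment of burn masks against ground truth.

Burn is the positive class.  The three alarm rates share the all-pixel
denominator N so they always sum to 100%:

    missed = 100 * FN / N      (burn called unburn)
    false  = 100 * FP / N      (unburn called burn)
    right  = 100 * (TP + TN) / N

Cohen's kappa corrects the right rate for chance agreement from the class
marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "alarm_rates",
    "kappa",
    "evaluate_mask",
    "compare_methods",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvalReport:
    method: str
    missed_pct: float
    false_pct: float
    right_pct: float
    kappa: float
    iterations: int | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "missed_pct": self.missed_pct,
            "false_pct": self.false_pct,
            "right_pct": self.right_pct,
            "kappa": self.kappa,
            "iterations": self.iterations,
        }


def confusion(
    pred: np.ndarray,
    truth: np.ndarray,
    valid: np.ndarray | None = None,
) -> ConfusionCounts:
    """Pixel confusion counts; ``valid`` excludes nodata pixels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for arr, name in ((pred, "pred"), (truth, "truth")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary in {{0, 1}}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    if valid is not None:
        p, t = p[valid], t[valid]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fn=int(np.count_nonzero(~p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def alarm_rates(c: ConfusionCounts) -> tuple[float, float, float]:
    """(missed %, false %, right %) over all valid pixels; sums to 100."""
    n = c.total
    if n == 0:
        raise ValueError("empty confusion")
    return (100.0 * c.fn / n, 100.0 * c.fp / n, 100.0 * (c.tp + c.tn) / n)


def kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa from the confusion counts."""
    n = c.total
    if n == 0:
        raise ValueError("empty confusion")
    p_o = (c.tp + c.tn) / n
    p_yes = ((c.tp + c.fp) / n) * ((c.tp + c.fn) / n)
    p_no = ((c.fn + c.tn) / n) * ((c.fp + c.tn) / n)
    p_e = p_yes + p_no
    if p_e == 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def evaluate_mask(
    pred: np.ndarray,
    truth: np.ndarray,
    method: str = "",
    iterations: int | None = None,
    valid: np.ndarray | None = None,
) -> EvalReport:
    c = confusion(pred, truth, valid)
    missed, false, right = alarm_rates(c)
    return EvalReport(method=method, missed_pct=missed, false_pct=false,
                      right_pct=right, kappa=kappa(c), iterations=iterations)


def compare_methods(pre, post, truth, config=None) -> pd.DataFrame:
    """Run all four extraction methods on one scene pair and tabulate accuracy.

    Returns a DataFrame with one row per method (proposed, otsu, fcm, tcv)
    and columns missed/false/right alarm rates, kappa, and the iteration
    count for the level-set methods.
    """
    from .pipeline import run_method  # local import: avoids a cycle

    config = config or {}
    rows = []
    for method in ("proposed", "otsu", "fcm", "tcv"):
        out = run_method(pre, post, method=method, **config)
        rows.append(
            evaluate_mask(out.mask, truth, method=method,
                          iterations=out.iterations).to_dict()
        )
    return pd.DataFrame(rows).set_index("method")
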