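"""Scarring-outcome classification from day-40 fold changes.

Each simulated wound is scored by the fold change of its collagen and
fibroblast concentrations at the final time point (day 40) relative to the
reference (default-parameter, normal-healing) simulation, then labelled:

* four-way label, both fold changes jointly —
  ``normal``  : both <= 1
  ``mild``    : both within [5, 10]
  ``severe``  : both > 10
  ``excluded``: any other combination (ambiguous outcomes are dropped from
  the distribution screen, not from the regression analysis)
* binary label, collagen only — ``pathological`` iff the collagen fold
  change exceeds 10 (strict), else ``normal``; applied to every successful
  draw.

All comparisons use the literal inequalities above with no epsilon slack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortResult

__all__ = ["Thresholds", "fold_changes", "classify4", "binary_label", "label_cohort"]

CLASS4 = ("normal", "mild", "severe", "excluded")


@dataclass(frozen=True)
class Thresholds:
    normal_max: float = 1.0
    mild_lo: float = 5.0
    mild_hi: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.normal_max <= self.mild_lo <= self.mild_hi):
            raise ValueError("thresholds must satisfy 0 < normal_max <= mild_lo <= mild_hi")


def fold_changes(cohort: CohortResult, day: int = 40) -> pd.DataFrame:
    """Per-draw collagen and fibroblast fold changes vs the reference run.

    Returns a frame with columns ``draw_id, fc_col, fc_fib``.
    """
    col_state, fib_state = _role_states(cohort)
    ref = cohort.reference.at_day(day)
    ref_col = float(ref[col_state])
    ref_fib = float(ref[fib_state])
    if ref_col <= 0:
        raise ValueError(
            f"reference day-{day} {col_state} is not positive; fold change undefined"
        )
    if ref_fib <= 0:
        raise ValueError(
            f"reference day-{day} {fib_state} is not positive; fold change undefined"
        )
    return pd.DataFrame(
        {
            "draw_id": cohort.success_ids,
            "fc_col": cohort.values_at_day(col_state, day) / ref_col,
            "fc_fib": cohort.values_at_day(fib_state, day) / ref_fib,
        }
    )


def _role_states(cohort: CohortResult) -> tuple[str, str]:
    # Cohorts carry state names only; the collagen / fibroblast states follow
    # the surrogate role map unless overridden via cohort attributes.
    col = getattr(cohort, "collagen_state", "COL")
    fib = getattr(cohort, "fibroblast_state", "F")
    return col, fib


def classify4(
    fc_col: np.ndarray, fc_fib: np.ndarray, thresholds: Thresholds = Thresholds()
) -> np.ndarray:
    """Vectorised four-way label; both fold changes must satisfy the rule."""
    fc_col = np.asarray(fc_col, dtype=float)
    fc_fib = np.asarray(fc_fib, dtype=float)
    if np.any(~np.isfinite(fc_col)) or np.any(~np.isfinite(fc_fib)):
        raise ValueError("fold changes must be finite")
    if np.any(fc_col < 0) or np.any(fc_fib < 0):
        raise ValueError("fold changes must be non-negative")
    t = thresholds
    out = np.full(fc_col.shape, "excluded", dtype=object)
    out[(fc_col <= t.normal_max) & (fc_fib <= t.normal_max)] = "normal"
    mild = (
        (fc_col >= t.mild_lo) & (fc_col <= t.mild_hi)
        & (fc_fib >= t.mild_lo) & (fc_fib <= t.mild_hi)
    )
    out[mild] = "mild"
    out[(fc_col > t.mild_hi) & (fc_fib > t.mild_hi)] = "severe"
    return out


def binary_label(
    fc_col: np.ndarray, thresholds: Thresholds = Thresholds()
) -> np.ndarray:
    """Binary outcome from collagen fold change alone (> mild_hi, strict)."""
    fc_col = np.asarray(fc_col, dtype=float)
    if np.any(~np.isfinite(fc_col)):
        raise ValueError("fold changes must be finite")
    return np.where(fc_col > thresholds.mild_hi, "pathological", "normal")


def label_cohort(
    cohort: CohortResult, thresholds: Thresholds = Thresholds(), day: int = 40
) -> pd.DataFrame:
    """Fold changes plus both labels for every successful draw.

    Columns: draw_id, fc_col, fc_fib, class4, binary.
    """
    fc = fold_changes(cohort, day=day)
    fc["class4"] = classify4(fc["fc_col"].to_numpy(), fc["fc_fib"].to_numpy(), thresholds)
    fc["binary"] = binary_label(fc["fc_col"].to_numpy(), thresholds)
    return fc
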