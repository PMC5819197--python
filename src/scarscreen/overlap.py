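"""Distribution-overlap biomarker screening via the Bhattacharyya coefficient.

For every screened protein, day, and outcome-group pair, the per-simulation
concentration values of the two groups are binned into 50 shared, equal-width
bins spanning the pooled min/max, normalised to fractions, and compared with
the Bhattacharyya coefficient BC = sum_i sqrt(p_i * q_i) in [0, 1] (1 =
identical distributions, 0 = disjoint support).  Small overlap marks a
candidate biomarker: at day 40 the ranking is *diagnostic*, at days 7/14/21
*prognostic*.

Plotting histograms (each group binned over its own range, as percentage
curves) are a separate artifact from comparison histograms: a common support
is mathematically required for BC.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .cohort import CohortResult

__all__ = [
    "HistogramDensity",
    "OverlapResult",
    "histogram",
    "bhattacharyya",
    "shared_range",
    "screen",
    "overlap_reduction",
]

N_BINS_DEFAULT = 50
GROUP_PAIRS = (("normal", "mild"), ("normal", "severe"))


@dataclass(frozen=True)
class HistogramDensity:
    """Normalised equal-width histogram of per-simulation concentrations."""

    protein: str
    day: int
    group: str
    bin_edges: np.ndarray  # n_bins + 1, strictly increasing
    fractions: np.ndarray  # n_bins, non-negative, sums to 1

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        frac = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must be non-negative and sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "fractions", frac)


@dataclass(frozen=True)
class OverlapResult:
    protein: str
    day: int
    group_pair: tuple[str, str]
    bc: float
    bin_edges: np.ndarray
    n_a: int
    n_b: int


def shared_range(*value_sets: np.ndarray) -> tuple[float, float]:
    """Pooled [min, max] across groups, widened if degenerate.

    A degenerate (single-valued) range is widened symmetrically by
    max(1e-12, 1e-9*|lo|) so single-valued groups remain representable.
    """
    lo = min(float(np.min(v)) for v in value_sets)
    hi = max(float(np.max(v)) for v in value_sets)
    if lo == hi:
        eps = max(1e-12, 1e-9 * abs(lo))
        lo, hi = lo - eps, hi + eps
    return lo, hi


def histogram(
    values,
    protein: str = "",
    day: int = 0,
    group: str = "",
    n_bins: int = N_BINS_DEFAULT,
    value_range: tuple[float, float] | None = None,
) -> HistogramDensity:
    """Equal-width binned fraction-of-simulations histogram.

    Bins are right-open except the last (closed), numpy convention.  All
    values must fall inside ``value_range``; the caller passes an enclosing
    (possibly pooled) range.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("histogram needs at least one value")
    if not np.all(np.isfinite(values)):
        raise ValueError("histogram values must be finite")
    lo, hi = value_range if value_range is not None else shared_range(values)
    if lo >= hi:
        lo, hi = shared_range(np.array([lo, hi]))
    if values.min() < lo or values.max() > hi:
        raise ValueError(
            "values fall outside the histogram range; pass an enclosing range"
        )
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return HistogramDensity(
        protein=protein,
        day=day,
        group=group,
        bin_edges=edges,
        fractions=counts / values.size,
    )


def bhattacharyya(h1: HistogramDensity, h2: HistogramDensity) -> float:
    """BC = sum_i sqrt(p_i * q_i); requires identical bin edges."""
    if h1.bin_edges.shape != h2.bin_edges.shape or not np.allclose(
        h1.bin_edges, h2.bin_edges, rtol=0, atol=0
    ):
        raise ValueError("Bhattacharyya coefficient requires shared bin edges")
    bc = float(np.sqrt(h1.fractions * h2.fractions).sum())
    # guard against fp drift just past the theoretical bounds
    return min(max(bc, 0.0), 1.0)


def overlap_reduction(bc_early: float, bc_late: float) -> float:
    """Percent reduction in overlap, 100*(bc_early - bc_late)/bc_early.

    Positive values mean less overlap (better separation) at the later day.
    Undefined for bc_early == 0 (raises; callers report not-applicable).
    """
    if bc_early == 0:
        raise ZeroDivisionError("overlap reduction undefined for zero early overlap")
    return 100.0 * (bc_early - bc_late) / bc_early


def screen(
    cohort: CohortResult,
    labels: pd.DataFrame,
    days=(7, 14, 21, 40),
    proteins=None,
    n_bins: int = N_BINS_DEFAULT,
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Overlap screen across proteins and days.

    For each protein and day, computes BC(normal, mild) and
    BC(normal, severe) on shared 50-bin supports, then ranks proteins per day
    by the mean of the two coefficients, ascending (smallest overlap first =
    strongest candidate).  Day-40 rankings are diagnostic; earlier days
    prognostic.  Excluded-class draws never enter the histograms.

    Returns (overlap table, {day: ranked protein list}).
    """
    if proteins is None:
        raise ValueError("pass the model's screened protein set")
    proteins = tuple(proteins)
    unknown = set(proteins) - set(cohort.state_names)
    if unknown:
        raise ValueError(f"proteins not in the model state set: {sorted(unknown)}")
    labels = labels.set_index("draw_id").loc[cohort.success_ids]
    group_masks = {
        g: (labels["class4"] == g).to_numpy() for g in ("normal", "mild", "severe")
    }
    rows = []
    for day in days:
        for protein in proteins:
            values = {
                g: cohort.values_at_day(protein, day)[m]
                for g, m in group_masks.items()
            }
            for ga, gb in GROUP_PAIRS:
                va, vb = values[ga], values[gb]
                if va.size == 0 or vb.size == 0:
                    warnings.warn(
                        f"empty group in pair {ga}-vs-{gb}; skipped for "
                        f"{protein} day {day}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    continue
                rng = shared_range(va, vb)
                ha = histogram(va, protein, day, ga, n_bins=n_bins, value_range=rng)
                hb = histogram(vb, protein, day, gb, n_bins=n_bins, value_range=rng)
                rows.append(
                    {
                        "protein": protein,
                        "day": day,
                        "pair": f"{ga}-vs-{gb}",
                        "bc": bhattacharyya(ha, hb),
                        "n_normal": int(va.size),
                        "n_path": int(vb.size),
                    }
                )
    table = pd.DataFrame(rows)
    rankings: dict[int, list[str]] = {}
    for day in days:
        sub = table[table["day"] == day]
        if sub.empty:
            rankings[int(day)] = []
            continue
        mean_bc = sub.groupby("protein")["bc"].mean().sort_values(kind="stable")
        rankings[int(day)] = mean_bc.index.tolist()
    return table, rankings


def plotting_histograms(
    cohort: CohortResult,
    labels: pd.DataFrame,
    protein: str,
    day: int,
    n_bins: int = N_BINS_DEFAULT,
) -> list[HistogramDensity]:
    """Per-group percentage-curve histograms, each over its own min/max range."""
    labels = labels.set_index("draw_id").loc[cohort.success_ids]
    out = []
    for g in ("normal", "mild", "severe"):
        vals = cohort.values_at_day(protein, day)[(labels["class4"] == g).to_numpy()]
        if vals.size == 0:
            continue
        out.append(histogram(vals, protein, day, g, n_bins=n_bins))
    return out
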