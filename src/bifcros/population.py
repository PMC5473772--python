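"""Population-level analyses: area binning, control subtraction, regression,
and copy-number fold-change estimation.

These are the procedures applied to per-cell quantifications when comparing
strains: group cells by area (growth stage proxy) and average fluorescence per
group; subtract the mean of a no-array control strain as the background of
the split-reporter system; regress per-cell background on per-cell signal
(a flat slope means focus intensity grows without dragging the cytoplasmic
background along — the hallmark of a low-background system); and estimate the
copy-number fold change between strains from control-subtracted whole-cell
means, optionally restricted to the brightest half of each population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from scipy import stats

from .quantify import CellQuant

__all__ = [
    "BinSummary",
    "RegressionResult",
    "FoldChange",
    "bin_by_area",
    "subtract_control",
    "regress_signal_vs_background",
    "estimate_fold_change",
]


@dataclass(frozen=True)
class BinSummary:
    """Mean whole-cell intensity of cells within one area window."""

    bin_lower: float
    bin_upper: float  # half-open [lower, upper)
    n_cells: int
    mean_intensity: float
    sd: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    n_points: int
    r_value: float = float("nan")


@dataclass(frozen=True)
class FoldChange:
    numerator_mean: float
    denominator_mean: float
    fold: float
    subset_fraction: float
    n_numerator: int
    n_denominator: int


def bin_by_area(
    quants: Sequence[CellQuant],
    window: float = 10.0,
    min_cells: int = 10,
    mode: str = "disjoint",
) -> list[BinSummary]:
    """Group cells by area and average their whole-cell mean intensities.

    ``disjoint`` mode tiles the area axis with half-open ``[k*window,
    (k+1)*window)`` bins; ``sliding`` mode moves a window of the given width
    in 1-pixel steps.  Windows holding fewer than ``min_cells`` cells are
    dropped (empty output is allowed).
    """
    if window < 1:
        raise ValueError("window must be >= 1 pixel")
    if mode not in ("disjoint", "sliding"):
        raise ValueError("mode must be 'disjoint' or 'sliding'")
    if not quants:
        return []
    areas = [q.area for q in quants]
    out: list[BinSummary] = []
    if mode == "disjoint":
        starts = sorted({math.floor(a / window) * window for a in areas})
        step = None
    else:
        starts = range(int(math.floor(min(areas))), int(math.floor(max(areas))) + 1)
        step = 1
    for lo in starts:
        hi = lo + window
        members = [q.mean_intensity for q in quants if lo <= q.area < hi]
        if len(members) < min_cells:
            continue
        n = len(members)
        mean = sum(members) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in members) / (n - 1)) if n > 1 else 0.0
        out.append(BinSummary(float(lo), float(hi), n, mean, sd))
    return out


def subtract_control(
    quants: Sequence[CellQuant], control_quants: Sequence[CellQuant]
) -> list[CellQuant]:
    """Subtract the control population's grand mean from each cell's mean.

    The control strain carries the split constructs but no array, so its mean
    whole-cell intensity estimates the system background.  Cells pushed below
    zero are clamped to 0 and flagged (``clamped``).  Returns new records;
    inputs are not mutated.
    """
    if not control_quants:
        raise ValueError("control population is empty")
    control_mean = sum(q.mean_intensity for q in control_quants) / len(control_quants)
    out = []
    for q in quants:
        adjusted = q.mean_intensity - control_mean
        out.append(
            replace(q, mean_intensity=max(adjusted, 0.0), clamped=adjusted < 0)
        )
    return out


def regress_signal_vs_background(
    quants: Sequence[CellQuant],
    x_cap: float = 65000.0,
    y_cap: float = 15000.0,
) -> RegressionResult:
    """OLS of per-cell background (y) on per-cell signal (x).

    Cells with signal above ``x_cap`` or background above ``y_cap`` are
    excluded before fitting; at least three points must survive.
    """
    pts = [(q.signal, q.background) for q in quants if q.signal <= x_cap and q.background <= y_cap]
    if len(pts) < 3:
        raise ValueError(
            f"only {len(pts)} cells survive the axis caps; need >= 3 for a fit"
        )
    xs, ys = zip(*pts)
    fit = stats.linregress(xs, ys)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=len(pts),
        r_value=float(fit.rvalue),
    )


def _brightest_subset(quants: Sequence[CellQuant], fraction: float) -> list[CellQuant]:
    if fraction >= 1.0:
        return list(quants)
    k = max(1, math.ceil(fraction * len(quants)))
    return sorted(quants, key=lambda q: q.mean_intensity, reverse=True)[:k]


def estimate_fold_change(
    strain_a: Sequence[CellQuant],
    strain_b: Sequence[CellQuant],
    subset_fraction: float = 1.0,
    control: Sequence[CellQuant] | None = None,
) -> FoldChange:
    """Fold change of mean whole-cell fluorescence, strain b over strain a.

    With ``subset_fraction`` 0.5 each strain is first restricted to its
    brightest half (by whole-cell mean); the control mean (if a control is
    given) is then subtracted from each cell before averaging.  The reference
    strain's subtracted mean must be positive.
    """
    if not strain_a or not strain_b:
        raise ValueError("both strains must be nonempty")
    if not (0.0 < subset_fraction <= 1.0):
        raise ValueError("subset_fraction must be in (0, 1]")
    a = _brightest_subset(strain_a, subset_fraction)
    b = _brightest_subset(strain_b, subset_fraction)
    if control:
        a = subtract_control(a, control)
        b = subtract_control(b, control)
    denom = sum(q.mean_intensity for q in a) / len(a)
    numer = sum(q.mean_intensity for q in b) / len(b)
    if denom <= 0:
        raise ValueError("reference strain mean is zero after control subtraction")
    return FoldChange(
        numerator_mean=numer,
        denominator_mean=denom,
        fold=numer / denom,
        subset_fraction=subset_fraction,
        n_numerator=len(b),
        n_denominator=len(a),
    )
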