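"""Per-cell signal/background statistics, quality filters, and pixel histograms.

The central statistic is an order-statistic ratio computed per cell: *signal*
is the mean of the brightest ``signal_fraction`` (default 10%) of the cell's
pixels, *background* the mean of the dimmest ``background_fraction`` (default
50%).  In a low-background labeling system the brightest pixels belong to the
focus and the dimmest to cytoplasm, so the ratio measures how cleanly the
locus signal stands out within a single cell.

Cells are screened by two filters before pixel-level analyses: a saturation
guard (maximum pixel intensity strictly below ``max_intensity``, default
65,000 counts on a 16-bit camera) and a strict signal-to-background cutoff
(ratio strictly greater than ``min_ratio``, default 5).

Pixel-count rounding: the top/bottom sets contain ``ceil(fraction * n)``
pixels (at least one), after a stable descending/ascending sort; ties at the
set boundary are broken by taking exactly the computed count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import CellMeasurement

__all__ = [
    "QuantConfig",
    "CellQuant",
    "signal_background",
    "quantify_measurements",
    "filter_cells",
    "pixel_histogram",
]


def _default_bins() -> tuple[float, ...]:
    return tuple(np.arange(0.0, 66001.0, 1000.0))


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and bin edges of the per-cell quantification."""

    signal_fraction: float = 0.10
    background_fraction: float = 0.50
    max_intensity: float = 65000.0
    min_ratio: float = 5.0
    histogram_bins: tuple[float, ...] = field(default_factory=_default_bins)
    #: apply ``max_intensity`` to the cell's maximum pixel ("pixel_max",
    #: saturation-guard reading) or to its whole-cell mean ("cell_mean")
    intensity_filter_mode: str = "pixel_max"

    def __post_init__(self) -> None:
        if not (0 < self.signal_fraction <= 1 and 0 < self.background_fraction <= 1):
            raise ValueError("fractions must be in (0, 1]")
        if self.max_intensity > 65535:
            raise ValueError("max_intensity cannot exceed the 16-bit ceiling")
        if self.intensity_filter_mode not in ("pixel_max", "cell_mean"):
            raise ValueError("intensity_filter_mode must be 'pixel_max' or 'cell_mean'")


@dataclass
class CellQuant:
    """Derived per-cell statistics."""

    cell_id: int
    area: int
    mean_intensity: float
    signal: float
    background: float
    ratio: float
    max_pixel: float
    passed_filters: bool | None = None
    clamped: bool = False


def signal_background(m: CellMeasurement, cfg: QuantConfig = QuantConfig()) -> CellQuant:
    """Compute the per-cell signal, background and their ratio.

    Signal is the mean of the top ``ceil(signal_fraction * n)`` pixels,
    background the mean of the bottom ``ceil(background_fraction * n)``
    pixels (each at least one pixel).  A zero background with nonzero signal
    yields an infinite ratio; uniform zero pixels yield ratio 1.
    """
    values = np.asarray(m.pixel_values, dtype=np.float64)
    n = values.size
    if n == 0:
        raise ValueError("empty pixel vector")
    ordered = np.sort(values, kind="stable")
    k_sig = max(1, math.ceil(cfg.signal_fraction * n))
    k_bg = max(1, math.ceil(cfg.background_fraction * n))
    signal = float(ordered[n - k_sig :].mean())
    background = float(ordered[:k_bg].mean())
    if background > 0:
        ratio = signal / background
    else:
        ratio = math.inf if signal > 0 else 1.0
    return CellQuant(
        cell_id=m.cell_id,
        area=int(n),
        mean_intensity=float(values.mean()),
        signal=signal,
        background=background,
        ratio=ratio,
        max_pixel=float(values.max()),
    )


def quantify_measurements(
    measurements: Iterable[CellMeasurement], cfg: QuantConfig = QuantConfig()
) -> list[CellQuant]:
    return [signal_background(m, cfg) for m in measurements]


def filter_cells(quants: Sequence[CellQuant], cfg: QuantConfig = QuantConfig()) -> list[CellQuant]:
    """Apply the saturation and ratio filters; returns the retained cells.

    Both cutoffs are strict: a cell is retained only if its intensity reading
    is strictly below ``max_intensity`` *and* its ratio strictly exceeds
    ``min_ratio``.  ``passed_filters`` is set on every input.
    """
    retained = []
    for q in quants:
        reading = q.max_pixel if cfg.intensity_filter_mode == "pixel_max" else q.mean_intensity
        q.passed_filters = bool(reading < cfg.max_intensity and q.ratio > cfg.min_ratio)
        if q.passed_filters:
            retained.append(q)
    return retained


def pixel_histogram(
    measurements: Sequence[CellMeasurement],
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Pooled pixel-intensity frequency distribution across cells.

    Returns a frame with ``bin_lower``, ``bin_upper`` and ``count`` columns;
    the counts sum to the pooled pixel number (the summed areas) as long as
    the bin edges span the data range.
    """
    if not measurements:
        raise ValueError("no cells to pool")
    edges = np.asarray(bins if bins is not None else _default_bins(), dtype=np.float64)
    pooled = np.concatenate([np.asarray(m.pixel_values, dtype=np.float64) for m in measurements])
    counts, _ = np.histogram(pooled, bins=edges)
    return pd.DataFrame(
        {"bin_lower": edges[:-1], "bin_upper": edges[1:], "count": counts}
    )
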