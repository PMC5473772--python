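"""End-to-end pipeline: simulate the four regimes, quantify, analyse, write artifacts.

Artifacts per regime: the rendered frames and label masks (TIFF), the ground
truth and per-cell pixel tables (CSV), per-cell quantifications (CSV), pooled
pixel histograms of filter-passing cells (CSV), and area-binned means (CSV).
Cross-regime artifacts: background-on-signal regressions (JSON) and the
1-copy vs 2-copy fold change with the no-array split strain as control
(JSON), plus a provenance log (seed, package version, config hash, per-stage
record counts).  Re-running with the same config reproduces the CSV/JSON
artifacts byte-for-byte.

All randomness flows from the single top-level seed through named substreams,
one per regime, so changing e.g. the quantification thresholds never changes
the simulated images.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .io import write_image, write_json, write_label_mask, write_pixel_table
from .population import bin_by_area, estimate_fold_change, regress_signal_vs_background
from .quantify import filter_cells, pixel_histogram, quantify_measurements
from .regimes import measure_images, regime, simulate_fields

__all__ = ["run_pipeline", "REGIME_PLAN"]

#: name -> (construct, n_arrays); the four regimes plus the 2-copy strain.
REGIME_PLAN = {
    "full_length_no_array": ("full_length", 0),
    "full_length_array": ("full_length", 1),
    "split_no_array": ("split", 0),
    "split_array": ("split", 1),
    "split_array_2x": ("split", 2),
    "empty_vector": ("empty", 0),
}


def _quants_frame(quants) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [q.cell_id for q in quants],
            "area": [q.area for q in quants],
            "mean_intensity": [q.mean_intensity for q in quants],
            "signal": [q.signal for q in quants],
            "background": [q.background for q in quants],
            "ratio": [q.ratio for q in quants],
            "max_pixel": [q.max_pixel for q in quants],
            "passed_filters": [q.passed_filters for q in quants],
        }
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full simulate -> quantify -> analyze pipeline into ``outdir``.

    Returns a summary dict (also written as ``provenance.json``).  Raises
    before writing anything if the configuration is degenerate.
    """
    if config.n_cells < 1:
        raise ValueError("config.n_cells must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")

    seeds = {
        name: int(child.generate_state(1)[0]) % (2**31)
        for name, child in zip(
            REGIME_PLAN, np.random.SeedSequence(config.seed).spawn(len(REGIME_PLAN))
        )
    }

    log: list[dict] = []
    quants_by_regime = {}
    for name, (construct, n_arrays) in REGIME_PLAN.items():
        spec = regime(
            construct,
            n_arrays,
            pool_size=config.occupancy(construct, n_arrays).pool_size,
            sites_per_array=config.sites_per_array,
            affinity=config.affinity,
            free_complementation_rate=config.free_complementation_rate,
        )
        images = simulate_fields(
            spec,
            config.n_cells,
            seeds[name],
            optics=config.optics,
            cells_per_field=config.cells_per_field,
            frame_shape=config.frame_shape,
        )
        rdir = outdir / name
        rdir.mkdir(exist_ok=True)
        for i, img in enumerate(images):
            write_image(rdir / f"field_{i:02d}.tif", img.pixels)
            write_label_mask(rdir / f"field_{i:02d}_mask.tif", img.label_mask)
        pd.concat([img.truth for img in images], ignore_index=True).to_csv(
            rdir / "truth.csv", index=False
        )
        measurements = measure_images(images)
        write_pixel_table(rdir / "pixels.csv", measurements)
        quants = quantify_measurements(measurements, config.quant)
        retained = filter_cells(quants, config.quant)
        _quants_frame(quants).to_csv(rdir / "cells.csv", index=False)
        retained_ids = {q.cell_id for q in retained}
        retained_measurements = [m for m in measurements if m.cell_id in retained_ids]
        if retained_measurements:
            pixel_histogram(retained_measurements, config.quant.histogram_bins).to_csv(
                rdir / "histogram.csv", index=False
            )
        bins = bin_by_area(
            quants, config.bin_window, config.bin_min_cells, config.bin_mode
        )
        pd.DataFrame(
            {
                "bin_lower": [b.bin_lower for b in bins],
                "bin_upper": [b.bin_upper for b in bins],
                "n_cells": [b.n_cells for b in bins],
                "mean_intensity": [b.mean_intensity for b in bins],
                "sd": [b.sd for b in bins],
            }
        ).to_csv(rdir / "bins.csv", index=False)
        quants_by_regime[name] = quants
        log.append(
            {
                "stage": name,
                "n_fields": len(images),
                "n_cells": len(measurements),
                "n_retained": len(retained),
            }
        )

    regressions = {}
    for name in ("full_length_array", "split_array"):
        fit = regress_signal_vs_background(
            quants_by_regime[name], config.regression_x_cap, config.regression_y_cap
        )
        regressions[name] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "n_points": fit.n_points,
            "r_value": fit.r_value,
        }
    write_json(outdir / "regression.json", regressions)

    fold = estimate_fold_change(
        quants_by_regime["split_array"],
        quants_by_regime["split_array_2x"],
        subset_fraction=config.fold_subset_fraction,
        control=quants_by_regime["split_no_array"],
    )
    fold_payload = {
        "numerator_mean": fold.numerator_mean,
        "denominator_mean": fold.denominator_mean,
        "fold": fold.fold,
        "subset_fraction": fold.subset_fraction,
        "comparison": "split_array_2x / split_array",
        "control": "split_no_array",
    }
    write_json(outdir / "fold_change.json", fold_payload)

    provenance = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": log,
    }
    write_json(outdir / "provenance.json", provenance)
    return {"regressions": regressions, "fold_change": fold_payload, "provenance": provenance}
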