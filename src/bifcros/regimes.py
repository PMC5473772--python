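"""Preset experimental regimes and multi-field simulation helpers.

The four qualitative regimes of a split-reporter operator-array experiment:

======================  ==========================================
regime                  expectation
======================  ==========================================
full-length, no array   bright diffuse cytoplasm, no foci
full-length, + array    bright diffuse cytoplasm plus foci
split, no array         near-autofluorescence, no foci
split, + array          dim cytoplasm, clear foci (low background)
empty vector            autofluorescence only
======================  ==========================================

Populations larger than one comfortable field of view are simulated as a
series of independent fields (as a microscope session would be) and pooled.
Default pool sizes are per-regime: the single full-length fusion is modelled
with a moderate induced pool (300 molecules) while the bicistronic split
system carries a larger pool (2000 pairs) of which only the array-bound and
spontaneously complemented fraction fluoresces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .binding import OccupancyParams
from .quantify import CellQuant, QuantConfig, quantify_measurements
from .segmentation import CellMeasurement, extract_measurements
from .simulate import (
    Construct,
    OpticsNoiseConfig,
    SimCellSpec,
    SyntheticImage,
    render_image,
    sample_population,
)

__all__ = [
    "RegimeSpec",
    "regime",
    "simulate_fields",
    "measure_images",
    "quantify_regime",
    "FULL_LENGTH_POOL",
    "SPLIT_POOL",
    "LIMITING_POOL",
]

#: Induced pool of the single full-length repressor fusion (molecules/cell).
FULL_LENGTH_POOL = 300.0
#: Induced pool of functional split-reporter pairs (pairs/cell).
SPLIT_POOL = 2000.0
#: Reporter pool of the limiting-pool (multicopy plasmid) scenario, chosen
#: well below the total site count of a multicopy array population so arrays
#: titrate the pool rather than the reverse.
LIMITING_POOL = 110.0


@dataclass(frozen=True)
class RegimeSpec:
    """A named experimental condition: construct class plus titration inputs."""

    construct: Construct
    occupancy: OccupancyParams
    name: str = ""


def regime(
    construct: Construct | str,
    n_arrays: int,
    pool_size: float | None = None,
    sites_per_array: int = 64,
    affinity: float = 10.0,
    free_complementation_rate: float = 0.002,
    platform_release_rate: float = 0.0,
) -> RegimeSpec:
    """Build a regime spec; the default pool depends on the construct class."""
    if isinstance(construct, str):
        construct = Construct(construct)
    if pool_size is None:
        pool_size = FULL_LENGTH_POOL if construct is Construct.FULL_LENGTH else SPLIT_POOL
        if construct is Construct.EMPTY:
            pool_size = 0.0
    params = OccupancyParams(
        pool_size=pool_size,
        n_arrays=n_arrays,
        sites_per_array=sites_per_array,
        affinity=affinity,
        free_complementation_rate=free_complementation_rate,
        platform_release_rate=platform_release_rate,
    )
    name = f"{construct.value}_{n_arrays}x"
    return RegimeSpec(construct=construct, occupancy=params, name=name)


def simulate_fields(
    spec: RegimeSpec,
    n_cells: int,
    seed: int,
    optics: OpticsNoiseConfig | None = None,
    cells_per_field: int = 60,
    frame_shape: tuple[int, int] = (512, 512),
    **population_kwargs,
) -> list[SyntheticImage]:
    """Simulate ``n_cells`` of a regime across as many fields as needed.

    Field seeds are spawned from the top-level seed, so images are
    independent but fully reproducible; the optics seed is re-derived per
    field as well.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    optics = optics or OpticsNoiseConfig()
    n_fields = math.ceil(n_cells / cells_per_field)
    children = np.random.SeedSequence(seed).spawn(n_fields)
    images = []
    remaining = n_cells
    for child in children:
        k = min(cells_per_field, remaining)
        remaining -= k
        pop_seed, cam_seed = (int(s) % (2**31) for s in child.generate_state(2))
        cells = sample_population(
            k,
            spec.construct,
            spec.occupancy,
            seed=pop_seed,
            frame_shape=frame_shape,
            **population_kwargs,
        )
        images.append(
            render_image(cells, replace(optics, seed=cam_seed), frame_shape=frame_shape)
        )
    return images


def measure_images(images: list[SyntheticImage]) -> list[CellMeasurement]:
    """Pool ground-truth-mask measurements across fields with unique cell ids."""
    out: list[CellMeasurement] = []
    offset = 0
    for img in images:
        for m in extract_measurements(img.pixels, img.label_mask):
            m.cell_id += offset
            out.append(m)
        offset = out[-1].cell_id if out else offset
    return out


def quantify_regime(
    spec: RegimeSpec,
    n_cells: int,
    seed: int,
    optics: OpticsNoiseConfig | None = None,
    cfg: QuantConfig | None = None,
    **kwargs,
) -> tuple[list[CellMeasurement], list[CellQuant]]:
    """Simulate, measure (ground-truth mask) and quantify one regime."""
    images = simulate_fields(spec, n_cells, seed, optics=optics, **kwargs)
    measurements = measure_images(images)
    quants = quantify_measurements(measurements, cfg or QuantConfig())
    return measurements, quants
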