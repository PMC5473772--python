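"""Seeded synthetic fluorescence microscopy of rod-shaped bacteria.

Renders 16-bit single-channel frames with per-cell ground truth, emulating the
four experimental regimes of a split-reporter operator-array experiment:

* ``FULL_LENGTH``: one repressor fused to an intact fluorophore — the whole
  expressed pool fluoresces, so cells show strong diffuse cytoplasmic signal,
  plus foci where arrays concentrate bound protein.
* ``SPLIT``: two repressors each carrying half of the fluorophore — only
  array-bound (complemented) protein and a small spontaneously self-assembled
  fraction fluoresce, so diffuse signal is near autofluorescence and foci
  dominate.
* ``EMPTY``: autofluorescence only.

Cells are capsules (rectangle plus semicircular caps) of varying area placed
without overlap.  Cytoplasmic fluorescence follows a cylindrical projection
profile (brighter over the cell axis, dimmer at the edges, total conserved);
each array copy contributes one diffraction-blurred focus on the midline whose
photon yield comes from the occupancy model.  The optics/camera chain is:
Gaussian PSF blur, Poisson shot noise, linear gain, offset, Gaussian read
noise, and 16-bit quantisation.  All randomness is seeded.

Geometry is specified in pixels throughout (no physical pixel size is
assumed); photon and count scales are set by the camera parameters.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .binding import OccupancyParams, OccupancyResult, compute_occupancy

__all__ = [
    "Construct",
    "SimCellSpec",
    "OpticsNoiseConfig",
    "SyntheticImage",
    "PlacementError",
    "sample_population",
    "render_image",
    "capsule_area",
]

#: Default mean photon yield of one bound, complemented fluorophore over the
#: exposure (exposure-time differences between strains are absorbed here and
#: in the camera gain).
DEFAULT_BRIGHTNESS_PER_FLUOROPHORE = 25.0
#: Cellular autofluorescence, photons per pixel.
DEFAULT_AUTOFLUORESCENCE = 3.0
#: Cell-to-cell coefficient of variation of expression (lognormal).
DEFAULT_EXPRESSION_CV = 0.3


class Construct(enum.Enum):
    FULL_LENGTH = "full_length"
    SPLIT = "split"
    EMPTY = "empty"


class PlacementError(RuntimeError):
    """Non-overlapping placement failed; the field is too crowded."""


def capsule_area(length: float, width: float) -> float:
    """Area of a rod: rectangle of ``length - width`` plus two semicircular caps."""
    return width * (length - width) + math.pi * (width / 2.0) ** 2


def _length_for_area(area: float, width: float) -> float:
    length = (area - math.pi * (width / 2.0) ** 2) / width + width
    return max(length, width)


@dataclass(frozen=True)
class SimCellSpec:
    """Ground truth for one simulated cell."""

    center: tuple[float, float]  # (row, col)
    length: float
    width: float
    orientation: float  # radians
    area: float
    construct: Construct
    n_arrays: int
    focus_positions: tuple[tuple[float, float], ...]
    diffuse_level: float  # mean photons / pixel over the cell (excl. autofl.)
    focus_photons: float  # photons per focus
    autofluorescence: float  # photons / pixel

    def __post_init__(self) -> None:
        if self.construct is Construct.SPLIT and self.n_arrays == 0 and self.focus_photons != 0:
            raise ValueError("split construct without arrays cannot form foci")
        geo = capsule_area(self.length, self.width)
        if abs(geo - self.area) > 0.10 * max(self.area, 1.0):
            raise ValueError("area inconsistent with rod geometry")

    @property
    def endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Endpoints of the midline segment (the capsule spine)."""
        h = (self.length - self.width) / 2.0
        dy, dx = math.sin(self.orientation) * h, math.cos(self.orientation) * h
        (r, c) = self.center
        return (r - dy, c - dx), (r + dy, c + dx)


@dataclass(frozen=True)
class OpticsNoiseConfig:
    """Microscope optics and camera model (EM-CCD-like defaults)."""

    psf_sigma: float = 1.3  # pixels
    read_noise_sd: float = 2.0  # counts
    gain: float = 20.0  # counts / photon
    offset: float = 10.0  # counts
    bit_depth: int = 16
    seed: int = 0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.read_noise_sd < 0 or self.gain < 0 or self.offset < 0:
            raise ValueError("camera parameters must be nonnegative")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class SyntheticImage:
    """A rendered frame with its ground truth.

    ``pixels`` are quantised camera counts; ``expected_photons`` is the
    noise-free post-PSF photon image (useful for conservation checks and as a
    noiseless rendering); ``label_mask`` assigns pixels to cells (0 =
    background) and ``truth`` holds one row per label.
    """

    pixels: np.ndarray
    label_mask: np.ndarray
    truth: pd.DataFrame
    expected_photons: np.ndarray

    def __post_init__(self) -> None:
        labels = np.unique(self.label_mask)
        labels = labels[labels > 0]
        k = len(labels)
        if k and not np.array_equal(labels, np.arange(1, k + 1)):
            raise ValueError("labels must be contiguous 1..K")
        if k != len(self.truth):
            raise ValueError("truth table must have one row per label")


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between two 2-D segments."""

    def seg_point(p, q, x):
        p, q, x = map(np.asarray, (p, q, x))
        d = q - p
        dd = float(d @ d)
        t = 0.0 if dd == 0 else float(np.clip((x - p) @ d / dd, 0.0, 1.0))
        return float(np.linalg.norm(p + t * d - x))

    def intersects(a, b, c, d):
        def orient(o, p, q):
            v = (p[1] - o[1]) * (q[0] - o[0]) - (p[0] - o[0]) * (q[1] - o[1])
            return (v > 0) - (v < 0)

        o1, o2 = orient(a, b, c), orient(a, b, d)
        o3, o4 = orient(c, d, a), orient(c, d, b)
        return o1 != o2 and o3 != o4

    if intersects(p1, q1, p2, q2):
        return 0.0
    return min(
        seg_point(p1, q1, p2),
        seg_point(p1, q1, q2),
        seg_point(p2, q2, p1),
        seg_point(p2, q2, q1),
    )


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def sample_population(
    n_cells: int,
    construct: Construct,
    occupancy: OccupancyParams | OccupancyResult,
    area_distribution: tuple[float, float] = (250.0, 60.0),
    seed: int = 0,
    *,
    frame_shape: tuple[int, int] = (512, 512),
    width_px: float = 9.0,
    brightness_per_fluorophore: float = DEFAULT_BRIGHTNESS_PER_FLUOROPHORE,
    autofluorescence: float = DEFAULT_AUTOFLUORESCENCE,
    expression_cv: float = DEFAULT_EXPRESSION_CV,
    margin: int = 12,
    min_gap: float = 6.0,
    max_tries: int = 2000,
) -> list[SimCellSpec]:
    """Draw a field of non-overlapping cells with regime-appropriate optics truth.

    ``occupancy`` may be an :class:`OccupancyParams` (the titration is then
    re-solved per cell with the cell's lognormal expression level, so focus
    and diffuse components covary as they do in real populations) or a
    pre-computed :class:`OccupancyResult` (scaled linearly per cell).

    Per construct class: ``FULL_LENGTH`` puts the whole unbound pool into the
    diffuse term; ``SPLIT`` only the spontaneously complemented (plus
    platform-released) fraction; ``EMPTY`` has autofluorescence only.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    mean_area, sd_area = area_distribution
    factors = _lognormal_factors(rng, n_cells, expression_cv)

    placed: list[tuple[tuple[float, float], tuple[float, float], float]] = []
    cells: list[SimCellSpec] = []
    for i in range(n_cells):
        area = float(np.clip(rng.normal(mean_area, sd_area), 0.5 * mean_area, 2.5 * mean_area))
        width = float(width_px * rng.uniform(0.95, 1.05))
        length = _length_for_area(area, width)
        area = capsule_area(length, width)  # keep truth exactly geometric
        half_extent = length / 2.0 + width / 2.0

        lo_r = margin + half_extent
        hi_r = frame_shape[0] - margin - half_extent
        lo_c = margin + half_extent
        hi_c = frame_shape[1] - margin - half_extent
        if hi_r <= lo_r or hi_c <= lo_c:
            raise PlacementError("frame too small for the requested cell size")
        for attempt in range(max_tries):
            center = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            orientation = rng.uniform(0.0, math.pi)
            h = (length - width) / 2.0
            dy, dx = math.sin(orientation) * h, math.cos(orientation) * h
            p = (center[0] - dy, center[1] - dx)
            q = (center[0] + dy, center[1] + dx)
            r = width / 2.0
            ok = all(
                _segment_distance(p, q, p2, q2) >= r + r2 + min_gap
                for p2, q2, r2 in placed
            )
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n_cells} after {max_tries} tries"
            )
        placed.append((p, q, r))

        f = float(factors[i])
        if isinstance(occupancy, OccupancyParams):
            params_i = replace(occupancy, pool_size=occupancy.pool_size * f)
            occ_i = compute_occupancy(params_i)
            pool_i = params_i.pool_size
            n_arrays = occupancy.n_arrays
        else:
            occ_i = OccupancyResult(
                bound_per_array=occupancy.bound_per_array * f,
                total_bound=occupancy.total_bound * f,
                free_complemented=occupancy.free_complemented * f,
                released_fluorescent=occupancy.released_fluorescent * f,
            )
            pool_i = (occupancy.total_bound + occupancy.free_complemented) * f
            n_arrays = 1 if occ_i.total_bound > 0 else 0

        if construct is Construct.EMPTY:
            n_arrays = 0
            focus_photons = 0.0
            diffuse = 0.0
        elif construct is Construct.FULL_LENGTH:
            focus_photons = occ_i.bound_per_array * brightness_per_fluorophore
            unbound = max(pool_i - occ_i.total_bound, 0.0)
            diffuse = unbound * brightness_per_fluorophore / area
        else:  # SPLIT
            focus_photons = occ_i.bound_per_array * brightness_per_fluorophore
            diffuse = occ_i.diffuse_fluorescent * brightness_per_fluorophore / area
        if n_arrays == 0:
            focus_photons = 0.0

        # foci sit on the central 80% of the midline
        foci = []
        for _ in range(n_arrays):
            t = rng.uniform(-0.4, 0.4)
            hh = (length - width) / 2.0
            foci.append(
                (
                    center[0] + math.sin(orientation) * hh * 2 * t,
                    center[1] + math.cos(orientation) * hh * 2 * t,
                )
            )

        cells.append(
            SimCellSpec(
                center=center,
                length=length,
                width=width,
                orientation=orientation,
                area=area,
                construct=construct,
                n_arrays=n_arrays,
                focus_positions=tuple(foci),
                diffuse_level=diffuse,
                focus_photons=focus_photons,
                autofluorescence=autofluorescence,
            )
        )
    return cells


def _rasterize(cells: list[SimCellSpec], frame_shape: tuple[int, int]):
    """Label mask and normalised cytoplasm profile (sums to cell area)."""
    labels = np.zeros(frame_shape, dtype=np.uint16)
    profile = np.zeros(frame_shape, dtype=np.float64)  # per-cell normalised weight
    rows, cols = np.indices(frame_shape)
    for i, cell in enumerate(cells, start=1):
        p, q = cell.endpoints
        r = cell.width / 2.0
        r0 = max(int(min(p[0], q[0]) - r - 1), 0)
        r1 = min(int(max(p[0], q[0]) + r + 2), frame_shape[0])
        c0 = max(int(min(p[1], q[1]) - r - 1), 0)
        c1 = min(int(max(p[1], q[1]) + r + 2), frame_shape[1])
        yy = rows[r0:r1, c0:c1].astype(float)
        xx = cols[r0:r1, c0:c1].astype(float)
        pv = np.array(p)
        d = np.array(q) - pv
        dd = float(d @ d)
        if dd == 0:
            t = np.zeros_like(yy)
        else:
            t = np.clip(((yy - pv[0]) * d[0] + (xx - pv[1]) * d[1]) / dd, 0.0, 1.0)
        dist = np.hypot(yy - (pv[0] + t * d[0]), xx - (pv[1] + t * d[1]))
        inside = dist <= r
        if labels[r0:r1, c0:c1][inside].any():
            raise ValueError("cells overlap; regenerate the population")
        labels[r0:r1, c0:c1][inside] = i
        # cylindrical projection: chord depth falls off toward the edges
        w = np.sqrt(np.clip(1.0 - (dist / r) ** 2, 0.0, None))
        w[~inside] = 0.0
        total = w.sum()
        if total > 0:
            profile[r0:r1, c0:c1] += w * (inside.sum() / total)
    return labels, profile


def _truth_table(cells: list[SimCellSpec], labels: np.ndarray) -> pd.DataFrame:
    counts = np.bincount(labels.ravel(), minlength=len(cells) + 1)
    return pd.DataFrame(
        {
            "label": np.arange(1, len(cells) + 1),
            "center_row": [c.center[0] for c in cells],
            "center_col": [c.center[1] for c in cells],
            "length": [c.length for c in cells],
            "width": [c.width for c in cells],
            "orientation": [c.orientation for c in cells],
            "area": [c.area for c in cells],
            "area_px": counts[1:],
            "construct": [c.construct.value for c in cells],
            "n_arrays": [c.n_arrays for c in cells],
            "n_foci": [len(c.focus_positions) for c in cells],
            "diffuse_level": [c.diffuse_level for c in cells],
            "focus_photons": [c.focus_photons for c in cells],
            "autofluorescence": [c.autofluorescence for c in cells],
        }
    )


def render_image(
    cells: list[SimCellSpec],
    config: OpticsNoiseConfig,
    frame_shape: tuple[int, int] = (512, 512),
) -> SyntheticImage:
    """Render a frame: photons -> PSF -> shot noise -> camera -> 16-bit counts.

    With ``shot_noise=False`` and ``read_noise_sd=0`` the rendering is the
    deterministic expected image; photon totals are conserved by the PSF blur
    as long as cells keep the default margin from the frame border.
    """
    labels, profile = _rasterize(cells, frame_shape)
    # diffuse + autofluorescence follow the cytoplasm depth profile; rescale
    # per cell so integrated photons = (diffuse + autofl) * area exactly
    level_map = np.zeros(frame_shape, dtype=np.float64)
    for i, cell in enumerate(cells, start=1):
        level_map[labels == i] = cell.diffuse_level + cell.autofluorescence
    photons = level_map * profile
    for i, cell in enumerate(cells, start=1):
        mask = labels == i
        tot = photons[mask].sum()
        target = (cell.diffuse_level + cell.autofluorescence) * cell.area
        if tot > 0:
            photons[mask] *= target / tot
    for cell in cells:
        for (fr, fc) in cell.focus_positions:
            r0, c0 = int(round(fr)), int(round(fc))
            if 0 <= r0 < frame_shape[0] and 0 <= c0 < frame_shape[1]:
                photons[r0, c0] += cell.focus_photons

    expected = gaussian_filter(photons, sigma=config.psf_sigma, mode="constant", truncate=4.0)

    rng = np.random.default_rng(config.seed)
    if config.shot_noise:
        detected = rng.poisson(expected).astype(np.float64)
    else:
        detected = expected
    counts = config.gain * detected + config.offset
    if config.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, config.read_noise_sd, size=counts.shape)
    pixels = np.clip(np.rint(counts), 0, config.max_count).astype(np.uint16)

    return SyntheticImage(
        pixels=pixels,
        label_mask=labels.astype(np.int32),
        truth=_truth_table(cells, labels),
        expected_photons=expected,
    )
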