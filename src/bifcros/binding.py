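"""Equilibrium titration of a split-reporter pool against array binding sites.

Each adjacent OL1/UAS pair on a hybrid array is one reconstitution site: when
both repressor fusions bind it, the two halves of the split fluorophore
complement and the site fluoresces.  The cell holds a finite pool of
functional reporter *pairs*; arrays hold a finite number of sites.  Binding is
modelled as a single class of independent, identical sites in equilibrium with
the free pool (no cooperativity), the classic two-reactant mass balance

    bound = K (pool - bound) (sites - bound),     K = affinity

whose closed form is the smaller root of the quadratic

    bound = ((P + S + 1/K) - sqrt((P + S + 1/K)^2 - 4 P S)) / 2

with ``P`` the pool, ``S`` the total site count.  This makes the saturation
argument quantitative: with the pool fixed, total bound signal is concave and
sub-linear in the number of array copies — many arrays dilute the pool over
many sites, so whole-cell fluorescence rises far less than copy number.

A small fraction of the unbound pool self-assembles in the cytoplasm
(``free_complementation_rate``), the residual background of the split system.
An optional "assembly platform" mode (``platform_release_rate``) lets a
fraction of complemented protein leave the array while remaining fluorescent,
adding a bound-proportional diffuse term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OccupancyParams",
    "OccupancyResult",
    "compute_occupancy",
    "expected_focus_brightness",
]


@dataclass(frozen=True)
class OccupancyParams:
    """Inputs of the pool-vs-sites titration.

    All quantities are per cell and dimensionless (molecule / site counts).
    ``affinity`` is the equilibrium constant on the molecule-count scale, i.e.
    ``1/affinity`` is the dissociation constant expressed in molecules per
    cell; the defaults are order-of-magnitude choices for an induced
    repressor-fusion system, not measured values.
    """

    pool_size: float = 2000.0
    n_arrays: int = 1
    sites_per_array: int = 64
    affinity: float = 10.0
    free_complementation_rate: float = 0.002
    platform_release_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pool_size < 0 or self.affinity < 0:
            raise ValueError("pool_size and affinity must be nonnegative")
        if self.n_arrays < 0:
            raise ValueError("n_arrays must be nonnegative")
        if self.sites_per_array < 1:
            raise ValueError("sites_per_array must be >= 1")
        if not (0.0 <= self.free_complementation_rate <= 1.0):
            raise ValueError("free_complementation_rate must be in [0, 1]")
        if not (0.0 <= self.platform_release_rate <= 1.0):
            raise ValueError("platform_release_rate must be in [0, 1]")


@dataclass(frozen=True)
class OccupancyResult:
    """Equilibrium occupancy of one cell's arrays."""

    bound_per_array: float
    total_bound: float
    free_complemented: float
    released_fluorescent: float = 0.0

    @property
    def diffuse_fluorescent(self) -> float:
        """Fluorescent molecules not localised at an array."""
        return self.free_complemented + self.released_fluorescent


def compute_occupancy(params: OccupancyParams) -> OccupancyResult:
    """Solve the pool/site mass balance in closed form.

    Degenerate inputs (zero pool, zero arrays, zero affinity) return zeros
    rather than raising; an infinite affinity returns the hard saturation
    limit ``bound = min(pool, sites)``.
    """
    p = float(params.pool_size)
    s = float(params.n_arrays * params.sites_per_array)
    if p == 0.0 or s == 0.0 or params.affinity == 0.0:
        bound = 0.0
    elif math.isinf(params.affinity):
        bound = min(p, s)
    else:
        kd = 1.0 / params.affinity
        b = p + s + kd
        # smaller root; rearranged for numerical stability when 4ps << b^2
        disc = math.sqrt(b * b - 4.0 * p * s)
        bound = 2.0 * p * s / (b + disc)
        bound = min(bound, p, s)
    free = p - bound
    released = params.platform_release_rate * bound
    return OccupancyResult(
        bound_per_array=(bound - released) / params.n_arrays if params.n_arrays else 0.0,
        total_bound=bound - released,
        free_complemented=params.free_complementation_rate * free,
        released_fluorescent=released,
    )


def expected_focus_brightness(result: OccupancyResult, brightness_per_fluorophore: float) -> float:
    """Expected photon yield of one array focus: linear in occupied sites."""
    if brightness_per_fluorophore < 0:
        raise ValueError("brightness_per_fluorophore must be nonnegative")
    return result.bound_per_array * brightness_per_fluorophore
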