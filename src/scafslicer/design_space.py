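"""Closed-form mathematics of the printable pore-pattern design space.

An FDM woodpile (cross-hatch) scaffold is built from rectangular fibers of
nozzle-width cross-section.  Adjacent fibers (fiber-fiber spacing 0) merge
into struts of width ``k x nozzle_diameter``; repeating the same strut
pattern on consecutive layers stacks fibers into struts whose height
approximates the pore width, which makes the pores isotropic: square
channels of equal width and height in top and side projections.

The repeating unit of such a lattice has in-plane period
``pore_size + strut_width``.  Every strut layer is a set of solid stripes of
width ``strut_width`` per period, so the solid fraction of any layer -- and
therefore of the whole unit cell -- is ``strut_width / (pore + strut)`` and
the design porosity is::

    porosity = pore_size / (pore_size + strut_width)

Porosity and pore size are thereby decoupled: several strut widths (integer
fiber counts) realize different porosities at one pore size, and one
porosity can be realized at several pore sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

__all__ = [
    "PorePattern",
    "DesignPoint",
    "FiberCount",
    "design_porosity",
    "max_porosity",
    "enumerate_design_space",
    "strut_fibers_for_porosity",
    "percent",
]


def percent(fraction: float) -> int:
    """Round a fraction to the nearest whole percent (half rounds up).

    A small epsilon absorbs binary-float artifacts (0.3/0.8 evaluates just
    under 0.375 and must still display as 38%).
    """
    return int(math.floor(fraction * 100.0 + 0.5 + 1e-9))


def design_porosity(pore_size: float, strut_width: float) -> float:
    """Void fraction of the repeating woodpile unit cell.

    Parameters
    ----------
    pore_size : float
        Pore width (= intended pore height) in mm.
    strut_width : float
        Strut width in mm (an integer number of nozzle-width fibers for a
        manufacturable pattern, but any positive width is accepted here).

    Returns
    -------
    float
        ``pore_size / (pore_size + strut_width)``, in (0, 1).
    """
    if pore_size <= 0:
        raise ValueError(f"pore_size must be positive, got {pore_size}")
    if strut_width <= 0:
        raise ValueError(f"strut_width must be positive, got {strut_width}")
    return pore_size / (pore_size + strut_width)


def max_porosity(pore_size: float, nozzle_diameter: float) -> float:
    """Highest porosity achievable at a pore size: a single-fiber strut."""
    return design_porosity(pore_size, nozzle_diameter)


@dataclass(frozen=True)
class PorePattern:
    """One porous microarchitecture.

    Attributes
    ----------
    pore_size : float
        Pore width in mm; the pore height is matched to it by stacking
        ``strut_layer_count`` print layers per strut.
    strut_fiber_count : int
        Number of adjacent nozzle-width fibers forming one strut.
    nozzle_diameter, layer_height : float
        Machine parameters in mm that fix the fiber cross-section.
    """

    pore_size: float
    strut_fiber_count: int = 1
    nozzle_diameter: float = 0.5
    layer_height: float = 0.2

    def __post_init__(self) -> None:
        if self.pore_size <= 0:
            raise ValueError(f"pore_size must be positive, got {self.pore_size}")
        if self.nozzle_diameter <= 0:
            raise ValueError(
                f"nozzle_diameter must be positive, got {self.nozzle_diameter}"
            )
        if self.layer_height <= 0:
            raise ValueError(f"layer_height must be positive, got {self.layer_height}")
        if int(self.strut_fiber_count) != self.strut_fiber_count or self.strut_fiber_count < 1:
            raise ValueError(
                f"strut_fiber_count must be a positive integer, got {self.strut_fiber_count}"
            )

    @property
    def strut_width(self) -> float:
        """Strut width in mm (fiber count x nozzle diameter)."""
        return self.strut_fiber_count * self.nozzle_diameter

    @property
    def strut_layer_count(self) -> int:
        """Print layers stacked per strut: nearest integer to pore/layer.

        Ties round toward more layers; minimum one layer.  Pore sizes that
        are not integer multiples of the layer height therefore get a strut
        height (= realized pore height) that deviates from the pore width;
        ``strut_height`` exposes the realized value.
        """
        return max(1, int(math.floor(self.pore_size / self.layer_height + 0.5)))

    @property
    def strut_height(self) -> float:
        """Realized strut height (= pore height) in mm."""
        return self.strut_layer_count * self.layer_height

    @property
    def in_plane_period(self) -> float:
        """Lattice period in the print plane: pore + strut, mm."""
        return self.pore_size + self.strut_width

    @property
    def z_period(self) -> float:
        """Vertical period: one x-strut block plus one y-strut block, mm."""
        return 2.0 * self.strut_height

    @property
    def porosity(self) -> float:
        """Design porosity of this pattern."""
        return design_porosity(self.pore_size, self.strut_width)

    @classmethod
    def from_porosity(
        cls,
        pore_size: float,
        porosity: float,
        nozzle_diameter: float = 0.5,
        layer_height: float = 0.2,
        max_strut_fibers: int = 32,
    ) -> "PorePattern":
        """Pattern whose achievable porosity is nearest the target."""
        fibers = strut_fibers_for_porosity(
            pore_size, porosity, nozzle_diameter, max_strut_fibers
        )
        return cls(pore_size, fibers.count, nozzle_diameter, layer_height)


@dataclass(frozen=True)
class DesignPoint:
    """A manufacturable (pattern, porosity) pair in the design space."""

    pattern: PorePattern
    porosity: float


class FiberCount(NamedTuple):
    count: int
    porosity: float


def enumerate_design_space(
    nozzle_diameter: float,
    layer_height: float,
    pore_sizes: Sequence[float],
    max_strut_fibers: int,
) -> list[DesignPoint]:
    """All (pore size, fiber count) combinations up to ``max_strut_fibers``.

    Returns design points sorted by pore size, then by descending porosity
    (i.e. ascending fiber count).  At a fixed pore size the porosities are
    strictly decreasing in fiber count, hence distinct.
    """
    if max_strut_fibers < 1:
        raise ValueError(f"max_strut_fibers must be >= 1, got {max_strut_fibers}")
    points = []
    for pore in sorted(pore_sizes):
        for k in range(1, max_strut_fibers + 1):
            pattern = PorePattern(pore, k, nozzle_diameter, layer_height)
            points.append(DesignPoint(pattern, pattern.porosity))
    return points


def strut_fibers_for_porosity(
    pore_size: float,
    target_porosity: float,
    nozzle_diameter: float,
    max_strut_fibers: int = 32,
) -> FiberCount:
    """Invert the porosity formula onto the discrete fiber-count lattice.

    Returns the fiber count whose porosity is nearest the target (ties break
    toward the smaller count, i.e. the higher porosity) together with the
    achieved porosity.  Raises if the target exceeds the single-fiber
    ceiling for this pore size and nozzle.
    """
    if not 0.0 < target_porosity < 1.0:
        raise ValueError(f"target_porosity must be in (0, 1), got {target_porosity}")
    ceiling = max_porosity(pore_size, nozzle_diameter)
    if target_porosity > ceiling + 1e-12:
        raise ValueError(
            f"target porosity {target_porosity:.4f} exceeds the achievable "
            f"ceiling {ceiling:.4f} ({100 * ceiling:.2f}%) for "
            f"{pore_size} mm pores with a {nozzle_diameter} mm nozzle"
        )
    best: FiberCount | None = None
    best_err = math.inf
    for k in range(1, max_strut_fibers + 1):
        phi = design_porosity(pore_size, k * nozzle_diameter)
        err = abs(phi - target_porosity)
        # strictly-less keeps the smaller count (higher porosity) on ties
        if err < best_err - 1e-15:
            best = FiberCount(k, phi)
            best_err = err
    assert best is not None
    return best
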