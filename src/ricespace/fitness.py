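"""Areal grain yield of a simulated canopy: the optimization objective.

The objective is grain biomass per unit ground area, computed over the
inner plants only.  Border plants intercept a surplus of lateral light
(the border effect) and are discarded; each inner plant is attributed a
spacing x spacing ground cell, which makes the fitness independent of
lattice size for a uniform stand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ricecanopy import Canopy

__all__ = ["FitnessResult", "evaluate_fitness"]


@dataclass(frozen=True)
class FitnessResult:
    """Areal grain yield of the inner stand.

    Attributes
    ----------
    grain_biomass : float
        Summed grain biomass of inner (non-border) plants, mol.
    area : float
        Ground area attributed to inner plants, cm^2 (count * spacing^2).
    fitness : float
        grain_biomass / area, mol cm^-2.
    """

    grain_biomass: float
    area: float
    fitness: float

    def __post_init__(self) -> None:
        if self.grain_biomass < 0 or self.area < 0 or self.fitness < 0:
            raise ValueError("FitnessResult fields must be non-negative")


def evaluate_fitness(canopy: Canopy) -> FitnessResult:
    """Grain biomass per unit ground area over inner plants.

    Raises a ``ValueError`` when the lattice has no inner plants.
    """
    inner = ~canopy.border_mask
    n_inner = int(inner.sum())
    if n_inner == 0:
        raise ValueError(
            f"no inner plants on a {canopy.rows}x{canopy.cols} lattice; "
            "rows and cols must each be >= 3"
        )
    grain = float(canopy.grain_biomass()[inner].sum())
    area = n_inner * canopy.spacing**2
    return FitnessResult(grain_biomass=grain, area=area, fitness=grain / area)
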