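"""Poisson statistics of single-cell encapsulation in water-in-oil droplets.

When a dilute cell suspension is emulsified, the number of cells per droplet
is Poisson distributed with mean ``lambda = cell density x droplet volume``.
These routines compute occupancy probabilities, invert empirical empty
fractions back to lambda, handle two-strain co-encapsulation mixtures, and
convert droplet counts into the number of organisms actually interrogated by
a screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "EncapsulationModel",
    "droplet_volume_nl",
    "poisson_pmf",
    "occupied_fraction",
    "estimate_lambda",
    "lambda_from_density",
    "mixture_fractions",
    "expected_cells_analyzed",
    "round_sigfigs",
]

#: cubic micrometres per nanolitre
_UM3_PER_NL = 1e6
#: cubic micrometres per millilitre
_UM3_PER_ML = 1e12


def droplet_volume_nl(diameter_um: float) -> float:
    """Volume of a spherical droplet, in nanolitres: (pi/6) d^3."""
    if diameter_um <= 0:
        raise ValueError(f"droplet diameter must be positive, got {diameter_um}")
    return math.pi / 6.0 * diameter_um**3 / _UM3_PER_NL


@dataclass(frozen=True)
class EncapsulationModel:
    """Per-strain mean loading and the droplet volume they refer to.

    Parameters
    ----------
    lambdas
        Mean cells per droplet for each strain label.
    droplet_diameter_um
        Droplet diameter; the volume is derived as (pi/6) d^3.
    """

    lambdas: dict[str, float]
    droplet_diameter_um: float = 120.0
    droplet_volume_nl: float = field(init=False)

    def __post_init__(self) -> None:
        for name, lam in self.lambdas.items():
            if not math.isfinite(lam) or lam < 0:
                raise ValueError(f"lambda for {name!r} must be finite and >= 0, got {lam}")
        object.__setattr__(
            self, "droplet_volume_nl", droplet_volume_nl(self.droplet_diameter_um)
        )

    @property
    def total_lambda(self) -> float:
        return float(sum(self.lambdas.values()))


def poisson_pmf(k: int, lam: float) -> float:
    """P(K = k) for K ~ Poisson(lam)."""
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a non-negative integer, got {k}")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return float(stats.poisson.pmf(int(k), lam))


def occupied_fraction(lam: float) -> float:
    """Fraction of droplets containing at least one cell: 1 - e^-lambda."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return -math.expm1(-lam)


def estimate_lambda(empty_fraction: float) -> float:
    """Invert an observed empty-droplet fraction to the Poisson mean.

    ``lambda = -ln(P(empty))``; the standard way to check the loading of a
    simulated or measured droplet population.
    """
    if not 0 < empty_fraction <= 1:
        raise ValueError(f"empty fraction must be in (0, 1], got {empty_fraction}")
    return -math.log(empty_fraction)


def lambda_from_density(cells_per_ml: float, droplet_diameter_um: float) -> float:
    """Mean cells per droplet from a hemocytometer count.

    lambda = density x droplet volume, with the volume taken as (pi/6) d^3.
    A density of zero is a valid (empty) suspension.
    """
    if cells_per_ml < 0:
        raise ValueError(f"cell density must be >= 0, got {cells_per_ml}")
    if droplet_diameter_um <= 0:
        raise ValueError(f"droplet diameter must be positive, got {droplet_diameter_um}")
    volume_ml = math.pi / 6.0 * droplet_diameter_um**3 / _UM3_PER_ML
    return cells_per_ml * volume_ml


def mixture_fractions(lam_a: float, lam_b: float) -> dict[str, float]:
    """Occupancy classes for two independently loaded strains.

    Returns the droplet fractions ``{"none", "only_a", "only_b", "both"}``
    under independent Poisson loading; the four fractions sum to 1.
    """
    if lam_a < 0 or lam_b < 0:
        raise ValueError(f"lambdas must be >= 0, got ({lam_a}, {lam_b})")
    p_empty_a = math.exp(-lam_a)
    p_empty_b = math.exp(-lam_b)
    return {
        "none": p_empty_a * p_empty_b,
        "only_a": (1 - p_empty_a) * p_empty_b,
        "only_b": p_empty_a * (1 - p_empty_b),
        "both": (1 - p_empty_a) * (1 - p_empty_b),
    }


def round_sigfigs(x: float, sigfigs: int = 2) -> float:
    """Round to a number of significant figures (headline reporting)."""
    if x == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(x)))
    return round(x, sigfigs - 1 - magnitude)


def expected_cells_analyzed(n_droplets: int, lam: float) -> tuple[float, float]:
    """Expected number of organisms interrogated by a droplet screen.

    Only occupied droplets carry cells, so a run of ``n_droplets`` analyzes
    ``n x (1 - e^-lambda)`` organisms (counting occupied droplets, i.e. at
    least one organism each). Returns ``(exact, rounded)`` where ``rounded``
    is the 2-significant-figure headline value.
    """
    if n_droplets < 0:
        raise ValueError(f"n_droplets must be >= 0, got {n_droplets}")
    exact = n_droplets * occupied_fraction(lam)
    return exact, round_sigfigs(exact, 2)
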