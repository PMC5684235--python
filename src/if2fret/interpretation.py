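"""Structural and thermodynamic interpretation of fitted quantities.

Converts mean FRET efficiencies to inter-fluorophore distances through the
Förster relation (isotropic κ² assumed, R₀ = 55 Å for Cy3–Cy5) and converts
dissociation constants plus total concentrations to predicted equilibrium
occupancies of IF2 on the 30S IC, with or without ligand depletion.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .config import DEFAULT_R0

__all__ = [
    "DistanceEstimate",
    "OccupancyEstimate",
    "efret_to_distance",
    "distance_to_efret",
    "occupancy",
    "occupancy_ratio",
]


@dataclasses.dataclass
class DistanceEstimate:
    efret: float
    r0: float
    distance: float  # Å

    @property
    def distance_rounded(self) -> int:
        return int(round(self.distance))


@dataclasses.dataclass
class OccupancyEstimate:
    kd_nM: float
    if2_total_nM: float
    ic_total_nM: float
    model: str
    theta: float  # bound fraction of 30S IC, in [0, 1]

    @property
    def percent(self) -> float:
        return 100.0 * self.theta


def efret_to_distance(efret: float, r0: float = DEFAULT_R0) -> DistanceEstimate:
    """Donor–acceptor distance d = R₀·(1/E − 1)^(1/6), in Å.

    Strictly decreasing in E with d(0.5) = R₀; undefined at E = 0 or 1.
    """
    if not (0.0 < efret < 1.0):
        raise ValueError(f"E must lie strictly in (0, 1), got {efret}")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    return DistanceEstimate(efret, r0, r0 * (1.0 / efret - 1.0) ** (1.0 / 6.0))


def distance_to_efret(distance: float, r0: float = DEFAULT_R0) -> float:
    """Inverse Förster relation E = 1 / (1 + (d/R₀)⁶)."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    return 1.0 / (1.0 + (distance / r0) ** 6)


def occupancy(
    kd_nM: float,
    if2_total_nM: float = 600.0,
    ic_total_nM: float = 360.0,
    model: Literal["simple", "depletion"] = "depletion",
) -> OccupancyEstimate:
    """Equilibrium fraction of 30S ICs with IF2 bound.

    ``simple`` treats the total IF2 concentration as free:
    θ = L/(L + K_d).  ``depletion`` solves the two-component mass-action
    quadratic B² − B(R + L + K_d) + R·L = 0 (B bound complex, R total 30S
    IC, L total IF2), taking the smaller root, θ = B/R.  The defaults are
    the subunit-joining assay concentrations (600 nM IF2, 360 nM 30S IC).
    """
    if kd_nM <= 0:
        raise ValueError("K_d must be positive")
    if if2_total_nM < 0 or ic_total_nM < 0:
        raise ValueError("concentrations must be non-negative")
    if model == "simple":
        theta = if2_total_nM / (if2_total_nM + kd_nM)
    elif model == "depletion":
        if ic_total_nM == 0:
            raise ValueError("depletion model undefined at zero 30S IC; "
                             "use model='simple'")
        s = ic_total_nM + if2_total_nM + kd_nM
        disc = s * s - 4.0 * ic_total_nM * if2_total_nM
        bound = (s - np.sqrt(disc)) / 2.0
        theta = bound / ic_total_nM
    else:
        raise ValueError(f"unknown model {model!r}")
    return OccupancyEstimate(kd_nM, if2_total_nM, ic_total_nM, model,
                             float(np.clip(theta, 0.0, 1.0)))


def occupancy_ratio(
    kd_a_nM: float,
    kd_b_nM: float,
    if2_total_nM: float = 600.0,
    ic_total_nM: float = 360.0,
    model: Literal["simple", "depletion"] = "depletion",
) -> float:
    """θ(K_d,A) / θ(K_d,B) under one stated binding model."""
    th_a = occupancy(kd_a_nM, if2_total_nM, ic_total_nM, model).theta
    th_b = occupancy(kd_b_nM, if2_total_nM, ic_total_nM, model).theta
    if th_b == 0:
        raise ValueError("denominator occupancy is zero")
    return th_a / th_b
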