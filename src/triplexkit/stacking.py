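"""Mean-field pi-pi stacking metric for the third strand.

Per plane i the third-strand base tilt alpha_i is the angle between the base
ring normal and the Watson-Crick pair normal, folded into [0, 90] degrees.
The effective ring area is

    A_eff_i = A0_i (cos alpha_i - sin alpha_i)

with A0 the aromatic ring area (4.95 A^2 for pyrimidines, 8.29 A^2 for
purines); A_eff_i is forced to zero beyond alpha = 45 degrees (T-shaped
stacking) and whenever the plane forms no in-plane hydrogen bond (H_eff_i =
0), so a detached or flipped-out base contributes nothing.  Step stacking is
the geometric mean of adjacent effective areas and the total their sum:

    S_eff_i = sqrt(A_eff_i A_eff_{i+1}),   S_eff = sum_i S_eff_i
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import chem
from .core import Residue
from .geometry import angle_between, plane_normal

ALPHA_CUTOFF = 45.0  # degrees


@dataclass
class StackingFrame:
    """Per-plane and per-step stacking quantities of one conformation."""

    alpha: list[float]  # degrees, per plane
    a_eff: list[float]  # Angstrom^2, per plane
    s_eff_steps: list[float]  # Angstrom^2, per step (n-1)
    s_eff: float  # Angstrom^2, total


def base_plane_normal(residue: Residue) -> np.ndarray:
    """Unit normal of the base's aromatic ring plane (least squares)."""
    if not residue.has_ring:
        raise ValueError(
            f"residue {residue.base} lacks ring atoms for a plane fit"
        )
    return plane_normal(residue.ring_coords())


def wc_pair_normal(purine: Residue, pyrimidine: Residue) -> np.ndarray:
    """Normal of the Watson-Crick pair, from the pooled ring atoms."""
    coords = np.vstack([purine.ring_coords(), pyrimidine.ring_coords()])
    return plane_normal(coords)


def alpha_angle(third: Residue, purine: Residue, pyrimidine: Residue) -> float:
    """Tilt of the third-strand base against its WC plane, in [0, 90] deg."""
    return angle_between(
        base_plane_normal(third), wc_pair_normal(purine, pyrimidine),
        fold=True,
    )


def effective_area(base: str, alpha: float, h_eff_i: int) -> float:
    """A_eff for one plane; zero beyond 45 degrees or without bonds."""
    if h_eff_i == 0 or alpha > ALPHA_CUTOFF:
        return 0.0
    a0 = chem.BASE_AREA[base]
    return a0 * (math.cos(math.radians(alpha)) - math.sin(math.radians(alpha)))


def effective_stacking(areas: list[float]) -> tuple[float, list[float]]:
    """(S_eff total, per-step S_eff_i) from the per-plane effective areas."""
    if len(areas) < 2:
        warnings.warn("fewer than two planes: no stacking steps")
        return 0.0, []
    steps = [math.sqrt(a * b) for a, b in zip(areas[:-1], areas[1:])]
    return sum(steps), steps


def max_stacking_area(third_bases: list[str]) -> float:
    """Upper bound on S_eff: coplanar, fully bonded third strand."""
    a0 = [chem.BASE_AREA[b] for b in third_bases]
    return sum(math.sqrt(x * y) for x, y in zip(a0[:-1], a0[1:]))


def stacking_frame(model, planes, h_eff_per_plane) -> StackingFrame:
    """Compute alpha/A_eff/S_eff for every plane of a triplex model."""
    alphas = []
    areas = []
    for i in range(planes.n_planes):
        third, pur, pyr = planes.residues(model, i)
        if not (third.has_ring and pur.has_ring and pyr.has_ring):
            warnings.warn(f"plane {i} unusable for stacking; area set to 0")
            alphas.append(float("nan"))
            areas.append(0.0)
            continue
        a = alpha_angle(third, pur, pyr)
        alphas.append(a)
        areas.append(effective_area(third.base, a, h_eff_per_plane[i]))
    total, steps = effective_stacking(areas)
    return StackingFrame(alphas, areas, steps, total)
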