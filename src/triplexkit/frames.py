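"""Standard base reference frames (Tsukuba convention) and frame fitting.

Each base has idealized planar coordinates in the standard reference frame:
origin at the Watson-Crick pair centre, x-axis pointing into the major
groove, y-axis along the long axis towards the strand-I backbone, z-axis out
of the plane (5'->3' sense of strand I).  Fitting the standard coordinates
onto an observed base by least squares yields the base frame used for
base-pair and step parameters.
"""

from __future__ import annotations

import numpy as np

from . import chem
from .geometry import superpose

#: Idealized base-atom coordinates (Angstrom) in the standard reference frame.
STANDARD_BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
        "C1'": (-2.479, 5.346, 0.000),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
        "C1'": (-2.477, 5.399, 0.000),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
        "C1'": (-2.477, 5.402, 0.000),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
        "C1'": (-2.481, 5.354, 0.000),
    },
    "U": {
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000),
        "N3": (-0.302, 2.397, 0.000),
        "C4": (0.989, 2.884, 0.000),
        "O4": (1.935, 2.094, -0.001),
        "C5": (1.089, 4.311, 0.000),
        "C6": (-0.024, 5.053, 0.000),
        "C1'": (-2.481, 5.354, 0.000),
    },
}


def standard_ring_coords(base: str) -> np.ndarray:
    return np.array([STANDARD_BASE_COORDS[base][n]
                     for n in chem.RING_ATOMS[base]])


def fit_base_frame(residue) -> tuple[np.ndarray, np.ndarray]:
    """Fit the standard frame to an observed base.

    Returns ``(origin, R)`` such that a point ``p`` in standard-frame
    coordinates maps to ``origin + R @ p`` in the global frame.
    """
    std = standard_ring_coords(residue.base)
    obs = residue.ring_coords()
    R, t, _ = superpose(std, obs)
    return np.asarray(t), R


def base_pair_frame(res_i, res_ii) -> tuple[np.ndarray, np.ndarray]:
    """Watson-Crick base-pair frame from the strand-I and strand-II bases.

    The strand-II base frame is flipped 180 degrees about its x-axis before
    averaging, per the standard convention.
    """
    o1, r1 = fit_base_frame(res_i)
    o2, r2 = fit_base_frame(res_ii)
    flip = np.diag([1.0, -1.0, -1.0])
    r2f = r2 @ flip
    origin = 0.5 * (o1 + o2)
    rot = _mean_rotation(r1, r2f)
    return origin, rot


def _mean_rotation(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Halfway rotation between two frames (geodesic midpoint)."""
    from scipy.spatial.transform import Rotation

    rel = Rotation.from_matrix(r2 @ r1.T)
    half = Rotation.from_rotvec(rel.as_rotvec() * 0.5)
    return half.as_matrix() @ r1
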