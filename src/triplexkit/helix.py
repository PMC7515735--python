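"""Duplex characterization: step parameters, Zp, A/B classification, RMSD,
base-step overlap area and triplex groove widths.

Base-pair and step frames follow the standard fitted-frame construction:
idealized base coordinates are superposed onto each observed base, strand-II
frames are flipped about x, pair frames averaged, and step parameters read
off the mid-step frame.  Zp is the mean phosphorus z-coordinate in the
mid-step frame (strand II dyad-equivalenced), the classic A/B discriminator:
Zp > 1.5 A and slide < -0.8 A mark A-form steps, Zp < 0.5 A and
slide > -0.8 A mark B-form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .core import Residue, StructureModel
from .frames import base_pair_frame, _mean_rotation
from .geometry import rotation_about_axis, superpose
from .hbond import PURINE_STRAND, PYRIMIDINE_STRAND, THIRD_STRAND

PHOSPHATE_RADIUS_CORRECTION = 5.8  # Angstrom, P van-der-Waals allowance

SLIDE_A_MAX = -0.8  # Angstrom
ZP_A_MIN = 1.5  # Angstrom
ZP_B_MAX = 0.5  # Angstrom


@dataclass
class StepParameters:
    """Parameters of one base-pair step (and its leading base pair)."""

    twist: float  # degrees
    roll: float  # degrees
    tilt: float  # degrees
    shift: float  # Angstrom
    slide: float  # Angstrom
    rise: float  # Angstrom (along mid-frame z)
    helical_twist: float  # degrees
    helical_rise: float  # Angstrom (along local helical axis)
    inclination: float  # degrees, of the leading base pair
    zp: float | None  # Angstrom; None if a flanking P is missing
    overlap_area: float  # Angstrom^2


def duplex_pairs(model: StructureModel) -> list[tuple[Residue, Residue]]:
    """(purine, pyrimidine) residues per plane, 5'->3' along the purines."""
    purines = model.strand(PURINE_STRAND)
    pyrs = model.strand(PYRIMIDINE_STRAND)
    if len(purines) != len(pyrs):
        raise ValueError("duplex strands differ in length")
    n = len(purines)
    return [(purines[i], pyrs[n - 1 - i]) for i in range(n)]


def _signed_angle(u, v, axis) -> float:
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    s = float(np.dot(np.cross(u, v), axis))
    c = float(np.dot(u, v))
    return float(np.degrees(np.arctan2(s, c)))


def _step_frames(f1, f2):
    """Mid-step frame plus (twist, roll, tilt) per the CEHS construction."""
    o1, r1 = f1
    o2, r2 = f2
    z1, z2 = r1[:, 2], r2[:, 2]
    cross = np.cross(z1, z2)
    gamma = _signed_angle(z1, z2, cross / np.linalg.norm(cross)) \
        if np.linalg.norm(cross) > 1e-12 else 0.0
    if np.linalg.norm(cross) > 1e-12:
        hinge = cross / np.linalg.norm(cross)
        r1p = rotation_about_axis(hinge, gamma / 2) @ r1
        r2p = rotation_about_axis(hinge, -gamma / 2) @ r2
    else:
        hinge = r1[:, 1]
        r1p, r2p = r1, r2
    zm = r1p[:, 2]
    twist = _signed_angle(r1p[:, 0], r2p[:, 0], zm)
    rm = rotation_about_axis(zm, twist / 2) @ r1p
    om = 0.5 * (o1 + o2)
    phase = _signed_angle(hinge, rm[:, 1], zm)
    roll = gamma * np.cos(np.radians(phase))
    tilt = gamma * np.sin(np.radians(phase))
    return (om, rm), twist, roll, tilt


def _helical_axis(f1, f2):
    """Local helical axis, twist and rise of one step."""
    from scipy.spatial.transform import Rotation

    o1, r1 = f1
    o2, r2 = f2
    rel = Rotation.from_matrix(r2 @ r1.T)
    rv = rel.as_rotvec()
    ang = np.linalg.norm(rv)
    if ang < 1e-12:
        u = r1[:, 2]
        ang = 0.0
    else:
        u = rv / ang
        if np.dot(u, r1[:, 2]) < 0:
            u, ang = -u, ang  # keep axis along the helix sense
    h_rise = float(np.dot(o2 - o1, u))
    return u, float(np.degrees(ang)), h_rise


def _base_polygon_2d(res: Residue, om, rm) -> Polygon:
    pts = (res.ring_coords() - om) @ rm
    return Polygon(pts[:, :2])


def _pair_polygon(pur: Residue, pyr: Residue, om, rm):
    p1 = _base_polygon_2d(pur, om, rm)
    p2 = _base_polygon_2d(pyr, om, rm)
    merged = p1.union(p2)
    return merged


def _step_overlap(pairs, i, om, rm) -> float:
    try:
        poly1 = _pair_polygon(*pairs[i], om, rm)
        poly2 = _pair_polygon(*pairs[i + 1], om, rm)
    except Exception:
        warnings.warn(f"degenerate base polygon at step {i}; overlap 0")
        return 0.0
    inter = poly1.intersection(poly2)
    return float(inter.area)


def _step_zp(model: StructureModel, i: int, om, rm) -> float | None:
    """Mean mid-frame phosphorus z of step i (strand II sign-flipped)."""
    purines = model.strand(PURINE_STRAND)
    pyrs = model.strand(PYRIMIDINE_STRAND)
    n = len(purines)
    res_i = purines[i + 1]  # 5'-P links purine i -> i+1
    res_ii = pyrs[n - 1 - i]  # 5'-P links the paired pyrimidines
    if not (res_i.has_atom("P") and res_ii.has_atom("P")):
        return None
    z1 = float(((res_i.atom("P").coords - om) @ rm)[2])
    z2 = float(((res_ii.atom("P").coords - om) @ rm)[2])
    return 0.5 * (z1 - z2)


def step_parameters(model: StructureModel) -> list[StepParameters]:
    """Per-step helical parameters of the Watson-Crick duplex part."""
    pairs = duplex_pairs(model)
    usable = [(pur.has_ring and pyr.has_ring) for pur, pyr in pairs]
    frames = [
        base_pair_frame(pur, pyr) if ok else None
        for (pur, pyr), ok in zip(pairs, usable)
    ]
    out: list[StepParameters] = []
    for i in range(len(pairs) - 1):
        if frames[i] is None or frames[i + 1] is None:
            warnings.warn(f"step {i} skipped: unpaired/unusable residues")
            continue
        (om, rm), twist, roll, tilt = _step_frames(frames[i], frames[i + 1])
        delta = frames[i + 1][0] - frames[i][0]
        shift, slide, rise = (delta @ rm).tolist()
        u, h_twist, h_rise = _helical_axis(frames[i], frames[i + 1])
        incl = float(np.degrees(np.arcsin(
            np.clip(np.dot(frames[i][1][:, 1], u), -1.0, 1.0))))
        zp = _step_zp(model, i, om, rm)
        overlap = _step_overlap(pairs, i, om, rm)
        out.append(StepParameters(twist, roll, tilt, shift, slide, rise,
                                  h_twist, h_rise, incl, zp, overlap))
    return out


def zp(model: StructureModel, inner_only: bool = True) -> tuple[float, list[float]]:
    """(mean Zp, per-step Zp).  ``inner_only`` drops the terminal steps."""
    params = step_parameters(model)
    vals = [p.zp for p in params if p.zp is not None]
    if inner_only and len(vals) > 2:
        vals = vals[1:-1]
    if not vals:
        raise ValueError("no step has both flanking phosphorus atoms")
    return float(np.mean(vals)), vals


def classify_form(slide: float, zp_value: float) -> str:
    """A/B/intermediate call from the two discriminating parameters."""
    if slide < SLIDE_A_MAX and zp_value > ZP_A_MIN:
        return "A"
    if slide > SLIDE_A_MAX and zp_value < ZP_B_MAX:
        return "B"
    return "intermediate"


def classify_duplex(model: StructureModel) -> tuple[str, list[str]]:
    """Per-step A/B calls plus the aggregate (mean slide/Zp) call."""
    params = step_parameters(model)
    calls = [
        classify_form(p.slide, p.zp) for p in params if p.zp is not None
    ]
    mean_slide = float(np.mean([p.slide for p in params]))
    mean_zp, _ = zp(model)
    return classify_form(mean_slide, mean_zp), calls


def rmsd(model: StructureModel, reference: StructureModel,
         selection: str = "heavy") -> float:
    """Least-squares superposition RMSD over paired atoms.

    ``selection``: "heavy" (non-hydrogen), "backbone" (P/C1'/O4') or "all".
    Atoms are paired by strand order, residue index and atom name; both
    models must yield the same pairing.
    """
    def pick(m: StructureModel):
        chosen = {}
        for sid, i, res in m.residues():
            for a in res.atoms:
                if selection == "heavy" and a.element == "H":
                    continue
                if selection == "backbone" and a.name not in ("P", "C1'", "O4'"):
                    continue
                chosen[(sid, i, a.name)] = a.coords
        return chosen

    c1, c2 = pick(model), pick(reference)
    keys = sorted(set(c1) & set(c2))
    if not keys or len(keys) != len(c1) or len(keys) != len(c2):
        raise ValueError(
            f"atom pairing mismatch: {len(c1)} vs {len(c2)} atoms, "
            f"{len(keys)} shared"
        )
    x = np.array([c1[k] for k in keys])
    y = np.array([c2[k] for k in keys])
    _, _, value = superpose(x, y)
    return value


def step_overlap_area(model: StructureModel, inner_only: bool = True
                      ) -> tuple[float, list[float]]:
    """(total, per-step) base-pair overlap areas, 3DNA-style projection."""
    params = step_parameters(model)
    areas = [p.overlap_area for p in params]
    chosen = areas[1:-1] if inner_only and len(areas) > 2 else areas
    return float(sum(chosen)), areas


def groove_widths(model: StructureModel) -> dict[str, float]:
    """Three labelled triplex groove widths (minimal P-P minus 5.8 A)."""
    def p_coords(sid):
        return np.array([
            res.atom("P").coords for res in model.strand(sid)
            if res.has_atom("P")
        ])

    pa = p_coords(PURINE_STRAND)
    pb = p_coords(PYRIMIDINE_STRAND)
    pc = p_coords(THIRD_STRAND)

    def min_pp(x, y):
        d = np.linalg.norm(x[:, None, :] - y[None, :, :], axis=-1)
        return float(d.min())

    return {
        "third-purine": min_pp(pc, pa) - PHOSPHATE_RADIUS_CORRECTION,
        "third-pyrimidine": min_pp(pc, pb) - PHOSPHATE_RADIUS_CORRECTION,
        "duplex-minor": min_pp(pa, pb) - PHOSPHATE_RADIUS_CORRECTION,
    }
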