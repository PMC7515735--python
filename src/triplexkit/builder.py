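"""De-novo construction of starting duplex and triplex models.

Duplexes are generated as idealized fiber models: base pairs are placed with
standard-frame geometry, displaced and inclined per helical form, and stacked
with the form's twist and rise.  The third strand of a triplex is docked in
the major groove plane by plane: for each base-triplet type the third base is
positioned in the Watson-Crick pair plane so that the initial hydrogen-bond
template of its H/RH class is satisfied (donor-acceptor distances near the
ideal 2.9 Angstrom, near-linear geometry), then mapped onto every plane by
helix symmetry.  Syn third strands have their sugar/phosphate rotated 180
degrees about the glycosidic bond.

All construction is deterministic: identical inputs give identical
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from . import chem
from .core import Atom, Residue, StructureModel
from .frames import STANDARD_BASE_COORDS
from .geometry import place_by_torsion, plane_normal, rot_x, rot_z, rotation_about_axis
from .hbond import (
    PURINE_STRAND,
    PYRIMIDINE_STRAND,
    THIRD_STRAND,
    TemplateBond,
    plane_assignment,
    template_bonds,
)
from .taxonomy import (
    BondClass,
    Chemistry,
    Glycosidic,
    Orientation,
    Protonation,
    StrandClass,
    TriplexSpec,
    step_types,
)

IDEAL_DONOR_ACCEPTOR = 2.88  # Angstrom
IDEAL_H_ACCEPTOR = 1.93  # Angstrom
CLASH_FLOOR = 2.0  # Angstrom, non-bonded heavy-atom steric floor


@dataclass(frozen=True)
class HelixFormParams:
    """Fiber-model helical parameters and per-nucleotide backbone geometry.

    ``p_local`` is the 5'-phosphorus position in the base standard frame;
    ``chi_anti`` the glycosidic torsion used for anti nucleotides.  The two
    parameter sets are calibrated so that generated duplexes land in the
    published A/B classification windows (slide/Zp).
    """

    form: str
    twist: float  # degrees / step
    rise: float  # Angstrom / step
    x_displacement: float  # Angstrom
    inclination: float  # degrees
    chi_anti: float  # degrees
    p_local: tuple[float, float, float]


FORMS: dict[str, HelixFormParams] = {
    "B": HelixFormParams("B", 36.0, 3.38, 0.0, 0.0, -117.0,
                         (-1.25, 8.91, -1.90)),
    "A": HelixFormParams("A", 32.7, 2.81, -4.40, 19.0, -157.0,
                         (-0.60, 8.80, 0.20)),
}


# -- nucleotide geometry ----------------------------------------------------

def _base_heavy_coords(base: str) -> dict[str, np.ndarray]:
    return {k: np.array(v) for k, v in STANDARD_BASE_COORDS[base].items()}


def base_hydrogen_positions(base: str, coords: dict[str, np.ndarray],
                            protonated_site: str | None = None
                            ) -> dict[str, np.ndarray]:
    """Polar base hydrogens placed from heavy-atom geometry.

    Ring N-H hydrogens go along the external bisector of the adjacent ring
    bonds; amino hydrogens sit in the base plane at +-60 degrees from the
    extended C-N bond.
    """
    out: dict[str, np.ndarray] = {}
    ring = [coords[n] for n in chem.RING_ATOMS[base] if n in coords]
    normal = plane_normal(np.array(ring))

    def ring_nh(n_name: str, nb1: str, nb2: str, h_name: str):
        n = coords[n_name]
        v1 = coords[nb1] - n
        v2 = coords[nb2] - n
        d = -(v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2))
        out[h_name] = n + 1.01 * d / np.linalg.norm(d)

    def amino(n_name: str, c_name: str, h1: str, h2: str):
        n = coords[n_name]
        axis = normal
        v = n - coords[c_name]
        v = v / np.linalg.norm(v)
        for h_name, sign in ((h1, 1.0), (h2, -1.0)):
            R = rotation_about_axis(axis, sign * 60.0)
            out[h_name] = n + 1.01 * (R @ v)

    if base == "A":
        amino("N6", "C6", "H61", "H62")
        if protonated_site == "N1":
            ring_nh("N1", "C2", "C6", "H1")
    elif base == "G":
        ring_nh("N1", "C2", "C6", "H1")
        amino("N2", "C2", "H21", "H22")
    elif base == "C":
        amino("N4", "C4", "H41", "H42")
        if protonated_site == "N3":
            ring_nh("N3", "C2", "C4", "H3")
    elif base in ("T", "U"):
        ring_nh("N3", "C2", "C4", "H3")
    return out


def _nucleotide_local_coords(
    base: str,
    form: HelixFormParams,
    chemistry: str = "DNA",
    glycosidic: str = "anti",
    protonated_site: str | None = None,
) -> dict[str, np.ndarray]:
    """All atoms of one nucleotide in the base standard frame.

    Backbone: P in the fiber position, O4' placed to realize the form's
    anti chi (syn rotates the sugar/phosphate 180 degrees about the
    glycosidic bond, shifting chi by 180).
    """
    coords = _base_heavy_coords(base)
    n_gly = chem.GLYCOSIDIC_N[base]
    chi_ref = chem.CHI_REFERENCE[base]
    c1p = coords["C1'"]
    coords["O4'"] = place_by_torsion(
        coords[chi_ref], coords[n_gly], c1p, 1.42, 108.0, form.chi_anti
    )
    coords["P"] = np.array(form.p_local, dtype=float)
    if chemistry == "RNA":
        c2p = place_by_torsion(coords["O4'"], coords[n_gly], c1p,
                               1.53, 114.0, 145.0)
        coords["C2'"] = c2p
        coords["O2'"] = place_by_torsion(coords[n_gly], c1p, c2p,
                                         1.41, 110.0, -120.0)
    if glycosidic == "syn":
        axis = c1p - coords[n_gly]
        R = rotation_about_axis(axis, 180.0)
        origin = coords[n_gly]
        for name in ("O4'", "P", "C2'", "O2'"):
            if name in coords:
                coords[name] = origin + R @ (coords[name] - origin)
    coords.update(base_hydrogen_positions(base, coords, protonated_site))
    return coords


_ELEMENTS = {"P": "P"}


def _element_of(name: str) -> str:
    if name in _ELEMENTS:
        return _ELEMENTS[name]
    return name[0] if name[0] in ("N", "C", "O", "H") else name[0]


def _make_residue(base: str, chemistry: str, local: dict[str, np.ndarray],
                  transform, protonated_site: str | None = None,
                  glycosidic_state: str | None = None) -> Residue:
    res = Residue(base, chemistry, [], protonated_site, glycosidic_state)
    for name, xyz in local.items():
        res.atoms.append(Atom(name, _element_of(name), transform(xyz)))
    return res


# -- helix placement --------------------------------------------------------

def _pair_frame_transform(i: int, form: HelixFormParams):
    """Map standard-pair-frame coordinates of plane i into the global frame."""
    Rg = rot_z(i * form.twist)
    Ri = rot_x(form.inclination)
    d = np.array([form.x_displacement, 0.0, 0.0])
    t = np.array([0.0, 0.0, i * form.rise])

    def transform(p: np.ndarray) -> np.ndarray:
        return Rg @ (Ri @ np.asarray(p, float) + d) + t

    return transform


_FLIP = np.diag([1.0, -1.0, -1.0])  # 180-degree rotation about x


def build_duplex(
    purine_seq: str,
    form: str = "B",
    chemistries: tuple[str, str] = ("DNA", "DNA"),
) -> StructureModel:
    """Watson-Crick paired antiparallel duplex from the purine sequence.

    ``chemistries`` is (purine strand, pyrimidine strand); the complementary
    pyrimidine strand is generated automatically, with U replacing T when its
    chemistry is RNA.  Strand ids: A (purine), B (pyrimidine).
    """
    purine_seq = purine_seq.upper()
    if set(purine_seq) - {"G", "A"}:
        raise ValueError("purine strand sequence must be over {G, A}")
    fp = FORMS[form]
    chem_r = getattr(chemistries[0], "value", chemistries[0])
    chem_y = getattr(chemistries[1], "value", chemistries[1])
    n = len(purine_seq)
    strand_a: list[Residue] = []
    strand_b: list[Residue] = []
    for i, b in enumerate(purine_seq):
        g = _pair_frame_transform(i, fp)
        local_r = _nucleotide_local_coords(b, fp, chem_r)
        strand_a.append(_make_residue(b, chem_r, local_r, g,
                                      glycosidic_state="anti"))
        comp = chem.watson_crick_partner(b, chem_y)
        local_y = _nucleotide_local_coords(comp, fp, chem_y)
        strand_b.append(_make_residue(
            comp, chem_y, local_y, lambda p, g=g: g(_FLIP @ p),
            glycosidic_state="anti"))
    strand_b.reverse()  # store 5'->3'
    model = StructureModel([(PURINE_STRAND, strand_a),
                            (PYRIMIDINE_STRAND, strand_b)])
    _index_atoms(model)
    return model


def _index_atoms(model: StructureModel) -> None:
    for sid, residues in model.strands:
        for i, res in enumerate(residues):
            for a in res.atoms:
                a.strand_id = sid
                a.residue_index = i


# -- third-strand placement -------------------------------------------------

def _pair_coords_for_duplex(purine: str, pyr: str):
    """Heavy-atom coords of a WC pair in the standard pair frame."""
    coords = {}
    for name, xyz in _base_heavy_coords(purine).items():
        coords[("purine", name)] = xyz
    for name, xyz in _base_heavy_coords(pyr).items():
        coords[("pyrimidine", name)] = xyz @ _FLIP.T
    # hydrogens of the purine (acceptor-angle targets use them indirectly)
    for h, xyz in base_hydrogen_positions(
            purine, _base_heavy_coords(purine)).items():
        coords[("purine", h)] = xyz
    for h, xyz in base_hydrogen_positions(pyr, _base_heavy_coords(pyr)).items():
        coords[("pyrimidine", h)] = xyz @ _FLIP.T
    return coords


def _inplane_transform(params: np.ndarray):
    theta, tx, ty = params

    def tf(p: np.ndarray) -> np.ndarray:
        R = rot_z(np.degrees(theta))
        return R @ p + np.array([tx, ty, 0.0])

    return tf


@lru_cache(maxsize=None)
def _third_base_placement(triplet: str, bond_class_value: str):
    """In-plane pose of the third base satisfying its bond template.

    Returns (placement function local->pair-frame incl. face flip, template).
    Solved once per (triplet, class); H-class bases sit face-up (same sense
    as the duplex purine), RH-class bases are flipped, which is exactly the
    Hoogsteen / reverse-Hoogsteen mirror relation.
    """
    third_sym, rest = triplet.split(".")
    purine, pyr = rest.split(":")
    third_base = third_sym.rstrip("+")
    third_prot = {"C+": "N3", "A+": "N1"}.get(third_sym)
    bonds = template_bonds(triplet, bond_class_value)
    duplex = _pair_coords_for_duplex(purine, pyr)
    face = np.eye(3) if bond_class_value == "H" else _FLIP

    base_local = _base_heavy_coords(third_base)
    h_local = base_hydrogen_positions(third_base, base_local, third_prot)
    all_local = {**base_local, **h_local}
    n_gly = chem.GLYCOSIDIC_N[third_base]

    donors = chem.donors(third_base, third_prot)

    # vectorized residual ingredients
    names = list(all_local)
    idx = {n: k for k, n in enumerate(names)}
    local_arr = np.array([face @ all_local[n] for n in names])
    duplex_heavy = np.array([
        xyz for (role, name), xyz in duplex.items()
        if not name.startswith("H")
    ])
    base_heavy_idx = [idx[n] for n in base_local]
    bond_terms = []  # (third atom idx, partner xyz, [H idxs] or fixed H dist)
    for b in bonds:
        partner = duplex[(b.duplex_role, b.duplex_atom)]
        if b.third_is_donor:
            h_idx = [idx[h] for h in donors[b.third_atom]]
            bond_terms.append((idx[b.third_atom], partner, h_idx, None))
        else:
            d_base = {"purine": purine, "pyrimidine": pyr}[b.duplex_role]
            h_xyz = np.array([
                duplex[(b.duplex_role, h)]
                for h in chem.donors(d_base, None)[b.duplex_atom]
            ])
            bond_terms.append((idx[b.third_atom], partner, None, h_xyz))

    def residuals(params):
        tf = _inplane_transform(params)
        placed = local_arr @ rot_z(np.degrees(params[0])).T \
            + np.array([params[1], params[2], 0.0])
        res = []
        for t_idx, partner, h_idx, h_xyz in bond_terms:
            t = placed[t_idx]
            res.append(np.linalg.norm(t - partner) - IDEAL_DONOR_ACCEPTOR)
            if h_idx is not None:
                hd = np.min(np.linalg.norm(placed[h_idx] - partner, axis=1))
            else:
                hd = np.min(np.linalg.norm(h_xyz - t, axis=1))
            res.append(hd - IDEAL_H_ACCEPTOR)
        # weak radial prior keeps the sugar at backbone radius
        res.append(0.25 * (np.linalg.norm(placed[idx[n_gly]]) - 8.3))
        # steric floor against the duplex heavy atoms (0 beyond 3.0 A)
        d = np.linalg.norm(
            placed[base_heavy_idx][:, None, :] - duplex_heavy[None, :, :],
            axis=-1,
        )
        res.extend(2.0 * np.clip(3.0 - d, 0.0, None).ravel())
        return res

    best = None
    for theta0 in np.linspace(0.0, 2 * np.pi, 9)[:-1]:
        for t0 in ((6.5, 0.0), (8.5, 2.0), (8.5, -2.0), (10.0, 0.0)):
            sol = least_squares(residuals, x0=[theta0, *t0], method="lm",
                                max_nfev=400)
            if best is None or sol.cost < best.cost:
                best = sol
    tf = _inplane_transform(best.x)

    def placement(p: np.ndarray) -> np.ndarray:
        return tf(face @ np.asarray(p, float))

    return placement, tuple(bonds)


def build_triplex(
    spec: TriplexSpec,
    n_repeats: int = 3,
    form: str = "B",
) -> StructureModel:
    """Build a starting triplex model for one enumerated spec.

    Strands: A = duplex purine, B = duplex pyrimidine, C = third strand
    (always DNA).  The third strand is docked in the major groove with every
    plane's template bonds formed and initial tilt alpha ~ 0.
    """
    fp = FORMS[form]
    n = 3 * n_repeats
    purine_seq = "GAA" * n_repeats
    duplex = build_duplex(
        purine_seq, form,
        (spec.duplex_purine_chemistry.value,
         spec.duplex_pyrimidine_chemistry.value),
    )
    types = step_types(spec, n_repeats)
    gly = spec.glycosidic.value
    third_by_plane: list[Residue] = []
    for i, st in enumerate(types):
        third_sym = st.triplet.split(".")[0]
        base = third_sym.rstrip("+")
        prot = {"C+": "N3", "A+": "N1"}.get(third_sym)
        placement, _ = _third_base_placement(st.triplet, st.bond_class.value)
        g = _pair_frame_transform(i, fp)
        local = _nucleotide_local_coords(base, fp, "DNA", gly, prot)

        def tfm(p, g=g, placement=placement):
            return g(placement(p))

        third_by_plane.append(
            _make_residue(base, "DNA", local, tfm, prot, gly)
        )
    if spec.orientation is Orientation.ANTIPARALLEL:
        third_by_plane.reverse()  # store 5'->3'
    model = StructureModel(duplex.strands + [(THIRD_STRAND, third_by_plane)])
    _index_atoms(model)
    _check_clashes(model)
    return model


def _check_clashes(model: StructureModel, floor: float = CLASH_FLOOR) -> None:
    """Warn if non-bonded heavy atoms of different residues come too close."""
    entries = []
    for sid, i, res in model.residues():
        for a in res.atoms:
            if a.element != "H":
                entries.append((sid, i, a))
    coords = np.array([a.coords for _, _, a in entries])
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for j, k in tree.query_pairs(floor):
        sj, ij, aj = entries[j]
        sk, ik, ak = entries[k]
        if sj == sk and abs(ij - ik) <= 1:
            continue  # bonded neighbours along a strand
        warnings.warn(
            f"steric clash {sj}:{ij}:{aj.name} - {sk}:{ik}:{ak.name} at "
            f"{np.linalg.norm(aj.coords - ak.coords):.2f} A"
        )


# -- template-bond refinement ----------------------------------------------

def template_violations(model: StructureModel, spec: TriplexSpec
                        ) -> list[tuple[int, TemplateBond, float]]:
    """Per-plane template bonds whose donor-acceptor distance exceeds 3.5 A."""
    n = len(model.strand(PURINE_STRAND))
    planes = plane_assignment(spec, n)
    types = step_types(spec, n // 3)
    out = []
    for i, st in enumerate(types):
        third, pur, pyr = planes.residues(model, i)
        for b in template_bonds(st.triplet, st.bond_class):
            dres = {"purine": pur, "pyrimidine": pyr}[b.duplex_role]
            d = float(np.linalg.norm(
                third.atom(b.third_atom).coords - dres.atom(b.duplex_atom).coords
            ))
            if d > 3.5:
                out.append((i, b, d))
    return out


def idealize_hbonds(model: StructureModel, spec: TriplexSpec,
                    max_iter: int = 20) -> StructureModel:
    """Rigid-base geometric refinement of the third strand.

    Iteratively moves each third-strand residue as a rigid body (small
    rotation + translation) to shrink template donor-acceptor distance
    violations, a deterministic stand-in for restrained equilibration.
    Returns the best model found; warns if violations stop improving while
    some remain unsatisfiable.
    """
    n = len(model.strand(PURINE_STRAND))
    planes = plane_assignment(spec, n)
    types = step_types(spec, n // 3)
    work = model.copy()

    def n_viol(m):
        return len(template_violations(m, spec))

    best = work.copy()
    best_v = n_viol(best)
    stall = 0
    for _ in range(max_iter):
        if best_v == 0:
            break
        for i, st in enumerate(types):
            third, pur, pyr = planes.residues(work, i)
            bonds = template_bonds(st.triplet, st.bond_class)
            targets = []
            movers = np.array([a.coords for a in third.atoms])
            names = [a.name for a in third.atoms]
            centre = movers.mean(axis=0)
            third_donors = chem.donors(third.base, third.protonated_site)
            for b in bonds:
                dres = {"purine": pur, "pyrimidine": pyr}[b.duplex_role]
                partner = dres.atom(b.duplex_atom).coords
                targets.append((names.index(b.third_atom), partner,
                                IDEAL_DONOR_ACCEPTOR))
                if b.third_is_donor:
                    h_idx = [names.index(h)
                             for h in third_donors[b.third_atom]
                             if h in names]
                    if h_idx:
                        targets.append((h_idx, partner, IDEAL_H_ACCEPTOR))
                else:
                    dup_donors = chem.donors(dres.base, dres.protonated_site)
                    for h in dup_donors.get(b.duplex_atom, ()):
                        if dres.has_atom(h):
                            targets.append((
                                names.index(b.third_atom),
                                dres.atom(h).coords, IDEAL_H_ACCEPTOR))
                            break

            def resid(x):
                rot = rotation_about_axis(
                    np.array([1.0, 0, 0]), np.degrees(x[0])) @ \
                    rotation_about_axis(np.array([0, 1.0, 0]), np.degrees(x[1])) @ \
                    rotation_about_axis(np.array([0, 0, 1.0]), np.degrees(x[2]))
                moved = (movers - centre) @ rot.T + centre + x[3:]
                res = []
                for k, t, ideal in targets:
                    if isinstance(k, list):
                        d = min(np.linalg.norm(moved[j] - t) for j in k)
                    else:
                        d = np.linalg.norm(moved[k] - t)
                    res.append(d - ideal)
                # small-move regularizer (also keeps the system determined)
                res.extend(0.01 * x)
                return res

            sol = least_squares(resid, x0=np.zeros(6), method="lm",
                                max_nfev=100)
            rot = rotation_about_axis(np.array([1.0, 0, 0]), np.degrees(sol.x[0])) @ \
                rotation_about_axis(np.array([0, 1.0, 0]), np.degrees(sol.x[1])) @ \
                rotation_about_axis(np.array([0, 0, 1.0]), np.degrees(sol.x[2]))
            moved = (movers - centre) @ rot.T + centre + sol.x[3:]
            for a, xyz in zip(third.atoms, moved):
                a.coords = xyz
        v = n_viol(work)
        if v < best_v:
            best = work.copy()
            best_v = v
            stall = 0
        else:
            stall += 1
            if stall >= 3:
                break
    if best_v:
        warnings.warn(
            f"{best_v} template bonds remain unsatisfied after refinement"
        )
    return best
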