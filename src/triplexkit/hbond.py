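"""Hydrogen-bond detection, plane assignment and the effective bond number.

Detection uses the trajectory-analysis convention: a bond is recorded for a
donor/acceptor heavy-atom pair when their distance is at most 3.5 Angstrom
and some donor-H-acceptor angle is at least 140 degrees.  The effective
hydrogen-bond number H_eff counts, per base-triplet plane, only the bonds the
third-strand base forms with duplex bases of the *same* plane; inter-plane
and duplex-internal (Watson-Crick) bonds are excluded, since they do not
hold the third strand in triplex register.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import chem
from .core import StructureModel
from .geometry import angle_between
from .taxonomy import Orientation, TriplexSpec, step_types

DISTANCE_CUTOFF = 3.5  # Angstrom, donor-acceptor heavy atoms
ANGLE_CUTOFF = 140.0  # degrees, donor-H-acceptor

#: Conventional strand ids used by the builder.
PURINE_STRAND = "A"
PYRIMIDINE_STRAND = "B"
THIRD_STRAND = "C"


@dataclass(frozen=True)
class HBondRecord:
    donor: tuple[str, int, str]  # (strand_id, residue_index, atom name)
    hydrogen: str
    acceptor: tuple[str, int, str]
    distance: float
    angle: float
    donor_plane: int | None
    acceptor_plane: int | None
    same_plane: bool
    third_strand_involved: bool


@dataclass(frozen=True)
class PlaneAssignment:
    """Plane index -> (third, purine, pyrimidine) residue indices.

    Planes are ordered 5'->3' along the duplex purine strand.  Residue
    indices are 0-based positions within each strand's 5'->3' list.
    """

    n_planes: int
    third: tuple[int, ...]
    purine: tuple[int, ...]
    pyrimidine: tuple[int, ...]

    def plane_of(self, strand_id: str, residue_index: int) -> int | None:
        table = {
            THIRD_STRAND: self.third,
            PURINE_STRAND: self.purine,
            PYRIMIDINE_STRAND: self.pyrimidine,
        }.get(strand_id)
        if table is None:
            return None
        try:
            return table.index(residue_index)
        except ValueError:
            return None

    def residues(self, model: StructureModel, plane: int):
        """(third, purine, pyrimidine) residues of one plane."""
        return (
            model.strand(THIRD_STRAND)[self.third[plane]],
            model.strand(PURINE_STRAND)[self.purine[plane]],
            model.strand(PYRIMIDINE_STRAND)[self.pyrimidine[plane]],
        )


def plane_assignment(spec: TriplexSpec, n_planes: int) -> PlaneAssignment:
    """Default plane assignment for a builder-produced triplex.

    The purine strand runs with the plane order; the pyrimidine strand and an
    antiparallel third strand run against it.
    """
    purine = tuple(range(n_planes))
    pyrimidine = tuple(n_planes - 1 - i for i in range(n_planes))
    if spec.orientation is Orientation.PARALLEL:
        third = purine
    else:
        third = pyrimidine
    return PlaneAssignment(n_planes, third, purine, pyrimidine)


# -- bond templates ---------------------------------------------------------

@dataclass(frozen=True)
class TemplateBond:
    third_atom: str
    duplex_role: str  # "purine" | "pyrimidine"
    duplex_atom: str
    third_is_donor: bool


def _load_raw():
    path = resources.files("triplexkit.data") / "hbond_templates.json"
    return json.loads(path.read_text())


_RAW = _load_raw()


def _bond_from_entry(entry, third_base: str, third_prot: str | None,
                     duplex_base_of_role) -> TemplateBond:
    third_atom, role, duplex_atom = entry
    duplex_base = duplex_base_of_role(role)
    third_donors = chem.donors(third_base, third_prot)
    duplex_donors = chem.donors(duplex_base, None)
    if third_atom in third_donors and duplex_atom in chem.acceptors(duplex_base, None):
        third_is_donor = True
    elif duplex_atom in duplex_donors and third_atom in chem.acceptors(third_base, third_prot):
        third_is_donor = False
    else:
        raise ValueError(
            f"template bond {third_atom}({third_base})-{duplex_atom}"
            f"({duplex_base}) is not a legal donor/acceptor pair"
        )
    return TemplateBond(third_atom, role, duplex_atom, third_is_donor)


def _split_triplet(triplet: str) -> tuple[str, str, str]:
    third, rest = triplet.split(".")
    purine, pyr = rest.split(":")
    return third, purine, pyr


def template_bonds(triplet: str, bond_class) -> list[TemplateBond]:
    """Initial template bonds for a triplet like ``C+.G:C`` of class H/RH."""
    third, purine, pyr = _split_triplet(triplet)
    key = f"{third}.{purine}|{getattr(bond_class, 'value', bond_class)}"
    try:
        entries = _RAW["templates"][key]
    except KeyError:
        raise KeyError(f"no hydrogen-bond template for {key}")
    third_base = third.rstrip("+")
    third_prot = {"C+": "N3", "A+": "N1"}.get(third)
    role_base = {"purine": purine, "pyrimidine": pyr}
    return [
        _bond_from_entry(e, third_base, third_prot, role_base.__getitem__)
        for e in entries
    ]


def variant_patterns(triplet: str) -> dict[str, frozenset]:
    """Named variant patterns (atom-pair sets) for a triplet's base pair."""
    third, purine, _ = _split_triplet(triplet)
    raw = _RAW["variants"].get(f"{third.rstrip('+')}" f".{purine}", {})
    # fall back on the protonated key if present
    raw = _RAW["variants"].get(f"{third}.{purine}", raw)
    return {
        name: frozenset((t, role, d) for t, role, d in entries)
        for name, entries in raw.items()
    }


def max_plane_bonds(triplet: str) -> int:
    """Chemical upper bound on H_eff_i for one triplet.

    Counts every legal donor/acceptor heavy-atom pairing between the
    third-strand base and either duplex base of the plane, regardless of
    geometry.
    """
    third_sym, purine, pyr = _split_triplet(triplet)
    third_base = third_sym.rstrip("+")
    third_prot = {"C+": "N3", "A+": "N1"}.get(third_sym)
    t_donors = chem.donors(third_base, third_prot)
    t_accs = chem.acceptors(third_base, third_prot)
    n = 0
    for dup in (purine, pyr):
        n += len(t_donors) * len(chem.acceptors(dup, None))
        n += len(chem.donors(dup, None)) * len(t_accs)
    return n


def template_bond_count(spec: TriplexSpec, n_repeats: int = 3) -> int:
    """Theoretical maximum H_eff: total template bonds over all planes."""
    return sum(
        len(template_bonds(st.triplet, st.bond_class))
        for st in step_types(spec, n_repeats)
    )


# -- detection --------------------------------------------------------------

def _residue_hb_atoms(res):
    """(donors, acceptors) for one residue: donor -> hydrogens present."""
    donors = {}
    for heavy, hyds in chem.donors(res.base, res.protonated_site).items():
        if res.has_atom(heavy):
            present = tuple(h for h in hyds if res.has_atom(h))
            donors[heavy] = present
    accs = tuple(a for a in chem.acceptors(res.base, res.protonated_site)
                 if res.has_atom(a))
    return donors, accs


def detect_hbonds(
    model: StructureModel,
    planes: PlaneAssignment | None = None,
    strict: bool = False,
) -> list[HBondRecord]:
    """All base-base hydrogen bonds satisfying both cutoffs.

    One record per donor/acceptor heavy-atom pair (a bifurcated donor yields
    one record per acceptor), using the best-angle hydrogen.  Records are
    ordered by (donor strand, residue, atom, acceptor strand, residue, atom).
    """
    residues = [(sid, i, res) for sid, i, res in model.residues()]
    records: list[HBondRecord] = []
    for sid_d, i_d, res_d in residues:
        donors, _ = _residue_hb_atoms(res_d)
        for heavy, hyds in sorted(donors.items()):
            if not hyds:
                msg = (f"donor {heavy} of {res_d.base} ({sid_d}:{i_d}) has "
                       f"no hydrogen; skipped")
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg)
                continue
            d_xyz = res_d.atom(heavy).coords
            for sid_a, i_a, res_a in residues:
                if sid_a == sid_d and i_a == i_d:
                    continue
                _, accs = _residue_hb_atoms(res_a)
                for acc in accs:
                    a_xyz = res_a.atom(acc).coords
                    dist = float(np.linalg.norm(a_xyz - d_xyz))
                    if dist > DISTANCE_CUTOFF:
                        continue
                    best = None
                    for h in hyds:
                        h_xyz = res_d.atom(h).coords
                        ang = angle_between(d_xyz - h_xyz, a_xyz - h_xyz)
                        if best is None or ang > best[1]:
                            best = (h, ang)
                    if best is None or best[1] < ANGLE_CUTOFF:
                        continue
                    dp = planes.plane_of(sid_d, i_d) if planes else None
                    ap = planes.plane_of(sid_a, i_a) if planes else None
                    records.append(HBondRecord(
                        donor=(sid_d, i_d, heavy),
                        hydrogen=best[0],
                        acceptor=(sid_a, i_a, acc),
                        distance=dist,
                        angle=best[1],
                        donor_plane=dp,
                        acceptor_plane=ap,
                        same_plane=(dp is not None and dp == ap),
                        third_strand_involved=(THIRD_STRAND in (sid_d, sid_a)),
                    ))
    records.sort(key=lambda r: (r.donor, r.acceptor))
    return records


def effective_hbond_number(
    model: StructureModel,
    planes: PlaneAssignment,
    records: list[HBondRecord] | None = None,
) -> tuple[int, list[int]]:
    """(H_eff total, per-plane H_eff_i).

    Counts bonds joining the third-strand base of plane i to a duplex base of
    the same plane i; everything else (Watson-Crick, inter-plane, bonds
    within the third strand) is excluded.
    """
    if records is None:
        records = detect_hbonds(model, planes)
    per_plane = [0] * planes.n_planes
    for rec in records:
        if not rec.third_strand_involved or not rec.same_plane:
            continue
        sid_d, _, _ = rec.donor
        sid_a, _, _ = rec.acceptor
        # exactly one side on the third strand (no third-third same-plane)
        if (sid_d == THIRD_STRAND) == (sid_a == THIRD_STRAND):
            continue
        per_plane[rec.donor_plane] += 1
    return sum(per_plane), per_plane


# -- per-plane pattern classification ---------------------------------------

def plane_bond_set(records: list[HBondRecord], planes: PlaneAssignment,
                   plane: int, model: StructureModel) -> frozenset:
    """Observed same-plane third/duplex atom pairs of one plane.

    Pairs are expressed as (third atom, duplex role, duplex atom), the
    representation used by templates and variants.
    """
    pairs = set()
    for rec in records:
        if not (rec.third_strand_involved and rec.same_plane):
            continue
        if rec.donor_plane != plane:
            continue
        if rec.donor[0] == THIRD_STRAND and rec.acceptor[0] != THIRD_STRAND:
            third_atom = rec.donor[2]
            duplex_sid, duplex_atom = rec.acceptor[0], rec.acceptor[2]
        elif rec.acceptor[0] == THIRD_STRAND and rec.donor[0] != THIRD_STRAND:
            third_atom = rec.acceptor[2]
            duplex_sid, duplex_atom = rec.donor[0], rec.donor[2]
        else:
            continue
        role = "purine" if duplex_sid == PURINE_STRAND else "pyrimidine"
        pairs.add((third_atom, role, duplex_atom))
    return frozenset(pairs)


def classify_plane_pattern(
    bond_set: frozenset, triplet: str, bond_class
) -> tuple[str, str]:
    """Classify one plane's bond set -> (pattern id, flag).

    flag is ``initial`` (matches the triplet's starting template),
    ``variant`` (matches a named recurring pattern), ``none`` (no bonds) or
    ``new`` (anything else, reported verbatim).
    """
    if not bond_set:
        return "none", "none"
    tmpl = frozenset(
        (b.third_atom, b.duplex_role, b.duplex_atom)
        for b in template_bonds(triplet, bond_class)
    )
    cls = getattr(bond_class, "value", bond_class)
    if bond_set == tmpl:
        third, purine, _ = _split_triplet(triplet)
        return f"{third}.{purine}|{cls}-initial", "initial"
    for name, pattern in variant_patterns(triplet).items():
        if bond_set == pattern:
            return name, "variant"
    desc = "+".join(f"{t}-{d}({r[:3]})" for t, r, d in sorted(bond_set))
    return f"new:{desc}", "new"


def pattern_timeline(
    trajectory: list[StructureModel],
    planes: PlaneAssignment,
    plane: int,
    triplet: str,
    bond_class,
) -> tuple[list[str], dict[str, float]]:
    """Per-frame pattern ids for one plane, plus occupancy fractions.

    Occupancies sum to 1 over the observed patterns.
    """
    if not trajectory:
        raise ValueError("pattern_timeline needs at least one frame")
    ids = []
    for frame in trajectory:
        records = detect_hbonds(frame, planes)
        bs = plane_bond_set(records, planes, plane, frame)
        pid, _ = classify_plane_pattern(bs, triplet, bond_class)
        ids.append(pid)
    occ: dict[str, float] = {}
    for pid in ids:
        occ[pid] = occ.get(pid, 0.0) + 1.0 / len(ids)
    return ids, occ
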