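"""Base chemistry tables shared across modules.

Atom names follow PDB v3 nucleic-acid conventions.  Only base atoms (plus the
base hydrogens the builder generates) take part in hydrogen-bond detection;
sugar/phosphate atoms are carried for helical and groove geometry.
"""

from __future__ import annotations

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "T", "U"})

#: Ring perimeter atoms in outline order (used for plane fits and overlap
#: polygons).  Purines trace the fused-ring perimeter.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Aromatic ring area A0 in Å^2 (one value per base class; published
#: estimates from the molecular structure).
BASE_AREA: dict[str, float] = {
    "A": 8.29,
    "G": 8.29,
    "C": 4.95,
    "T": 4.95,
    "U": 4.95,  # pyrimidine value; U matches T without the methyl
}

#: Glycosidic nitrogen per base.
GLYCOSIDIC_N: dict[str, str] = {
    "A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1",
}

#: Base atom defining the chi torsion together with O4'-C1'-N:
#: chi = O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines).
CHI_REFERENCE: dict[str, str] = {
    "A": "C4", "G": "C4", "C": "C2", "T": "C2", "U": "C2",
}

#: Hydrogen-bond donors: heavy atom -> hydrogens carried, per base.
#: Protonation (C+ at N3, A+ at N1) adds a donor.
BASE_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N6": ("H61", "H62")},
    "G": {"N1": ("H1",), "N2": ("H21", "H22")},
    "C": {"N4": ("H41", "H42")},
    "T": {"N3": ("H3",)},
    "U": {"N3": ("H3",)},
}

PROTONATION_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    # residue.protonated_site value -> extra donor
    "N3": {"N3": ("H3",)},  # cytosine C+
    "N1": {"N1": ("H1",)},  # adenine A+
}

#: Hydrogen-bond acceptors per base (base atoms only).
BASE_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7"),
    "G": ("O6", "N3", "N7"),
    "C": ("O2", "N3"),
    "T": ("O2", "O4"),
    "U": ("O2", "O4"),
}


def acceptors(base: str, protonated_site: str | None) -> tuple[str, ...]:
    """Acceptor atoms of a base; a protonated site stops accepting."""
    accs = BASE_ACCEPTORS[base]
    if protonated_site:
        accs = tuple(a for a in accs if a != protonated_site)
    return accs


def donors(base: str, protonated_site: str | None) -> dict[str, tuple[str, ...]]:
    """Donor heavy atoms -> hydrogen names, including any protonation site."""
    d = dict(BASE_DONORS[base])
    if protonated_site:
        d.update(PROTONATION_DONORS[protonated_site])
    return d


#: PDB residue names.
RESNAME: dict[tuple[str, str], str] = {
    ("A", "DNA"): "DA", ("G", "DNA"): "DG", ("C", "DNA"): "DC",
    ("T", "DNA"): "DT",
    ("A", "RNA"): "A", ("G", "RNA"): "G", ("C", "RNA"): "C",
    ("U", "RNA"): "U",
}

RESNAME_TO_BASE: dict[str, tuple[str, str]] = {
    v: k for k, v in RESNAME.items()
}
# tolerated aliases
RESNAME_TO_BASE.update({
    "DU": ("U", "DNA"),  # not produced, but parseable
    "RA": ("A", "RNA"), "RG": ("G", "RNA"), "RC": ("C", "RNA"),
    "RU": ("U", "RNA"),
    "DCP": ("C", "DNA"), "DAP": ("A", "DNA"),  # protonated-name variants
})


def watson_crick_partner(base: str, chemistry: str) -> str:
    """Complementary base on the opposite strand of a WC duplex."""
    pairs = {"G": "C", "C": "G", "A": "T" if chemistry == "DNA" else "U",
             "T": "A", "U": "A"}
    return pairs[base]
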