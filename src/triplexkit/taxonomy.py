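"""Enumeration, naming and symmetry of GAA/TTC triplex topologies.

A triplex here is a Watson-Crick GAA:TTC duplex plus a third strand bound in
the major groove.  The third strand is either the all-purine GAA repeat (class
``R``) or the all-pyrimidine TTC repeat (class ``Y``), runs parallel or
antiparallel to the duplex purine strand, may be register-shifted by one
nucleotide, may carry protonated cytosines (N3) or one protonated adenine (N1)
per repeat, and has its bases either all *anti* or all *syn* about the
glycosidic bond.  Eight base topologies exist; doubling over the glycosidic
state gives the canonical set of 16 pure-DNA triplexes.  Three further hybrid
topologies (collapsed R-loops) place an RNA strand inside the duplex.

Each base-triplet plane of a triplex carries a Hoogsteen-like (``H``) or
reverse-Hoogsteen-like (``RH``) bond pattern.  Two symmetry maps relate the
specs: *conformational* counterparts (third-strand direction and glycosidic
state both flipped; bond types preserved) and *directional* counterparts
(direction flipped only; H and RH swap).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum


class Chemistry(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class StrandClass(str, Enum):
    R = "R"  # purine GAA third strand
    Y = "Y"  # pyrimidine TTC third strand


class Orientation(str, Enum):
    PARALLEL = "parallel"
    ANTIPARALLEL = "antiparallel"


class Protonation(str, Enum):
    NONE = "none"
    CYTOSINE = "cytosine"  # N3-protonated C+
    ADENINE = "adenine"  # N1-protonated A+


class Glycosidic(str, Enum):
    ANTI = "anti"
    SYN = "syn"


class BondClass(str, Enum):
    H = "H"
    RH = "RH"


@dataclass(frozen=True)
class TriplexSpec:
    """Symbolic description of one triplex topology."""

    third_strand_class: StrandClass
    orientation: Orientation
    shifted: bool
    protonation: Protonation
    glycosidic: Glycosidic
    duplex_purine_chemistry: Chemistry = Chemistry.DNA
    duplex_pyrimidine_chemistry: Chemistry = Chemistry.DNA

    def __post_init__(self) -> None:
        if self.third_strand_class is StrandClass.Y:
            if self.protonation is not Protonation.CYTOSINE:
                raise ValueError(
                    "Y third strands must carry protonated cytosines; the "
                    "unprotonated pyrimidine triplexes are excluded as "
                    "unstable/marginal"
                )
            # The antiparallel pyrimidine strand is intrinsically shifted by
            # one nucleotide so that its C+ can reach the duplex guanines.
            expected = self.orientation is Orientation.ANTIPARALLEL
            if self.shifted != expected:
                raise ValueError(
                    "Y third strands are shifted exactly when antiparallel"
                )
        if self.protonation is Protonation.ADENINE:
            if self.third_strand_class is not StrandClass.R:
                raise ValueError("adenine protonation requires an R third strand")

    # -- derived properties -------------------------------------------------

    @property
    def is_hybrid(self) -> bool:
        return Chemistry.RNA in (
            self.duplex_purine_chemistry,
            self.duplex_pyrimidine_chemistry,
        )

    @property
    def label(self) -> str:
        return format_label(self)

    @property
    def bond_class(self) -> BondClass:
        """H/RH type of every plane of this spec (uniform within a spec).

        A parallel third strand with *anti* bases presents the Hoogsteen
        face; flipping either the strand direction or the glycosidic state
        flips the face (H <-> RH); flipping both restores it.
        """
        parallel = self.orientation is Orientation.PARALLEL
        anti = self.glycosidic is Glycosidic.ANTI
        return BondClass.H if parallel == anti else BondClass.RH

    @property
    def register_offset(self) -> int:
        """Offset of the third-strand repeat phase against the duplex GAA.

        With offset 0 an R strand pairs G-over-G / A-over-A; with offset 1 it
        pairs A-over-G / G-over-A.  A label shift ("-S") advances the register
        for a parallel strand, but for an antiparallel strand the direction
        reversal itself advances it, so the unshifted antiparallel strand
        already sits at offset 1 (hence the pR <-> apR-S pairings).
        """
        if self.third_strand_class is StrandClass.Y:
            return 0
        parallel = self.orientation is Orientation.PARALLEL
        effectively_shifted = self.shifted if parallel else not self.shifted
        return 1 if effectively_shifted else 0


@dataclass(frozen=True)
class TripleStepType:
    """One base-triplet plane type, e.g. ('C+.G:C', H)."""

    triplet: str
    bond_class: BondClass

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.bond_class.value}-type {self.triplet}"


# The eight base topologies (third-strand class, orientation, shifted,
# protonation), in the canonical documented order: lexicographic by
# (class, orientation, shifted, protonation).
_BASE_TOPOLOGIES = (
    # R, antiparallel
    (StrandClass.R, Orientation.ANTIPARALLEL, False, Protonation.NONE),  # apR
    (StrandClass.R, Orientation.ANTIPARALLEL, False, Protonation.ADENINE),  # apR(+)
    (StrandClass.R, Orientation.ANTIPARALLEL, True, Protonation.NONE),  # apR-S
    # R, parallel
    (StrandClass.R, Orientation.PARALLEL, False, Protonation.NONE),  # pR
    (StrandClass.R, Orientation.PARALLEL, True, Protonation.NONE),  # pR-S
    (StrandClass.R, Orientation.PARALLEL, True, Protonation.ADENINE),  # pR(+)-S
    # Y
    (StrandClass.Y, Orientation.ANTIPARALLEL, True, Protonation.CYTOSINE),  # apY
    (StrandClass.Y, Orientation.PARALLEL, False, Protonation.CYTOSINE),  # pY
)

# Topology partner under direction reversal, keyed by (class, orientation,
# shifted, protonation).  Reversing the third strand direction at fixed
# triplet register maps pR <-> apR-S, pR-S <-> apR, pR(+)-S <-> apR(+) and
# pY <-> apY (the antiparallel Y being intrinsically shifted).
def _partner_topology(
    topo: tuple[StrandClass, Orientation, bool, Protonation],
) -> tuple[StrandClass, Orientation, bool, Protonation]:
    cls, orient, shifted, prot = topo
    flipped = (
        Orientation.ANTIPARALLEL
        if orient is Orientation.PARALLEL
        else Orientation.PARALLEL
    )
    if cls is StrandClass.Y:
        return (cls, flipped, flipped is Orientation.ANTIPARALLEL, prot)
    # R strand: preserve the register offset, hence toggle the shift flag.
    return (cls, flipped, not shifted, prot)


def enumerate_dna_triplexes() -> list[TriplexSpec]:
    """The 16 canonical pure-DNA triplex specs (8 topologies x anti/syn).

    Order is deterministic: lexicographic by (class, orientation, shift,
    protonation, glycosidic).
    """
    specs = []
    for cls, orient, shifted, prot in _BASE_TOPOLOGIES:
        for gly in (Glycosidic.ANTI, Glycosidic.SYN):
            specs.append(
                TriplexSpec(
                    third_strand_class=cls,
                    orientation=orient,
                    shifted=shifted,
                    protonation=prot,
                    glycosidic=gly,
                )
            )
    return specs


def enumerate_hybrid_triplexes() -> list[TriplexSpec]:
    """The three DNA.RNA:DNA hybrid triplexes (collapsed R-loops).

    Keeping the two DNA strands antiparallel to each other admits only
    apY = d(TTC+).d(GAA):r(UUC), pR = d(GAA).r(GAA):d(TTC) and its
    adenine-protonated shifted variant pR(+)-S = d(GA+A).r(GAA):d(TTC);
    all bases anti.
    """
    apy = TriplexSpec(
        third_strand_class=StrandClass.Y,
        orientation=Orientation.ANTIPARALLEL,
        shifted=True,
        protonation=Protonation.CYTOSINE,
        glycosidic=Glycosidic.ANTI,
        duplex_purine_chemistry=Chemistry.DNA,
        duplex_pyrimidine_chemistry=Chemistry.RNA,
    )
    pr = TriplexSpec(
        third_strand_class=StrandClass.R,
        orientation=Orientation.PARALLEL,
        shifted=False,
        protonation=Protonation.NONE,
        glycosidic=Glycosidic.ANTI,
        duplex_purine_chemistry=Chemistry.RNA,
        duplex_pyrimidine_chemistry=Chemistry.DNA,
    )
    prs_plus = replace(pr, shifted=True, protonation=Protonation.ADENINE)
    return [apy, pr, prs_plus]


# -- label grammar ----------------------------------------------------------

_LABEL_RE = re.compile(
    r"^(?P<orient>ap|p)(?P<cls>[RY])(?P<prot>\(\+\))?(?P<shift>-S)?"
    r"\((?P<gly>[as])\)$"
)


def format_label(spec: TriplexSpec) -> str:
    """Canonical label, e.g. ``pR(+)-S(a)``.

    The "-S" suffix is reserved for R strands; the antiparallel Y strand is
    intrinsically shifted and carries no suffix.  Cytosine protonation of Y
    strands is implied and not written.
    """
    parts = ["p" if spec.orientation is Orientation.PARALLEL else "ap"]
    parts.append(spec.third_strand_class.value)
    if spec.protonation is Protonation.ADENINE:
        parts.append("(+)")
    if spec.shifted and spec.third_strand_class is StrandClass.R:
        parts.append("-S")
    parts.append("(a)" if spec.glycosidic is Glycosidic.ANTI else "(s)")
    return "".join(parts)


class LabelError(ValueError):
    """Raised for labels outside the grammar or the enumerated sets."""


def parse_label(label: str, hybrid: bool = False) -> TriplexSpec:
    """Parse a label back into its spec.

    With ``hybrid=True`` the label is resolved within the three-member hybrid
    set (same grammar, different strand chemistries); otherwise within the
    canonical 16-member pure-DNA set.  Labels that fit the grammar but name a
    topology outside the enumerated set (e.g. ``pY-S(a)``) are rejected.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        # point at the first token that breaks the grammar
        offending = label
        for tok_re in (r"^(ap|p)", r"^(ap|p)[RY]"):
            if not re.match(tok_re, label):
                break
            offending = label[re.match(tok_re, label).end():]
        raise LabelError(f"malformed triplex label {label!r}: near {offending!r}")
    pool = enumerate_hybrid_triplexes() if hybrid else enumerate_dna_triplexes()
    for spec in pool:
        if spec.label == label:
            return spec
    raise LabelError(
        f"label {label!r} is grammatical but outside the enumerated "
        f"{'hybrid' if hybrid else 'DNA'} set"
    )


# -- symmetry maps ----------------------------------------------------------

def _topology_of(spec: TriplexSpec):
    return (
        spec.third_strand_class,
        spec.orientation,
        spec.shifted,
        spec.protonation,
    )


def _require_dna(spec: TriplexSpec) -> None:
    if spec.is_hybrid or _topology_of(spec) not in _BASE_TOPOLOGIES:
        raise ValueError(f"{spec.label} is not in the enumerated pure-DNA set")


def conformational_counterpart(spec: TriplexSpec) -> TriplexSpec:
    """Flip third-strand direction AND glycosidic state; bond types persist."""
    _require_dna(spec)
    cls, orient, shifted, prot = _partner_topology(_topology_of(spec))
    gly = Glycosidic.SYN if spec.glycosidic is Glycosidic.ANTI else Glycosidic.ANTI
    return replace(
        spec, orientation=orient, shifted=shifted, glycosidic=gly
    )


def directional_counterpart(spec: TriplexSpec) -> TriplexSpec:
    """Flip third-strand direction only; every plane swaps H <-> RH."""
    _require_dna(spec)
    cls, orient, shifted, prot = _partner_topology(_topology_of(spec))
    return replace(spec, orientation=orient, shifted=shifted)


# -- per-plane step types ---------------------------------------------------

_PURINE_REPEAT = ("G", "A", "A")


def step_types(spec: TriplexSpec, n_repeats: int = 3) -> list[TripleStepType]:
    """Per-plane triplet types, ordered 5'->3' along the duplex purine strand.

    The duplex purine strand reads (GAA)*n, the pyrimidine strand pairs C
    under G and T (or U for RNA) under A.  A Y third strand always pairs C+
    over G and T over A; an R third strand pairs per its register offset.
    Adenine protonation marks the A that sits over a G plane as A+.
    """
    pyr_t = "U" if spec.duplex_pyrimidine_chemistry is Chemistry.RNA else "T"
    out = []
    for i in range(3 * n_repeats):
        purine = _PURINE_REPEAT[i % 3]
        wc_pyr = "C" if purine == "G" else pyr_t
        if spec.third_strand_class is StrandClass.Y:
            third = "C+" if purine == "G" else "T"
        else:
            third = _PURINE_REPEAT[(i + spec.register_offset) % 3]
            if (
                spec.protonation is Protonation.ADENINE
                and third == "A"
                and purine == "G"
            ):
                third = "A+"
        out.append(
            TripleStepType(f"{third}.{purine}:{wc_pyr}", spec.bond_class)
        )
    return out


def triplet_table() -> dict[TripleStepType, list[str]]:
    """Map each (triplet, bond class) to the labels of the specs containing it.

    Reconstructs the published triplet-membership table from the enumeration.
    """
    table: dict[TripleStepType, list[str]] = {}
    for spec in enumerate_dna_triplexes():
        for st in set(step_types(spec, n_repeats=1)):
            table.setdefault(st, [])
            if spec.label not in table[st]:
                table[st].append(spec.label)
    return table
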