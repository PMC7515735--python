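# Methods

## Scope and model

triplexkit treats a GAA/TTC triplex at three levels: a symbolic topology
(`TriplexSpec`), an idealized all-atom starting structure, and per-frame
stability metrics over conformations or trajectories. Molecular dynamics
itself is out of scope: the builder produces starting models of the kind an
MD study would equilibrate, and the metrics are pure geometry, applicable to
any coordinates (built, simulated elsewhere, or synthetic).

## Enumeration and symmetry

The canonical pure-DNA set contains 16 specs: 8 base topologies (pY, apY,
pR, apR, pR-S, apR-S, pR(+)-S, apR(+)) times anti/syn glycosidic states of
the third strand. Unprotonated pyrimidine third strands are excluded from
the canonical set (they form no stable bonding pattern); apY is intrinsically
register-shifted so its C⁺ can reach the duplex guanines, and the "-S"
label suffix is reserved for purine strands. Hybrid (collapsed R-loop)
specs keep the two DNA strands mutually antiparallel, which admits exactly
apY = d(TTC⁺)·d(GAA):r(UUC), pR = d(GAA)·r(GAA):d(TTC) and
pR(+)-S = d(GA⁺A)·r(GAA):d(TTC), all anti.

Bond class follows one rule: a plane is H-type when the third strand is
parallel with anti bases or antiparallel with syn bases, RH-type otherwise.
Geometrically, flipping either the strand direction or the glycosidic state
flips which base face meets the duplex; flipping both restores it. The two
counterpart maps are involutions implemented on the base-topology pairing
pY↔apY, pR↔apR-S, pR-S↔apR, pR(+)-S↔apR(+) (the register offset is
preserved because direction reversal itself advances the register by one —
this is why the unshifted antiparallel pR pairs with the shifted parallel
one).

Register convention: a "shifted" strand is modelled as the phase-rotated
repeat (e.g. d(AAG)₃ against d(GAA)₃) rather than a 9-mer with
single-nucleotide overhangs, so every plane carries a full triplet. Plane
order is 5'→3' along the duplex purine strand.

## Builder

Duplexes are ideal fiber models. Base atoms use the standard (Tsukuba
convention) reference-frame coordinates; strand II bases are rotated 180°
about the pair x-axis. Pair frames are stacked with per-form parameters:

| form | twist | rise | x-displacement | inclination | chi(anti) |
|------|-------|------|----------------|-------------|-----------|
| B | 36.0° | 3.38 Å | 0.0 Å | 0° | −117° |
| A | 32.7° | 2.81 Å | −4.4 Å | +19° | −157° |

Each nucleotide carries P, C1', O4' (plus C2'/O2' for RNA), the base heavy
atoms and the polar base hydrogens (placed from heavy-atom geometry: ring
N–H along the external bisector, amino H in-plane at ±60° from the extended
C–N bond). The per-form local phosphorus position is calibrated so built
duplexes land at canonical fiber values: B-form Zp −0.21 Å, slide 0.0 Å,
P–P 6.5 Å; A-form Zp 2.19 Å, slide −1.47 Å, P–P 6.1 Å — inside the
published A/B classification windows by construction, which is the
builder's contract.

Third-strand docking is solved once per (triplet, bond class) in the
standard pair frame: the third base — face-up for H, mirrored for RH — is
moved in-plane (rotation + translation) by least squares to put every
template donor–acceptor pair at 2.88 Å with near-linear hydrogens, with a
weak radial prior (glycosidic N at ~8.3 Å from the axis) and a soft steric
floor against the duplex. The pose is then mapped onto every plane by helix
symmetry, so the initial third-base tilt α is ~0 everywhere. Syn states
rotate the sugar/phosphate 180° about the glycosidic bond (equivalent to
the base flip, and what makes chi land in the syn range); the backbone
z-sense then automatically realizes the parallel/antiparallel orientation
implied by the spec. Builds are deterministic and clash-checked
(non-bonded heavy-atom floor 2.0 Å).

`idealize_hbonds` is a deterministic rigid-base refinement (per-residue
small rotations/translations shrinking template-bond violations), standing
in for restrained equilibration; it reports bonds that remain
unsatisfiable and returns the best model found.

## Hydrogen-bond templates

Initial per-triplet bond templates are versioned JSON data
(`triplexkit/data/hbond_templates.json`), seeded from canonical
Hoogsteen/reverse-Hoogsteen triad chemistry: C⁺·G (N3/N4 to N7/O6), T·A
(N3/O4 or O2 to N7/N6), G·G (N1/N2 to O6/N7), A⁺·G (N1/N6 to N7/O6),
single-bond A·G and G·A patterns, and symmetric A·A (N6–N7 + N7–N6). One
chemical choice deserves note: the literal mirror of the H-type A·A pair is
not satisfiable by a major-groove third strand (the bond-only solution
buries the base inside the duplex), so the RH A·A template uses the trans
WC/Hoogsteen pairing N6(A)–N7(A) + N1(A)–N6(A), the same N1(A)–N6(A) motif
that recurs in relaxed A·A:T planes. A registry of named variant patterns
(bifurcated guanine bonds, duplex-bridging adenine bonds, etc.) supports
per-plane pattern classification and occupancy timelines; unknown patterns
are reported verbatim.

## Metrics

Detection uses the common trajectory-analysis convention: heavy-atom
donor–acceptor distance ≤ 3.5 Å and donor–H–acceptor angle ≥ 140°, one
record per donor–acceptor pair (a bifurcated donor contributes one record
per acceptor). H_eff counts only same-plane third-strand↔duplex bonds;
Watson–Crick, inter-plane and intra-strand bonds are excluded. α is the
unsigned angle (folded to [0°, 90°]) between the third base's
least-squares ring normal and the pooled-ring normal of its own plane's
Watson–Crick pair (for shifted specs the same-index plane is used). A_eff
uses the printed ring areas (4.95 Å² T/C, 8.29 Å² A/G; U inherits the
pyrimidine value, G the purine value) and is zeroed beyond 45° and for
bond-free planes; the cutoff and the cos−sin form agree at the 45°
boundary. S_eff is the sum of geometric means of adjacent A_eff values.

Helical parameters follow the standard fitted-frame construction (base
frames fitted by superposing standard coordinates; CEHS mid-step frame for
twist/roll/tilt/shift/slide/rise; local step rotation axis for helical
twist/rise and inclination). Zp is the mean mid-step-frame z-coordinate of
the two step phosphates with the strand-II value dyad-equivalenced
(sign-flipped), matching the published discriminating values (>1.5 Å
A-form, <0.5 Å B-form). Overlap areas intersect the projected ring-outline
polygons of successive base pairs on the mid-step plane (ring atoms only;
conventions that include exocyclic atoms give systematically larger
values). Groove widths are minimal inter-strand P–P distances minus a
5.8 Å phosphate-exclusion allowance; in idealized builds the parallel
third strand sits closest to the purine strand and the antiparallel
pyrimidine strand closest to the TTC strand, while antiparallel purine
builds need relaxation before the published groove ordering emerges —
groove output for starting models is descriptive only.

## Trajectory analysis and stability calls

`analyze_trajectory` computes per-frame H_eff/S_eff (optionally excluding
the two terminal planes, which simulation protocols restrain against
fraying); the default analysis window is the last 80% of frames. The 2-D
histogram uses integer-width H bins and 1 Å² S bins. The stability score is
the fraction of windowed frames with H_eff ≥ 0.5·H_max and
S_eff ≥ 0.5·S_max, where H_max is the spec's total template-bond count and
S_max the coplanar stacking bound; calls are stable (≥ 0.8), unstable
(< 0.2), marginal otherwise. The numeric thresholds are a design choice —
they make the visual "upper-right quadrant" judgement reproducible — and
are explicit configuration, not measured constants.

## Synthetic data

The generator emulates four behaviours: *stable* (per-atom isotropic
Gaussian jitter, default σ = 0.1 Å, independent across frames), *detaching*
(0.2 Å/frame displacement of each third-strand residue along its
groove-exit direction — radially away from its own plane's duplex centre,
so the wound strand separates along its whole length), *flipping*
(scheduled rotation of individual bases about the glycosidic bond plus a
2.5 Å outward excursion, since a flipped-out base leaves the stack rather
than rotating in place), and *stacked_detached* (a fixed 8 Å outward
offset: α stays ≈ 0 but no same-plane bond survives, so the coupling rule
forces S_eff to 0). Ground-truth per-plane attachment/flip labels accompany
every frame; everything is reproducible from the seed. Expected calls:
stable and flipping (a local defect) → stable; detaching and
stacked_detached → unstable.

What the generator does not emulate: temporal correlation (frames are
independent), backbone strain, partial or plane-by-plane detachment
kinetics, solvent/ion effects, and temperature dependence. Passing the
label-recovery suite therefore shows the metric pipeline separates the
four constructed behaviours, not that it ranks real MD ensembles.

## Problem sizes and numerics

Default models are 3 repeats (9 planes, 27 nucleotides); test trajectories
use 40–100 frames and up to 5 seeds per scenario, sizes at which the whole
suite runs in well under a minute while exercising every code path. All
optimizations are deterministic least squares from fixed start grids;
degenerate inputs (fewer than 2 planes, missing phosphates or ring atoms,
donors without hydrogens) degrade to warnings with the affected plane or
step excluded. Coordinates are Å throughout; PDB output is fixed-width
with 3-decimal coordinates, and protonated residues keep standard residue
names plus the extra proton (a switch emits DCP/DAP names instead).

## Known limitations

- Starting models are idealized: relaxed MD geometry (groove widths of
  antiparallel purine triplexes, duplex unwinding by the third strand,
  A↔B convergence of hybrids) is not reproduced at the build stage.
- Hydrogen-bond templates beyond the atom pairs named for relaxed
  structures are chemical reconstructions; they are data, editable without
  code changes.
- The overlap-area polygon uses ring atoms only.
- No mixed-sequence strands, RNA third strands, or intramolecular H-DNA
  loop topologies.
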