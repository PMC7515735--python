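# triplexkit

Structural analysis toolkit for the non-B DNA structures formed by GAA/TTC
trinucleotide repeats — the triplexes (H-DNA) and RNA:DNA hybrid structures
implicated in Friedreich's ataxia. It is aimed at people modelling or
simulating these structures who need (i) a systematic enumeration of every
non-equivalent triplex topology, (ii) idealized starting coordinates for
them, and (iii) quantitative, triplex-aware stability metrics for
conformations and trajectories.

## What it computes

**Taxonomy.** A GAA/TTC triplex is a Watson–Crick R:Y duplex plus a third
strand in the major groove: the purine strand d(GAA) (class R) or the
pyrimidine strand d(TTC) (class Y, cytosines protonated as C⁺). Varying the
third-strand direction (p/ap), register shift (-S), adenine protonation
((+)) and glycosidic state ((a)/(s)) yields 8 base topologies and 16
non-equivalent pure-DNA triplexes, plus 3 DNA·RNA:DNA hybrid triplexes
(collapsed R-loops). Each base-triplet plane carries a Hoogsteen-like (H)
or reverse-Hoogsteen-like (RH) bond pattern; *conformational* counterparts
(direction and glycosidic state both flipped) share step types, while
*directional* counterparts (direction only) swap H↔RH.

**Builder.** Fiber-style ideal duplexes (B or A form, DNA/RNA/hybrid) from
standard base reference frames, and triplex starting models with the third
strand docked plane-by-plane so that each triplet's initial hydrogen-bond
template is satisfied.

**Stability metrics.** For a third strand over planes *i*:

- effective hydrogen-bond number `H_eff = Σᵢ H_eff_i`, counting only bonds
  between the third-strand base of plane *i* and duplex bases of the *same*
  plane (detection: donor–acceptor ≤ 3.5 Å, donor–H–acceptor ≥ 140°);
- effective stacking area `A_eff_i = A⁰ᵢ (cos αᵢ − sin αᵢ)` with αᵢ the
  third-base tilt against its Watson–Crick plane (A⁰ = 4.95 Å² for T/C,
  8.29 Å² for A/G), forced to zero for αᵢ > 45° or `H_eff_i = 0`;
- step stacking `S_eff_i = √(A_eff_i · A_eff_{i+1})`, total
  `S_eff = Σᵢ S_eff_i`.

2-D histograms of `S_eff` vs `H_eff` over a trajectory window summarize
stability; the H→S coupling rule guarantees that a perfectly stacked but
detached third strand scores zero.

**Helical analysis.** Base-pair step parameters (twist, roll, slide, rise,
inclination), the phosphorus-based Zp parameter, A/B-form classification
(A: slide < −0.8 Å and Zp > 1.5 Å; B: slide > −0.8 Å and Zp < 0.5 Å),
RMSD to reference forms, 3DNA-style base-step overlap areas, and triplex
groove widths.

**Synthetic trajectories.** A seeded generator produces labelled test
trajectories for four behaviours: stable (thermal jitter), progressive
third-strand detachment, base flip-out events, and the pathological
stacked-but-detached strand.

## Worked example

```python
import triplexkit as tk
from triplexkit.hbond import plane_assignment, effective_hbond_number
from triplexkit.stacking import stacking_frame
from triplexkit.pipeline import analyze_trajectory, default_window, stability_call
from triplexkit.synthetic import ScenarioConfig, generate_trajectory

spec = tk.parse_label("pR(+)-S(a)")
print(spec.label, spec.bond_class.value,
      [t.triplet for t in tk.step_types(spec, 1)])

model = tk.build_triplex(spec, n_repeats=3, form="B")
planes = plane_assignment(spec, 9)
h_total, h_per_plane = effective_hbond_number(model, planes)
sf = stacking_frame(model, planes, h_per_plane)
print(f"H_eff = {h_total}, S_eff = {sf.s_eff:.1f} A^2")

frames, _ = generate_trajectory(
    spec, ScenarioConfig(scenario="detaching", n_frames=100, seed=7))
metrics = analyze_trajectory(frames, spec, frame_range=default_window(100))
call, score = stability_call(metrics, spec)
print(f"detaching trajectory -> {call} (score {score:.2f})")
```

prints

```
pR(+)-S(a) H ['A+.G:C', 'A.A:T', 'G.A:T']
H_eff = 21, S_eff = 66.3 A^2
detaching trajectory -> unstable (score 0.00)
```

`pR(+)-S(a)` is the parallel, shifted, adenine-protonated GAA third strand
with anti bases: an H-type triplex whose repeat planes are A⁺·G:C, A·A:T and
G·A:T. The idealized build forms 21 same-plane hydrogen bonds over its nine
planes and a total effective stacking area of 66.3 Å²; a trajectory in which
the third strand progressively leaves the groove is called unstable because
almost no frame in the analysis window stays in the upper-right (high-H,
high-S) quadrant.

A command-line interface mirrors the library:

```sh
triplexkit enumerate                 # the 16 DNA topologies + step types
triplexkit build --spec "pY(a)" -o py_a.pdb
triplexkit synth --spec "pY(a)" --scenario detaching --frames 100 --seed 7 \
    -o traj.pdb --labels labels.tsv
triplexkit metrics traj.pdb --spec "pY(a)" -o metrics.tsv
triplexkit classify traj.pdb --spec "pY(a)"
triplexkit helixparams py_a.pdb
```

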