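"""Labelled synthetic trajectories emulating the behaviours seen in triplex
molecular dynamics: a stable triplex (thermal jitter only), progressive
detachment of the third strand, individual base flip-out events, and the
pathological "perfectly stacked but detached" third strand.

Frames are the idealized build plus independent isotropic per-atom Gaussian
jitter and a deterministic scenario transform; every trajectory carries
per-frame, per-plane ground-truth labels and is exactly reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .builder import build_triplex
from .core import StructureModel
from .geometry import rotation_about_axis
from .hbond import THIRD_STRAND, plane_assignment
from .taxonomy import TriplexSpec

SCENARIOS = ("stable", "detaching", "flipping", "stacked_detached")

#: Third-strand displacement beyond which a plane is labelled detached
#: (template bonds start ~2.9 A; the detection cutoff is 3.5 A).
DETACH_DISPLACEMENT = 1.0  # Angstrom


@dataclass
class ScenarioConfig:
    scenario: str = "stable"
    n_frames: int = 100
    jitter_sigma: float = 0.1  # Angstrom, per-atom thermal jitter
    detach_rate: float = 0.2  # Angstrom / frame, rigid displacement
    stacked_offset: float = 8.0  # Angstrom, rigid offset of the
    # stacked-but-detached strand
    flip_schedule: list[tuple[int, int, float]] = field(default_factory=list)
    # (plane, start frame, rotation degrees); default set per trajectory
    flip_out_shift: float = 2.5  # Angstrom, outward excursion of a
    # flipping base (a flipped base leaves the stack, it does not rotate
    # in place)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")

    @property
    def expected_call(self) -> str:
        """Ground-truth stability call the analysis should recover.

        A flip-out of one or two bases is a local defect of an otherwise
        stable triplex; detachment and the stacked-but-unbonded strand are
        unstable.
        """
        if self.scenario in ("detaching", "stacked_detached"):
            return "unstable"
        return "stable"


@dataclass
class FrameLabels:
    frame_index: int
    plane_attached: list[bool]
    plane_flipped: list[bool]


def groove_exit_vector(model: StructureModel) -> np.ndarray:
    """Unit vector from the duplex axis out through the third strand."""
    duplex_pts = [a.coords for sid, i, r in model.residues()
                  for a in r.atoms if sid != THIRD_STRAND]
    third_pts = [a.coords for sid, i, r in model.residues()
                 for a in r.atoms if sid == THIRD_STRAND]
    v = np.mean(third_pts, axis=0) - np.mean(duplex_pts, axis=0)
    v = v / np.linalg.norm(v)
    return v


def _exit_directions(model: StructureModel, planes) -> list[np.ndarray]:
    """Per-residue groove-exit direction for the third strand.

    Each third-strand residue leaves radially, away from the centre of its
    own plane's Watson-Crick pair, so a displaced strand separates from the
    duplex along its whole length (a single rigid direction would sweep the
    wound strand through the duplex).
    """
    out = []
    third = model.strand(THIRD_STRAND)
    dirs: dict[int, np.ndarray] = {}
    for p in range(planes.n_planes):
        t_res, pur, pyr = planes.residues(model, p)
        centre = 0.5 * (pur.ring_coords().mean(axis=0)
                        + pyr.ring_coords().mean(axis=0))
        v = t_res.ring_coords().mean(axis=0) - centre
        dirs[planes.third[p]] = v / np.linalg.norm(v)
    for i in range(len(third)):
        out.append(dirs[i])
    return out


def generate_trajectory(
    spec: TriplexSpec,
    config: ScenarioConfig,
    n_repeats: int = 3,
    form: str = "B",
) -> tuple[list[StructureModel], list[FrameLabels]]:
    """(frames, per-frame ground-truth labels) for one scenario.

    Frame 0 is the idealized build (no jitter); later frames add Gaussian
    jitter of ``jitter_sigma`` plus the scenario transform.
    """
    base = build_triplex(spec, n_repeats, form)
    n_planes = 3 * n_repeats
    planes = plane_assignment(spec, n_planes)
    schedule = list(config.flip_schedule)
    if config.scenario == "flipping" and not schedule:
        schedule = [(n_planes // 2, config.n_frames // 4, 180.0)]
    for plane, _, _ in schedule:
        if not 0 <= plane < n_planes:
            raise ValueError(f"flip schedule plane {plane} out of range")
    exit_dirs = _exit_directions(base, planes)
    rng = np.random.default_rng(config.seed)

    frames: list[StructureModel] = []
    labels: list[FrameLabels] = []
    for k in range(config.n_frames):
        frame = base.copy()
        frame.frame_index = k
        attached = [True] * n_planes
        flipped = [False] * n_planes
        displacement = 0.0
        if k > 0 and config.jitter_sigma > 0:
            for a in frame.atoms():
                a.coords = a.coords + rng.normal(
                    0.0, config.jitter_sigma, size=3)
        elif config.jitter_sigma > 0:
            # keep the stream aligned across frames for reproducibility
            pass
        if config.scenario == "detaching":
            displacement = config.detach_rate * k
        elif config.scenario == "stacked_detached":
            displacement = config.stacked_offset
        if displacement > 0:
            for res_i, res in enumerate(frame.strand(THIRD_STRAND)):
                shift = displacement * exit_dirs[res_i]
                for a in res.atoms:
                    a.coords = a.coords + shift
            if displacement > DETACH_DISPLACEMENT:
                attached = [False] * n_planes
        if config.scenario == "flipping":
            for plane, start, degrees in schedule:
                if k < start:
                    continue
                res = frame.strand(THIRD_STRAND)[planes.third[plane]]
                n_gly = res.atom(chem.GLYCOSIDIC_N[res.base]).coords
                c1p = res.atom("C1'").coords
                axis = c1p - n_gly
                R = rotation_about_axis(axis, degrees)
                out = config.flip_out_shift * exit_dirs[planes.third[plane]]
                for a in res.atoms:
                    if a.name in ("P", "C1'", "O4'", "C2'", "O2'"):
                        continue
                    a.coords = n_gly + R @ (a.coords - n_gly) + out
                if abs(degrees % 360.0) > 30.0:
                    flipped[plane] = True
                    attached[plane] = False
        frames.append(frame)
        labels.append(FrameLabels(k, attached, flipped))
    return frames, labels
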