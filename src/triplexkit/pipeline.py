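"""Per-frame metric orchestration, 2-D stability histograms, stability calls.

For every trajectory frame the effective hydrogen-bond number H_eff and the
effective stacking area S_eff are computed; their joint 2-D histogram over an
analysis window summarizes the stability of the third strand.  Well-bound
triplexes populate the upper-right quadrant (high H_eff, high S_eff); a
detaching or merely-stacked-but-unbonded third strand collapses towards the
origin because the H->S coupling rule zeroes the stacking of bond-free
planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import StructureModel
from .hbond import (
    PlaneAssignment,
    detect_hbonds,
    effective_hbond_number,
    plane_assignment,
    plane_bond_set,
    classify_plane_pattern,
    template_bond_count,
)
from .stacking import max_stacking_area, stacking_frame
from .taxonomy import TriplexSpec, step_types


@dataclass
class FrameMetrics:
    frame_index: int
    h_eff: int
    h_eff_per_plane: list[int]
    s_eff: float
    s_eff_per_step: list[float]
    alpha_per_plane: list[float]
    patterns: list[str] | None = None


@dataclass
class Histogram2D:
    h_edges: np.ndarray  # integer-width bins on the H axis
    s_edges: np.ndarray  # 1 A^2 bins on the S axis
    counts: np.ndarray  # shape (len(h_edges)-1, len(s_edges)-1)
    spec_label: str = ""
    frame_range: tuple[int, int] | None = None

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())


@dataclass
class StabilityThresholds:
    """Quadrant thresholds, normalized by per-spec theoretical maxima."""

    h_frac: float = 0.5
    s_frac: float = 0.5
    stable_min: float = 0.8
    unstable_max: float = 0.2


def _check_topology(frames: list[StructureModel]) -> None:
    sig0 = None
    for k, f in enumerate(frames):
        sig = tuple(
            (sid, len(residues), tuple(len(r.atoms) for r in residues))
            for sid, residues in f.strands
        )
        if sig0 is None:
            sig0 = sig
        elif sig != sig0:
            raise ValueError(f"topology drift at frame {k}")


def analyze_trajectory(
    frames: list[StructureModel],
    spec: TriplexSpec,
    frame_range: tuple[int, int] | None = None,
    exclude_terminal_planes: bool = False,
    classify_patterns: bool = False,
) -> list[FrameMetrics]:
    """One FrameMetrics per selected frame.

    ``frame_range`` is a half-open (start, stop) on frame positions, e.g. the
    tail of a run; ``exclude_terminal_planes`` drops the two end planes from
    the totals (the ends are restrained against fraying in simulation work).
    """
    if not frames:
        raise ValueError("empty trajectory")
    _check_topology(frames)
    if frame_range is not None:
        frames = frames[frame_range[0]:frame_range[1]]
    n = len(frames[0].strand("A"))
    planes = plane_assignment(spec, n)
    types = step_types(spec, n // 3)
    keep = range(planes.n_planes)
    if exclude_terminal_planes:
        keep = range(1, planes.n_planes - 1)
    out: list[FrameMetrics] = []
    for f in frames:
        records = detect_hbonds(f, planes)
        _, per_plane = effective_hbond_number(f, planes, records)
        sf = stacking_frame(f, planes, per_plane)
        sel = list(keep)
        h_sel = [per_plane[i] for i in sel]
        a_sel = [sf.a_eff[i] for i in sel]
        from .stacking import effective_stacking

        s_total, s_steps = effective_stacking(a_sel)
        patterns = None
        if classify_patterns:
            patterns = []
            for i in sel:
                bs = plane_bond_set(records, planes, i, f)
                pid, _ = classify_plane_pattern(
                    bs, types[i].triplet, types[i].bond_class
                )
                patterns.append(pid)
        out.append(FrameMetrics(
            frame_index=f.frame_index,
            h_eff=sum(h_sel),
            h_eff_per_plane=h_sel,
            s_eff=s_total,
            s_eff_per_step=s_steps,
            alpha_per_plane=[sf.alpha[i] for i in sel],
            patterns=patterns,
        ))
    return out


def default_window(n_frames: int) -> tuple[int, int]:
    """Analysis window: the last 80% of frames (as a 1 us run's last 800 ns)."""
    return (n_frames - int(round(0.8 * n_frames)), n_frames)


def histogram2d(
    metrics: list[FrameMetrics],
    h_max: int | None = None,
    s_max: float | None = None,
    spec_label: str = "",
) -> Histogram2D:
    """Joint histogram of S_eff vs H_eff with integer / 1 A^2 bins."""
    if not metrics:
        raise ValueError("no metrics to histogram")
    h = np.array([m.h_eff for m in metrics])
    s = np.array([m.s_eff for m in metrics])
    hm = int(h_max if h_max is not None else max(h.max(), 1))
    sm = float(s_max if s_max is not None else max(np.ceil(s.max()), 1.0))
    h_edges = np.arange(0, hm + 2)  # [k, k+1) bins
    s_edges = np.arange(0.0, np.ceil(sm) + 2.0)
    counts, _, _ = np.histogram2d(
        np.clip(h, 0, hm + 0.5), np.clip(s, 0.0, s_edges[-1] - 0.5),
        bins=(h_edges, s_edges),
    )
    fr = (metrics[0].frame_index, metrics[-1].frame_index)
    return Histogram2D(h_edges, s_edges, counts, spec_label, fr)


def theoretical_maxima(spec: TriplexSpec, n_repeats: int = 3,
                       exclude_terminal_planes: bool = False
                       ) -> tuple[int, float]:
    """(H_max, S_max) for normalizing the quadrant thresholds."""
    types = step_types(spec, n_repeats)
    sel = types[1:-1] if exclude_terminal_planes else types
    from .hbond import template_bonds

    h_max = sum(len(template_bonds(t.triplet, t.bond_class)) for t in sel)
    bases = [t.triplet.split(".")[0].rstrip("+") for t in sel]
    s_max = max_stacking_area(bases)
    return h_max, s_max


def stability_score(
    metrics: list[FrameMetrics],
    h_max: int,
    s_max: float,
    thresholds: StabilityThresholds = StabilityThresholds(),
) -> float:
    """Fraction of frames in the upper-right quadrant (normalized axes)."""
    if not metrics:
        raise ValueError("no metrics")
    good = sum(
        1 for m in metrics
        if m.h_eff >= thresholds.h_frac * h_max
        and m.s_eff >= thresholds.s_frac * s_max
    )
    return good / len(metrics)


def stability_call(
    metrics: list[FrameMetrics],
    spec: TriplexSpec,
    n_repeats: int = 3,
    thresholds: StabilityThresholds = StabilityThresholds(),
    exclude_terminal_planes: bool = False,
) -> tuple[str, float]:
    """('stable' | 'marginal' | 'unstable', score).

    The score is the upper-right-quadrant occupancy at thresholds normalized
    by the spec's theoretical maxima; the call is monotone in the score.
    """
    h_max, s_max = theoretical_maxima(spec, n_repeats,
                                      exclude_terminal_planes)
    score = stability_score(metrics, h_max, s_max, thresholds)
    if score >= thresholds.stable_min:
        return "stable", score
    if score < thresholds.unstable_max:
        return "unstable", score
    return "marginal", score


def metrics_table(metrics: list[FrameMetrics]):
    """Per-frame metrics as a pandas DataFrame (TSV-friendly)."""
    import pandas as pd

    return pd.DataFrame({
        "frame": [m.frame_index for m in metrics],
        "H_eff": [m.h_eff for m in metrics],
        "S_eff": [m.s_eff for m in metrics],
    })
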