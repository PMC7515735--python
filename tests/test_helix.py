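"""Step parameters, Zp and A/B calls, RMSD and overlap-area oracles."""

import math

import numpy as np
import pytest

import triplexkit as tk
from triplexkit.builder import FORMS
from triplexkit.geometry import rotation_about_axis
from triplexkit.helix import (
    classify_form,
    groove_widths,
    rmsd,
    step_overlap_area,
    step_parameters,
    zp,
)


class TestStepParameters:
    def test_b_form_self_consistency(self, b_duplex):
        params = step_parameters(b_duplex)
        assert len(params) == 8
        assert np.mean([p.twist for p in params]) == pytest.approx(36.0,
                                                                   abs=0.5)
        assert np.mean([p.helical_rise for p in params]) == pytest.approx(
            3.38, abs=0.02)

    def test_a_form_slide_below_minus_08(self, a_duplex):
        params = step_parameters(a_duplex)
        assert np.mean([p.slide for p in params]) < -0.8
        assert np.mean([p.inclination for p in params]) == pytest.approx(
            19.0, abs=1.0)
        assert np.mean([p.helical_rise for p in params]) == pytest.approx(
            2.81, abs=0.02)

    def test_rigid_motion_invariance(self, b_duplex, rigid_motion):
        moved = b_duplex.transform(*rigid_motion)
        p0 = step_parameters(b_duplex)
        p1 = step_parameters(moved)
        for a, b in zip(p0, p1):
            for field in ("twist", "roll", "slide", "rise", "zp",
                          "overlap_area"):
                assert getattr(a, field) == pytest.approx(
                    getattr(b, field), abs=1e-6)


class TestZp:
    def test_b_form_below_05(self, b_duplex):
        mean_zp, per_step = zp(b_duplex)
        assert mean_zp < 0.5
        assert all(v < 0.5 for v in per_step)

    def test_a_form_above_15(self, a_duplex):
        mean_zp, per_step = zp(a_duplex)
        assert mean_zp > 1.5
        assert all(v > 1.5 for v in per_step)

    def test_agrees_with_analytic_fiber_oracle(self, b_duplex):
        """For the symmetric B fiber the mid-step frame is the global frame
        rotated halfway, so Zp must equal p_z + rise/2 exactly."""
        fp = FORMS["B"]
        expected = fp.p_local[2] + fp.rise / 2.0
        mean_zp, per_step = zp(b_duplex, inner_only=False)
        for v in per_step:
            assert v == pytest.approx(expected, abs=0.01)

    def test_missing_phosphorus_skips_step(self, b_duplex):
        broken = b_duplex.copy()
        res = broken.strand("A")[4]
        res.atoms = [a for a in res.atoms if a.name != "P"]
        params = step_parameters(broken)
        assert sum(p.zp is None for p in params) == 1


class TestClassifyForm:
    @pytest.mark.parametrize("slide,zpv,expected", [
        (0.0, -0.2, "B"),
        (-1.5, 2.2, "A"),
        (-1.5, 1.0, "intermediate"),
        (0.0, 1.0, "intermediate"),
        (-1.5, 0.2, "intermediate"),
    ])
    def test_threshold_logic(self, slide, zpv, expected):
        assert classify_form(slide, zpv) == expected


class TestRmsd:
    def test_self_and_rigid_copy_are_zero(self, b_duplex, rigid_motion):
        assert rmsd(b_duplex, b_duplex) == pytest.approx(0.0, abs=1e-9)
        moved = b_duplex.transform(*rigid_motion)
        assert rmsd(b_duplex, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, b_duplex, a_duplex):
        assert rmsd(b_duplex, a_duplex, "backbone") == pytest.approx(
            rmsd(a_duplex, b_duplex, "backbone"), abs=1e-9)

    def test_atom_count_mismatch_rejected(self, b_duplex):
        shorter = tk.build_duplex("GAA" * 2, "B")
        with pytest.raises(ValueError, match="mismatch"):
            rmsd(b_duplex, shorter)

    def test_matches_quaternion_oracle_on_toys(self):
        """Horn's closed-form quaternion superposition as the oracle."""
        def horn_rmsd(x, y):
            xc = x - x.mean(axis=0)
            yc = y - y.mean(axis=0)
            S = xc.T @ yc
            K = np.array([
                [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1],
                 S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
                [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2],
                 S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
                [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0],
                 -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
                [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0], S[1, 2] + S[2, 1],
                 -S[0, 0] - S[1, 1] + S[2, 2]],
            ])
            lam = np.linalg.eigvalsh(K)[-1]
            e = float((xc ** 2).sum() + (yc ** 2).sum() - 2.0 * lam)
            return math.sqrt(max(e, 0.0) / len(x))

        rng = np.random.default_rng(13)
        from triplexkit.geometry import superpose

        for _ in range(20):
            x = rng.normal(size=(4, 3))
            y = rng.normal(size=(4, 3))
            _, _, got = superpose(x, y)
            assert got == pytest.approx(horn_rmsd(x, y), abs=1e-6)


class TestOverlapArea:
    def test_eclipsed_polygons_give_polygon_area(self):
        from shapely.geometry import Polygon
        from triplexkit.helix import _base_polygon_2d
        from triplexkit.core import Atom, Residue
        from triplexkit.frames import STANDARD_BASE_COORDS

        res = Residue("G", "DNA")
        for name, xyz in STANDARD_BASE_COORDS["G"].items():
            if name != "C1'":
                res.atoms.append(Atom(name, name[0], np.array(xyz)))
        poly = _base_polygon_2d(res, np.zeros(3), np.eye(3))
        assert poly.intersection(poly).area == pytest.approx(poly.area)

    def test_laterally_displaced_beyond_diameter_is_zero(self, b_duplex):
        shifted = b_duplex.copy()
        # move every second base pair sideways far beyond any ring diameter
        for i, res in enumerate(shifted.strand("A")):
            if i % 2:
                for a in res.atoms:
                    a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        for i, res in enumerate(shifted.strand("B")):
            if (len(shifted.strand("B")) - 1 - i) % 2:
                for a in res.atoms:
                    a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        _, areas = step_overlap_area(shifted, inner_only=False)
        assert all(a == pytest.approx(0.0, abs=1e-9) for a in areas)

    def test_matches_monte_carlo_oracle(self, b_duplex, a_duplex):
        """Point-sampling oracle via matplotlib's path containment."""
        from matplotlib.path import Path
        from triplexkit.frames import base_pair_frame
        from triplexkit.helix import duplex_pairs, _pair_polygon, \
            _step_frames

        rng = np.random.default_rng(99)
        for model in (b_duplex, a_duplex):
            pairs = duplex_pairs(model)
            frames = [base_pair_frame(p, q) for p, q in pairs]
            for i in (2, 4):
                (om, rm), *_ = _step_frames(frames[i], frames[i + 1])
                p1 = _pair_polygon(*pairs[i], om, rm)
                p2 = _pair_polygon(*pairs[i + 1], om, rm)
                exact = p1.intersection(p2).area

                def ring_paths(model_pairs_idx):
                    pur, pyr = pairs[model_pairs_idx]
                    out = []
                    for res in (pur, pyr):
                        pts = (res.ring_coords() - om) @ rm
                        out.append(Path(pts[:, :2]))
                    return out

                paths1 = ring_paths(i)
                paths2 = ring_paths(i + 1)
                b1 = np.array(p1.bounds)
                b2 = np.array(p2.bounds)
                lo = np.minimum(b1[:2], b2[:2]) - 0.5
                hi = np.maximum(b1[2:], b2[2:]) + 0.5
                pts = rng.uniform(lo, hi, size=(400000, 2))
                in1 = np.zeros(len(pts), bool)
                for p in paths1:
                    in1 |= p.contains_points(pts)
                in2 = np.zeros(len(pts), bool)
                for p in paths2:
                    in2 |= p.contains_points(pts)
                mc = (in1 & in2).mean() * np.prod(hi - lo)
                assert mc == pytest.approx(exact, rel=0.05, abs=0.05)


class TestGrooves:
    def test_parallel_triplex_narrowest_along_purine_strand(self, py_a_model,
                                                            pr_a_model):
        for model in (py_a_model, pr_a_model):
            gw = groove_widths(model)
            assert min(gw, key=gw.get) == "third-purine"

    def test_antiparallel_pyrimidine_strand_hugs_ttc(self):
        m = tk.build_triplex(tk.parse_label("apY(a)"))
        gw = groove_widths(m)
        assert min(gw, key=gw.get) == "third-pyrimidine"

    def test_rigid_motion_invariance(self, py_a_model, rigid_motion):
        g0 = groove_widths(py_a_model)
        g1 = groove_widths(py_a_model.transform(*rigid_motion))
        for k in g0:
            assert g0[k] == pytest.approx(g1[k], abs=1e-9)
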