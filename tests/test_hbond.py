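"""Hydrogen-bond detection cutoffs, H_eff and pattern classification."""

import math

import numpy as np
import pytest

import triplexkit as tk
from triplexkit import chem
from triplexkit.core import Atom, Residue, StructureModel
from triplexkit.geometry import angle_between
from triplexkit.hbond import (
    ANGLE_CUTOFF,
    DISTANCE_CUTOFF,
    HBondRecord,
    PlaneAssignment,
    classify_plane_pattern,
    detect_hbonds,
    effective_hbond_number,
    max_plane_bonds,
    pattern_timeline,
    plane_assignment,
    plane_bond_set,
    template_bonds,
)


def _probe_model(distance: float, angle: float) -> StructureModel:
    """Minimal donor/acceptor geometry: T N3-H3 donor vs adenine N7.

    The acceptor is placed at the requested donor-acceptor distance and
    donor-H-acceptor angle.
    """
    n3 = np.zeros(3)
    h3 = np.array([1.0, 0.0, 0.0])
    theta = math.radians(angle)
    u = np.array([-math.cos(theta), math.sin(theta), 0.0])
    c = math.cos(theta)
    s = c + math.sqrt(max(c * c - 1.0 + distance * distance, 0.0))
    acc = h3 + s * u
    donor = Residue("T", "DNA", [Atom("N3", "N", n3, 0, "C"),
                                 Atom("H3", "H", h3, 0, "C")])
    acceptor = Residue("A", "DNA", [Atom("N7", "N", acc, 0, "A")])
    dummy = Residue("T", "DNA", [])
    return StructureModel([("A", [acceptor]), ("B", [dummy]),
                           ("C", [donor])])


def _oracle_h_eff(model, planes):
    """Brute force: every atom pair under both cutoffs, then the same-plane
    third-strand/duplex filter.  Independent of detect_hbonds."""
    per_plane = [0] * planes.n_planes
    for i in range(planes.n_planes):
        third, pur, pyr = planes.residues(model, i)
        for d_res, a_res in ((third, pur), (third, pyr),
                             (pur, third), (pyr, third)):
            donors = chem.donors(d_res.base, d_res.protonated_site)
            accs = chem.acceptors(a_res.base, a_res.protonated_site)
            for heavy, hyds in donors.items():
                if not d_res.has_atom(heavy):
                    continue
                hs = [h for h in hyds if d_res.has_atom(h)]
                for acc in accs:
                    if not a_res.has_atom(acc):
                        continue
                    d_xyz = d_res.atom(heavy).coords
                    a_xyz = a_res.atom(acc).coords
                    if np.linalg.norm(a_xyz - d_xyz) > DISTANCE_CUTOFF:
                        continue
                    angles = [angle_between(d_xyz - d_res.atom(h).coords,
                                            a_xyz - d_res.atom(h).coords)
                              for h in hs]
                    if angles and max(angles) >= ANGLE_CUTOFF:
                        per_plane[i] += 1
    return sum(per_plane), per_plane


class TestCutoffs:
    @pytest.mark.parametrize("distance,angle,expected", [
        (3.40, 180.0, True),   # inside both cutoffs
        (3.60, 180.0, False),  # distance too long
        (3.20, 120.0, False),  # angle too bent
        (3.499, 180.0, True),
        (3.501, 180.0, False),
        (3.20, 140.1, True),
        (3.20, 139.9, False),
    ])
    def test_threshold_recovery(self, distance, angle, expected):
        model = _probe_model(distance, angle)
        records = detect_hbonds(model)
        assert bool(records) is expected
        if records:
            rec = records[0]
            assert rec.distance == pytest.approx(distance, abs=1e-6)
            assert rec.angle == pytest.approx(angle, abs=1e-6)

    def test_fine_sweep_recovers_both_thresholds(self):
        dists = np.arange(2.8, 4.21, 0.1)
        found = [d for d in dists if detect_hbonds(_probe_model(d, 175.0))]
        assert max(found) == pytest.approx(3.5, abs=0.051)
        angs = np.arange(100.0, 181.0, 2.5)
        found = [a for a in angs if detect_hbonds(_probe_model(3.0, a))]
        assert min(found) == pytest.approx(140.0, abs=1.26)

    def test_donor_without_hydrogen_skipped_or_strict_error(self):
        model = _probe_model(3.0, 170.0)
        model.strand("C")[0].atoms = [
            a for a in model.strand("C")[0].atoms if a.name != "H3"]
        with pytest.warns(UserWarning, match="no hydrogen"):
            assert detect_hbonds(model) == []
        with pytest.raises(ValueError, match="no hydrogen"):
            detect_hbonds(model, strict=True)


class TestEffectiveHbondNumber:
    def test_matches_brute_force_oracle_on_builds(self):
        for label in ("pY(a)", "pR(a)", "apR(+)(a)", "pR-S(s)", "apY(s)"):
            spec = tk.parse_label(label)
            model = tk.build_triplex(spec)
            planes = plane_assignment(spec, 9)
            assert effective_hbond_number(model, planes) == \
                _oracle_h_eff(model, planes)

    def test_matches_oracle_on_jittered_frames(self, py_a_spec):
        from triplexkit.synthetic import ScenarioConfig, generate_trajectory

        frames, _ = generate_trajectory(
            py_a_spec, ScenarioConfig(scenario="detaching", n_frames=8,
                                      detach_rate=0.3, seed=11))
        planes = plane_assignment(py_a_spec, 9)
        for f in frames:
            assert effective_hbond_number(f, planes) == \
                _oracle_h_eff(f, planes)

    def test_idealized_py_a_counts_two_bonds_per_plane(self, py_a_model,
                                                       py_a_spec):
        planes = plane_assignment(py_a_spec, 9)
        total, per_plane = effective_hbond_number(py_a_model, planes)
        assert total == 18
        assert per_plane == [2] * 9

    def test_rigid_motion_invariance(self, py_a_model, py_a_spec,
                                     rigid_motion):
        planes = plane_assignment(py_a_spec, 9)
        moved = py_a_model.transform(*rigid_motion)
        assert effective_hbond_number(moved, planes) == \
            effective_hbond_number(py_a_model, planes)

    def test_inter_plane_bond_not_counted(self):
        probe = _probe_model(3.0, 170.0)
        # donor sits on plane 0, acceptor on plane 1: detected but H_eff 0
        dummy_t = Residue("T", "DNA", [])
        dummy_a = Residue("A", "DNA", [])
        model = StructureModel([
            ("A", [dummy_a, probe.strand("A")[0]]),
            ("B", [Residue("T", "DNA", []), Residue("T", "DNA", [])]),
            ("C", [probe.strand("C")[0], dummy_t]),
        ])
        planes = PlaneAssignment(2, (0, 1), (0, 1), (1, 0))
        records = detect_hbonds(model, planes)
        assert len(records) == 1 and not records[0].same_plane
        assert effective_hbond_number(model, planes) == (0, [0, 0])

    def test_displaced_strand_has_zero_h_eff(self, py_a_model, py_a_spec):
        planes = plane_assignment(py_a_spec, 9)
        far = py_a_model.copy()
        for res in far.strand("C"):
            for a in res.atoms:
                a.coords = a.coords + np.array([10.0, 0.0, 0.0])
        assert effective_hbond_number(far, planes)[0] == 0

    def test_per_plane_counts_below_chemical_bound(self, pr_a_model,
                                                   pr_a_spec):
        planes = plane_assignment(pr_a_spec, 9)
        _, per_plane = effective_hbond_number(pr_a_model, planes)
        for h, st in zip(per_plane, tk.step_types(pr_a_spec)):
            assert 0 <= h <= max_plane_bonds(st.triplet)


class TestPatternClassification:
    def test_initial_template_recognized(self):
        tmpl = frozenset(
            (b.third_atom, b.duplex_role, b.duplex_atom)
            for b in template_bonds("C+.G:C", "H"))
        pid, flag = classify_plane_pattern(tmpl, "C+.G:C", "H")
        assert flag == "initial"

    def test_named_variant_recognized(self):
        variant = frozenset({("N6", "pyrimidine", "O4"),
                             ("N1", "purine", "N6")})
        pid, flag = classify_plane_pattern(variant, "A.A:T", "H")
        assert (pid, flag) == ("AA-duplex-bridge", "variant")

    def test_empty_set_is_none(self):
        assert classify_plane_pattern(frozenset(), "T.A:T", "H") == \
            ("none", "none")

    def test_unknown_set_reported_verbatim(self):
        odd = frozenset({("O2", "purine", "N6")})
        pid, flag = classify_plane_pattern(odd, "C+.G:C", "H")
        assert flag == "new" and "O2" in pid

    def test_built_model_planes_classify_as_initial(self, py_a_model,
                                                    py_a_spec):
        planes = plane_assignment(py_a_spec, 9)
        records = detect_hbonds(py_a_model, planes)
        for i, st in enumerate(tk.step_types(py_a_spec)):
            bs = plane_bond_set(records, planes, i, py_a_model)
            _, flag = classify_plane_pattern(bs, st.triplet, st.bond_class)
            assert flag == "initial"


class TestPatternTimeline:
    def test_single_frame_occupancy_one(self, py_a_model, py_a_spec):
        planes = plane_assignment(py_a_spec, 9)
        st = tk.step_types(py_a_spec)[4]
        ids, occ = pattern_timeline([py_a_model], planes, 4, st.triplet,
                                    st.bond_class)
        assert len(ids) == 1
        assert occ == {ids[0]: 1.0}

    def test_two_state_alternation_half_half(self, py_a_model, py_a_spec):
        planes = plane_assignment(py_a_spec, 9)
        detached = py_a_model.copy()
        for res in detached.strand("C"):
            for a in res.atoms:
                a.coords = a.coords + np.array([10.0, 0.0, 0.0])
        st = tk.step_types(py_a_spec)[4]
        traj = [py_a_model, detached, py_a_model, detached]
        _, occ = pattern_timeline(traj, planes, 4, st.triplet, st.bond_class)
        assert occ["none"] == pytest.approx(0.5)
        assert sum(occ.values()) == pytest.approx(1.0)

    def test_stable_scenario_dominant_pattern(self, py_a_spec):
        from triplexkit.synthetic import ScenarioConfig, generate_trajectory

        frames, _ = generate_trajectory(
            py_a_spec, ScenarioConfig(scenario="stable", n_frames=20,
                                      seed=5))
        planes = plane_assignment(py_a_spec, 9)
        st = tk.step_types(py_a_spec)[4]
        _, occ = pattern_timeline(frames, planes, 4, st.triplet,
                                  st.bond_class)
        dominant = max(occ, key=occ.get)
        assert occ[dominant] > max(
            (v for k, v in occ.items() if k != dominant), default=0.0)
        assert sum(occ.values()) == pytest.approx(1.0)
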