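"""Helix-axis fitting, rotational phase, and Fa-Fd classification."""

import numpy as np
import pandas as pd
import pytest

from bilayerbind.core import AtomGroup, Frame, select
from bilayerbind.geometry import bilayer_reference, depth_profile
from bilayerbind.orientation import (build_initial_states, class_of_psi,
                                     classify_orientation, fit_helix_axis,
                                     orientation_table, rotate_about_axis,
                                     rotational_phase)
from bilayerbind.synthetic import (BilayerSpec, PeptideSpec, ScriptSpec,
                                   generate_bilayer, generate_peptide,
                                   generate_scripted_trajectory)


def circdiff(a, b):
    """Signed circular difference a - b in (-180, 180]."""
    return -((b - a + 180.0) % 360.0 - 180.0)


def _phase_of(frame, top):
    pep = AtomGroup(top, np.arange(top.n_atoms))
    hf = fit_helix_axis(frame, pep)
    from bilayerbind.geometry import residue_centroid_z
    resids, z = residue_centroid_z(frame, pep, "sidechain")
    depths = pd.DataFrame({"resid": resids, "sidechain_z": z})
    return rotational_phase(frame, hf, depths)


class TestAxisFit:
    # 18 residues at 100 deg/residue = 5 full turns: the C-alpha cloud is
    # rotationally balanced, so the least-squares line is the true axis
    FULL_TURNS = (5, 22)

    def test_ideal_helix_axis_along_x(self, helix):
        _, top, frame = helix
        hf = fit_helix_axis(frame, AtomGroup(top, np.arange(top.n_atoms)),
                            residue_range=self.FULL_TURNS)
        assert abs(hf.axis @ np.array([1.0, 0, 0])) > 1 - 1e-6
        assert hf.axis[0] > 0        # N- to C-terminal sense

    def test_equivariance_under_z_rotation(self):
        top, frame = generate_peptide(PeptideSpec(axis_azimuth_deg=30.0))
        hf = fit_helix_axis(frame, AtomGroup(top, np.arange(top.n_atoms)),
                            residue_range=self.FULL_TURNS)
        expected = np.array([np.cos(np.radians(30)),
                             np.sin(np.radians(30)), 0.0])
        assert abs(hf.axis @ expected) > 1 - 1e-6

    def test_jittered_axis_recovered_within_5_degrees(self):
        # fit over the full helical span (residues 5-28)
        for seed in range(100):
            top, frame = generate_peptide(PeptideSpec(jitter=0.02,
                                                      seed=seed))
            hf = fit_helix_axis(frame,
                                AtomGroup(top, np.arange(top.n_atoms)),
                                residue_range=(5, 28))
            ang = np.degrees(np.arccos(min(1.0, abs(hf.axis[0]))))
            assert ang < 5.0

    def test_too_few_calphas_rejected(self, helix):
        _, top, frame = helix
        short = select(top, "peptide and resid 8-10")
        with pytest.raises(ValueError, match="four"):
            fit_helix_axis(frame, short, residue_range=(8, 10))


class TestRotationalPhase:
    def test_anchor_face_down_is_zero(self):
        top, frame = generate_peptide(PeptideSpec(phase_deg=0.0))
        assert circdiff(_phase_of(frame, top), 0.0) == pytest.approx(
            0.0, abs=2.0)

    @pytest.mark.parametrize("delta", [90.0, 180.0, 270.0])
    def test_equivariance_about_fitted_axis(self, delta, helix):
        _, top, frame = helix
        pep = AtomGroup(top, np.arange(top.n_atoms))
        hf = fit_helix_axis(frame, pep)
        psi0 = _phase_of(frame, top)
        rot = Frame(rotate_about_axis(frame.coordinates, hf.axis, hf.point,
                                      delta), frame.box)
        psi1 = _phase_of(rot, top)
        assert circdiff(psi1, psi0 + delta) == pytest.approx(0.0, abs=2.0)

    def test_flat_depth_profile_rejected(self, helix):
        _, top, frame = helix
        pep = AtomGroup(top, np.arange(top.n_atoms))
        hf = fit_helix_axis(frame, pep)
        flat = pd.DataFrame({"resid": np.arange(1, 38),
                             "sidechain_z": np.zeros(37)})
        with pytest.raises(ValueError, match="asymmetry"):
            rotational_phase(frame, hf, flat)

    def test_steeply_tilted_helix_rejected(self, helix):
        _, top, frame = helix
        pep = AtomGroup(top, np.arange(top.n_atoms))
        depths = pd.DataFrame({"resid": np.arange(1, 38),
                               "sidechain_z": np.linspace(0, 1, 37)})
        # 75-degree pitch: an axis this far out of the membrane plane is
        # not a binding-competent pose
        th = np.radians(75.0)
        rot = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                        [-np.sin(th), 0, np.cos(th)]])
        tilted = Frame(frame.coordinates @ rot.T, frame.box * 2)
        hf = fit_helix_axis(tilted, pep)
        with pytest.raises(ValueError, match="60 degrees"):
            rotational_phase(tilted, hf, depths)

    def test_fully_upright_helix_rejected_at_fit(self, helix):
        _, top, frame = helix
        pep = AtomGroup(top, np.arange(top.n_atoms))
        rot = np.array([[0.0, 0, 1], [0, 1, 0], [-1, 0, 0]])
        up = Frame(frame.coordinates @ rot.T, frame.box * 2)
        with pytest.raises(ValueError, match="membrane normal"):
            fit_helix_axis(up, pep)


class TestClassification:
    def test_quadrant_boundaries(self):
        assert class_of_psi(0.0) == "Fd"
        assert class_of_psi(44.9) == "Fd"
        assert class_of_psi(45.0) == "Fa"
        assert class_of_psi(180.0) == "Fb"
        assert class_of_psi(-44.9 % 360) == "Fd"
        assert class_of_psi(315.0) == "Fd"
        assert class_of_psi(314.9) == "Fc"

    def test_anchor_down_run_is_fd_and_rotations_cycle(self):
        """A bound run with R11/F15/S19 down classifies Fd; +90 degree
        rolls advance the class cyclically."""
        expected = {0: "Fd", 90: "Fa", 180: "Fb", 270: "Fc"}
        for psi0, label in expected.items():
            top, traj, _ = generate_scripted_trajectory(
                BilayerSpec(lipids_per_leaflet=16, seed=4), PeptideSpec(),
                ScriptSpec(n_frames=5,
                           keyframes=((0, 0.25, 0.25, psi0),
                                      (1e9, 0.25, 0.25, psi0))))
            res = classify_orientation(traj, select(top, "peptide"),
                                       select(top, "lipid and name P"))
            assert res.label == label
            assert res.confidence > 0.99

    def test_desorbed_peptide_reports_unbound(self):
        top, traj, _ = generate_scripted_trajectory(
            BilayerSpec(lipids_per_leaflet=16, seed=4), PeptideSpec(),
            ScriptSpec(n_frames=5, keyframes=((0, 2.0, 2.0, 0),
                                              (1e9, 2.0, 2.0, 0))))
        res = classify_orientation(traj, select(top, "peptide"),
                                   select(top, "lipid and name P"))
        assert res.label == "unbound"

    def test_jittered_recovery_all_seeds(self):
        """Noisy (+-20 degree frame-to-frame) runs at each quadrant center
        classify correctly for every seed."""
        n_correct = 0
        n_total = 0
        for psi0 in (0, 90, 180, 270):
            for seed in range(25):
                top, traj, _ = generate_scripted_trajectory(
                    BilayerSpec(lipids_per_leaflet=16, seed=seed),
                    PeptideSpec(),
                    ScriptSpec(n_frames=4,
                               keyframes=((0, 0.25, 0.25, psi0),
                                          (1e9, 0.25, 0.25, psi0)),
                               psi_jitter_deg=20.0, seed=seed))
                res = classify_orientation(traj, select(top, "peptide"),
                                           select(top, "lipid and name P"))
                n_total += 1
                n_correct += (res.label == class_of_psi(psi0))
        assert n_correct == n_total


class TestInitialStates:
    def test_separation_phase_and_determinism(self, helix, neat_bilayer):
        _, ptop, pframe = helix
        _, btop, btraj = neat_bilayer
        from bilayerbind.core import min_image_distance_matrix
        combined, frames = build_initial_states(ptop, pframe, btop,
                                                btraj[0])
        pep = select(combined, "peptide")
        lip = select(combined, "lipid")
        phos = select(combined, "lipid and name P")
        psis = []
        for fr in frames:
            gap = min_image_distance_matrix(
                pep.heavy().positions(fr), lip.heavy().positions(fr),
                fr.box).min()
            assert gap >= 1.4 - 1e-9
            ref = bilayer_reference(fr, phos, pep)
            hf = fit_helix_axis(fr, pep)
            psis.append(rotational_phase(
                fr, hf, depth_profile(fr, pep, ref)))
        for k in (1, 2, 3):
            assert circdiff(psis[k], psis[0] + 90.0 * k) \
                == pytest.approx(0.0, abs=2.0)
        # deterministic rebuild
        _, frames2 = build_initial_states(ptop, pframe, btop, btraj[0])
        for f1, f2 in zip(frames, frames2):
            assert np.array_equal(f1.coordinates, f2.coordinates)

    def test_small_box_rejected(self, helix, neat_bilayer):
        _, ptop, pframe = helix
        _, btop, btraj = neat_bilayer
        squeezed = Frame(btraj[0].coordinates,
                         btraj[0].box * np.array([1.0, 1.0, 0.75]))
        with pytest.raises(ValueError, match="box"):
            build_initial_states(ptop, pframe, btop, squeezed,
                                 separation=3.0)


class TestOrientationTable:
    def test_scripted_runs_reproduce_their_labels(self):
        """Twelve scripted runs ending in prescribed classes tabulate
        row by row, with unbound runs excluded from frequencies."""
        script_psi = {"Fd": 0, "Fa": 90, "Fb": 180, "Fc": 270}
        plan = [("S(0)", "Fb"), ("S(0)", "Fd"), ("S(90)", "Fa"),
                ("S(90)", "Fd"), ("S(180)", "Fc"), ("S(270)", "Fd")]
        runs, labels, want = [], [], []
        for i, (state, cls) in enumerate(plan):
            top, traj, _ = generate_scripted_trajectory(
                BilayerSpec(lipids_per_leaflet=16, seed=i), PeptideSpec(),
                ScriptSpec(n_frames=4,
                           keyframes=((0, 0.25, 0.25, script_psi[cls]),
                                      (1e9, 0.25, 0.25, script_psi[cls]))))
            runs.append((traj, select(top, "peptide"),
                         select(top, "lipid and name P")))
            labels.append(state)
            want.append(cls)
        table, freq = orientation_table(runs, labels)
        assert list(table["orientation"]) == want
        assert freq.sum() == pytest.approx(1.0)
        assert freq["Fd"] == pytest.approx(3 / 6)

    def test_empty_run_list_rejected(self):
        with pytest.raises(ValueError):
            orientation_table([], [])
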