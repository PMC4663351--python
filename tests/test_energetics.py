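"""Cutoff Coulomb / Lennard-Jones pair sums and the U_inter identity."""

import numpy as np
import pytest

from bilayerbind.core import AtomGroup, Frame, Trajectory, select
from bilayerbind.energetics import (COULOMB_PREFACTOR, NonbondedSettings,
                                    coulomb_pair, group_interaction,
                                    interaction_timeseries, lj_pair)

from conftest import toy_topology


class TestPairTerms:
    def test_unit_charges_at_one_nm(self):
        assert coulomb_pair(1.0, 1.0, 1.0) == pytest.approx(138.935458,
                                                            abs=1e-9)

    def test_zero_charge_is_zero(self):
        assert coulomb_pair(0.7, 0.0, 1.0) == 0.0

    def test_coulomb_cutoff(self):
        assert coulomb_pair(1.3, 1.0, 1.0) == 0.0
        assert coulomb_pair(1.19, 1.0, 1.0) > 0.0

    def test_lj_zero_parameters(self):
        assert lj_pair(0.5, 0.0, 0.0) == 0.0

    def test_lj_minimum_closed_form(self):
        c6, c12 = 0.005, 1.0e-5
        r_star = (2 * c12 / c6) ** (1 / 6)
        assert lj_pair(r_star, c6, c12) == pytest.approx(
            -c6**2 / (4 * c12), rel=1e-12)

    def test_lj_cutoff(self):
        assert lj_pair(1.5, 0.005, 1e-5) == 0.0

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            coulomb_pair(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            lj_pair(0.0, 0.005, 1e-5)


def _random_charged_system(rng, n=30):
    top = toy_topology(2 * n,
                       charges=rng.uniform(-1, 1, 2 * n),
                       c6=rng.uniform(0, 0.01, 2 * n),
                       c12=rng.uniform(0, 2e-5, 2 * n))
    fr = Frame(rng.uniform(0, 4.0, size=(2 * n, 3)),
               np.array([4.0, 4.0, 4.0]))
    return top, fr, AtomGroup(top, np.arange(n)), \
        AtomGroup(top, np.arange(n, 2 * n))


class TestGroupInteraction:
    def test_opposite_unit_charges(self):
        top = toy_topology(2, charges=[1.0, -1.0])
        fr = Frame(np.array([[1.0, 1, 1], [2.0, 1, 1]]),
                   np.array([5.0, 5.0, 5.0]))
        e = group_interaction(fr, AtomGroup(top, np.array([0])),
                              AtomGroup(top, np.array([1])))
        assert e.electrostatic == pytest.approx(-138.935458, abs=1e-9)
        assert e.vdw == 0.0
        assert e.total == e.electrostatic

    def test_matches_brute_force_double_loop(self):
        """Vectorized cross-pair sum equals explicit per-pair evaluation
        (with geometric-mean C6/C12 combination) to 1e-9 relative."""
        rng = np.random.default_rng(19)
        s = NonbondedSettings()
        for _ in range(10):
            top, fr, ga, gb = _random_charged_system(rng)
            elec = vdw = 0.0
            for i in ga.indices:
                for j in gb.indices:
                    d = fr.coordinates[j] - fr.coordinates[i]
                    d -= fr.box * np.round(d / fr.box)
                    r = np.linalg.norm(d)
                    if r < s.coulomb_cutoff:
                        elec += (COULOMB_PREFACTOR * top.charges[i]
                                 * top.charges[j] / r)
                    if r < s.lj_cutoff:
                        c6 = np.sqrt(top.c6[i] * top.c6[j])
                        c12 = np.sqrt(top.c12[i] * top.c12[j])
                        vdw += c12 / r**12 - c6 / r**6
            e = group_interaction(fr, ga, gb, s)
            assert e.electrostatic == pytest.approx(elec, rel=1e-9)
            assert e.vdw == pytest.approx(vdw, rel=1e-9)

    def test_u_inter_difference_identity(self):
        """U(A+B) - U(A) - U(B) from total-energy evaluations equals the
        cross-pair sum, as it must for pairwise-additive potentials."""
        rng = np.random.default_rng(23)
        top, fr, ga, gb = _random_charged_system(rng, n=20)
        s = NonbondedSettings()

        def total_energy(indices):
            e = 0.0
            for ii, i in enumerate(indices):
                for j in indices[ii + 1:]:
                    d = fr.coordinates[j] - fr.coordinates[i]
                    d -= fr.box * np.round(d / fr.box)
                    r = np.linalg.norm(d)
                    if r < s.coulomb_cutoff:
                        e += (COULOMB_PREFACTOR * top.charges[i]
                              * top.charges[j] / r)
                    if r < s.lj_cutoff:
                        e += (np.sqrt(top.c12[i] * top.c12[j]) / r**12
                              - np.sqrt(top.c6[i] * top.c6[j]) / r**6)
            return e

        u_ab = total_energy(list(ga.indices) + list(gb.indices))
        u_a = total_energy(list(ga.indices))
        u_b = total_energy(list(gb.indices))
        direct = group_interaction(fr, ga, gb, s).total
        assert u_ab - u_a - u_b == pytest.approx(direct, rel=1e-9)

    def test_symmetry_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(31)
        top, fr, ga, gb = _random_charged_system(rng, n=15)
        e_ab = group_interaction(fr, ga, gb)
        e_ba = group_interaction(fr, gb, ga)
        assert e_ab.electrostatic == pytest.approx(e_ba.electrostatic,
                                                   rel=1e-12)
        # quarter-turn about z is an exact symmetry of the periodic box
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        c = fr.box / 2
        moved = Frame(((fr.coordinates - c) @ rot.T + c
                       + np.array([0.7, 0.2, -0.5])) % fr.box, fr.box)
        e_rot = group_interaction(moved, ga, gb)
        assert e_rot.electrostatic == pytest.approx(e_ab.electrostatic,
                                                    rel=1e-9)
        assert e_rot.vdw == pytest.approx(e_ab.vdw, rel=1e-9)

    def test_beyond_cutoff_contributes_exactly_zero(self):
        top = toy_topology(2, charges=[1.0, 1.0], c6=[0.01, 0.01],
                           c12=[1e-5, 1e-5])
        fr = Frame(np.array([[0.5, 1, 1], [2.0, 1, 1]]),
                   np.array([8.0, 8.0, 8.0]))
        e = group_interaction(fr, AtomGroup(top, np.array([0])),
                              AtomGroup(top, np.array([1])))
        assert e.electrostatic == 0.0 and e.vdw == 0.0

    def test_overlap_rejected(self):
        top = toy_topology(3)
        fr = Frame(np.eye(3) + 1.0, np.array([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="overlap"):
            group_interaction(fr, AtomGroup(top, np.array([0, 1])),
                              AtomGroup(top, np.array([1, 2])))


class TestTimeseries:
    def test_distant_peptide_gives_all_zero_series(self):
        """Beyond both cutoffs every frame's energy vanishes exactly."""
        from bilayerbind.synthetic import (BilayerSpec, PeptideSpec,
                                           ScriptSpec,
                                           generate_scripted_trajectory)
        top, traj, _ = generate_scripted_trajectory(
            BilayerSpec(lipids_per_leaflet=16, seed=3), PeptideSpec(),
            ScriptSpec(n_frames=3,
                       keyframes=((0.0, 2.6, 2.6, 0.0),
                                  (1e9, 2.6, 2.6, 0.0))))
        pep = select(top, "peptide")
        lip = select(top, "lipid")
        from bilayerbind.core import min_image_distance_matrix
        gap = min_image_distance_matrix(pep.positions(traj[0]),
                                        lip.positions(traj[0]),
                                        traj[0].box).min()
        assert gap > 1.4    # hovering beyond both cutoffs
        df = interaction_timeseries(traj, pep, lip)
        assert (df[["electrostatic", "vdw", "total"]] == 0.0).all().all()

    def test_per_lipid_normalization(self, hovering_run):
        top, traj, _ = hovering_run
        pep = select(top, "peptide")
        lip = select(top, "lipid")
        raw = interaction_timeseries(traj, pep, lip, normalization="raw")
        per = interaction_timeseries(traj, pep, lip,
                                     normalization="per-lipid")
        n_lip = 72
        assert np.allclose(per["total"] * n_lip, raw["total"], rtol=1e-12)

    def test_cation_repelled_by_choline_topped_bilayer(self, neat_bilayer):
        """A cation just above the choline layer of a PC-like bilayer sees
        a positive electrostatic energy: the cationic choline sits closer
        to the water than the phosphate."""
        from bilayerbind.core import Topology, concatenate_topologies
        spec, top, traj = neat_bilayer
        fr = traj[0]
        phos = select(top, "lipid and name P")
        ion_top = Topology(
            names=np.array(["ION"], dtype=object),
            elements=np.array(["NA"], dtype=object),
            resids=np.array([999]),
            resnames=np.array(["ION"], dtype=object),
            molids=np.array([0]),
            molkinds=np.array(["ion"], dtype=object),
            charges=np.array([1.0]), c6=np.zeros(1), c12=np.zeros(1),
            n_implicit_h=np.zeros(1, dtype=int),
            donor=np.zeros(1, bool), acceptor=np.zeros(1, bool))
        comb = concatenate_topologies(top, ion_top)
        x0, y0, zp = fr.coordinates[phos.indices[0]]
        coords = np.vstack([fr.coordinates, [[x0, y0, zp + 0.35]]])
        e = group_interaction(Frame(coords, fr.box),
                              AtomGroup(comb, np.array([comb.n_atoms - 1])),
                              select(comb, "lipid"))
        assert e.electrostatic > 0
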