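"""Hydrogen-bond counting, chi torsions, and RMSD-to-average geometry."""

import numpy as np
import pytest

from cagrna import contacts
from cagrna.contacts import (HBondCriteria, Topology, Trajectory,
                             backbone_selection, chi_torsions, classify_moieties,
                             count_hbonds, dihedral, interaction_delta,
                             read_trajectory, rmsd_to_average,
                             trajectory_interactions, write_trajectory,
                             InteractionTable)
from cagrna.synthetic import gen_atp_binding_trajectory, gen_cag_hairpin, plant_atp


def _random_rotation(seed):
    rng = np.random.default_rng(seed)
    A = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(A) < 0:
        A[:, 0] *= -1
    return A


# --- independent brute-force oracle --------------------------------------

def brute_force_hbond_counts(frame, top, criteria):
    """All-pairs double loop over every donor/acceptor combination."""
    def angle(d, h, a):
        v1, v2 = d - h, a - h
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    atoms = [
        {"name": str(top.atom_name[i]), "res": str(top.residue_name[i]),
         "resi": int(top.residue_index[i]), "chain": str(top.chain_id[i]),
         "xyz": frame[i]}
        for i in range(top.n_atoms)]
    by_res = {}
    for a in atoms:
        by_res.setdefault((a["chain"], a["resi"]), {})[a["name"]] = a

    donors, acceptors = [], []   # (side, heavy atom dict, [H dicts]) / (side, dict)
    for (_, resi), amap in by_res.items():
        res = next(iter(amap.values()))["res"]
        if res in contacts.RNA_RESIDUES:
            for (r, n), hs in contacts.RNA_DONORS.items():
                if r == res and n in amap:
                    hlist = [amap[h] for h in hs if h in amap]
                    if hlist:
                        donors.append(("rna", amap[n], hlist))
            for n in contacts.RNA_ACCEPTORS[res]:
                if n in amap:
                    acceptors.append(("rna", amap[n]))
        else:
            for n, hs in contacts.ATP_DONORS.items():
                if n in amap:
                    hlist = [amap[h] for h in hs if h in amap]
                    if hlist:
                        donors.append(("atp", amap[n], hlist))
            for n in contacts.ATP_ACCEPTORS:
                if n in amap:
                    acceptors.append(("atp", amap[n]))

    counts = {k: 0.0 for k in [("base", b) for b in "ACGU"]
              + [("ribose", ""), ("phosphate", "")]}
    for d_side, d, hlist in donors:
        for a_side, a in acceptors:
            if d_side == a_side:
                continue
            if np.linalg.norm(d["xyz"] - a["xyz"]) >= criteria.d_max:
                continue
            if not any(angle(d["xyz"], h["xyz"], a["xyz"]) > criteria.theta_min
                       for h in hlist):
                continue
            rna_atom = a if d_side == "atp" else d
            name, res = rna_atom["name"], rna_atom["res"]
            if name in contacts.PHOSPHATE_ATOMS:
                counts[("phosphate", "")] += 1
            elif name in contacts.RIBOSE_ATOMS:
                counts[("ribose", "")] += 1
            else:
                counts[("base", res)] += 1
    return counts


class TestMoietyClassification:
    def test_definition_table(self, hairpin4):
        top = hairpin4.trajectory.topology
        mm = classify_moieties(top)
        g_p = np.nonzero((top.residue_name == "G") & (top.atom_name == "P"))[0][0]
        assert mm.moiety[g_p] == "phosphate"
        a_n1 = np.nonzero((top.residue_name == "A") & (top.atom_name == "N1"))[0][0]
        assert mm.moiety[a_n1] == "base" and mm.wc_edge[a_n1]

    def test_every_heavy_atom_classified(self, hairpin4):
        top = hairpin4.trajectory.topology
        mm = classify_moieties(top)
        heavy_rna = (top.element != "H") & np.isin(top.residue_name, list("ACGU"))
        assert np.all(mm.moiety[heavy_rna] != "")
        assert np.all(mm.moiety[~heavy_rna] == "")

    def test_unknown_atom_raises(self):
        top = Topology(atom_name=["XX"], residue_name=["G"], residue_index=[1],
                       chain_id=["R"], element=["X"])
        with pytest.raises(contacts.MoietyClassificationError, match="XX"):
            classify_moieties(top)


def _two_atom_system(d_da, theta_deg):
    """One ATP N6-H61 donor aimed at one RNA G O6 acceptor."""
    h = np.array([0.10, 0.0, 0.0])
    ang = np.radians(180.0 - theta_deg)
    r = d_da - 0.10 if theta_deg == 180.0 else None
    # place acceptor so that d(D,A)=d_da and angle(D,H,A)=theta
    # D at origin, H at +x: acceptor at angle theta from D as seen from H
    from scipy.optimize import brentq
    def f(rr):
        a = h + rr * np.array([np.cos(np.pi - np.radians(theta_deg)),
                               np.sin(np.pi - np.radians(theta_deg)), 0.0])
        return np.linalg.norm(a) - d_da
    rr = brentq(f, 1e-4, 5.0)
    a_xyz = h + rr * np.array([np.cos(np.pi - np.radians(theta_deg)),
                               np.sin(np.pi - np.radians(theta_deg)), 0.0])
    top = Topology(atom_name=["N6", "H61", "O6"], residue_name=["ATP", "ATP", "G"],
                   chain_id=["T", "T", "R"], residue_index=[2, 2, 1],
                   element=["N", "H", "O"])
    frame = np.stack([np.zeros(3), h, a_xyz])
    return top, frame


class TestHBondCounting:
    def test_collinear_close_pair_counted(self):
        top, frame = _two_atom_system(0.28, 179.9)
        counts = count_hbonds(frame, top, HBondCriteria())
        assert counts[("base", "G")] == 1

    def test_distance_criterion_rejects(self):
        top, frame = _two_atom_system(0.50, 179.9)
        assert sum(count_hbonds(frame, top, HBondCriteria()).values()) == 0

    def test_angle_criterion_rejects(self):
        top, frame = _two_atom_system(0.30, 100.0)
        assert sum(count_hbonds(frame, top, HBondCriteria()).values()) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle_on_random_fixtures(self, hairpin4, seed):
        """Vectorized counting equals the all-pairs loop on random coordinates."""
        traj = plant_atp(hairpin4, 6, "O6")
        rng = np.random.default_rng(seed)
        crit = HBondCriteria()
        for _ in range(3):
            frame = rng.uniform(0.0, 1.6, size=(traj.topology.n_atoms, 3))
            assert count_hbonds(frame, traj.topology, crit) == \
                brute_force_hbond_counts(frame, traj.topology, crit)

    def test_planted_bond_found_exactly(self, hairpin20):
        """An ATP planted at donor-acceptor geometry against an exposed
        WC-edge atom yields exactly the planted bond."""
        for resi, atom, base in [(30, "O6", "G"), (14, "N7", "A")]:
            traj = plant_atp(hairpin20, resi, atom, distance=0.29, angle_deg=175.0)
            counts = count_hbonds(traj.coords[0], traj.topology, HBondCriteria())
            assert counts[("base", base)] == 1
            assert sum(counts.values()) == 1

    def test_base_total_equals_sum_of_nucleobases(self, hairpin20):
        traj = gen_atp_binding_trajectory(hairpin20, 30, "O6", n_frames=6,
                                          bound_fraction=0.5)
        table = trajectory_interactions(traj, "native")
        assert table.base_total == pytest.approx(
            sum(v for (m, _), v in table.counts.items() if m == "base"))


class TestInteractionDelta:
    def _table(self, state, over=None):
        counts = {k: 0.0 for k in [("base", b) for b in "ACGU"]
                  + [("ribose", ""), ("phosphate", "")]}
        counts.update(over or {})
        return InteractionTable(state=state, n_frames=10, counts=counts)

    def test_identical_tables_zero_delta(self):
        t = self._table("native", {("base", "A"): 1.5})
        assert all(v == 0 for v in interaction_delta(t, t).values())

    def test_unit_shift_in_adenine(self):
        nat = self._table("native", {("base", "A"): 1.0})
        unw = self._table("unwound", {("base", "A"): 2.0})
        delta = interaction_delta(nat, unw)
        assert delta[("base", "A")] == 1.0
        assert all(v == 0 for k, v in delta.items() if k != ("base", "A"))

    def test_mismatched_indices_rejected(self):
        t = self._table("native")
        broken = InteractionTable(state="unwound", n_frames=10,
                                  counts={("base", "A"): 1.0})
        with pytest.raises(ValueError, match="mismatched"):
            interaction_delta(t, broken)

    def test_planted_wc_contacts_shift_base_not_phosphate(self, hairpin20):
        """More frequent WC-edge binding in the unwound topology shows up as
        a positive base delta with zero phosphate delta."""
        native = trajectory_interactions(
            gen_atp_binding_trajectory(hairpin20, 30, "O6", 10, 0.2), "native")
        unwound = trajectory_interactions(
            gen_atp_binding_trajectory(hairpin20, 30, "O6", 10, 0.8), "unwound")
        delta = interaction_delta(native, unwound)
        assert delta[("base", "G")] == pytest.approx(0.6, abs=1e-12)
        assert delta[("phosphate", "")] == 0.0


class TestChiTorsions:
    def test_cis_is_zero_and_trans_is_180(self):
        p = [np.array([1.0, 1.0, 0.0]), np.array([0.0, 1.0, 0.0]),
             np.array([0.0, 0.0, 0.0])]
        assert dihedral(p[0], p[1], p[2], np.array([1.0, 0.0, 0.0])) == pytest.approx(0.0, abs=1e-12)
        assert abs(dihedral(p[0], p[1], p[2], np.array([-1.0, 0.0, 0.0]))) == pytest.approx(180.0, abs=1e-12)

    def test_rotation_invariance(self, hairpin20):
        frame = hairpin20.trajectory.coords[0]
        top = hairpin20.trajectory.topology
        chi0 = chi_torsions(frame, top)
        rotated = frame @ _random_rotation(1).T + np.array([0.5, -2.0, 3.0])
        chi1 = chi_torsions(rotated, top)
        assert max(abs(chi0[k] - chi1[k]) for k in chi0) < 1e-9

    def test_missing_atom_gives_nan(self):
        top = Topology(atom_name=["O4'", "C1'", "N1"], residue_name=["C"] * 3,
                       residue_index=[1] * 3, chain_id=["R"] * 3,
                       element=["O", "C", "N"])
        chi = chi_torsions(np.eye(3), top)
        assert np.isnan(chi[("R", 1)])

    def test_every_nucleotide_has_chi(self, hairpin20):
        chi = chi_torsions(hairpin20.trajectory.coords[0],
                           hairpin20.trajectory.topology)
        assert len(chi) == 60
        assert all(np.isfinite(v) for v in chi.values())
        assert all(-180.0 < v <= 180.0 for v in chi.values())


class TestRMSD:
    def test_identical_frames_zero(self, hairpin4):
        coords = np.repeat(hairpin4.trajectory.coords, 4, axis=0)
        traj = Trajectory(topology=hairpin4.trajectory.topology, coords=coords)
        assert np.allclose(rmsd_to_average(traj), 0.0, atol=1e-12)

    def test_rigid_transforms_removed(self, hairpin4):
        base = hairpin4.trajectory.coords[0]
        frames = [base @ _random_rotation(s).T + np.array([s, -s, 2.0 * s])
                  for s in range(5)]
        traj = Trajectory(topology=hairpin4.trajectory.topology,
                          coords=np.stack(frames))
        r = rmsd_to_average(traj, backbone_selection(traj.topology))
        assert np.max(r) < 1e-9

    def test_two_frame_single_displacement_closed_form(self):
        """One atom displaced by d (others fixed): RMSD per frame is the
        brute-force value of the 2-frame average problem."""
        rng = np.random.default_rng(5)
        base = rng.normal(size=(8, 3))
        top = Topology(atom_name=["C1'"] * 8, residue_name=["A"] * 8,
                       residue_index=list(range(1, 9)), chain_id=["R"] * 8,
                       element=["C"] * 8)
        moved = base.copy()
        moved[0] += np.array([0.1, 0.0, 0.0])
        traj = Trajectory(topology=top, coords=np.stack([base, moved]))
        r = rmsd_to_average(traj, refine_iterations=0)

        # brute-force oracle: superpose frame1 on frame0, average, measure
        from cagrna.contacts import _superpose
        aligned = np.stack([base, _superpose(moved, base)])
        avg = aligned.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((aligned - avg) ** 2, axis=2), axis=1))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_monotone_under_scaled_displacements(self, hairpin4):
        base = hairpin4.trajectory.coords[0]
        rng = np.random.default_rng(2)
        noise = rng.normal(size=base.shape)
        rms = []
        for scale in (0.01, 0.02, 0.05):
            traj = Trajectory(topology=hairpin4.trajectory.topology,
                              coords=np.stack([base, base + scale * noise]))
            rms.append(float(rmsd_to_average(traj).max()))
        assert rms[0] < rms[1] < rms[2]

    def test_degenerate_selection_warns(self):
        top = Topology(atom_name=["C1'"] * 4, residue_name=["A"] * 4,
                       residue_index=[1, 2, 3, 4], chain_id=["R"] * 4,
                       element=["C"] * 4)
        line = np.stack([np.array([float(i), 0.0, 0.0]) for i in range(4)])
        traj = Trajectory(topology=top, coords=np.stack([line, line + 0.1]))
        with pytest.warns(UserWarning, match="collinear"):
            rmsd_to_average(traj)


class TestPDBRoundTrip:
    def test_multimodel_roundtrip(self, hairpin4, tmp_path):
        traj = gen_atp_binding_trajectory(hairpin4, 6, "O6", n_frames=3,
                                          bound_fraction=0.5)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 3
        assert back.topology.n_atoms == traj.topology.n_atoms
        assert list(back.topology.atom_name) == list(traj.topology.atom_name)
        # PDB stores angstroms to 3 decimals -> 5e-5 nm quantization
        assert np.max(np.abs(back.coords - traj.coords)) < 1e-4
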