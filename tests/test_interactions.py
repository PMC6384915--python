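"""Hydrogen-bond detection, side-chain contacts, and Phe stacking."""

import numpy as np
import pytest

from pepagg import interactions as ia
from pepagg.core import Atom, Frame, Residue, Topology, Trajectory, make_residue
from pepagg.geometry import min_image_distance


def gly_residue_with_h():
    return make_residue("GLY", 1)  # atoms N, H, CA, C, O


def hbond_frame(da_distance, box=104.0, same_peptide=False):
    """Two GLY residues with a linear N-H...O=C geometry at the given D-A
    distance (donor on peptide 0 unless same_peptide)."""
    # donor residue: N at x=0, H toward +x; acceptor: O at x=da, C beyond
    donor = np.array(
        [
            [0.0, 0.0, 0.0],  # N
            [1.0, 0.0, 0.0],  # H
            [-0.7, 1.2, 0.0],  # CA
            [-2.1, 1.3, 0.0],  # C
            [-2.8, 2.3, 0.0],  # O
        ]
    )
    acceptor = np.array(
        [
            [da_distance + 4.0, 3.0, 0.0],  # N
            [da_distance + 4.5, 2.2, 0.0],  # H
            [da_distance + 2.8, 2.6, 0.0],  # CA
            [da_distance + 1.23, 0.0, 0.0],  # C
            [da_distance, 0.0, 0.0],  # O
        ]
    )
    coords = np.vstack([donor, acceptor]) + 20.0
    if same_peptide:
        res1 = gly_residue_with_h()
        res2 = make_residue("GLY", 2)
        topo = Topology([[res1, res2]])
    else:
        topo = Topology([[gly_residue_with_h()], [gly_residue_with_h()]])
    return topo, Frame(coords, box)


class TestHBonds:
    def test_ideal_geometry_gives_one_mm_bond(self):
        topo, fr = hbond_frame(2.9)
        bonds = ia.detect_hbonds(fr, topo)
        assert len(bonds) == 1
        assert bonds[0].hbond_class == "MM"

    def test_intra_peptide_bond_excluded(self):
        topo, fr = hbond_frame(2.9, same_peptide=True)
        assert ia.detect_hbonds(fr, topo) == []

    def test_long_distance_rejected(self):
        topo, fr = hbond_frame(4.5)
        assert ia.detect_hbonds(fr, topo) == []

    def test_sidechain_acceptor_classified_ms(self):
        # replace the acceptor carbonyl O by a Ser hydroxyl O at the same spot
        topo, fr = hbond_frame(2.9)
        ser = make_residue("SER", 1)
        coords = np.zeros((len(ser.atoms), 3))
        name_to_slot = {a.atom_name: k for k, a in enumerate(ser.atoms)}
        coords[name_to_slot["N"]] = [10.0, 10.0, 0.0]
        coords[name_to_slot["H"]] = [10.0, 11.0, 0.0]
        coords[name_to_slot["CA"]] = [11.2, 9.4, 0.0]
        coords[name_to_slot["C"]] = [12.6, 9.9, 0.0]
        coords[name_to_slot["O"]] = [13.6, 9.2, 0.0]
        coords[name_to_slot["CB"]] = [11.3, 7.9, 0.0]
        coords[name_to_slot["OG"]] = fr.coordinates[9]  # acceptor O position
        donor_coords = fr.coordinates[:5]
        topo2 = Topology([[gly_residue_with_h()], [ser]])
        fr2 = Frame(np.vstack([donor_coords, coords]), fr.box_edge)
        classes = {b.hbond_class for b in ia.detect_hbonds(fr2, topo2)}
        assert "MS" in classes

    def test_summary_total_is_sum_of_classes(self, small_aggregation):
        _, traj, _ = small_aggregation
        out = ia.hbond_summary(traj, 0.0, traj.times[-1])
        assert out["Total"] == pytest.approx(
            out["MM"] + out["MS"] + out["SS"], abs=1e-15
        )

    def test_summary_normalisation(self):
        topo, fr = hbond_frame(2.9)
        frames = [
            Frame(fr.coordinates, fr.box_edge, time=10.0 * k) for k in range(4)
        ]
        out = ia.hbond_summary(Trajectory(topo, frames))
        # 1 MM bond per frame, 2 sequence residues
        assert out["MM"] == pytest.approx(0.5)
        assert out["Total"] == pytest.approx(0.5)

    def test_zero_bond_system_all_zero(self):
        topo, fr = hbond_frame(20.0)
        out = ia.hbond_summary(Trajectory(topo, [fr]))
        assert set(out.values()) == {0.0}


def pair_frame(resname_a, resname_b, atom_a, atom_b, separation, box=104.0):
    """Two single-residue peptides with the named side-chain atoms placed
    ``separation`` apart; all other atoms far away from everything."""
    res_a = make_residue(resname_a, 7 if resname_a == "SER" else 1)
    res_b = make_residue(resname_b, 8 if resname_b == "SER" else 1)
    topo = Topology([[res_a], [res_b]])
    coords = np.zeros((topo.n_atoms, 3))
    offset = 0
    spread = 30.0
    for r, (res, target, xyz) in enumerate(
        [
            (res_a, atom_a, np.array([20.0, 20.0, 20.0])),
            (res_b, atom_b, np.array([20.0 + separation, 20.0, 20.0])),
        ]
    ):
        for k, atom in enumerate(res.atoms):
            if atom.atom_name == target:
                coords[offset + k] = xyz
            else:
                coords[offset + k] = [spread + 3.0 * (offset + k), 80.0, 80.0]
        offset += len(res.atoms)
    return topo, Frame(coords, box)


class TestSidechainContacts:
    def test_ile_leu_within_cutoff(self):
        topo, fr = pair_frame("ILE", "LEU", "CD1", "CD1", 5.0)
        contacts = ia.sidechain_contacts(fr, topo)
        assert len(contacts) == 1
        ((ra, rb),) = contacts
        assert ia.residue_pair_label(topo, ra, rb) == ("I", "L")

    def test_beyond_cutoff_no_contact(self):
        topo, fr = pair_frame("ILE", "LEU", "CD1", "CD1", 5.6)
        assert ia.sidechain_contacts(fr, topo) == {}

    def test_gly_has_no_aliphatic_carbons(self):
        topo, fr = pair_frame("GLY", "GLY", "CA", "CA", 1.0)
        assert ia.sidechain_contacts(fr, topo) == {}

    def test_residue_pair_counted_once_per_frame(self):
        # place whole Leu side chains on top of each other: many atom pairs
        topo = Topology([[make_residue("LEU", 1)], [make_residue("LEU", 1)]])
        coords = np.zeros((topo.n_atoms, 3))
        n = len(topo.peptides[0][0].atoms)
        for k in range(n):
            coords[k] = [20.0 + 1.3 * k, 20.0, 20.0]
            coords[n + k] = [20.0 + 1.3 * k, 22.0, 20.0]
        contacts = ia.sidechain_contacts(Frame(coords, 104.0), topo)
        assert sum(contacts.values()) == 1

    def test_ser7_ser8_kept_distinct(self):
        topo, fr = pair_frame("SER", "PHE", "CB", "CB", 5.0)
        contacts = ia.sidechain_contacts(fr, topo)
        ((ra, rb),) = contacts
        assert ia.residue_pair_label(topo, ra, rb) == ("F", "S7")

    def test_matches_bruteforce_on_random_frames(self, small_aggregation):
        """Periodic-tree contact search equals the all-pairs oracle."""
        _, traj, _ = small_aggregation
        topo = traj.topology
        ali = np.where(topo.atom_is_aliphatic_sc & ~topo.atom_is_cap)[0]
        for fr in traj.frames[::4]:
            got = ia.sidechain_contacts(fr, topo)
            xyz = fr.coordinates[ali]
            d = min_image_distance(
                xyz[:, None, :], xyz[None, :, :], fr.box_edge
            )
            want = set()
            for i in range(len(ali)):
                for j in range(i + 1, len(ali)):
                    if (
                        d[i, j] < ia.SIDECHAIN_CUTOFF
                        and topo.atom_peptide[ali[i]] != topo.atom_peptide[ali[j]]
                    ):
                        want.add(
                            tuple(
                                sorted(
                                    (
                                        int(topo.atom_residue[ali[i]]),
                                        int(topo.atom_residue[ali[j]]),
                                    )
                                )
                            )
                        )
            assert set(got) == want


class TestContactSummary:
    def _trajectory_with_counts(self):
        """3 frames; Ile-Leu contact in all 3, Phe-Ser contact in 1."""
        frames = []
        for k in range(3):
            il_sep = 5.0
            fs_sep = 5.0 if k == 0 else 20.0
            topo_a, fr_a = pair_frame("ILE", "LEU", "CD1", "CD1", il_sep)
            topo_b, fr_b = pair_frame("PHE", "SER", "CB", "CB", fs_sep)
            topo = Topology(topo_a.peptides + topo_b.peptides)
            coords = np.vstack(
                [fr_a.coordinates, fr_b.coordinates + np.array([0, 40.0, 0])]
            )
            frames.append(Frame(coords, 104.0, time=10.0 * k))
        return Trajectory(topo, frames)

    def test_highest_contact_percentage(self):
        table = ia.contact_summary(self._trajectory_with_counts())
        assert table.highest_pair[0] == ("I", "L")
        assert table.highest_pair[1] == pytest.approx(75.0)
        assert table.pair_counts[("I", "L")] == pytest.approx(1.0)

    def test_single_pair_is_100_percent(self):
        topo, fr = pair_frame("ILE", "LEU", "CD1", "CD1", 5.0)
        table = ia.contact_summary(Trajectory(topo, [fr]))
        assert table.highest_pair == (("I", "L"), pytest.approx(100.0))

    def test_total_conventions_differ_by_factor_two(self):
        table = ia.contact_summary(self._trajectory_with_counts())
        assert table.total_per_residue_participating == pytest.approx(
            2 * table.total_per_residue
        )

    def test_empty_window_errors(self):
        topo, fr = pair_frame("ILE", "LEU", "CD1", "CD1", 5.0)
        with pytest.raises(ValueError, match="window"):
            ia.contact_summary(Trajectory(topo, [fr]), 100.0, 200.0)

    def test_frame_reordering_invariance(self, small_aggregation):
        _, traj, _ = small_aggregation
        t = ia.contact_summary(traj)
        reversed_frames = [
            Frame(fr.coordinates, fr.box_edge, time=tm)
            for fr, tm in zip(traj.frames[::-1], traj.times)
        ]
        t_rev = ia.contact_summary(Trajectory(traj.topology, reversed_frames))
        assert t.pair_counts == t_rev.pair_counts
        assert t.total_per_residue == pytest.approx(t_rev.total_per_residue)


class TestPheStacking:
    def _phe_pair(self, separation):
        from pepagg.builder import single_peptide_topology

        topo1, fr1 = single_peptide_topology("F", capped=False, box_edge=104.0)
        topo = Topology([topo1.peptides[0],
                         [make_residue("PHE", 1)]])
        shift = np.array([separation, 0.0, 0.0])
        coords = np.vstack([fr1.coordinates, fr1.coordinates + shift])
        fr = Frame(coords, 104.0)
        resids, cents = ia.phe_ring_centroids(fr, topo)
        actual = min_image_distance(cents[0], cents[1], 104.0)
        return topo, fr, actual

    def test_stacked_rings_counted(self):
        topo, fr, d = self._phe_pair(4.0)
        assert d == pytest.approx(4.0)
        assert ia.phe_stacking(fr, topo) == 1

    def test_separated_rings_not_counted(self):
        topo, fr, d = self._phe_pair(6.0)
        assert ia.phe_stacking(fr, topo) == 0

    def test_phe_free_system_always_zero(self):
        from pepagg.synthetic import AggregationParams, gen_aggregation_trajectory

        params = AggregationParams(
            n_peptides=4, box_edge=60.0, sequence="NAGAILSS", label="F2A",
            n_frames=10, seed=2,
        )
        traj = gen_aggregation_trajectory(params)
        assert (ia.phe_stacking_series(traj) == 0).all()
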