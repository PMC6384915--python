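"""Kabsch–Sander assignment against a reference DSSP implementation.

The oracle is mdtraj's DSSP port, run on PDB files written by the fixture
generators.  H/G/E/B codes must match exactly; T/S/C boundary choices may
differ between DSSP variants and are not compared.
"""

import numpy as np
import pytest

from pepagg import io
from pepagg import secondary_structure as ss
from pepagg.builder import single_peptide_topology
from pepagg.core import Frame
from pepagg.synthetic import gen_beta_sheet, gen_ideal_helix

mdtraj = pytest.importorskip("mdtraj")

STRUCTURED = set("HGEB")


def reference_codes(tmp_path, topo, frame, name):
    path = tmp_path / f"{name}.pdb"
    io.write_pdb(path, topo, frame)
    ref = mdtraj.compute_dssp(mdtraj.load(str(path)), simplified=False)[0]
    return np.where(ref == " ", "C", ref)


def structured_match(mine, ref):
    """H/G/E/B agree position by position; loopish codes not compared."""
    mine = [c for c in mine if c != "-"]
    assert len(mine) == len(ref)
    return all(
        m == r
        for m, r in zip(mine, ref)
        if m in STRUCTURED or r in STRUCTURED
    )


def fixture_structures():
    yield "helix8", lambda: gen_ideal_helix(8)
    yield "helix10", lambda: gen_ideal_helix(10)
    yield "helix12", lambda: gen_ideal_helix(12)
    yield "helix15", lambda: gen_ideal_helix(15)
    yield "helix_seq", lambda: gen_ideal_helix(8, sequence="NFGAILSS")
    yield "g-helix", lambda: single_peptide_topology(
        "A" * 10, phi=-49, psi=-26, capped=False, box_edge=200.0
    )
    yield "anti2", lambda: gen_beta_sheet(2, "antiparallel", 8)
    yield "anti3", lambda: gen_beta_sheet(3, "antiparallel", 8)
    yield "anti2_long", lambda: gen_beta_sheet(2, "antiparallel", 10,
                                               sequence="A" * 10)
    yield "anti_seq", lambda: gen_beta_sheet(2, "antiparallel", 8,
                                             sequence="NFGAILSS")
    yield "par2", lambda: gen_beta_sheet(2, "parallel", 8)
    yield "par3", lambda: gen_beta_sheet(3, "parallel", 8)
    yield "par2_long", lambda: gen_beta_sheet(2, "parallel", 10,
                                              sequence="A" * 10)
    yield "par_seq", lambda: gen_beta_sheet(2, "parallel", 8,
                                            sequence="NFGAILSS")
    yield "extended", lambda: single_peptide_topology(
        "A" * 10, phi=-139, psi=135, capped=False, box_edge=200.0
    )
    yield "ppii", lambda: single_peptide_topology(
        "A" * 10, phi=-75, psi=145, capped=False, box_edge=200.0
    )
    yield "far_strands", lambda: gen_beta_sheet(
        2, "antiparallel", 8, strand_separation=30.0
    )
    for k in range(3):
        rng = np.random.default_rng(100 + k)
        phi = rng.uniform(-160, -50, size=10)
        psi = rng.uniform(-60, 160, size=10)
        yield f"coil{k}", (
            lambda phi=phi, psi=psi: single_peptide_topology(
                "A" * 10, phi=phi, psi=psi, capped=False, box_edge=200.0
            )
        )


@pytest.mark.parametrize(
    "name,make", list(fixture_structures()), ids=lambda x: x if isinstance(x, str) else ""
)
def test_codes_match_reference_dssp(tmp_path, name, make):
    topo, frame = make()
    mine, _ = ss.assign_ss_frame(frame, topo)
    ref = reference_codes(tmp_path, topo, frame, name)
    assert structured_match(mine, ref), (
        f"{name}: mine={''.join(mine)} ref={''.join(ref)}"
    )


def test_helix_fraction_matches_reference_exactly(tmp_path):
    topo, frame = gen_ideal_helix(12)
    mine, _ = ss.assign_ss_frame(frame, topo)
    ref = reference_codes(tmp_path, topo, frame, "hfrac")
    mine_seq = [c for c in mine if c != "-"]
    assert np.mean(np.isin(mine_seq, list("GHI"))) == pytest.approx(
        np.mean(np.isin(ref, list("GHI")))
    )
    assert np.mean(np.isin(mine_seq, list("EB"))) == pytest.approx(
        np.mean(np.isin(ref, list("EB")))
    )


class TestHBondEnergy:
    def test_helix_i_to_i_minus_4_is_bonded(self):
        topo, frame = gen_ideal_helix(12)
        bb = ss._BackboneIndex(topo)
        xyz = frame.coordinates
        # donor residue 6 N-H to acceptor residue 2 C=O
        h = ss.reconstruct_amide_h(
            xyz[bb.idx["N"][6]], xyz[bb.idx["C"][5]], xyz[bb.idx["O"][5]],
            frame.box_edge,
        )
        e = ss.backbone_hbond_energy(
            xyz[bb.idx["N"][6]], h, xyz[bb.idx["C"][2]], xyz[bb.idx["O"][2]],
            frame.box_edge,
        )
        assert e < -0.5

    def test_distant_pair_has_negligible_energy(self):
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        c = np.array([50.0, 0.0, 0.0])
        o = np.array([51.23, 0.0, 0.0])
        e = ss.backbone_hbond_energy(n, h, c, o, 200.0)
        assert abs(e) < 0.5

    def test_formula_is_directional(self):
        topo, frame = gen_ideal_helix(12)
        bb = ss._BackboneIndex(topo)
        xyz = frame.coordinates
        h6 = ss.reconstruct_amide_h(
            xyz[bb.idx["N"][6]], xyz[bb.idx["C"][5]], xyz[bb.idx["O"][5]],
            frame.box_edge,
        )
        h2 = ss.reconstruct_amide_h(
            xyz[bb.idx["N"][2]], xyz[bb.idx["C"][1]], xyz[bb.idx["O"][1]],
            frame.box_edge,
        )
        forward = ss.backbone_hbond_energy(
            xyz[bb.idx["N"][6]], h6, xyz[bb.idx["C"][2]], xyz[bb.idx["O"][2]],
            frame.box_edge,
        )
        backward = ss.backbone_hbond_energy(
            xyz[bb.idx["N"][2]], h2, xyz[bb.idx["C"][6]], xyz[bb.idx["O"][6]],
            frame.box_edge,
        )
        assert forward < -0.5 < backward


class TestAssignmentRules:
    def test_short_helix_has_no_H(self):
        topo, frame = gen_ideal_helix(4, sequence="AAAA")
        codes, _ = ss.assign_ss_frame(frame, topo)
        assert "H" not in codes

    def test_isolated_strand_has_no_E_or_B(self):
        topo, frame = single_peptide_topology(
            "A" * 10, phi=-139, psi=135, capped=False, box_edge=200.0
        )
        codes, _ = ss.assign_ss_frame(frame, topo)
        assert not set(codes) & {"E", "B"}

    def test_rigid_motion_invariance(self):
        topo, frame = gen_ideal_helix(12)
        codes0, _ = ss.assign_ss_frame(frame, topo)
        rng = np.random.default_rng(5)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = 1.1
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
             [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
        centre = frame.coordinates.mean(axis=0)
        moved = (frame.coordinates - centre) @ R.T + centre + 13.7
        codes1, _ = ss.assign_ss_frame(Frame(moved, frame.box_edge), topo)
        np.testing.assert_array_equal(codes0, codes1)

    def test_caps_are_excluded(self):
        topo, frame = single_peptide_topology(
            "NFGAILSS", phi=-57, psi=-47, capped=True, box_edge=200.0
        )
        codes, _ = ss.assign_ss_frame(frame, topo)
        assert codes[0] == "-" and codes[-1] == "-"
        assert len(codes) == topo.n_residues


class TestFractions:
    def make_matrix(self, rows, bridges=None):
        codes = np.array([list(r) for r in rows])
        return ss.SSMatrix(
            codes=codes,
            times=10.0 * np.arange(len(rows)),
            bridges=bridges or [[] for _ in rows],
            sequence_mask=np.ones(codes.shape[1], bool),
        )

    def test_hand_counted_fractions(self):
        m = self.make_matrix(["CEEECHHC"])
        beta, helix = ss.ss_fractions(m)
        assert (beta, helix) == (pytest.approx(37.5), pytest.approx(25.0))

    def test_all_coil_and_all_helix(self):
        assert ss.ss_fractions(self.make_matrix(["CCCC"])) == (0.0, 0.0)
        assert ss.ss_fractions(self.make_matrix(["HHHH"])) == (0.0, 100.0)

    def test_fractions_bounded(self, small_aggregation):
        _, traj, _ = small_aggregation
        m = ss.assign_ss(traj)
        beta, helix = ss.ss_fraction_series(m)
        assert (beta >= 0).all() and (helix >= 0).all()
        assert (beta + helix <= 100).all()

    def test_window_selection(self):
        m = self.make_matrix(["CCCC", "EEEE"])
        assert ss.ss_fractions(m, 10, 10)[0] == pytest.approx(100.0)
        with pytest.raises(ValueError, match="window"):
            ss.ss_fractions(m, 100, 200)

    def test_beta_topology_fractions(self):
        topo_a, fr_a = gen_beta_sheet(2, "antiparallel", 8)
        m = ss.assign_ss(fr_a, topo_a)
        par, anti = ss.beta_topology_fractions(m)
        assert par == 0.0 and anti > 0.0
        topo_p, fr_p = gen_beta_sheet(2, "parallel", 8)
        m = ss.assign_ss(fr_p, topo_p)
        par, anti = ss.beta_topology_fractions(m)
        assert par > 0.0 and anti == 0.0
        topo_f, fr_f = gen_beta_sheet(2, "antiparallel", 8,
                                      strand_separation=30.0)
        m = ss.assign_ss(fr_f, topo_f)
        assert ss.beta_topology_fractions(m) == (0.0, 0.0)
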