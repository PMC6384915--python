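"""Internal-coordinate construction of idealised peptide geometries.

Builds capped or uncapped peptides at prescribed backbone dihedrals using
the NeRF (natural extension reference frame) placement, with side chains
from fixed representative rotamers.  This is fixture/starting-structure
geometry: chemically plausible bond lengths and angles, not an energy
minimum.
"""

from __future__ import annotations

import numpy as np

from . import residues as rt
from .core import Frame, Topology, make_residue


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position of atom d given chain a-b-c, |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    sequence: str,
    phi: float | np.ndarray = -139.0,
    psi: float | np.ndarray = 135.0,
    omega: float = 180.0,
    capped: bool = True,
    radii_table: str = "bondi",
):
    """Build one peptide; returns (list_of_Residue, coords (n_atoms, 3)).

    ``sequence`` is one-letter code; ``phi``/``psi`` may be scalars or
    per-residue arrays (degrees).  When ``capped`` the chain carries an
    N-terminal acetyl (ACE) and a C-terminal N-methyl amide (NME).
    """
    n = len(sequence)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n,))
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n,))
    resnames = [rt.ONE_TO_THREE[c] for c in sequence]

    # --- backbone trace: [C'(-1)], N, CA, C, N, CA, C, ... -----------------
    # seed triangle for the first residue (ACE methyl-C, carbonyl C) or a
    # virtual previous carbonyl when uncapped.
    coords: dict[tuple[int, str], np.ndarray] = {}
    # virtual/cap previous residue atoms: CH3 - C(=O) preceding N(0)
    ch3 = np.array([0.0, 0.0, 0.0])
    c_prev = np.array([rt.BOND_C_CH3, 0.0, 0.0])
    n0 = place_atom(
        ch3 + np.array([0.0, 1.0, 0.0]), ch3, c_prev,
        rt.BOND_C_N, rt.ANGLE_CA_C_N, 0.0,
    )
    prev_ca, prev_c = ch3, c_prev  # stand in for CA(i-1), C(i-1)
    o_prev = None
    backbone = []  # per residue dict of N, CA, C, O, H
    for i in range(n):
        if i == 0:
            N = n0
        else:
            N = place_atom(
                backbone[i - 1]["N"], backbone[i - 1]["CA"], backbone[i - 1]["C"],
                rt.BOND_C_N, rt.ANGLE_CA_C_N, psi[i - 1],
            )
        CA = place_atom(
            prev_ca, prev_c, N, rt.BOND_N_CA, rt.ANGLE_C_N_CA, omega
        )
        C = place_atom(prev_c, N, CA, rt.BOND_CA_C, rt.ANGLE_N_CA_C, phi[i])
        # carbonyl O: trans to the next N, i.e. torsion psi+180 about N-CA-C
        O = place_atom(N, CA, C, rt.BOND_C_O, rt.ANGLE_CA_C_O, psi[i] + 180.0)
        # amide H: in the peptide plane, anti to the previous carbonyl O
        if o_prev is not None:
            h_dir = prev_c - o_prev
        else:
            h_dir = N - 0.5 * (prev_c + CA)
        H = N + rt.BOND_N_H * h_dir / np.linalg.norm(h_dir)
        backbone.append({"N": N, "CA": CA, "C": C, "O": O, "H": H})
        prev_ca, prev_c, o_prev = CA, C, O

    ace_o = None
    if capped:
        # ACE carbonyl O on the seed carbonyl carbon, trans to N-H(0)
        ace_o = place_atom(
            n0, ch3, c_prev, rt.BOND_C_O, rt.ANGLE_CA_C_O, 180.0
        )
        # recompute H(0) anti to the now-known ACE carbonyl
        h_dir = c_prev - ace_o
        backbone[0]["H"] = backbone[0]["N"] + rt.BOND_N_H * h_dir / np.linalg.norm(h_dir)

    # --- side chains -------------------------------------------------------
    sidechains = []
    for i, resname in enumerate(resnames):
        placed = dict(backbone[i])
        out = {}
        for (name, r1, r2, r3, bond, ang, tor) in rt.SIDECHAIN_ZMATRIX.get(
            resname, []
        ):
            pos = place_atom(placed[r3], placed[r2], placed[r1], bond, ang, tor)
            placed[name] = pos
            out[name] = pos
        sidechains.append(out)

    # --- assemble residues in template atom order --------------------------
    residues = []
    coords_list = []
    if capped:
        residues.append(make_residue("ACE", 0, radii_table))
        coords_list.extend([ch3, c_prev, ace_o])  # CH3, C, O
    for i, resname in enumerate(resnames):
        res = make_residue(resname, i + 1, radii_table)
        residues.append(res)
        for atom in res.atoms:
            src = backbone[i] if atom.atom_name in backbone[i] else sidechains[i]
            coords_list.append(src[atom.atom_name])
    if capped:
        residues.append(make_residue("NME", n + 1, radii_table))
        last = backbone[-1]
        nme_n = place_atom(
            last["N"], last["CA"], last["C"],
            rt.BOND_C_N, rt.ANGLE_CA_C_N, psi[-1],
        )
        h_dir = last["C"] - last["O"]
        nme_h = nme_n + rt.BOND_N_H * h_dir / np.linalg.norm(h_dir)
        nme_ch3 = place_atom(
            last["CA"], last["C"], nme_n, rt.BOND_N_CA, rt.ANGLE_C_N_CA, omega
        )
        coords_list.extend([nme_n, nme_h, nme_ch3])  # N, H, CH3
    return residues, np.array(coords_list)


def single_peptide_topology(
    sequence: str,
    phi=-139.0,
    psi=135.0,
    capped: bool = True,
    box_edge: float = 104.0,
    label: str = "",
    radii_table: str = "bondi",
):
    """Convenience: one peptide as (Topology, Frame), centred in the box."""
    residues, coords = build_peptide(
        sequence, phi=phi, psi=psi, capped=capped, radii_table=radii_table
    )
    coords = coords - coords.mean(axis=0) + box_edge / 2.0
    topo = Topology([residues], label=label or sequence)
    return topo, Frame(coordinates=coords, box_edge=box_edge, time=0.0)
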