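"""Residue chemistry tables.

Covers the residues that occur in the NFGAILSS octapeptide and its
alanine-scanned mutants (Asn, Phe, Gly, Ala, Ile, Leu, Ser) plus the
acetyl / N-methyl capping groups.  Tables drive topology flagging
(main chain vs side chain, aliphatic side-chain carbons, Phe ring atoms,
H-bond donors/acceptors) and the internal-coordinate peptide builder.
"""

from __future__ import annotations

# --- van der Waals radii tables (angstrom), selectable by name ------------

BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

RADII_TABLES = {"bondi": BONDI_RADII}

ONE_TO_THREE = {
    "A": "ALA", "N": "ASN", "F": "PHE", "G": "GLY",
    "I": "ILE", "L": "LEU", "S": "SER",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

CAP_RESIDUES = {"ACE", "NME"}

WILD_TYPE_SEQUENCE = "NFGAILSS"

#: the wild type and its seven alanine-scanned variants, as named in the field
SYSTEM_LABELS = ("Wild", "N1A", "F2A", "G3A", "I5A", "L6A", "S7A", "S8A")


def mutant_sequence(label: str) -> str:
    """Sequence of an alanine-scan variant, e.g. ``'I5A'`` -> ``'NFGAALSS'``."""
    if label in ("Wild", "WT", "wild"):
        return WILD_TYPE_SEQUENCE
    orig, pos, new = label[0], int(label[1:-1]), label[-1]
    seq = list(WILD_TYPE_SEQUENCE)
    if seq[pos - 1] != orig:
        raise ValueError(f"label {label!r} does not match wild-type sequence")
    seq[pos - 1] = new
    return "".join(seq)


# --- per-residue atom tables (heavy atoms + amide H) -----------------------

BACKBONE_ATOMS = ("N", "H", "CA", "C", "O")

SIDECHAIN_ATOMS = {
    "ALA": ("CB",),
    "GLY": (),
    "SER": ("CB", "OG"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    # caps have no side chain; their atoms are listed as main chain below
    "ACE": (),
    "NME": (),
}

CAP_ATOMS = {
    "ACE": ("CH3", "C", "O"),
    "NME": ("N", "H", "CH3"),
}

#: sp3 side-chain carbons ("aliphatic"); Phe ring carbons are excluded and
#: feed the ring-centroid stacking criterion instead, keeping the two
#: criteria disjoint.  Asn CG is an sp2 amide carbon, also excluded.
ALIPHATIC_SIDECHAIN_CARBONS = {
    "ALA": ("CB",),
    "GLY": (),
    "SER": ("CB",),
    "ASN": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "PHE": ("CB",),
    "ACE": (),
    "NME": (),
}

PHE_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

#: H-bond donor heavy atoms (need an attached/reconstructable H) and acceptors
HBOND_DONORS = {
    "backbone": ("N",),
    "SER": ("OG",),
    "ASN": ("ND2",),
    "NME": ("N",),
}
HBOND_ACCEPTORS = {
    "backbone": ("O",),
    "SER": ("OG",),
    "ASN": ("OD1",),
    "ACE": ("O",),
}


def element_of(atom_name: str) -> str:
    """Element from a PDB atom name (sufficient for the residues covered)."""
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def residue_atom_names(resname: str) -> tuple[str, ...]:
    """Expected atom names for a residue in the builder's order."""
    if resname in CAP_RESIDUES:
        return CAP_ATOMS[resname]
    if resname not in SIDECHAIN_ATOMS:
        raise ValueError(f"unknown residue name {resname!r}")
    return BACKBONE_ATOMS + SIDECHAIN_ATOMS[resname]


# --- internal coordinates for side-chain construction ----------------------
# Each entry: atom -> (ref_bond, ref_angle, ref_dihedral, bond A, angle deg,
# dihedral deg).  References name atoms of the same residue or, for CB, the
# backbone.  Dihedrals are fixed representative rotamers; the builder only
# needs chemically plausible, clash-free geometry.

SIDECHAIN_ZMATRIX = {
    "ALA": [("CB", "CA", "N", "C", 1.53, 110.5, 122.5)],
    "GLY": [],
    "SER": [
        ("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
        ("OG", "CB", "CA", "N", 1.42, 110.8, -60.0),
    ],
    "ASN": [
        ("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
        ("CG", "CB", "CA", "N", 1.52, 112.6, -60.0),
        ("OD1", "CG", "CB", "CA", 1.23, 120.8, -60.0),
        ("ND2", "CG", "CB", "CA", 1.33, 116.5, 120.0),
    ],
    "ILE": [
        ("CB", "CA", "N", "C", 1.54, 110.5, 122.5),
        ("CG1", "CB", "CA", "N", 1.53, 110.4, -60.0),
        ("CG2", "CB", "CA", "N", 1.52, 110.5, 60.0),
        ("CD1", "CG1", "CB", "CA", 1.52, 113.8, 170.0),
    ],
    "LEU": [
        ("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
        ("CG", "CB", "CA", "N", 1.53, 116.3, -60.0),
        ("CD1", "CG", "CB", "CA", 1.52, 110.7, 65.0),
        ("CD2", "CG", "CB", "CA", 1.52, 110.7, -175.0),
    ],
    "PHE": [
        ("CB", "CA", "N", "C", 1.53, 110.5, 122.5),
        ("CG", "CB", "CA", "N", 1.50, 113.8, -60.0),
        ("CD1", "CG", "CB", "CA", 1.39, 120.8, 90.0),
        ("CD2", "CG", "CB", "CA", 1.39, 120.8, -90.0),
        ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
        ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
        ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
    ],
}

# backbone geometry constants (angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_C_CH3 = 1.51
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
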