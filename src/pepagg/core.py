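"""Topology and trajectory containers.

A :class:`Topology` is the static description of a multi-peptide system:
atoms grouped into residues grouped into peptides, with van der Waals radii
and classification flags populated from the residue tables.  A
:class:`Trajectory` is a time-ordered list of coordinate :class:`Frame`\\ s
in a cubic periodic box.  The containers keep per-atom numpy arrays so that
per-frame geometry is vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import residues as res_tables


@dataclass(frozen=True)
class Atom:
    """A single atom with the flags the analysis criteria need."""

    atom_name: str
    element: str
    vdw_radius: float
    is_mainchain: bool
    is_sidechain_aliphatic_carbon: bool
    is_phe_ring_atom: bool

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if self.is_mainchain and self.is_sidechain_aliphatic_carbon:
            raise ValueError("atom cannot be both main-chain and side-chain")


@dataclass
class Residue:
    """A residue: 3-letter name, 1-based position in its peptide, atoms."""

    residue_name: str
    position: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_cap(self) -> bool:
        return self.residue_name in res_tables.CAP_RESIDUES


class Topology:
    """Static system description: peptides of residues of atoms.

    Parameters
    ----------
    peptides : list of list of Residue
        One inner list per peptide, residues in chain order (caps included
        where present).
    label : str
        System label, e.g. ``"Wild"`` or ``"I5A"``.
    """

    def __init__(self, peptides: list[list[Residue]], label: str = ""):
        if len(peptides) < 1:
            raise ValueError("topology needs at least one peptide")
        self.peptides = peptides
        self.label = label
        self._build_arrays()

    # -- construction -------------------------------------------------------

    def _build_arrays(self) -> None:
        names, elements, radii = [], [], []
        mainchain, aliphatic, ring, cap = [], [], [], []
        atom_peptide, atom_residue = [], []
        residue_list: list[Residue] = []
        residue_peptide: list[int] = []
        residue_is_cap: list[bool] = []
        for p_idx, pep in enumerate(self.peptides):
            for res in pep:
                r_idx = len(residue_list)
                residue_list.append(res)
                residue_peptide.append(p_idx)
                residue_is_cap.append(res.is_cap)
                for atom in res.atoms:
                    names.append(atom.atom_name)
                    elements.append(atom.element)
                    radii.append(atom.vdw_radius)
                    mainchain.append(atom.is_mainchain)
                    aliphatic.append(atom.is_sidechain_aliphatic_carbon)
                    ring.append(atom.is_phe_ring_atom)
                    cap.append(res.is_cap)
                    atom_peptide.append(p_idx)
                    atom_residue.append(r_idx)
        self.residues = residue_list
        self.atom_names = np.array(names, dtype=object)
        self.elements = np.array(elements, dtype=object)
        self.vdw_radii = np.array(radii, dtype=float)
        self.atom_is_mainchain = np.array(mainchain, dtype=bool)
        self.atom_is_aliphatic_sc = np.array(aliphatic, dtype=bool)
        self.atom_is_phe_ring = np.array(ring, dtype=bool)
        self.atom_is_cap = np.array(cap, dtype=bool)
        self.atom_peptide = np.array(atom_peptide, dtype=np.intp)
        self.atom_residue = np.array(atom_residue, dtype=np.intp)
        self.residue_peptide = np.array(residue_peptide, dtype=np.intp)
        self.residue_is_cap = np.array(residue_is_cap, dtype=bool)
        self.residue_names = np.array(
            [r.residue_name for r in residue_list], dtype=object
        )
        self.residue_positions = np.array(
            [r.position for r in residue_list], dtype=np.intp
        )
        # atom index within each residue for named lookup
        self._atom_index = {}
        start = 0
        self._residue_atom_slices = []
        for r_idx, res in enumerate(residue_list):
            stop = start + len(res.atoms)
            self._residue_atom_slices.append((start, stop))
            for k, atom in enumerate(res.atoms):
                self._atom_index[(r_idx, atom.atom_name)] = start + k
            start = stop
        self.n_atoms = start

    # -- basic accessors ----------------------------------------------------

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence_residue_indices(self) -> np.ndarray:
        """Global indices of non-cap (sequence) residues."""
        return np.where(~self.residue_is_cap)[0]

    @property
    def n_sequence_residues(self) -> int:
        return int(np.sum(~self.residue_is_cap))

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Global atom index of ``atom_name`` in residue ``residue_index``.

        Returns -1 when the residue has no atom of that name.
        """
        return self._atom_index.get((residue_index, atom_name), -1)

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        start, stop = self._residue_atom_slices[residue_index]
        return np.arange(start, stop, dtype=np.intp)

    def backbone_indices(self, atom_name: str) -> np.ndarray:
        """Per-residue global index of a backbone atom (-1 where absent)."""
        return np.array(
            [self.atom_index(i, atom_name) for i in range(self.n_residues)],
            dtype=np.intp,
        )

    def sequence(self, peptide_index: int = 0) -> str:
        """One-letter sequence of a peptide, caps excluded."""
        letters = []
        for res in self.peptides[peptide_index]:
            if not res.is_cap:
                letters.append(res_tables.THREE_TO_ONE[res.residue_name])
        return "".join(letters)


def make_residue(resname: str, position: int, radii_table: str = "bondi") -> Residue:
    """Residue with atoms and flags populated from the chemistry tables."""
    try:
        radii = res_tables.RADII_TABLES[radii_table]
    except KeyError:
        raise ValueError(f"unknown radii table {radii_table!r}") from None
    atoms = []
    aliphatic = set(res_tables.ALIPHATIC_SIDECHAIN_CARBONS.get(resname, ()))
    for name in res_tables.residue_atom_names(resname):
        element = res_tables.element_of(name)
        is_main = (
            name in res_tables.BACKBONE_ATOMS or resname in res_tables.CAP_RESIDUES
        )
        atoms.append(
            Atom(
                atom_name=name,
                element=element,
                vdw_radius=radii[element],
                is_mainchain=is_main,
                is_sidechain_aliphatic_carbon=name in aliphatic,
                is_phe_ring_atom=(
                    resname == "PHE" and name in res_tables.PHE_RING_ATOMS
                ),
            )
        )
    return Residue(residue_name=resname, position=position, atoms=atoms)


@dataclass
class Frame:
    """One time point: per-atom coordinates (A), cubic box edge (A), time (ps)."""

    coordinates: np.ndarray
    box_edge: float
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")


class Trajectory:
    """Time-ordered frames over a fixed topology."""

    def __init__(self, topology: Topology, frames: list[Frame]):
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        for k, fr in enumerate(frames):
            if fr.coordinates.shape[0] != topology.n_atoms:
                raise ValueError(
                    f"frame {k}: {fr.coordinates.shape[0]} atoms, "
                    f"topology has {topology.n_atoms}"
                )
        times = [fr.time for fr in frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)
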