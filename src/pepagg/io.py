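"""Readers and writers for topologies and trajectories.

Two on-disk dialects are supported:

* **PDB** — standard ATOM/HETATM/TER/CRYST1 records; trajectories as
  multi-model PDB (MODEL/ENDMDL), frame times in ``REMARK 250 TIME`` lines.
* **xyz-box** — a minimal per-frame text format: a header line
  ``natoms box_edge time_ps`` followed by one ``element x y z`` line per
  atom; frames concatenated in one file.
"""

from __future__ import annotations

import numpy as np

from . import residues as res_tables
from .core import Atom, Frame, Residue, Topology, Trajectory

_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789abcdefghijklmnopqrstuvwxyz"
)


# --------------------------------------------------------------------------
# topology reading
# --------------------------------------------------------------------------

def load_topology(path, radii_table: str = "bondi", label: str = "") -> Topology:
    """Parse a PDB file into a :class:`Topology`.

    Peptide boundaries come from chain IDs or TER records.  Every residue
    name must be in the chemistry tables; every non-cap residue must have a
    complete N/CA/C/O backbone.  Radii and classification flags are
    populated from ``radii_table``.
    """
    try:
        radii = res_tables.RADII_TABLES[radii_table]
    except KeyError:
        raise ValueError(f"unknown radii table {radii_table!r}") from None

    peptides: list[list[Residue]] = []
    current: list[Residue] = []
    current_key = None  # (chain_id, resseq)
    current_chain = None

    def close_peptide():
        nonlocal current
        if current:
            peptides.append(current)
            current = []

    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "TER":
                close_peptide()
                current_key = None
                current_chain = None
            elif rec == "ENDMDL":
                break  # topology from first model only
            elif rec in ("ATOM", "HETATM"):
                atom_name = line[12:16].strip()
                resname = line[17:20].strip()
                chain_id = line[21]
                resseq = int(line[22:26])
                if resname not in res_tables.SIDECHAIN_ATOMS:
                    raise ValueError(
                        f"unknown residue {resname!r} at {chain_id}{resseq}"
                    )
                if current_chain is not None and chain_id != current_chain:
                    close_peptide()
                    current_key = None
                current_chain = chain_id
                key = (chain_id, resseq)
                if key != current_key:
                    current.append(Residue(residue_name=resname, position=0))
                    current_key = key
                res = current[-1]
                element = (
                    line[76:78].strip() or res_tables.element_of(atom_name)
                ).upper()
                if element not in radii:
                    raise ValueError(
                        f"atom {atom_name!r} in {resname}: no radius for "
                        f"element {element!r}"
                    )
                known = set(res_tables.residue_atom_names(resname))
                if atom_name not in known and element != "H":
                    raise ValueError(
                        f"unknown atom {atom_name!r} in residue {resname!r}"
                    )
                aliphatic = atom_name in res_tables.ALIPHATIC_SIDECHAIN_CARBONS.get(
                    resname, ()
                )
                is_main = (
                    atom_name in res_tables.BACKBONE_ATOMS
                    or resname in res_tables.CAP_RESIDUES
                )
                res.atoms.append(
                    Atom(
                        atom_name=atom_name,
                        element=element,
                        vdw_radius=radii[element],
                        is_mainchain=is_main,
                        is_sidechain_aliphatic_carbon=aliphatic,
                        is_phe_ring_atom=(
                            resname == "PHE"
                            and atom_name in res_tables.PHE_RING_ATOMS
                        ),
                    )
                )
    close_peptide()
    if not peptides:
        raise ValueError(f"no ATOM records found in {path}")

    # assign sequence positions (caps get 0 before / n+1 after)
    for pep in peptides:
        pos = 0
        for res in pep:
            if res.is_cap:
                res.position = pos if res.residue_name == "ACE" else pos + 1
            else:
                pos += 1
                res.position = pos
        for res in pep:
            if res.residue_name == "NME":
                res.position = pos + 1
            if not res.is_cap:
                missing = {"N", "CA", "C", "O"} - {a.atom_name for a in res.atoms}
                if missing:
                    raise ValueError(
                        f"residue {res.residue_name}{res.position} missing "
                        f"backbone atom(s) {sorted(missing)}"
                    )
    return Topology(peptides, label=label)


def read_box_edge(path) -> float | None:
    """Cubic box edge from the CRYST1 record of a PDB file, if present."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                a, b, c = (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                return float(a) if np.isclose(a, b) and np.isclose(a, c) else a
    return None


# --------------------------------------------------------------------------
# trajectory reading
# --------------------------------------------------------------------------

def load_trajectory(
    topology: Topology,
    paths,
    dialect: str = "multi-model-pdb",
    stride_ps: float = 10.0,
    box_edge: float | None = None,
    on_unsorted: str = "error",
) -> Trajectory:
    """Read coordinate frames for an existing topology.

    Frame times come from file metadata when present, otherwise
    ``frame_index * stride_ps``.  ``on_unsorted`` is ``"error"`` (default)
    or ``"sort"`` for frames whose recorded times are out of order.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    raw: list[tuple[float | None, float | None, np.ndarray]] = []
    for path in paths:
        if dialect in ("multi-model-pdb", "pdb"):
            raw.extend(_read_pdb_frames(path))
        elif dialect in ("xyz-box", "xyz"):
            raw.extend(_read_xyz_frames(path))
        else:
            raise ValueError(f"unknown trajectory dialect {dialect!r}")
    frames = []
    for k, (time, box, coords) in enumerate(raw):
        if coords.shape[0] != topology.n_atoms:
            raise ValueError(
                f"frame {k}: atom count {coords.shape[0]} does not match "
                f"topology ({topology.n_atoms})"
            )
        edge = box if box is not None else box_edge
        if edge is None:
            raise ValueError(
                f"frame {k}: no box in file and no box_edge given"
            )
        t = time if time is not None else k * stride_ps
        frames.append(Frame(coordinates=coords, box_edge=edge, time=t))
    times = [fr.time for fr in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        if on_unsorted == "sort":
            frames.sort(key=lambda fr: fr.time)
        else:
            raise ValueError("frame times not strictly increasing")
    return Trajectory(topology, frames)


def _read_pdb_frames(path):
    frames = []
    coords: list[list[float]] = []
    time = None
    box = None
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "CRYST1":
                box = float(line[6:15])
            elif rec == "MODEL":
                in_model = True
                coords = []
                time = None
            elif rec == "REMARK" and "TIME" in line:
                try:
                    time = float(line.split("TIME")[1].split()[0])
                except (ValueError, IndexError):
                    pass
            elif rec in ("ATOM", "HETATM"):
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            elif rec == "ENDMDL":
                frames.append((time, box, np.array(coords)))
                coords = []
                in_model = False
    if coords and not in_model:
        frames.append((time, box, np.array(coords)))
    elif coords:
        frames.append((time, box, np.array(coords)))
    return frames


def _read_xyz_frames(path):
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            parts = header.split()
            natoms, box, time = int(parts[0]), float(parts[1]), float(parts[2])
            coords = np.empty((natoms, 3))
            for i in range(natoms):
                fields = fh.readline().split()
                coords[i] = [float(x) for x in fields[1:4]]
            frames.append((time, box, coords))
    return frames


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, element):
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {pad_name:<4s}"
        f" {resname:<3s} {chain}{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def _write_model(fh, topology: Topology, coords: np.ndarray):
    serial = 0
    ai = 0
    for p_idx, pep in enumerate(topology.peptides):
        chain = _CHAIN_IDS[p_idx % len(_CHAIN_IDS)]
        resseq = 0
        for res in pep:
            resseq += 1
            for atom in res.atoms:
                serial += 1
                fh.write(
                    _pdb_atom_line(
                        serial, atom.atom_name, res.residue_name, chain,
                        resseq, coords[ai], atom.element,
                    )
                )
                ai += 1
        fh.write(f"TER   {serial + 1:>5d}      {pep[-1].residue_name:<3s} "
                 f"{chain}{resseq:>4d}\n")
        serial += 1


def write_pdb(path, topology: Topology, frames, title: str = "") -> None:
    """Write one frame (or a Frame list / Trajectory) as (multi-model) PDB."""
    if isinstance(frames, Trajectory):
        frames = frames.frames
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        if title:
            fh.write(f"TITLE     {title}\n")
        box = frames[0].box_edge
        fh.write(
            f"CRYST1{box:9.3f}{box:9.3f}{box:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
        )
        multi = len(frames) > 1
        for k, fr in enumerate(frames):
            if multi:
                fh.write(f"MODEL     {k + 1:>4d}\n")
            fh.write(f"REMARK 250 TIME {fr.time:.3f} PS\n")
            _write_model(fh, topology, fr.coordinates)
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_xyz(path, topology: Topology, frames) -> None:
    """Write frames in the xyz-box dialect."""
    if isinstance(frames, Trajectory):
        frames = frames.frames
    if isinstance(frames, Frame):
        frames = [frames]
    elements = topology.elements
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{topology.n_atoms} {fr.box_edge:.5f} {fr.time:.5f}\n")
            for el, xyz in zip(elements, fr.coordinates):
                fh.write(f"{el} {xyz[0]:.5f} {xyz[1]:.5f} {xyz[2]:.5f}\n")
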