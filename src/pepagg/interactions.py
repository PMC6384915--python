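"""Inter-peptide interaction statistics.

Three geometric criteria, all minimum-image:

* **Hydrogen bonds** — HBPLUS-style defaults: donor-acceptor < 3.9 A,
  H-acceptor < 2.5 A, D-H-A angle > 90 deg; each inter-peptide bond is
  classed MM/MS/SS by the main-chain/side-chain flags of donor and
  acceptor heavy atoms.
* **Side-chain contacts** — any pair of side-chain aliphatic carbons of
  two residues on different peptides within 5.5 A; a residue pair counts
  at most once per frame.
* **Phe ring stacking** — ring centroids of two phenylalanines on
  different peptides within 5 A.

Capping groups are excluded from all of these statistics.  "Per residue"
normalisation divides by the number of sequence residues in the system
(27 x 8 = 216 for the systems studied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import residues as rt
from .core import Frame, Topology, Trajectory
from .geometry import min_image_displacement, periodic_pairs
from .secondary_structure import reconstruct_amide_h

HBOND_DA_CUTOFF = 3.9  # A
HBOND_HA_CUTOFF = 2.5  # A
HBOND_DHA_MIN_ANGLE = 90.0  # degrees
SIDECHAIN_CUTOFF = 5.5  # A
STACKING_CUTOFF = 5.0  # A


@dataclass(frozen=True)
class HBond:
    """One detected inter-peptide hydrogen bond."""

    donor_atom: int
    acceptor_atom: int
    donor_residue: int
    acceptor_residue: int
    hbond_class: str  # MM / MS / SS
    frame_time: float


@dataclass
class ContactTable:
    """Side-chain contact summary over a trajectory window."""

    pair_counts: dict  # label pair -> mean contacts per frame
    total_per_residue: float
    total_per_residue_participating: float
    highest_pair: tuple  # ((label_a, label_b), percent)
    n_frames: int


class _InteractionIndex:
    """Cached per-topology donor/acceptor/aliphatic/ring atom indices."""

    def __init__(self, topology: Topology):
        topo = topology
        donors = []  # (heavy atom idx, H atom idx or -1, prev C, prev O)
        acceptors = []
        seq = set(int(i) for i in topo.sequence_residue_indices)
        for r_idx in range(topo.n_residues):
            if r_idx not in seq:
                continue
            resname = topo.residue_names[r_idx]
            # backbone donor N (H explicit or reconstructable from prev residue)
            n_i = topo.atom_index(r_idx, "N")
            if n_i >= 0:
                h_i = topo.atom_index(r_idx, "H")
                prev_c = prev_o = -1
                if h_i < 0 and r_idx > 0:
                    if topo.residue_peptide[r_idx - 1] == topo.residue_peptide[r_idx]:
                        prev_c = topo.atom_index(r_idx - 1, "C")
                        prev_o = topo.atom_index(r_idx - 1, "O")
                if h_i >= 0 or (prev_c >= 0 and prev_o >= 0):
                    donors.append((n_i, h_i, prev_c, prev_o))
            for name in rt.HBOND_DONORS.get(resname, ()):
                a_i = topo.atom_index(r_idx, name)
                h_i = topo.atom_index(r_idx, "H" + name[1:])
                if a_i >= 0 and h_i >= 0:
                    donors.append((a_i, h_i, -1, -1))
            for name in rt.HBOND_ACCEPTORS["backbone"] + rt.HBOND_ACCEPTORS.get(
                resname, ()
            ):
                a_i = topo.atom_index(r_idx, name)
                if a_i >= 0:
                    acceptors.append(a_i)
        self.donor_heavy = np.array([d[0] for d in donors], dtype=np.intp)
        self.donor_h = np.array([d[1] for d in donors], dtype=np.intp)
        self.donor_prev_c = np.array([d[2] for d in donors], dtype=np.intp)
        self.donor_prev_o = np.array([d[3] for d in donors], dtype=np.intp)
        self.acceptors = np.unique(np.array(acceptors, dtype=np.intp))
        self.aliphatic = np.where(topo.atom_is_aliphatic_sc & ~topo.atom_is_cap)[0]
        # Phe rings: list of (residue index, 6 ring atom indices)
        self.phe_rings = []
        for r_idx in range(topo.n_residues):
            if topo.residue_names[r_idx] == "PHE":
                ring = [topo.atom_index(r_idx, nm) for nm in rt.PHE_RING_ATOMS]
                if all(i >= 0 for i in ring):
                    self.phe_rings.append((r_idx, np.array(ring, dtype=np.intp)))


def _index(topology: Topology) -> _InteractionIndex:
    # cached on the topology instance itself
    cached = getattr(topology, "_interaction_index_cache", None)
    if cached is None:
        cached = _InteractionIndex(topology)
        topology._interaction_index_cache = cached
    return cached


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    da_cutoff: float = HBOND_DA_CUTOFF,
    ha_cutoff: float = HBOND_HA_CUTOFF,
    min_angle: float = HBOND_DHA_MIN_ANGLE,
) -> list[HBond]:
    """Inter-peptide hydrogen bonds in one frame.

    Donors without an explicit amide H get the standard DSSP
    reconstruction; side-chain donors require an explicit H.
    """
    ix = _index(topology)
    xyz = frame.coordinates
    box = frame.box_edge
    if len(ix.donor_heavy) == 0 or len(ix.acceptors) == 0:
        return []
    d_xyz = xyz[ix.donor_heavy]
    h_xyz = np.empty_like(d_xyz)
    has_h = ix.donor_h >= 0
    h_xyz[has_h] = xyz[ix.donor_h[has_h]]
    rec = ~has_h
    if np.any(rec):
        h_xyz[rec] = reconstruct_amide_h(
            d_xyz[rec], xyz[ix.donor_prev_c[rec]], xyz[ix.donor_prev_o[rec]], box
        )
    a_xyz = xyz[ix.acceptors]
    # candidate pairs by D-A distance
    da = min_image_displacement(d_xyz[:, None, :], a_xyz[None, :, :], box)
    da_dist = np.sqrt(np.sum(da * da, axis=-1))
    di, aj = np.where(da_dist < da_cutoff)
    bonds = []
    pep = topology.atom_peptide
    resid = topology.atom_residue
    main = topology.atom_is_mainchain
    for k in range(len(di)):
        d_at = int(ix.donor_heavy[di[k]])
        a_at = int(ix.acceptors[aj[k]])
        if pep[d_at] == pep[a_at]:
            continue
        if d_at == a_at:
            continue
        ha = min_image_displacement(h_xyz[di[k]], a_xyz[aj[k]], box)
        if np.linalg.norm(ha) >= ha_cutoff:
            continue
        hd = min_image_displacement(h_xyz[di[k]], d_xyz[di[k]], box)
        cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle <= min_angle:
            continue
        cls = ("M" if main[d_at] else "S") + ("M" if main[a_at] else "S")
        cls = {"MM": "MM", "MS": "MS", "SM": "MS", "SS": "SS"}[cls]
        bonds.append(
            HBond(
                donor_atom=d_at,
                acceptor_atom=a_at,
                donor_residue=int(resid[d_at]),
                acceptor_residue=int(resid[a_at]),
                hbond_class=cls,
                frame_time=frame.time,
            )
        )
    return bonds


def hbond_summary(
    trajectory: Trajectory, t_start=None, t_end=None, **cutoffs
) -> dict:
    """Mean inter-peptide H-bonds per residue by class over a window.

    Returns ``{"MM": ..., "MS": ..., "SS": ..., "Total": ...}``; Total is
    the exact sum of the classes.  The denominator is the number of
    sequence residues in the system.
    """
    topo = trajectory.topology
    n_res = topo.n_sequence_residues
    frames = _window_frames(trajectory, t_start, t_end)
    counts = {"MM": 0, "MS": 0, "SS": 0}
    for fr in frames:
        for b in detect_hbonds(fr, topo, **cutoffs):
            counts[b.hbond_class] += 1
    n_frames = len(frames)
    out = {k: v / n_frames / n_res for k, v in counts.items()}
    out["Total"] = out["MM"] + out["MS"] + out["SS"]
    return out


def _window_frames(trajectory: Trajectory, t_start, t_end):
    frames = [
        fr
        for fr in trajectory.frames
        if (t_start is None or fr.time >= t_start)
        and (t_end is None or fr.time <= t_end)
    ]
    if not frames:
        raise ValueError("no frames in the requested window")
    return frames


def residue_pair_label(topology: Topology, r_a: int, r_b: int) -> tuple:
    """Sorted residue-type pair label; Ser distinguished by position (S7/S8)."""

    def one(r):
        name = topology.residue_names[r]
        code = rt.THREE_TO_ONE[name]
        if code == "S":
            code = f"S{topology.residue_positions[r]}"
        return code

    return tuple(sorted((one(r_a), one(r_b))))


def sidechain_contacts(
    frame: Frame, topology: Topology, cutoff: float = SIDECHAIN_CUTOFF
) -> dict:
    """Inter-peptide residue-pair side-chain contacts for one frame.

    Returns ``{(res_i, res_j): 1}`` over global residue-index pairs; each
    pair appears at most once however many aliphatic-carbon pairs are
    within the cutoff.  Residues without aliphatic side-chain carbons
    (Gly, caps) contribute nothing.
    """
    ix = _index(topology)
    if len(ix.aliphatic) == 0:
        return {}
    coords = frame.coordinates[ix.aliphatic]
    pairs = periodic_pairs(coords, cutoff, frame.box_edge)
    pep = topology.atom_peptide[ix.aliphatic]
    resid = topology.atom_residue[ix.aliphatic]
    out = {}
    for i, j in pairs:
        if pep[i] == pep[j]:
            continue
        key = tuple(sorted((int(resid[i]), int(resid[j]))))
        out[key] = 1
    return out


def contact_summary(
    trajectory: Trajectory,
    t_start=None,
    t_end=None,
    cutoff: float = SIDECHAIN_CUTOFF,
) -> ContactTable:
    """Side-chain contact table over a window (residue-type-pair resolution).

    ``total_per_residue`` counts each contact once and divides by the number
    of sequence residues; ``total_per_residue_participating`` counts each
    contact once per participating residue (twice).  ``highest_pair`` is the
    pair with the largest mean count and its percentage of all contacts.
    """
    topo = trajectory.topology
    frames = _window_frames(trajectory, t_start, t_end)
    pair_totals: dict = {}
    grand_total = 0
    for fr in frames:
        contacts = sidechain_contacts(fr, topo, cutoff=cutoff)
        for (ra, rb) in contacts:
            label = residue_pair_label(topo, ra, rb)
            pair_totals[label] = pair_totals.get(label, 0) + 1
            grand_total += 1
    n_frames = len(frames)
    n_res = topo.n_sequence_residues
    pair_counts = {k: v / n_frames for k, v in sorted(pair_totals.items())}
    if grand_total:
        top_label = max(pair_totals, key=lambda k: (pair_totals[k], k))
        highest = (top_label, 100.0 * pair_totals[top_label] / grand_total)
    else:
        highest = (None, 0.0)
    return ContactTable(
        pair_counts=pair_counts,
        total_per_residue=grand_total / n_frames / n_res,
        total_per_residue_participating=2.0 * grand_total / n_frames / n_res,
        highest_pair=highest,
        n_frames=n_frames,
    )


def phe_ring_centroids(frame: Frame, topology: Topology) -> tuple:
    """(residue indices, centroids) of Phe rings, unwrapped across the box."""
    ix = _index(topology)
    resids, cents = [], []
    for r_idx, ring in ix.phe_rings:
        xyz = frame.coordinates[ring]
        ref = xyz[0]
        unwrapped = ref + min_image_displacement(ref, xyz, frame.box_edge)
        resids.append(r_idx)
        cents.append(unwrapped.mean(axis=0))
    return np.array(resids, dtype=np.intp), (
        np.array(cents) if cents else np.empty((0, 3))
    )


def phe_stacking(
    frame: Frame, topology: Topology, cutoff: float = STACKING_CUTOFF
) -> int:
    """Number of inter-peptide Phe pairs with ring centroids within cutoff."""
    resids, cents = phe_ring_centroids(frame, topology)
    if len(resids) < 2:
        return 0
    pep = topology.residue_peptide[resids]
    d = min_image_displacement(cents[:, None, :], cents[None, :, :], frame.box_edge)
    dist = np.sqrt(np.sum(d * d, axis=-1))
    ii, jj = np.triu_indices(len(resids), k=1)
    hit = (dist[ii, jj] < cutoff) & (pep[ii] != pep[jj])
    return int(np.sum(hit))


def phe_stacking_series(trajectory: Trajectory, cutoff: float = STACKING_CUTOFF):
    """Per-frame stacked-Phe-pair counts."""
    return np.array(
        [phe_stacking(fr, trajectory.topology, cutoff) for fr in trajectory.frames]
    )
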