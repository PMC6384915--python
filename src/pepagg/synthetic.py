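"""Synthetic input generators.

Everything the analysis pipeline consumes can be generated here with no
MD engine: a lattice starting configuration of 27 capped octapeptides in
a 104 A periodic box, sticky rigid-body aggregation trajectories, ideal
helix and beta-sheet fixtures, and categorical Markov chains with known
transition matrices.  All generators take a seed and are bit-reproducible.

The aggregation generator emulates the qualitative behaviour of the MD it
stands in for — peptides diffuse, meet, and coalesce into clusters that
then move as units — not its physics: peptide internal geometry is rigid,
there is no excluded volume between non-contacting peptides, and a small
drift toward the nearest neighbouring cluster plays the role of the
effective attraction that makes aggregation-prone peptides coalesce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import residues as rt
from .builder import build_peptide
from .core import Frame, Topology, Trajectory
from .geometry import min_image_displacement, wrap_coordinates
from .msm import StateSeries


@dataclass
class AggregationParams:
    """Study conditions for the synthetic aggregation trajectory.

    Defaults are the multi-peptide system conditions: 27 capped
    octapeptides on a 25 A grid in a cubic 104 A periodic box, frames
    every 10 ps.
    """

    n_peptides: int = 27
    box_edge: float = 104.0
    grid_spacing: float = 25.0
    sequence: str = rt.WILD_TYPE_SEQUENCE
    label: str = "Wild"
    step_size: float = 2.5  # A / frame translational step (per axis sigma)
    rotation_deg: float = 10.0  # sigma of per-frame rigid rotation
    drift: float = 1.0  # A / frame drift toward the nearest cluster
    stick_probability: float = 1.0
    unstick_probability: float = 0.0
    n_frames: int = 100
    stride_ps: float = 10.0
    seed: int = 0
    radii_table: str = "bondi"
    #: fraction of peptides frozen in an ideal helical conformation instead
    #: of the extended one (0 = the all-extended starting conditions)
    helix_fraction: float = 0.0

    def __post_init__(self):
        for p in (
            self.stick_probability,
            self.unstick_probability,
            self.helix_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        m = math.ceil(self.n_peptides ** (1.0 / 3.0) - 1e-9)
        if m * self.grid_spacing > self.box_edge:
            raise ValueError(
                f"lattice of {m}^3 cells at {self.grid_spacing} A spacing "
                f"does not fit in a {self.box_edge} A box"
            )
        for ch in self.sequence:
            if ch not in rt.ONE_TO_THREE:
                raise ValueError(f"unknown residue code {ch!r} in sequence")


@dataclass
class ChainParams:
    """Ground-truth Markov chain ensemble parameters."""

    P_true: np.ndarray
    n_chains: int = 50
    n_steps: int = 2000
    seed: int = 0

    def __post_init__(self):
        self.P_true = np.asarray(self.P_true, dtype=float)
        if (
            self.P_true.ndim != 2
            or self.P_true.shape[0] != self.P_true.shape[1]
            or np.any(self.P_true < 0)
            or not np.allclose(self.P_true.sum(axis=1), 1.0, atol=1e-10)
        ):
            raise ValueError("P_true must be a square row-stochastic matrix")


# --------------------------------------------------------------------------
# lattice start
# --------------------------------------------------------------------------

def _rotation_to_diagonal(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``axis`` to the box diagonal (1,1,1)/sqrt(3)."""
    a = axis / np.linalg.norm(axis)
    b = np.ones(3) / np.sqrt(3.0)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _template_peptide(params: AggregationParams, helical: bool = False):
    """One capped peptide, centred at the origin, long axis along the box
    diagonal (so 25 A grid neighbours start well out of contact)."""
    phi, psi = (-57.0, -47.0) if helical else (-139.0, 135.0)
    residues, xyz = build_peptide(
        params.sequence, phi=phi, psi=psi, capped=True,
        radii_table=params.radii_table,
    )
    xyz = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz, full_matrices=False)
    xyz = xyz @ vt.T  # principal frame, axis 0 = long axis
    rot = _rotation_to_diagonal(np.array([1.0, 0.0, 0.0]))
    return residues, xyz @ rot.T


def gen_lattice_start(params: AggregationParams | None = None):
    """Initial configuration: peptides on a cubic grid, parallel orientation.

    Returns ``(topology, frame)``.
    """
    params = params or AggregationParams()
    templates = {False: _template_peptide(params, helical=False)}
    n_helical = int(round(params.helix_fraction * params.n_peptides))
    if n_helical:
        templates[True] = _template_peptide(params, helical=True)
    m = math.ceil(params.n_peptides ** (1.0 / 3.0) - 1e-9)
    start = (params.box_edge - (m - 1) * params.grid_spacing) / 2.0
    centres = []
    for i in range(m):
        for j in range(m):
            for k in range(m):
                if len(centres) < params.n_peptides:
                    centres.append(
                        start + params.grid_spacing * np.array([i, j, k], float)
                    )
    peptides = []
    coords = []
    for p, c in enumerate(centres):
        tmpl_res, tmpl_xyz = templates[p < n_helical]
        pep_res = [
            # fresh Residue objects so peptides do not share atom lists
            type(r)(r.residue_name, r.position, list(r.atoms))
            for r in tmpl_res
        ]
        peptides.append(pep_res)
        coords.append(tmpl_xyz + c)
    topo = Topology(peptides, label=params.label)
    frame = Frame(
        coordinates=np.vstack(coords), box_edge=params.box_edge, time=0.0
    )
    return topo, frame


# --------------------------------------------------------------------------
# sticky rigid-body aggregation
# --------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    vx = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * vx + (1 - np.cos(angle)) * (vx @ vx)


class _AggState:
    """Mutable generator state: per-peptide coordinates + cluster partition."""

    def __init__(self, topo: Topology, frame: Frame, radii: np.ndarray):
        self.box = frame.box_edge
        n_pep = topo.n_peptides
        self.pep_atoms = [
            np.where(topo.atom_peptide == p)[0] for p in range(n_pep)
        ]
        self.coords = frame.coordinates.copy()
        self.radii = radii
        self.cluster_of = np.arange(n_pep)  # cluster id per peptide
        self.pep_radius = max(
            np.max(
                np.linalg.norm(
                    self.coords[idx] - self.coords[idx].mean(axis=0), axis=1
                )
            )
            for idx in self.pep_atoms
        ) + float(radii.max())

    def members(self, cid: int) -> np.ndarray:
        return np.where(self.cluster_of == cid)[0]

    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.cluster_of)

    def atoms_of(self, peptides) -> np.ndarray:
        return np.concatenate([self.pep_atoms[p] for p in peptides])

    def centroid(self, peptides) -> np.ndarray:
        return self.coords[self.atoms_of(peptides)].mean(axis=0)

    def peptides_in_contact(self, p: int, q: int) -> bool:
        ia, ib = self.pep_atoms[p], self.pep_atoms[q]
        ca = self.coords[ia].mean(axis=0)
        cb = self.coords[ib].mean(axis=0)
        gap = np.linalg.norm(min_image_displacement(ca, cb, self.box))
        if gap > 2 * self.pep_radius:
            return False
        d = min_image_displacement(
            self.coords[ia][:, None, :], self.coords[ib][None, :, :], self.box
        )
        dist2 = np.sum(d * d, axis=-1)
        rsum = self.radii[ia][:, None] + self.radii[ib][None, :]
        return bool(np.any(dist2 < rsum**2))

    def clusters_in_contact(self, cid: int, other: int):
        """A contacting peptide pair (p, q) between two clusters, or None."""
        for p in self.members(cid):
            for q in self.members(other):
                if self.peptides_in_contact(p, q):
                    return (int(p), int(q))
        return None

    def contacting_clusters(self, cid: int) -> list[tuple]:
        """[(other_cid, p, q), ...] for clusters in contact with cid."""
        out = []
        for other in self.cluster_ids():
            if other == cid:
                continue
            pair = self.clusters_in_contact(cid, other)
            if pair is not None:
                out.append((int(other), pair[0], pair[1]))
        return out

    def make_contiguous(self, absorber_pep: int, other_cid: int,
                        other_pep: int) -> None:
        """Translate cluster ``other_cid`` by whole box vectors so it is
        Euclidean-contiguous with the absorbing cluster.

        Merged clusters move as rigid units; if an absorbed cluster sat in
        a neighbouring periodic image, rigid rotation would otherwise
        change minimum-image distances and break the frozen contacts.
        """
        ca = self.coords[self.pep_atoms[absorber_pep]].mean(axis=0)
        cb = self.coords[self.pep_atoms[other_pep]].mean(axis=0)
        shift = -self.box * np.round((cb - ca) / self.box)
        if np.any(shift != 0.0):
            self.coords[self.atoms_of(self.members(other_cid))] += shift

    def resplit(self, cid: int) -> None:
        """Re-partition a cluster into contact-connected components.

        Needed after a peptide leaves: the leaver may have been the only
        bridge holding the remaining members together.
        """
        members = sorted(int(p) for p in self.members(cid))
        if len(members) < 2:
            return
        remaining = list(members)
        components = []
        while remaining:
            comp = [remaining.pop(0)]
            queue = list(comp)
            while queue:
                p = queue.pop(0)
                linked = [q for q in remaining if self.peptides_in_contact(p, q)]
                for q in linked:
                    remaining.remove(q)
                    comp.append(q)
                    queue.append(q)
            components.append(comp)
        if len(components) > 1:
            for comp in components[1:]:
                new_cid = int(np.max(self.cluster_of)) + 1
                self.cluster_of[np.array(comp)] = new_cid


def gen_aggregation_trajectory(
    params: AggregationParams | None = None, return_labels: bool = False
):
    """Sticky rigid-body random-walk aggregation trajectory.

    Clusters take Gaussian translational steps plus a small drift toward
    the nearest other cluster and random rigid rotations.  A move that
    brings a cluster into atom-level vdW contact with another cluster
    merges them with probability ``stick_probability`` (they then move as
    one rigid unit) and is otherwise rejected, so in every emitted frame
    peptides of different bookkeeping clusters are never in contact.
    Multi-peptide clusters shed a random member with probability
    ``unstick_probability`` per frame.  Fixed seed => identical output.

    Returns a :class:`Trajectory`; with ``return_labels`` also the
    generator's own per-frame cluster labels for cross-validation against
    the clustering module.
    """
    params = params or AggregationParams()
    rng = np.random.default_rng(params.seed)
    topo, frame0 = gen_lattice_start(params)
    state = _AggState(topo, frame0, topo.vdw_radii)
    frames = [
        Frame(
            coordinates=wrap_coordinates(state.coords, state.box),
            box_edge=state.box,
            time=0.0,
        )
    ]
    labels = [state.cluster_of.copy()]
    for step in range(1, params.n_frames):
        _advance(state, params, rng)
        frames.append(
            Frame(
                coordinates=wrap_coordinates(state.coords, state.box),
                box_edge=state.box,
                time=step * params.stride_ps,
            )
        )
        labels.append(state.cluster_of.copy())
    traj = Trajectory(topo, frames)
    if return_labels:
        return traj, labels
    return traj


def _advance(state: _AggState, params: AggregationParams, rng) -> None:
    box = state.box
    # deterministic cluster order: by smallest member peptide
    cids = sorted(state.cluster_ids(), key=lambda c: state.members(c)[0])
    centroids = {c: state.centroid(state.members(c)) for c in cids}
    for cid in cids:
        if cid not in centroids:  # merged away earlier this step
            continue
        members = state.members(cid)
        atoms = state.atoms_of(members)
        old = state.coords[atoms].copy()
        centre = centroids[cid]
        # drift toward nearest other cluster
        move = rng.normal(0.0, params.step_size, size=3)
        others = [c for c in centroids if c != cid]
        if others and params.drift > 0:
            deltas = np.array(
                [min_image_displacement(centre, centroids[c], box) for c in others]
            )
            nearest = deltas[np.argmin(np.sum(deltas * deltas, axis=1))]
            norm = np.linalg.norm(nearest)
            if norm > 1e-9:
                move = move + params.drift * nearest / norm
        axis = rng.normal(size=3)
        angle = np.deg2rad(rng.normal(0.0, params.rotation_deg))
        R = _rotation_matrix(axis, angle)
        state.coords[atoms] = (state.coords[atoms] - centre) @ R.T + centre + move
        touching = state.contacting_clusters(cid)
        if touching:
            # all-or-nothing: merging only some of the touching clusters
            # would leave an unmerged pair in contact, breaking the
            # contact <=> same-cluster invariant of emitted frames
            accept = all(
                rng.random() < params.stick_probability for _ in touching
            )
            if not accept:
                state.coords[atoms] = old  # reject move, stay contact-free
                continue
            for other, p_mine, p_other in touching:
                state.make_contiguous(p_mine, other, p_other)
                state.cluster_of[state.members(other)] = cid
                centroids.pop(other, None)
            members = state.members(cid)
        centroids[cid] = state.centroid(members)
    # unsticking: a multi-peptide cluster sheds one random member
    if params.unstick_probability > 0:
        for cid in sorted(state.cluster_ids(), key=lambda c: state.members(c)[0]):
            members = state.members(cid)
            if len(members) < 2:
                continue
            if rng.random() >= params.unstick_probability:
                continue
            leaver = int(members[rng.integers(len(members))])
            atoms = state.pep_atoms[leaver]
            old = state.coords[atoms].copy()
            centre = old.mean(axis=0)
            prev_cid = int(state.cluster_of[leaver])
            for _ in range(50):
                target = rng.uniform(0.0, box, size=3)
                state.coords[atoms] = old - centre + target
                new_cid = int(np.max(state.cluster_of)) + 1
                state.cluster_of[leaver] = new_cid
                if not state.contacting_clusters(new_cid):
                    break
                state.cluster_of[leaver] = prev_cid
                state.coords[atoms] = old
            if state.cluster_of[leaver] != prev_cid:
                # the leaver may have bridged the remaining members
                state.resplit(prev_cid)


# --------------------------------------------------------------------------
# ideal secondary-structure fixtures
# --------------------------------------------------------------------------

def gen_ideal_helix(
    n_res: int, sequence: str | None = None, box_edge: float = 200.0
):
    """Ideal alpha-helix (phi=-57, psi=-47): returns (topology, frame)."""
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    sequence = sequence or "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    residues, xyz = build_peptide(sequence, phi=-57.0, psi=-47.0, capped=False)
    xyz = xyz - xyz.mean(axis=0) + box_edge / 2.0
    topo = Topology([residues], label="ideal-helix")
    return topo, Frame(coordinates=xyz, box_edge=box_edge, time=0.0)


#: frozen sheet placements (strand-axis offset, inter-strand spacing) that
#: produce clean Kabsch-Sander ladders of the requested topology
_SHEET_GEOMETRY = {
    "antiparallel": {"phi": -139.0, "psi": 135.0, "dx": -2.25, "dy": 4.5,
                     "flip": True},
    "parallel": {"phi": -119.0, "psi": 113.0, "dx": -1.75, "dy": 4.5,
                 "flip": False},
}


def gen_beta_sheet(
    n_strands: int = 2,
    sheet_topology: str = "antiparallel",
    strand_len: int = 8,
    sequence: str | None = None,
    strand_separation: float | None = None,
    box_edge: float = 200.0,
):
    """Idealised beta sheet, one peptide per strand: (topology, frame).

    ``sheet_topology`` is ``"parallel"`` or ``"antiparallel"``; the
    inter-strand placement uses frozen offsets that give the correct
    H-bond registry.  ``strand_separation`` overrides the inter-strand
    spacing (e.g. 30 A to produce strands with no bridges).
    """
    if n_strands < 2:
        raise ValueError("n_strands must be >= 2")
    try:
        geom = _SHEET_GEOMETRY[sheet_topology]
    except KeyError:
        raise ValueError(
            f"sheet_topology must be 'parallel' or 'antiparallel', "
            f"got {sheet_topology!r}"
        ) from None
    sequence = sequence or "A" * strand_len
    if len(sequence) != strand_len:
        raise ValueError("sequence length must equal strand_len")
    dy = geom["dy"] if strand_separation is None else float(strand_separation)
    _, xyz = build_peptide(
        sequence, phi=geom["phi"], psi=geom["psi"], capped=False
    )
    xyz = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz, full_matrices=False)
    xyz = xyz @ vt.T  # principal frame
    flip = np.diag([-1.0, 1.0, -1.0])
    peptides = []
    coords = []
    for k in range(n_strands):
        res_k, _ = build_peptide(
            sequence, phi=geom["phi"], psi=geom["psi"], capped=False
        )
        peptides.append(res_k)
        if geom["flip"] and k % 2 == 1:
            coords.append(xyz @ flip.T + np.array([geom["dx"], k * dy, 0.0]))
        else:
            coords.append(xyz + np.array([k * geom["dx"] if not geom["flip"]
                                          else 0.0, k * dy, 0.0]))
    all_xyz = np.vstack(coords)
    all_xyz = all_xyz - all_xyz.mean(axis=0) + box_edge / 2.0
    topo = Topology(peptides, label=f"ideal-{sheet_topology}-sheet")
    return topo, Frame(coordinates=all_xyz, box_edge=box_edge, time=0.0)


# --------------------------------------------------------------------------
# Markov chains with known transition matrices
# --------------------------------------------------------------------------

def gen_markov_chains(params: ChainParams) -> StateSeries:
    """Independent realisations of a known chain; initial states uniform.

    Returns a :class:`StateSeries` with ``n_steps`` transitions per chain
    (``n_steps + 1`` frames).
    """
    rng = np.random.default_rng(params.seed)
    k = params.P_true.shape[0]
    cum = np.cumsum(params.P_true, axis=1)
    states = np.empty((params.n_chains, params.n_steps + 1), dtype=int)
    states[:, 0] = rng.integers(0, k, size=params.n_chains)
    for t in range(params.n_steps):
        u = rng.random(params.n_chains)
        nxt = np.array(
            [np.searchsorted(cum[s], x, side="right") for s, x in
             zip(states[:, t], u)]
        )
        states[:, t + 1] = np.minimum(nxt, k - 1)
        # np.minimum guards the measure-zero u == 1.0 edge
    return StateSeries(
        states=states, state_space=tuple(range(k)), entity_kind="chain"
    )
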