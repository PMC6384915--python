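"""Kabsch–Sander secondary-structure assignment (DSSP codes).

Implements the Kabsch–Sander electrostatic backbone H-bond model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

with a bond assigned when E < -0.5 kcal/mol, and the pattern rules built
on it: n-turns give 3_10/alpha/pi helices (G/H/I, two consecutive turns
required), parallel/antiparallel bridge patterns give isolated bridges (B)
and ladders/strands (E), plus turns (T), bends (S) and coil (C).

Inter-peptide H-bonds participate in bridge patterns (the systems studied
form beta structure by inter-peptide association); n-turn patterns are
intra-peptide.  All distances are minimum-image, since peptides may
straddle the periodic boundary.  Capping groups are excluded from the
residue set.  Priority when patterns overlap follows Kabsch–Sander:
E/B assigned first, alpha helix (H) overrides, then G, then I into
remaining coil, then T, then S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Topology, Trajectory
from .geometry import min_image_displacement

KS_COUPLING = 0.084 * 332.0  # kcal/mol * A
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
MIN_HBOND_ENERGY = -9.9
CA_PREFILTER = 9.0  # A
BEND_KAPPA = 70.0  # degrees

HELIX_CODES = ("G", "H", "I")
STRAND_CODES = ("E", "B")


@dataclass
class SSMatrix:
    """Frame x residue secondary-structure codes plus bridge annotations.

    ``codes`` covers every topology residue; capping groups carry ``'-'``
    and are excluded from all statistics.  ``bridges[k]`` lists
    ``(res_i, res_j, 'parallel'|'antiparallel')`` with global residue
    indices for frame k.
    """

    codes: np.ndarray  # (n_frames, n_residues) of single chars
    times: np.ndarray
    bridges: list[list[tuple[int, int, str]]]
    sequence_mask: np.ndarray  # True for non-cap residues


class _BackboneIndex:
    """Cached per-topology backbone atom indices over sequence residues."""

    def __init__(self, topology: Topology):
        seq = topology.sequence_residue_indices
        self.residues = seq
        self.n = len(seq)
        self.chain = topology.residue_peptide[seq]
        self.idx = {
            name: np.array(
                [topology.atom_index(int(r), name) for r in seq], dtype=np.intp
            )
            for name in ("N", "CA", "C", "O", "H")
        }
        for name in ("N", "CA", "C", "O"):
            if np.any(self.idx[name] < 0):
                bad = seq[np.where(self.idx[name] < 0)[0][0]]
                raise ValueError(
                    f"residue {topology.residue_names[bad]} (index {bad}) "
                    f"missing backbone atom {name}"
                )
        # neighbour-in-chain masks (sequence residues are contiguous per peptide)
        self.has_prev = np.zeros(self.n, dtype=bool)
        self.has_prev[1:] = self.chain[1:] == self.chain[:-1]
        self.has_next = np.zeros(self.n, dtype=bool)
        self.has_next[:-1] = self.chain[:-1] == self.chain[1:]


def _backbone_index(topology: Topology) -> _BackboneIndex:
    # cached on the topology instance itself
    cached = getattr(topology, "_backbone_index_cache", None)
    if cached is None:
        cached = _BackboneIndex(topology)
        topology._backbone_index_cache = cached
    return cached


def reconstruct_amide_h(
    n_xyz: np.ndarray,
    prev_c: np.ndarray,
    prev_o: np.ndarray,
    box_edge: float,
) -> np.ndarray:
    """Standard DSSP amide-H reconstruction: H = N + unit(C_prev - O_prev)."""
    d = min_image_displacement(prev_o, prev_c, box_edge)
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    return n_xyz + d / norm


def backbone_hbond_energy(
    n_xyz, h_xyz, c_xyz, o_xyz, box_edge: float
) -> np.ndarray:
    """Kabsch–Sander H-bond energy (kcal/mol) for donor(N,H) -> acceptor(C,O).

    Broadcasts over leading dimensions; distances are minimum-image.
    """
    def dist(a, b):
        d = min_image_displacement(a, b, box_edge)
        return np.sqrt(np.sum(d * d, axis=-1))

    r_on = dist(n_xyz, o_xyz)
    r_ch = dist(h_xyz, c_xyz)
    r_oh = dist(h_xyz, o_xyz)
    r_cn = dist(n_xyz, c_xyz)
    tiny = (
        (r_on < 0.5) | (r_ch < 0.5) | (r_oh < 0.5) | (r_cn < 0.5)
    )
    with np.errstate(divide="ignore"):
        e = KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    e = np.where(tiny, MIN_HBOND_ENERGY, e)
    return np.maximum(e, MIN_HBOND_ENERGY)


def _hbond_matrix(frame: Frame, bb: _BackboneIndex) -> np.ndarray:
    """Boolean matrix B[d, a]: N-H of residue d bonds to C=O of residue a."""
    xyz = frame.coordinates
    box = frame.box_edge
    N = xyz[bb.idx["N"]]
    CA = xyz[bb.idx["CA"]]
    C = xyz[bb.idx["C"]]
    O = xyz[bb.idx["O"]]
    H = np.full_like(N, np.nan)
    has_h = bb.idx["H"] >= 0
    H[has_h] = xyz[bb.idx["H"][has_h]]
    need = ~has_h & bb.has_prev
    if np.any(need):
        prev = np.where(need)[0] - 1
        H[need] = reconstruct_amide_h(N[need], C[prev], O[prev], box)
    donor_ok = has_h | bb.has_prev

    ca_d = min_image_displacement(CA[:, None, :], CA[None, :, :], box)
    close = np.sum(ca_d * ca_d, axis=-1) < CA_PREFILTER**2
    np.fill_diagonal(close, False)
    close &= donor_ok[:, None]

    d_idx, a_idx = np.where(close)
    e = backbone_hbond_energy(
        N[d_idx], H[d_idx], C[a_idx], O[a_idx], box
    )
    bond = np.zeros((bb.n, bb.n), dtype=bool)
    bond[d_idx, a_idx] = e < HBOND_ENERGY_CUTOFF
    return bond


def _find_bridges(bond: np.ndarray, bb: _BackboneIndex):
    """Bridge list [(i, j, type)] over sequence-residue indices, i < j."""
    n = bb.n
    chain = bb.chain

    def hb(acceptor, donor):
        # Kabsch-Sander Hbond(a, b): CO of a accepts from NH of b
        return bond[donor, acceptor]

    bridges = []
    # candidate pairs: some H-bond within the +-1 neighbourhood is necessary
    cand = bond | bond.T
    pad = np.zeros((n + 2, n + 2), dtype=bool)
    pad[1:-1, 1:-1] = cand
    near = (
        pad[:-2, :-2] | pad[:-2, 1:-1] | pad[:-2, 2:]
        | pad[1:-1, :-2] | pad[1:-1, 1:-1] | pad[1:-1, 2:]
        | pad[2:, :-2] | pad[2:, 1:-1] | pad[2:, 2:]
    )
    ii, jj = np.where(near)
    for i, j in zip(ii, jj):
        if j <= i:
            continue
        if chain[i] == chain[j] and j < i + 3:
            continue
        ok_i = bb.has_prev[i] and bb.has_next[i]
        ok_j = bb.has_prev[j] and bb.has_next[j]
        if not (ok_i and ok_j):
            continue
        if (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1)):
            bridges.append((i, j, "parallel"))
        elif (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1)):
            bridges.append((i, j, "antiparallel"))
    return bridges


def _ladders(bridges):
    """Group bridges into ladders; returns list of lists of bridge tuples."""
    index = {(i, j): k for k, (i, j, _) in enumerate(bridges)}
    parent = list(range(len(bridges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for k, (i, j, typ) in enumerate(bridges):
        nxt = (i + 1, j + 1) if typ == "parallel" else (i + 1, j - 1)
        if nxt in index and bridges[index[nxt]][2] == typ:
            union(k, index[nxt])
    groups: dict[int, list] = {}
    for k, br in enumerate(bridges):
        groups.setdefault(find(k), []).append(br)
    return list(groups.values())


def assign_ss_frame(frame: Frame, topology: Topology):
    """Per-residue DSSP codes and bridges for one frame.

    Returns ``(codes, bridges)`` where ``codes`` has one character per
    topology residue (caps: ``'-'``) and ``bridges`` lists
    ``(res_i, res_j, topology)`` with global residue indices.
    """
    bb = _backbone_index(topology)
    bond = _hbond_matrix(frame, bb)
    n = bb.n
    chain = bb.chain
    code = np.full(n, "C", dtype="<U1")

    # n-turns: N-H of i+k bonds back to C=O of i, all within one peptide
    turn = {}
    for k in (3, 4, 5):
        t = np.zeros(n, dtype=bool)
        if n > k:
            same = chain[k:] == chain[:-k]
            t[: n - k] = bond[np.arange(k, n), np.arange(n - k)] & same
        turn[k] = t

    # bridges and ladders -> E / B
    bridges = _find_bridges(bond, bb)
    for ladder in _ladders(bridges):
        mark = "B" if len(ladder) == 1 else "E"
        for (i, j, _) in ladder:
            # E (ladder) never downgraded to B by an overlapping single bridge
            for r in (i, j):
                if not (mark == "B" and code[r] == "E"):
                    code[r] = mark

    # helices: two consecutive n-turn starts -> stretch of n residues
    def mark_helix(k, letter, allowed):
        starts = np.where(turn[k][1:] & turn[k][:-1])[0] + 1
        for s in starts:
            span = slice(s, s + k)
            if allowed is not None and not np.all(
                np.isin(code[span], allowed)
            ):
                continue
            code[span] = letter

    mark_helix(4, "H", None)  # alpha overrides strand, per DSSP ordering
    mark_helix(3, "G", ("C", "G"))
    mark_helix(5, "I", ("C", "I"))

    # turns: interior residues of any n-turn
    for k in (3, 4, 5):
        for s in np.where(turn[k])[0]:
            for r in range(s + 1, min(s + k, n)):
                if code[r] == "C":
                    code[r] = "T"

    # bends: kappa angle at CA(i) from CA(i-2), CA(i+2)
    xyz = frame.coordinates
    CA = xyz[bb.idx["CA"]]
    if n >= 5:
        ok = np.zeros(n, dtype=bool)
        ok[2:-2] = (chain[2:-2] == chain[:-4]) & (chain[2:-2] == chain[4:])
        idx = np.where(ok)[0]
        u = min_image_displacement(CA[idx - 2], CA[idx], frame.box_edge)
        v = min_image_displacement(CA[idx], CA[idx + 2], frame.box_edge)
        cosk = np.sum(u * v, axis=1) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        kappa = np.degrees(np.arccos(np.clip(cosk, -1.0, 1.0)))
        for r, kap in zip(idx, kappa):
            if kap > BEND_KAPPA and code[r] == "C":
                code[r] = "S"

    full = np.full(topology.n_residues, "-", dtype="<U1")
    full[bb.residues] = code
    bridges_global = [
        (int(bb.residues[i]), int(bb.residues[j]), typ)
        for (i, j, typ) in bridges
    ]
    return full, bridges_global


def assign_ss(trajectory_or_frame, topology: Topology | None = None) -> SSMatrix:
    """Secondary-structure matrix for a trajectory (or a single frame)."""
    if isinstance(trajectory_or_frame, Frame):
        frames = [trajectory_or_frame]
        assert topology is not None
    else:
        frames = trajectory_or_frame.frames
        topology = trajectory_or_frame.topology
    codes, bridges = [], []
    for fr in frames:
        c, b = assign_ss_frame(fr, topology)
        codes.append(c)
        bridges.append(b)
    return SSMatrix(
        codes=np.stack(codes),
        times=np.array([fr.time for fr in frames]),
        bridges=bridges,
        sequence_mask=~topology.residue_is_cap,
    )


def _frame_mask(ss: SSMatrix, t_start=None, t_end=None) -> np.ndarray:
    mask = np.ones(len(ss.times), dtype=bool)
    if t_start is not None:
        mask &= ss.times >= t_start
    if t_end is not None:
        mask &= ss.times <= t_end
    if not np.any(mask):
        raise ValueError("no frames in the requested window")
    return mask


def ss_fractions(ss: SSMatrix, t_start=None, t_end=None):
    """(beta_percent, helix_percent) over a frame window, caps excluded.

    beta = E + B; helix = G + H + I; denominator = sequence residues
    times frames in the window.
    """
    sel = ss.codes[_frame_mask(ss, t_start, t_end)][:, ss.sequence_mask]
    total = sel.size
    beta = np.isin(sel, STRAND_CODES).sum()
    helix = np.isin(sel, HELIX_CODES).sum()
    return 100.0 * beta / total, 100.0 * helix / total


def ss_fraction_series(ss: SSMatrix):
    """Per-frame (beta_percent, helix_percent) arrays."""
    sel = ss.codes[:, ss.sequence_mask]
    total = sel.shape[1]
    beta = np.isin(sel, STRAND_CODES).sum(axis=1) * 100.0 / total
    helix = np.isin(sel, HELIX_CODES).sum(axis=1) * 100.0 / total
    return beta, helix


def beta_topology_fractions(ss: SSMatrix, t_start=None, t_end=None):
    """(parallel_percent, antiparallel_percent) of residue-frames in bridges.

    A residue-frame counts toward a topology class when it participates in
    at least one bridge of that class; percentages are over all sequence
    residue-frames in the window.
    """
    mask = _frame_mask(ss, t_start, t_end)
    n_res = int(ss.sequence_mask.sum())
    total = n_res * int(mask.sum())
    par = 0
    anti = 0
    for k in np.where(mask)[0]:
        pset, aset = set(), set()
        for (i, j, typ) in ss.bridges[k]:
            (pset if typ == "parallel" else aset).update((i, j))
        par += len(pset)
        anti += len(aset)
    return 100.0 * par / total, 100.0 * anti / total
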