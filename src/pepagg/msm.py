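"""Markov state models built from raw transition counts.

Discrete entities (peptides or residues) visit discrete states frame by
frame.  The count matrix pools transitions over all entities at a lag of
one saved frame,

    T(S_i, S_j) = number of (entity, t) with state i at t and j at t+1,

the transition probability matrix is the row normalisation
P(S_i, S_j) = T(S_i, S_j) / N_i with N_i = sum_j T(S_i, S_j), and
occupancies propagate as pi(n) = pi(0) P^n.  No reversibility constraint
and no implied-timescale analysis: raw counts only.

Two state spaces are used: the N cluster-size states (monomer ... N-mer)
and six residue-level states crossing secondary structure
(coil/strand/helix) with the parent peptide's oligomeric status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterSeries
from .secondary_structure import HELIX_CODES, SSMatrix, STRAND_CODES

RESIDUE_STATE_SPACE = (
    "monomeric coil",
    "oligomeric coil",
    "monomeric strand",
    "oligomeric strand",
    "monomeric helix",
    "oligomeric helix",
)


@dataclass
class StateSeries:
    """Entity x frame grid of discrete state indices."""

    states: np.ndarray  # (n_entities, n_frames) int indices into state_space
    state_space: tuple
    entity_kind: str = "entity"

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D (entities x frames) grid")
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= len(self.state_space)
        ):
            raise ValueError("state index outside the declared state space")

    @property
    def n_entities(self) -> int:
        return self.states.shape[0]

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def empirical_occupancy(self, frame: int = 0) -> np.ndarray:
        """Fraction of entities in each state at one frame."""
        counts = np.bincount(
            self.states[:, frame], minlength=len(self.state_space)
        )
        return counts / counts.sum()


def assign_cluster_states(series: ClusterSeries) -> StateSeries:
    """Cluster-size state per peptide per frame: state s = member of an s-mer."""
    cs = series.cluster_sizes.T  # (n_peptides, n_frames)
    n = series.n_peptides
    space = tuple(range(1, n + 1))
    return StateSeries(states=cs - 1, state_space=space, entity_kind="peptide")


def assign_residue_states(
    ss: SSMatrix, clusters: ClusterSeries, residue_peptide: np.ndarray
) -> StateSeries:
    """Six residue-level states: {coil, strand, helix} x {monomeric, oligomeric}.

    Strand = {E, B}; helix = {G, H, I}; every other code is coil.  A residue
    is oligomeric when its parent peptide's cluster size is >= 2.
    ``residue_peptide`` maps each topology residue to its peptide index.
    """
    if ss.codes.shape[0] != len(clusters.assignments):
        raise ValueError("secondary-structure and cluster series frame counts differ")
    if not np.allclose(ss.times, clusters.times):
        raise ValueError("secondary-structure and cluster series times differ")
    codes = ss.codes[:, ss.sequence_mask]  # (frames, residues)
    pep_of_res = residue_peptide[ss.sequence_mask]
    cs = clusters.cluster_sizes  # (frames, peptides)
    oligo = cs[:, pep_of_res] >= 2  # (frames, residues)
    strand = np.isin(codes, STRAND_CODES)
    helix = np.isin(codes, HELIX_CODES)
    ss_class = np.zeros(codes.shape, dtype=int)  # 0 coil, 1 strand, 2 helix
    ss_class[strand] = 1
    ss_class[helix] = 2
    states = (2 * ss_class + oligo.astype(int)).T  # (residues, frames)
    return StateSeries(
        states=states, state_space=RESIDUE_STATE_SPACE, entity_kind="residue"
    )


def count_transitions(series: StateSeries, lag: int = 1):
    """Count matrix T and per-state totals N_i at the given lag (frames)."""
    if series.n_frames < lag + 1:
        raise ValueError("need at least lag+1 frames to count transitions")
    k = len(series.state_space)
    src = series.states[:, :-lag].ravel()
    dst = series.states[:, lag:].ravel()
    T = np.zeros((k, k), dtype=np.int64)
    np.add.at(T, (src, dst), 1)
    return T, T.sum(axis=1)


def transition_probability(T: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Row-normalised P = T / N_i; unvisited states get an identity row."""
    k = T.shape[0]
    P = np.eye(k)
    visited = N > 0
    P[visited] = T[visited] / N[visited, None]
    return P


@dataclass
class PropagationResult:
    """Occupancy trajectories pi(0..n) under pi(n) = pi(0) P^n."""

    pi: np.ndarray  # (n_steps + 1, n_states)
    pi0: np.ndarray
    state_space: tuple

    def state_series(self, state) -> np.ndarray:
        return self.pi[:, self.state_space.index(state)]


def propagate(P: np.ndarray, pi0: np.ndarray, n_steps: int,
              state_space: tuple | None = None) -> PropagationResult:
    """Propagate an occupancy row vector: pi(n) = pi(0) P^n for n = 0..n_steps."""
    pi0 = np.asarray(pi0, dtype=float)
    if np.any(pi0 < 0) or not np.isclose(pi0.sum(), 1.0, atol=1e-8):
        raise ValueError("pi0 must be non-negative and sum to 1")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("P must be row-stochastic")
    out = np.empty((n_steps + 1, len(pi0)))
    out[0] = pi0
    cur = pi0
    for n in range(1, n_steps + 1):
        cur = cur @ P
        out[n] = cur
    space = state_space if state_space is not None else tuple(range(len(pi0)))
    return PropagationResult(pi=out, pi0=pi0, state_space=space)


def max_state_fraction(result: PropagationResult, states) -> float:
    """Max over steps of the summed occupancy of a state subset, as percent."""
    if not states:
        return 0.0
    idx = [result.state_space.index(s) for s in states]
    return float(100.0 * result.pi[:, idx].sum(axis=1).max())


def nmer_fraction_series(
    result: PropagationResult, threshold: float = 0.05
) -> dict:
    """Occupancy curve per n-mer state, keeping states that ever exceed
    ``threshold`` (display filter only; propagation keeps all states)."""
    out = {}
    for k, state in enumerate(result.state_space):
        curve = result.pi[:, k]
        if curve.max() > threshold:
            out[state] = curve
    return out


class MarkovStateModel:
    """Markov state model estimated from a :class:`StateSeries`.

    Statsmodels-style: the model holds the data and lag; :meth:`fit`
    returns an :class:`MSMResults` with the count and probability matrices
    and propagation/diagnostic methods.
    """

    def __init__(self, series: StateSeries, lag: int = 1):
        if lag < 1:
            raise ValueError("lag must be >= 1")
        self.series = series
        self.lag = lag

    def fit(self) -> "MSMResults":
        T, N = count_transitions(self.series, lag=self.lag)
        P = transition_probability(T, N)
        return MSMResults(model=self, T=T, N=N, P=P)


@dataclass
class MSMResults:
    """Estimated transition model: counts T, totals N_i, probabilities P."""

    model: MarkovStateModel
    T: np.ndarray
    N: np.ndarray
    P: np.ndarray

    @property
    def state_space(self) -> tuple:
        return self.model.series.state_space

    @property
    def unvisited_states(self) -> list:
        return [s for s, n in zip(self.state_space, self.N) if n == 0]

    def propagate(
        self, pi0: np.ndarray | None = None, n_steps: int = 100
    ) -> PropagationResult:
        """Propagate an initial occupancy (default: empirical first frame)."""
        if pi0 is None:
            pi0 = self.model.series.empirical_occupancy(0)
        return propagate(self.P, pi0, n_steps, state_space=self.state_space)

    def max_state_fraction(self, states, pi0=None, n_steps: int = 100) -> float:
        return max_state_fraction(self.propagate(pi0, n_steps), states)

    def summary(self) -> str:
        """Plain-text summary: state occupancies and transition probabilities."""
        space = [str(s) for s in self.state_space]
        occ = self.N / self.N.sum() if self.N.sum() else self.N
        df = pd.DataFrame(
            {"N_i": self.N, "occupancy": np.round(occ, 4)}, index=space
        )
        pdf = pd.DataFrame(np.round(self.P, 4), index=space, columns=space)
        lines = [
            "Markov state model (raw transition counts)",
            f"entities: {self.model.series.n_entities} "
            f"({self.model.series.entity_kind}s), "
            f"frames: {self.model.series.n_frames}, lag: {self.model.lag}",
            "",
            "State occurrence totals:",
            df.to_string(),
            "",
            "Transition probability matrix P:",
            pdf.to_string(),
        ]
        if self.unvisited_states:
            lines.append(
                f"\nunvisited states (identity rows): {self.unvisited_states}"
            )
        return "\n".join(lines)
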