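"""Shared fixtures: tiny constructed systems used across test modules."""

import numpy as np
import pytest

from pepagg.core import Atom, Frame, Residue, Topology


def point_atom(name="C", element="C", radius=1.70, mainchain=False,
               aliphatic=False, ring=False):
    return Atom(
        atom_name=name,
        element=element,
        vdw_radius=radius,
        is_mainchain=mainchain,
        is_sidechain_aliphatic_carbon=aliphatic,
        is_phe_ring_atom=ring,
    )


def point_topology(n_peptides, resname="GLY", **atom_kwargs):
    """n single-atom peptides — minimal system for contact-criterion tests."""
    peptides = [
        [Residue(resname, 1, [point_atom(**atom_kwargs)])]
        for _ in range(n_peptides)
    ]
    return Topology(peptides)


@pytest.fixture
def two_carbon_system():
    """Two one-atom 'peptides' (C, Bondi radius 1.70 A)."""
    topo = point_topology(2)

    def frame(separation, box=104.0):
        coords = np.array([[10.0, 10.0, 10.0],
                           [10.0 + separation, 10.0, 10.0]])
        return Frame(coordinates=coords, box_edge=box)

    return topo, frame


@pytest.fixture(scope="session")
def small_aggregation():
    """An 8-peptide, 40-frame sticky trajectory reused by several modules."""
    from pepagg.synthetic import AggregationParams, gen_aggregation_trajectory

    params = AggregationParams(
        n_peptides=8, box_edge=70.0, n_frames=40, seed=11
    )
    traj, labels = gen_aggregation_trajectory(params, return_labels=True)
    return params, traj, labels
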