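"""Shared fixtures: small synthetic complexes and hand-built toy topologies."""

from __future__ import annotations

import numpy as np
import pytest

from nucdyn.synthetic import SyntheticSpec, generate_structure
from nucdyn.topology import AtomSite, ComplexTopology


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Study geometry (147 bp, full chain set) at test-sized trial counts."""
    return SyntheticSpec(
        dna_bp=147,
        n_trials=2,
        n_frames=200,
        breathing_extent_bp=10,
        breathing_period_frames=50,
        seed=7,
    )


@pytest.fixture(scope="session")
def canonical_structure(small_spec):
    return generate_structure(small_spec)


def build_toy_topology(
    chain_specs: list[tuple[str, str, list[tuple[int, list[tuple[str, str]]]]]],
) -> tuple[ComplexTopology, np.ndarray]:
    """Hand-build a topology from (chain_id, role, [(res_idx, [(atom, element)])]).

    Coordinates are a deterministic non-degenerate spread.
    """
    atoms = []
    coords = []
    aid = 1
    for cid, _role, residues in chain_specs:
        for res, atom_list in residues:
            for name, element in atom_list:
                pos = np.array(
                    [aid * 1.7 % 13.0, (aid * 2.3) % 7.0, aid * 0.9 % 11.0]
                )
                atoms.append(AtomSite(aid, name, element, cid, res, "ALA", pos))
                coords.append(pos)
                aid += 1
    topo = ComplexTopology([(c, r) for c, r, _ in chain_specs], atoms)
    return topo, np.array(coords)


@pytest.fixture()
def h2a_chain_topology():
    """One H2A chain with residues 1..128, CA + N (hydrogen) per residue."""
    residues = [(i, [("CA", "C"), ("H1", "H")]) for i in range(1, 129)]
    return build_toy_topology([("C", "H2A", residues)])
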