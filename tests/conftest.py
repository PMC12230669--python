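"""Shared fixtures: tiny hand-built structures and decoy pools."""

import numpy as np
import pytest

from dockjury.structure import Atom, Chain, Residue, Structure


def make_structure(label, chains):
    """Build a Structure from {chain_id: [(res_seq, res_name, {atom: xyz})]}."""
    out = []
    for cid, residues in chains.items():
        chain = Chain(cid)
        for res_seq, res_name, atoms in residues:
            res = Residue(res_seq, " ", res_name)
            for name, xyz in atoms.items():
                element = name[0] if name[0] in "CNOS" else "C"
                res.atoms[name] = Atom(name, element, *map(float, xyz))
            chain.residues.append(res)
        out.append(chain)
    return Structure(label, out)


def ca_chain(cid, coords, res_name="ALA", start=1):
    """Chain of CA-only residues at the given coordinates."""
    return (
        cid,
        [
            (start + i, res_name, {"CA": xyz})
            for i, xyz in enumerate(coords)
        ],
    )


def structure_from_ca(label, *chains):
    return make_structure(label, dict(chains))


@pytest.fixture
def ca_line_trio():
    """Reference: 3 CA atoms on a line at 0/4/8 A; model moves atom 3 out 3 A."""
    ref = structure_from_ca(
        "ref", ca_chain("A", [(0, 0, 0), (4, 0, 0), (8, 0, 0)])
    )
    model = structure_from_ca(
        "mod", ca_chain("A", [(0, 0, 0), (4, 0, 0), (11, 0, 0)])
    )
    return model, ref


@pytest.fixture
def identity_mapping():
    from dockjury.assembly import ChainMapping

    def build(s):
        keys = s.residue_keys()
        return ChainMapping(
            {c: c for c in s.chain_ids}, {k: k for k in keys}
        )

    return build


@pytest.fixture(scope="session")
def a2_reference():
    from dockjury.decoys import DecoySpec, make_reference

    return make_reference(DecoySpec(stoichiometry="A2", chain_length=16, seed=0))


@pytest.fixture(scope="session")
def a3_reference():
    from dockjury.decoys import DecoySpec, make_reference

    return make_reference(DecoySpec(stoichiometry="A3", chain_length=12, seed=0))


@pytest.fixture(scope="session")
def hetero_reference():
    from dockjury.decoys import DecoySpec, make_reference

    return make_reference(
        DecoySpec(stoichiometry="A1B1C1", chain_length=12, seed=0)
    )


def random_rigid_transform(rng):
    """Random proper rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return Q, t


def transform_structure(s, Q, t):
    from dockjury.structure import Atom

    out = s.copy()
    for chain in out.chains:
        for res in chain.residues:
            for name, a in list(res.atoms.items()):
                p = Q @ np.array([a.x, a.y, a.z]) + t
                res.atoms[name] = Atom(a.name, a.element, *p, a.bfactor)
    return out
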