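"""Seeded generator of synthetic reference complexes and graded decoy pools.

The generator builds idealized helical toy assemblies — each chain a
poly-amino-acid alpha-helix (backbone N, CA, C, O plus CB, rise 1.5 A,
100 degrees per residue) — arranged with C_n symmetry for homomers and
collinear offsets for heteromers, with inter-axis spacing tuned so that
adjacent chains form interfaces at the 5 A heavy-atom contact distance.
Perturbation ladders then produce decoy pools of graded quality: each
rung applies a rigid-body rotation/translation to one chain plus
isotropic Gaussian coordinate noise.  Identical specs (including the
seed) produce bitwise-identical coordinates, so every metric and the
jury engine are testable without any external data.

These toys emulate the geometry of real assemblies (chain interfaces,
graded divergence) but not their side-chain packing, sequence diversity
or physical plausibility; see the methods note for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .assembly import Stoichiometry, interchain_contacts, parse_stoichiometry
from .errors import GenerationError
from .structure import Atom, Chain, Residue, Structure

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # CA helix radius, A

# one residue type per chain group: distinct sequences => distinct groups
GROUP_RESIDUES = ("ALA", "GLY", "SER", "VAL", "LEU", "THR")

DEFAULT_LADDER = (
    (5.0, 0.5, 0.05),
    (10.0, 1.0, 0.15),
    (25.0, 3.0, 0.40),
    (60.0, 8.0, 1.00),
)


@dataclass(frozen=True)
class DecoySpec:
    """Conditions for one synthetic target and its decoy pool."""

    stoichiometry: str = "A2"
    chain_length: int = 16
    ladder: tuple = DEFAULT_LADDER  # (rotation deg, translation A, noise sigma A)
    seed: int = 0

    def __post_init__(self):
        if self.chain_length < 5:
            raise GenerationError("chain_length must be >= 5")
        mags = [sum(r) for r in self.ladder]
        if mags != sorted(mags):
            raise GenerationError("ladder must be sorted by increasing magnitude")


def _helix_chain(chain_id: str, length: int, res_name: str) -> Chain:
    """Ideal helical chain along +z, axis through the origin."""
    chain = Chain(chain_id)
    thetas = np.deg2rad(HELIX_TWIST) * np.arange(length + 2)
    ca = np.column_stack(
        [
            HELIX_RADIUS * np.cos(thetas),
            HELIX_RADIUS * np.sin(thetas),
            HELIX_RISE * np.arange(length + 2),
        ]
    )
    for i in range(1, length + 1):
        prev_dir = ca[i - 1] - ca[i]
        next_dir = ca[i + 1] - ca[i]
        tangent = next_dir - prev_dir
        tangent /= np.linalg.norm(tangent)
        radial = np.array([np.cos(thetas[i]), np.sin(thetas[i]), 0.0])
        pos_ca = ca[i]
        pos_n = pos_ca - 1.45 * tangent
        pos_c = pos_ca + 1.52 * tangent
        pos_o = pos_c + 1.23 * radial
        res = Residue(i, " ", res_name)
        res.atoms["N"] = Atom("N", "N", *pos_n)
        res.atoms["CA"] = Atom("CA", "C", *pos_ca)
        res.atoms["C"] = Atom("C", "C", *pos_c)
        res.atoms["O"] = Atom("O", "O", *pos_o)
        if res_name != "GLY":
            pos_cb = pos_ca + 1.53 * radial
            res.atoms["CB"] = Atom("CB", "C", *pos_cb)
        chain.residues.append(res)
    return chain


def _transform_chain(chain: Chain, rotation: np.ndarray, translation: np.ndarray):
    for res in chain.residues:
        for name, a in list(res.atoms.items()):
            p = rotation @ np.array([a.x, a.y, a.z]) + translation
            res.atoms[name] = Atom(a.name, a.element, *p, a.bfactor)


def _rot_z(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _chain_heavy(chain: Chain) -> np.ndarray:
    return np.array(
        [(a.x, a.y, a.z) for r in chain.residues for a in r.atoms.values()]
    )


def _min_interchain_distance(chains: list[Chain]) -> float:
    best = np.inf
    tables = [_chain_heavy(c) for c in chains]
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            best = min(best, float(cdist(tables[i], tables[j]).min()))
    return best


def make_reference(spec: DecoySpec) -> Structure:
    """Build the synthetic reference assembly for a spec.

    Homomer chains are placed with C_n symmetry around the z axis;
    heteromer groups are laid out along x with per-pair spacing.  The
    inter-axis spacing is searched deterministically so the closest
    heavy-atom approach between adjacent chains falls in the contact
    window (3.2-4.8 A), guaranteeing at least one 5 A interface.
    """
    st = (
        spec.stoichiometry
        if isinstance(spec.stoichiometry, Stoichiometry)
        else parse_stoichiometry(spec.stoichiometry)
    )
    if st.n_groups > len(GROUP_RESIDUES):
        raise GenerationError(
            f"at most {len(GROUP_RESIDUES)} distinct subunit groups supported"
        )
    chain_ids = [chr(ord("A") + i) for i in range(st.total_copies)]
    chains: list[Chain] = []
    idx = 0
    specs = []  # (chain_id, group index, copy index)
    for gi, (_, count) in enumerate(st.counts):
        for ci in range(count):
            specs.append((chain_ids[idx], gi, ci))
            idx += 1
    n = len(specs)

    def build(spacing: float) -> list[Chain]:
        placed = []
        for k, (cid, gi, _) in enumerate(specs):
            chain = _helix_chain(cid, spec.chain_length, GROUP_RESIDUES[gi])
            if n == 1:
                placed.append(chain)
                continue
            if st.n_groups == 1 and n > 2:
                # C_n ring: chain axis at distance R, rotated into place
                R = spacing / (2.0 * np.sin(np.pi / n))
                _transform_chain(chain, _rot_z(k * 360.0 / n),
                                 _rot_z(k * 360.0 / n) @ np.array([R, 0.0, 0.0]))
            else:
                # collinear row along x (dimers and heteromers); the z
                # stagger breaks exact swap symmetry so chain mapping is
                # unambiguous, as in real (asymmetric) interfaces
                _transform_chain(
                    chain, _rot_z(180.0 * (k % 2)),
                    np.array([k * spacing, 0.0, k * 2.7])
                )
            placed.append(chain)
        return placed

    if n == 1:
        chains = build(0.0)
    else:
        chains = None
        for spacing in np.arange(7.0, 20.0, 0.25):
            cand = build(float(spacing))
            dmin = _min_interchain_distance(cand)
            if 3.2 <= dmin <= 4.2:
                chains = cand
                break
        if chains is None:
            raise GenerationError(
                "could not place chains with a clash-free 5 A interface"
            )
    structure = Structure(f"ref_{st}", chains)
    if n > 1 and len(interchain_contacts(structure, 5.0)) == 0:
        raise GenerationError("generated geometry has no inter-chain contacts")
    return structure


def _rotation_about_axis(axis: np.ndarray, angle_deg: float):
    angle = np.deg2rad(angle_deg)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def perturb(
    s: Structure,
    chain_id: str,
    rotation_deg: float = 0.0,
    translation: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    axis=None,
    direction=None,
) -> Structure:
    """Rigid-body perturbation of one chain about its centroid, plus noise.

    The rotation axis and translation direction are drawn from the seeded
    RNG unless given explicitly; Gaussian noise of the given sigma is
    then added to every atom of that chain.  All other chains are
    untouched.
    """
    out = s.copy()
    chain = out.chain(chain_id)  # KeyError on unknown chain
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = rng.normal(size=3)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = _rotation_about_axis(axis, rotation_deg)
    if direction is None:
        direction = rng.normal(size=3)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    t = translation * direction
    coords = _chain_heavy(chain)
    centroid = coords.mean(axis=0)
    for res in chain.residues:
        for name, a in list(res.atoms.items()):
            p = np.array([a.x, a.y, a.z])
            p = R @ (p - centroid) + centroid + t
            if noise_sigma > 0:
                p = p + rng.normal(scale=noise_sigma, size=3)
            res.atoms[name] = Atom(a.name, a.element, *p, a.bfactor)
    return out


@dataclass
class DecoyPool:
    reference: Structure
    models: list[Structure]
    manifest: list[dict] = field(default_factory=list)  # true-quality ordering


def make_pool(spec: DecoySpec) -> DecoyPool:
    """Reference copy plus one decoy per ladder rung, with true ordering.

    Each rung perturbs the same chain along its own rigid mode from a
    fixed schedule of mutually orthogonal or antiparallel rotation axes
    and translation directions, plus seeded Gaussian noise.  Real decoy
    pools have this property naturally — independent methods err in
    nearly orthogonal directions of a very high-dimensional conformation
    space — but a chain's rigid-body space has only 6 dimensions, so
    random directions would be strongly correlated; the fixed schedule
    restores the decorrelation.  Decoy quality is then monotone in the
    rung index, which the manifest records as the ground-truth ordering.
    """
    if len(spec.ladder) < 2:
        raise GenerationError("ladder must have at least 2 rungs")
    ex, ey, ez = np.eye(3)
    axes = [ex, ey, ez, -ex, -ey, -ez]
    directions = [ey, ez, -ey, -ez, ex, -ex]
    ref = make_reference(spec)
    target_chain = ref.chains[-1].chain_id
    models = [ref.copy(label="rung00")]
    manifest = [
        {"label": "rung00", "rung": 0, "rotation": 0.0, "translation": 0.0,
         "noise": 0.0}
    ]
    for k, (rot, trans, sigma) in enumerate(spec.ladder, start=1):
        decoy = perturb(ref, target_chain, rot, trans, sigma,
                        seed=(spec.seed * 1009 + k) % (2**31),
                        axis=axes[(k - 1) % len(axes)],
                        direction=directions[(k - 1) % len(directions)])
        decoy.label = f"rung{k:02d}"
        models.append(decoy)
        manifest.append(
            {"label": decoy.label, "rung": k, "rotation": rot,
             "translation": trans, "noise": sigma}
        )
    return DecoyPool(ref, models, manifest)
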