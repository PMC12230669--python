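"""Stoichiometry handling, chain grouping and model-to-reference chain mapping.

A stoichiometry is a mapping from sequence-group labels (A, B, C, ...) to
copy counts, written the way CASP writes it ("A3", "A1B1C1").  When a
template search returns several candidate assemblies, the stoichiometry
assigned to the target is the modal (most frequent) one among the hits,
with deterministic tie-breaks.

Chain mapping between a model and a reference assembly is the substrate
of every assembly-comparison metric: chains are first partitioned into
sequence-compatible groups, then within each group model chains are
assigned to reference chains so as to maximize the number of shared
inter-chain residue contacts.  For small permutation spaces the
assignment is exhaustive; otherwise a superposition-seeded greedy
assignment with pairwise-swap refinement is used.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .errors import MappingError, RangeError, StoichiometryError
from .structure import ResidueKey, Structure

# ---------------------------------------------------------------------------
# Stoichiometry

_STOICH_RE = re.compile(r"([A-Z])(\d+)")


@dataclass(frozen=True)
class Stoichiometry:
    """Copy counts per unique-sequence subunit, canonical labels A, B, C..."""

    counts: tuple  # tuple of (label, count), labels consecutive from 'A'

    def __post_init__(self):
        labels = [l for l, _ in self.counts]
        expected = [chr(ord("A") + i) for i in range(len(labels))]
        if labels != expected:
            raise StoichiometryError(
                f"labels must be consecutive from 'A', got {labels}"
            )
        for _, c in self.counts:
            if not isinstance(c, int) or c < 1:
                raise RangeError(f"copy count must be a positive integer, got {c}")

    @property
    def total_copies(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def n_groups(self) -> int:
        return len(self.counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        return format_stoichiometry(self)


def parse_stoichiometry(s: str) -> Stoichiometry:
    """Parse a CASP stoichiometry string like "A3" or "A1B1C1"."""
    if not s or not re.fullmatch(r"(?:[A-Z]\d+)+", s):
        raise StoichiometryError(f"malformed stoichiometry string {s!r}")
    pairs = []
    seen = []
    for label, num in _STOICH_RE.findall(s):
        count = int(num)
        if count == 0:
            raise RangeError(f"copy count 0 for subunit {label} in {s!r}")
        if label in seen:
            raise StoichiometryError(f"repeated label {label} in {s!r}")
        seen.append(label)
        pairs.append(count)
    # normalize labels to A, B, C... in order of first appearance
    counts = tuple(
        (chr(ord("A") + i), c) for i, c in enumerate(pairs)
    )
    return Stoichiometry(counts)


def format_stoichiometry(st: Stoichiometry) -> str:
    return "".join(f"{label}{count}" for label, count in st.counts)


@dataclass(frozen=True)
class TemplateHit:
    template_id: str
    stoichiometry: Stoichiometry


def modal_stoichiometry(hits: list[TemplateHit]) -> Stoichiometry:
    """Assign the most frequent stoichiometry among template hits.

    Ties are broken by smallest total subunit count, then by
    lexicographically smallest canonical string.  An empty hit list is an
    error: with no templates a sequence-based predictor must take over,
    which is outside this package.
    """
    if not hits:
        raise MappingError(
            "no template hits; sequence-based stoichiometry prediction required"
        )
    tally: dict[str, int] = {}
    by_string: dict[str, Stoichiometry] = {}
    for hit in hits:
        key = format_stoichiometry(hit.stoichiometry)
        tally[key] = tally.get(key, 0) + 1
        by_string[key] = hit.stoichiometry
    best = min(
        tally,
        key=lambda k: (-tally[k], by_string[k].total_copies, k),
    )
    return by_string[best]


def read_template_hits(text: str) -> list[TemplateHit]:
    """Parse a template-hit table: template_id <tab> stoichiometry per line."""
    hits = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise StoichiometryError(f"malformed template-hit line {line!r}")
        hits.append(TemplateHit(fields[0], parse_stoichiometry(fields[1])))
    return hits


# ---------------------------------------------------------------------------
# Sequence grouping

@dataclass
class ChainGroup:
    members: list[tuple[str, str]]  # (structure tag 'model'/'reference', chain_id)
    representative: str  # sequence

    def chains_of(self, tag: str) -> list[str]:
        return [cid for t, cid in self.members if t == tag]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -0.5
    # end gaps free: modelling truncations should not count against identity
    try:
        a.end_insertion_score = 0.0
        a.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


def _identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Fraction of identical aligned positions, normalized by shorter length."""
    if not seq_a or not seq_b:
        return 0.0
    if seq_a == seq_b:
        return 1.0
    if aligner is None:
        aligner = _aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    matches = 0
    for (ta, tb), (qa, qb) in zip(*aln.aligned):
        sa, sb = seq_a[ta:tb], seq_b[qa:qb]
        matches += sum(1 for x, y in zip(sa, sb) if x == y)
    return matches / min(len(seq_a), len(seq_b))


def _aligned_pairs(seq_a: str, seq_b: str, aligner=None) -> list[tuple[int, int]]:
    """Order-preserving list of aligned residue index pairs."""
    if seq_a == seq_b:
        return [(i, i) for i in range(len(seq_a))]
    if aligner is None:
        aligner = _aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (ta, tb), (qa, qb) in zip(*aln.aligned):
        pairs.extend(zip(range(ta, tb), range(qa, qb)))
    return pairs


def group_chains(
    model: Structure,
    reference: Structure,
    identity_threshold: float = 0.95,
) -> list[ChainGroup]:
    """Partition all chains of both structures by sequence identity.

    Chains join a group when their identity to the group representative is
    at least ``identity_threshold``.  Chains shorter than 3 residues only
    join on exact sequence match (with a warning), since percent identity
    is meaningless at that length.
    """
    if not model.chains or not reference.chains:
        raise MappingError("empty structure cannot be grouped")
    aligner = _aligner()
    groups: list[ChainGroup] = []
    entries = [("model", c) for c in model.chains] + [
        ("reference", c) for c in reference.chains
    ]
    for tag, chain in entries:
        seq = chain.sequence
        short = len(seq) < 3
        if short:
            warnings.warn(
                f"chain {chain.chain_id} has <3 residues; grouping by exact "
                "sequence match only",
                stacklevel=2,
            )
        placed = False
        for g in groups:
            if short or len(g.representative) < 3:
                ok = seq == g.representative
            else:
                ok = _identity(seq, g.representative, aligner) >= identity_threshold
            if ok:
                g.members.append((tag, chain.chain_id))
                placed = True
                break
        if not placed:
            groups.append(ChainGroup([(tag, chain.chain_id)], seq))
    return groups


# ---------------------------------------------------------------------------
# Inter-chain contacts

@dataclass
class ContactSet:
    """Unordered inter-chain residue pairs within a heavy-atom distance."""

    pairs: set  # frozenset-like: set of tuple(sorted((key_i, key_j)))
    threshold: float

    def __len__(self):
        return len(self.pairs)

    def __contains__(self, pair):
        return tuple(sorted(pair)) in self.pairs


def _heavy_atom_table(s: Structure, atom_filter=None):
    coords = []
    keys = []
    for chain_id, res, atom in s.iter_atoms():
        if atom_filter is not None and not atom_filter(atom):
            continue
        coords.append((atom.x, atom.y, atom.z))
        keys.append((chain_id, res.res_seq, res.ins_code))
    return np.asarray(coords, dtype=float), keys


def interchain_contacts(s: Structure, threshold: float = 5.0) -> ContactSet:
    """All inter-chain residue pairs with min heavy-atom distance <= threshold."""
    if threshold <= 0:
        raise RangeError(f"contact threshold must be positive, got {threshold}")
    coords, keys = _heavy_atom_table(s)
    pairs: set = set()
    if len(coords) >= 2:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(threshold):
            ki, kj = keys[i], keys[j]
            if ki[0] != kj[0]:
                pairs.add(tuple(sorted((ki, kj))))
    return ContactSet(pairs, threshold)


# ---------------------------------------------------------------------------
# Chain mapping

PERMUTATION_CUTOFF = 720  # exhaustive search bound: exact up to 6 copies


@dataclass
class ChainMapping:
    """Partial bijection model chain -> reference chain with residue pairs."""

    chain_pairs: dict[str, str]
    residue_pairs: dict[ResidueKey, ResidueKey]  # model key -> reference key
    shared_contacts: int = 0

    @property
    def reverse_residue_pairs(self) -> dict[ResidueKey, ResidueKey]:
        return {v: k for k, v in self.residue_pairs.items()}

    def ref_key(self, model_key: ResidueKey) -> ResidueKey | None:
        return self.residue_pairs.get(model_key)


def _chain_residue_pairs(model_chain, ref_chain, aligner):
    """Residue-key correspondence for one chain pair via sequence alignment."""
    idx = _aligned_pairs(model_chain.sequence, ref_chain.sequence, aligner)
    out = {}
    for i, j in idx:
        rm = model_chain.residues[i]
        rr = ref_chain.residues[j]
        out[(model_chain.chain_id, rm.res_seq, rm.ins_code)] = (
            ref_chain.chain_id,
            rr.res_seq,
            rr.ins_code,
        )
    return out


def _relabeled_shared_contacts(
    model_contacts: ContactSet,
    ref_contacts: ContactSet,
    residue_pairs: dict,
) -> int:
    shared = 0
    for a, b in model_contacts.pairs:
        ra, rb = residue_pairs.get(a), residue_pairs.get(b)
        if ra is None or rb is None:
            continue
        if tuple(sorted((ra, rb))) in ref_contacts.pairs:
            shared += 1
    return shared


def _build_mapping(
    model: Structure,
    reference: Structure,
    assignment: dict[str, str],
    aligner,
    model_contacts: ContactSet,
    ref_contacts: ContactSet,
) -> ChainMapping:
    residue_pairs: dict = {}
    for mc, rc in assignment.items():
        residue_pairs.update(
            _chain_residue_pairs(model.chain(mc), reference.chain(rc), aligner)
        )
    shared = _relabeled_shared_contacts(model_contacts, ref_contacts, residue_pairs)
    return ChainMapping(dict(assignment), residue_pairs, shared)


def _chain_ca_coords(chain):
    pts = []
    for r in chain.residues:
        a = r.atoms.get("CA")
        if a is not None:
            pts.append((a.x, a.y, a.z))
    return np.asarray(pts, dtype=float)


def _chain_centroid(chain) -> np.ndarray:
    pts = [(a.x, a.y, a.z) for r in chain.residues for a in r.atoms.values()]
    return np.mean(np.asarray(pts, dtype=float), axis=0)


def _greedy_assignment(model, reference, group_pairs, aligner,
                       model_contacts, ref_contacts):
    """Superposition-seeded greedy chain assignment with swap refinement."""
    from .global_scores import kabsch  # deferred: avoids import cycle

    # seed on the largest model chain that has candidates
    seed_group = max(
        (gp for gp in group_pairs if gp[0] and gp[1]),
        key=lambda gp: max(len(model.chain(c).residues) for c in gp[0]),
    )
    seed_chain = max(
        seed_group[0], key=lambda c: (len(model.chain(c).residues), c)
    )
    best = None
    for seed_ref in sorted(seed_group[1]):
        # superpose model on reference using the seeded chain pair
        pairs = _chain_residue_pairs(
            model.chain(seed_chain), reference.chain(seed_ref), aligner
        )
        P, Q = [], []
        for mk, rk in pairs.items():
            am = model.residue(mk).atoms.get("CA")
            ar = reference.residue(rk).atoms.get("CA")
            if am is not None and ar is not None:
                P.append((am.x, am.y, am.z))
                Q.append((ar.x, ar.y, ar.z))
        assignment = {seed_chain: seed_ref}
        if len(P) >= 3:
            sup = kabsch(np.asarray(P), np.asarray(Q))
            transform = lambda x: x @ sup.rotation.T + sup.translation  # noqa: E731
        else:
            transform = lambda x: x  # noqa: E731
        # assign remaining chains by transformed-centroid proximity
        for mchains, rchains in group_pairs:
            avail = [c for c in sorted(rchains) if c not in assignment.values()]
            for mc in sorted(c for c in mchains if c != seed_chain):
                if not avail:
                    break
                mcen = transform(_chain_centroid(model.chain(mc)))
                pick = min(
                    avail,
                    key=lambda rc: (
                        float(np.linalg.norm(mcen - _chain_centroid(reference.chain(rc)))),
                        rc,
                    ),
                )
                assignment[mc] = pick
                avail.remove(pick)
        cand = _build_mapping(model, reference, assignment, aligner,
                              model_contacts, ref_contacts)
        if best is None or cand.shared_contacts > best.shared_contacts:
            best = cand
    # pairwise swap refinement within groups
    improved = True
    while improved:
        improved = False
        chains = sorted(best.chain_pairs)
        for a, b in itertools.combinations(chains, 2):
            # only swap within the same group
            in_same = any(
                a in gp[0] and b in gp[0] for gp in group_pairs
            )
            if not in_same:
                continue
            swapped = dict(best.chain_pairs)
            swapped[a], swapped[b] = swapped[b], swapped[a]
            cand = _build_mapping(model, reference, swapped, aligner,
                                  model_contacts, ref_contacts)
            if cand.shared_contacts > best.shared_contacts:
                best = cand
                improved = True
    return best


def map_chains(
    model: Structure,
    reference: Structure,
    groups: list[ChainGroup] | None = None,
    contact_threshold: float = 5.0,
) -> ChainMapping:
    """Assign model chains to reference chains maximizing contact overlap.

    The search is exhaustive over per-group permutations when the total
    permutation count is at most 720, else greedy with swap refinement.
    Deterministic: ties resolve to the lexicographically smallest
    assignment (by sorted chain_id order).
    """
    if groups is None:
        groups = group_chains(model, reference)
    group_pairs = []
    for g in groups:
        mc, rc = g.chains_of("model"), g.chains_of("reference")
        if mc and rc:
            group_pairs.append((mc, rc))
    if not group_pairs:
        raise MappingError("model and reference share no sequence group")

    aligner = _aligner()
    model_contacts = interchain_contacts(model, contact_threshold)
    ref_contacts = interchain_contacts(reference, contact_threshold)

    n_perm = 1
    for mc, rc in group_pairs:
        k = min(len(mc), len(rc))
        n = max(len(mc), len(rc))
        n_perm *= math.perm(n, k)
    if n_perm <= PERMUTATION_CUTOFF:
        best = None
        per_group = []
        for mc, rc in group_pairs:
            mc, rc = sorted(mc), sorted(rc)
            if len(mc) <= len(rc):
                opts = [
                    dict(zip(mc, perm))
                    for perm in itertools.permutations(rc, len(mc))
                ]
            else:
                opts = [
                    dict(zip(perm, rc))
                    for perm in itertools.permutations(mc, len(rc))
                ]
            per_group.append(opts)
        for combo in itertools.product(*per_group):
            assignment = {}
            for d in combo:
                assignment.update(d)
            cand = _build_mapping(model, reference, assignment, aligner,
                                  model_contacts, ref_contacts)
            if best is None or cand.shared_contacts > best.shared_contacts or (
                cand.shared_contacts == best.shared_contacts
                and sorted(cand.chain_pairs.items()) < sorted(best.chain_pairs.items())
            ):
                best = cand
        return best
    return _greedy_assignment(model, reference, group_pairs, aligner,
                              model_contacts, ref_contacts)
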