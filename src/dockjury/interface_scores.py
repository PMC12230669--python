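"""Interface-centric comparison scores between a model and a reference.

Covers the fraction of native contacts (fnat), the DockQ composite and
its assembly-wide contact-weighted aggregate (DockQ-wave), the weighted
quaternary-structure contact score (QS-global / QS-best), the interface
contact similarity F1 (ICS), an analytic contact-area-difference proxy
(CAD), and per-residue PatchQS / PatchDockQ tracks evaluated on local
neighborhoods around each model interface residue.

Conventions (exposed as module constants):

* generic contacts — 5 A minimal heavy-atom distance, inter-chain;
* DockQ — interface residues from a 10 A backbone-atom criterion,
  iRMSD scale 1.5 A, LRMSD scale 8.5 A:
      DockQ = (fnat + 1/(1+(iRMSD/1.5)^2) + 1/(1+(LRMSD/8.5)^2)) / 3
* QS weights on CB atoms (CA for glycine):
      w(d) = 1                          for d <= 5 A
           = exp(-(d-5)^2 / (2*4.28^2)) for 5 < d <= 12 A
           = 0                          beyond.

The CAD score here is an analytic overlap proxy, not a Voronoi
tessellation: the contact area between residues i and j is approximated
as the sum over their heavy-atom pairs of max(0, r_i + r_j + 1.4 - d)
with Bondi-style van der Waals radii and a 1.4 A water probe.  Output
metadata flags it as "cad-proxy".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .assembly import ChainMapping, interchain_contacts
from .errors import DegenerateInputError
from .global_scores import kabsch
from .structure import BACKBONE_ATOMS, LocalScoreTrack, ResidueKey, Structure

CONTACT_THRESHOLD = 5.0
DOCKQ_INTERFACE_THRESHOLD = 10.0
DOCKQ_IRMSD_SCALE = 1.5
DOCKQ_LRMSD_SCALE = 8.5
QS_CONTACT = 5.0
QS_MAX = 12.0
QS_SIGMA = 4.28
CAD_PROBE = 1.4
PATCH_SIZE = 20

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90}


@dataclass
class InterfaceScore:
    name: str
    value: float | None
    breakdown: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# coordinate helpers


def residue_heavy_coords(s: Structure) -> dict[ResidueKey, np.ndarray]:
    out = {}
    for chain in s.chains:
        for res in chain.residues:
            out[(chain.chain_id, res.res_seq, res.ins_code)] = np.array(
                [(a.x, a.y, a.z) for a in res.atoms.values()], dtype=float
            )
    return out


def residue_cb_coords(s: Structure) -> dict[ResidueKey, np.ndarray]:
    """CB coordinate per residue, CA for glycine / CB-less residues."""
    out = {}
    for chain in s.chains:
        for res in chain.residues:
            atom = res.atoms.get("CB") or res.atoms.get("CA")
            if atom is None:
                atom = next(iter(res.atoms.values()))
            out[(chain.chain_id, res.res_seq, res.ins_code)] = np.array(
                (atom.x, atom.y, atom.z)
            )
    return out


def _min_heavy_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(cdist(a, b).min())


def _backbone_pairs(model, reference, mapping, ref_keys):
    """Matched backbone coordinates (model, reference) for given ref residues."""
    rev = mapping.reverse_residue_pairs
    P, Q = [], []
    for rk in ref_keys:
        mk = rev.get(rk)
        if mk is None:
            continue
        mres = model.residue(mk)
        rres = reference.residue(rk)
        if mres is None or rres is None:
            continue
        for name in BACKBONE_ATOMS:
            am, ar = mres.atoms.get(name), rres.atoms.get(name)
            if am is not None and ar is not None:
                P.append((am.x, am.y, am.z))
                Q.append((ar.x, ar.y, ar.z))
    return np.asarray(P, dtype=float), np.asarray(Q, dtype=float)


# ---------------------------------------------------------------------------
# fnat


def _reproduced_contacts(model, reference, mapping, ref_contacts):
    """For each reference contact, is it present in the model under the mapping?"""
    rev = mapping.reverse_residue_pairs
    model_heavy = residue_heavy_coords(model)
    out = {}
    for pair in ref_contacts.pairs:
        ra, rb = pair
        ma, mb = rev.get(ra), rev.get(rb)
        if ma is None or mb is None or ma not in model_heavy or mb not in model_heavy:
            out[pair] = False
            continue
        out[pair] = (
            _min_heavy_distance(model_heavy[ma], model_heavy[mb])
            <= ref_contacts.threshold
        )
    return out


def fnat(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
    chain_pair: tuple[str, str] | None = None,
) -> InterfaceScore:
    """Fraction of reference inter-chain contacts reproduced by the model.

    ``chain_pair`` (reference chain ids) restricts to a single interface.
    """
    ref_contacts = interchain_contacts(reference, CONTACT_THRESHOLD)
    pairs = ref_contacts.pairs
    if chain_pair is not None:
        want = frozenset(chain_pair)
        pairs = {p for p in pairs if frozenset((p[0][0], p[1][0])) == want}
    if not pairs:
        return InterfaceScore("fnat", None, {"n_reference_contacts": 0})
    ref_contacts.pairs = pairs
    reproduced = _reproduced_contacts(model, reference, mapping, ref_contacts)
    value = sum(reproduced.values()) / len(pairs)
    return InterfaceScore(
        "fnat", float(value), {"n_reference_contacts": len(pairs)}
    )


# ---------------------------------------------------------------------------
# DockQ


def dockq_from_terms(fnat_value: float, irmsd: float, lrmsd: float) -> float:
    """DockQ composite from its three ingredients."""
    return (
        fnat_value
        + 1.0 / (1.0 + (irmsd / DOCKQ_IRMSD_SCALE) ** 2)
        + 1.0 / (1.0 + (lrmsd / DOCKQ_LRMSD_SCALE) ** 2)
    ) / 3.0


def _interface_residues(reference: Structure, chain_pair) -> list[ResidueKey]:
    """Reference residues of the pair within 10 A backbone-atom contact."""
    c1, c2 = chain_pair

    def backbone_table(cid):
        coords, keys = [], []
        chain = reference.chain(cid)
        for res in chain.residues:
            for name in BACKBONE_ATOMS:
                a = res.atoms.get(name)
                if a is not None:
                    coords.append((a.x, a.y, a.z))
                    keys.append((cid, res.res_seq, res.ins_code))
        return np.asarray(coords, dtype=float), keys

    xyz1, keys1 = backbone_table(c1)
    xyz2, keys2 = backbone_table(c2)
    if len(xyz1) == 0 or len(xyz2) == 0:
        return []
    D = cdist(xyz1, xyz2)
    mask = D <= DOCKQ_INTERFACE_THRESHOLD
    out = []
    for i in np.flatnonzero(mask.any(axis=1)):
        if keys1[i] not in out:
            out.append(keys1[i])
    for j in np.flatnonzero(mask.any(axis=0)):
        if keys2[j] not in out:
            out.append(keys2[j])
    return out


def dockq(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
    chain_pair: tuple[str, str],
) -> InterfaceScore:
    """DockQ for one reference chain-pair interface."""
    fn = fnat(model, reference, mapping, chain_pair)
    if fn.value is None:
        return InterfaceScore("DockQ", None, {"chain_pair": chain_pair})

    iface = _interface_residues(reference, chain_pair)
    P, Q = _backbone_pairs(model, reference, mapping, iface)
    if len(P) < 3:
        return InterfaceScore("DockQ", None, {"chain_pair": chain_pair})
    irmsd = kabsch(P, Q).rmsd

    c1, c2 = chain_pair
    n1 = len(reference.chain(c1).residues)
    n2 = len(reference.chain(c2).residues)
    receptor, ligand = (c1, c2) if n1 >= n2 else (c2, c1)

    def chain_keys(cid):
        return [
            (cid, r.res_seq, r.ins_code) for r in reference.chain(cid).residues
        ]

    RP, RQ = _backbone_pairs(model, reference, mapping, chain_keys(receptor))
    LP, LQ = _backbone_pairs(model, reference, mapping, chain_keys(ligand))
    if len(RP) < 3 or len(LP) == 0:
        return InterfaceScore("DockQ", None, {"chain_pair": chain_pair})
    sup = kabsch(RP, RQ)
    lrmsd = float(np.sqrt(((sup.apply(LP) - LQ) ** 2).sum() / len(LP)))

    value = dockq_from_terms(fn.value, irmsd, lrmsd)
    return InterfaceScore(
        "DockQ",
        value,
        {
            "chain_pair": chain_pair,
            "fnat": fn.value,
            "iRMSD": irmsd,
            "LRMSD": lrmsd,
        },
    )


def reference_interfaces(reference: Structure) -> dict[tuple[str, str], int]:
    """Reference chain pairs with >=1 generic contact, with contact counts."""
    contacts = interchain_contacts(reference, CONTACT_THRESHOLD)
    counts: dict[tuple[str, str], int] = {}
    for (ka, kb) in contacts.pairs:
        pair = tuple(sorted((ka[0], kb[0])))
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def dockq_wave(
    model: Structure, reference: Structure, mapping: ChainMapping
) -> InterfaceScore:
    """Contact-count-weighted mean of per-interface DockQ values."""
    counts = reference_interfaces(reference)
    if not counts:
        return InterfaceScore("DockQ-wave", None, {})
    breakdown = {}
    num = den = 0.0
    for pair in sorted(counts):
        score = dockq(model, reference, mapping, pair)
        if score.value is None:
            continue
        w = counts[pair]
        breakdown[pair] = {"DockQ": score.value, "weight": w}
        num += w * score.value
        den += w
    if den == 0:
        return InterfaceScore("DockQ-wave", None, breakdown)
    return InterfaceScore("DockQ-wave", num / den, breakdown)


# ---------------------------------------------------------------------------
# QS-score


def qs_weight(d: np.ndarray) -> np.ndarray:
    w = np.exp(-((d - QS_CONTACT) ** 2) / (2.0 * QS_SIGMA**2))
    w = np.where(d <= QS_CONTACT, 1.0, w)
    return np.where(d <= QS_MAX, w, 0.0)


def _interchain_cb_weights(s: Structure) -> dict[tuple, float]:
    """w(d) per inter-chain residue pair (keys of this structure), d<=12 A."""
    cb = residue_cb_coords(s)
    keys = list(cb)
    xyz = np.array([cb[k] for k in keys])
    out: dict[tuple, float] = {}
    if len(keys) < 2:
        return out
    tree = cKDTree(xyz)
    for i, j in tree.query_pairs(QS_MAX):
        ki, kj = keys[i], keys[j]
        if ki[0] == kj[0]:
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        out[tuple(sorted((ki, kj)))] = float(qs_weight(np.array(d)))
    return out


def _qs_weight_maps(model, reference, mapping):
    """Model and reference pair weights, both keyed on model residue pairs."""
    w_model = _interchain_cb_weights(model)
    w_ref_refkeys = _interchain_cb_weights(reference)
    rev = mapping.reverse_residue_pairs
    w_ref = {}
    for (ra, rb), w in w_ref_refkeys.items():
        ma, mb = rev.get(ra), rev.get(rb)
        if ma is None or mb is None:
            continue
        w_ref[tuple(sorted((ma, mb)))] = w
    return w_model, w_ref


def qs_score(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
    pair_filter=None,
) -> InterfaceScore:
    """Weighted shared-contact conservation (QS-global and QS-best).

    ``pair_filter(key_a, key_b)`` optionally restricts the residue pairs
    considered (used by the patch scores); keys are model residue keys.
    """
    w_model, w_ref = _qs_weight_maps(model, reference, mapping)
    union = set(w_model) | set(w_ref)
    if pair_filter is not None:
        union = {p for p in union if pair_filter(p[0], p[1])}
    if not union:
        return InterfaceScore("QS", None, {})

    # chain pairs interfacing in both structures (model chain labels)
    chains_model = {frozenset((a[0], b[0])) for a, b in w_model}
    chains_ref = {frozenset((a[0], b[0])) for a, b in w_ref}
    both = chains_model & chains_ref

    num_g = den_g = num_b = den_b = 0.0
    for p in union:
        wm = w_model.get(p, 0.0)
        wr = w_ref.get(p, 0.0)
        num_g += min(wm, wr)
        den_g += max(wm, wr)
        if frozenset((p[0][0], p[1][0])) in both:
            num_b += min(wm, wr)
            den_b += max(wm, wr)
    qs_global = num_g / den_g if den_g > 0 else None
    qs_best = num_b / den_b if den_b > 0 else qs_global
    return InterfaceScore(
        "QS",
        qs_global,
        {"QSglobal": qs_global, "QSbest": qs_best,
         "n_pairs": len(union)},
    )


# ---------------------------------------------------------------------------
# ICS


def ics(
    model: Structure, reference: Structure, mapping: ChainMapping
) -> InterfaceScore:
    """F1 of model vs reference inter-chain contact sets."""
    ref_contacts = interchain_contacts(reference, CONTACT_THRESHOLD)
    model_contacts = interchain_contacts(model, CONTACT_THRESHOLD)
    if not ref_contacts.pairs and not model_contacts.pairs:
        return InterfaceScore("ICS", None, {})
    fwd = mapping.residue_pairs
    model_as_ref = set()
    for a, b in model_contacts.pairs:
        ra, rb = fwd.get(a), fwd.get(b)
        if ra is not None and rb is not None:
            model_as_ref.add(tuple(sorted((ra, rb))))
    shared = model_as_ref & ref_contacts.pairs
    n_model = len(model_contacts.pairs)
    n_ref = len(ref_contacts.pairs)
    precision = len(shared) / n_model if n_model else 0.0
    recall = len(shared) / n_ref if n_ref else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return InterfaceScore(
        "ICS", f1, {"precision": precision, "recall": recall,
                    "shared": len(shared)}
    )


# ---------------------------------------------------------------------------
# CAD proxy


def _residue_contact_areas(s: Structure, restrict_keys=None) -> dict[tuple, float]:
    """Approximate contact areas A(i,j) between distinct residues.

    A(i,j) = sum over heavy-atom pairs of max(0, r_i + r_j + probe - d).
    Pairs of residues in the same or different chains both count.
    """
    coords, keys, radii = [], [], []
    for chain in s.chains:
        for res in chain.residues:
            key = (chain.chain_id, res.res_seq, res.ins_code)
            if restrict_keys is not None and key not in restrict_keys:
                continue
            for a in res.atoms.values():
                coords.append((a.x, a.y, a.z))
                keys.append(key)
                radii.append(VDW_RADII.get(a.element.upper(), 1.70))
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    areas: dict[tuple, float] = {}
    if len(coords) < 2:
        return areas
    max_reach = 2 * max(VDW_RADII.values()) + CAD_PROBE
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(max_reach):
        ki, kj = keys[i], keys[j]
        if ki == kj:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        overlap = radii[i] + radii[j] + CAD_PROBE - d
        if overlap > 0:
            p = tuple(sorted((ki, kj)))
            areas[p] = areas.get(p, 0.0) + overlap
    return areas


def cad_score(
    model: Structure, reference: Structure, mapping: ChainMapping
) -> tuple[InterfaceScore, LocalScoreTrack]:
    """Contact-area-difference agreement (analytic proxy) with local track.

    CAD = 1 - min(1, sum|A_ref - A_model| / sum A_ref) over residue pairs
    with A_ref > 0; the local score restricts the sums to pairs touching
    each residue.  Keys of the local track are model residues.
    """
    areas_ref = _residue_contact_areas(reference)
    rev = mapping.reverse_residue_pairs
    fwd = mapping.residue_pairs
    areas_model_raw = _residue_contact_areas(model)
    # express model areas in reference keys
    areas_model = {}
    for (ma, mb), area in areas_model_raw.items():
        ra, rb = fwd.get(ma), fwd.get(mb)
        if ra is not None and rb is not None:
            areas_model[tuple(sorted((ra, rb)))] = area

    track = LocalScoreTrack()
    if not areas_ref:
        return InterfaceScore("CAD", None, {"flavor": "cad-proxy"}), track

    total_ref = sum(areas_ref.values())
    total_diff = sum(
        abs(a - areas_model.get(p, 0.0)) for p, a in areas_ref.items()
    )
    global_value = 1.0 - min(1.0, total_diff / total_ref)

    per_res_ref: dict = {}
    per_res_diff: dict = {}
    for p, a in areas_ref.items():
        diff = abs(a - areas_model.get(p, 0.0))
        for rk in p:
            per_res_ref[rk] = per_res_ref.get(rk, 0.0) + a
            per_res_diff[rk] = per_res_diff.get(rk, 0.0) + diff
    for mk in model.residue_keys():
        rk = fwd.get(mk)
        if rk is None or rk not in per_res_ref:
            track[mk] = None
        else:
            track[mk] = 1.0 - min(1.0, per_res_diff[rk] / per_res_ref[rk])
    return (
        InterfaceScore("CAD", global_value, {"flavor": "cad-proxy"}),
        track,
    )


# ---------------------------------------------------------------------------
# Patch scores


def _patch_members(center, cb_coords, patch_size):
    keys = list(cb_coords)
    xyz = np.array([cb_coords[k] for k in keys])
    c = cb_coords[center]
    d = np.linalg.norm(xyz - c, axis=1)
    order = sorted(range(len(keys)), key=lambda i: (d[i], keys[i]))
    members = []
    for i in order:
        members.append(keys[i])
        if len(members) >= patch_size:
            break
    if center not in members:
        members[-1] = center
    return set(members)


def patch_scores(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
    patch_size: int = PATCH_SIZE,
) -> tuple[LocalScoreTrack, LocalScoreTrack]:
    """Per-residue PatchQS and PatchDockQ tracks on model interface residues.

    A patch is the residue plus its ``patch_size - 1`` nearest residues
    by CB distance in the model (any chain).  PatchQS restricts the QS
    computation to residue pairs inside the patch; PatchDockQ combines
    the patch-restricted fnat with scaled patch backbone RMSDs in the
    DockQ functional form.  Residues not at a model interface are
    UNSCORED.
    """
    model_contacts = interchain_contacts(model, CONTACT_THRESHOLD)
    interface_residues = sorted({k for pair in model_contacts.pairs for k in pair})
    track_qs = LocalScoreTrack()
    track_dq = LocalScoreTrack()
    all_keys = model.residue_keys()
    for mk in all_keys:
        track_qs[mk] = None
        track_dq[mk] = None
    if not interface_residues:
        return track_qs, track_dq

    cb = residue_cb_coords(model)
    fwd = mapping.residue_pairs
    rev = mapping.reverse_residue_pairs
    ref_contacts = interchain_contacts(reference, CONTACT_THRESHOLD)
    reproduced = _reproduced_contacts(model, reference, mapping, ref_contacts)
    # reference contacts expressed in model keys
    ref_contacts_model_keys = {}
    for pair, ok in reproduced.items():
        ma, mb = rev.get(pair[0]), rev.get(pair[1])
        if ma is not None and mb is not None:
            ref_contacts_model_keys[tuple(sorted((ma, mb)))] = ok

    for center in interface_residues:
        patch = _patch_members(center, cb, patch_size)

        qsv = qs_score(
            model, reference, mapping,
            pair_filter=lambda a, b: a in patch and b in patch,
        )
        track_qs[center] = qsv.breakdown.get("QSglobal")

        # patch fnat
        in_patch = [
            ok
            for (ma, mb), ok in ref_contacts_model_keys.items()
            if ma in patch and mb in patch
        ]
        fnat_p = sum(in_patch) / len(in_patch) if in_patch else None

        # patch backbone RMSDs
        patch_ref_keys = [fwd[k] for k in sorted(patch) if k in fwd]
        P, Q = _backbone_pairs(model, reference, mapping, patch_ref_keys)
        irmsd_p = None
        if len(P) >= 3:
            try:
                irmsd_p = kabsch(P, Q).rmsd
            except DegenerateInputError:
                irmsd_p = None

        lrmsd_p = None
        chains_in_patch: dict = {}
        for k in patch:
            chains_in_patch.setdefault(k[0], []).append(k)
        if len(chains_in_patch) >= 2 and irmsd_p is not None:
            major = max(
                sorted(chains_in_patch), key=lambda c: len(chains_in_patch[c])
            )
            major_ref = [fwd[k] for k in sorted(chains_in_patch[major]) if k in fwd]
            minor_keys = [
                k for c, ks in chains_in_patch.items() if c != major for k in ks
            ]
            minor_ref = [fwd[k] for k in sorted(minor_keys) if k in fwd]
            MP, MQ = _backbone_pairs(model, reference, mapping, major_ref)
            NP, NQ = _backbone_pairs(model, reference, mapping, minor_ref)
            if len(MP) >= 3 and len(NP) > 0:
                try:
                    sup = kabsch(MP, MQ)
                    lrmsd_p = float(
                        np.sqrt(((sup.apply(NP) - NQ) ** 2).sum() / len(NP))
                    )
                except DegenerateInputError:
                    lrmsd_p = None
        if lrmsd_p is None:
            lrmsd_p = irmsd_p

        if fnat_p is None or irmsd_p is None:
            track_dq[center] = None
        else:
            track_dq[center] = dockq_from_terms(fnat_p, irmsd_p, lrmsd_p)
    return track_qs, track_dq
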