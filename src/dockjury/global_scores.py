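"""Whole-assembly similarity scores: RMSD, GDT_TS, TM-score and lDDT.

GDT_TS and the assembly TM-score use a deterministic fragment-seeded
superposition search: rigid fits are seeded from every contiguous
fragment of lengths {3, L/4, L/2, L} of the mapped CA trace (all chains
concatenated in chain order) and refined by iterative inclusion.  The
TM-score uses a single normalization length — the total number of mapped
residues — and the standard distance scale

    d0(L) = 1.24 * (L - 15)^(1/3) - 1.8   (clamped below at 0.5 A),

so one superposition and one d0 cover the whole assembly.

lDDT is superposition-free: every reference heavy-atom pair within the
inclusion radius (15 A, atoms in distinct residues, intra- and
inter-chain alike) is checked for preservation of its distance within
each threshold of {0.5, 1, 2, 4} A.  Atoms absent from the model count
as unpreserved.  Local scores are attributed to model residues through
the chain mapping so they can be written into B-factors and QMODE2
records directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .assembly import ChainMapping
from .errors import DegenerateInputError, MappingError
from .structure import LocalScoreTrack, Structure

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
LDDT_INCLUSION = 15.0
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation


@dataclass
class GlobalScore:
    name: str
    value: float
    length: int  # normalization length


def _axis_spread(X: np.ndarray) -> float:
    s = np.linalg.svd(X, compute_uv=False)
    return float(s[1] / max(s[0], 1e-12))


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of P onto Q (SVD, proper rotation)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateInputError("point sets must be matching Nx3 arrays")
    if len(P) < 3:
        raise DegenerateInputError("need at least 3 point pairs")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    Pm, Qm = P - Pc, Q - Qc
    H = Pm.T @ Qm
    U, S, Vt = np.linalg.svd(H)
    # a collinear/degenerate set leaves the cross-covariance rank-deficient
    scale = max(float(S[0]), 1e-12)
    if S[1] / scale < 1e-9 and (
        _axis_spread(Pm) < 1e-9 or _axis_spread(Qm) < 1e-9
    ):
        raise DegenerateInputError("collinear or degenerate point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return SuperpositionResult(R, t, rmsd)


def rmsd_after_superposition(P, Q) -> float:
    return kabsch(P, Q).rmsd


# ---------------------------------------------------------------------------
# mapped CA traces


def mapped_ca_coords(model: Structure, reference: Structure,
                     mapping: ChainMapping):
    """Paired CA coordinate arrays over mapped residues, chain order of model."""
    P, Q, keys = [], [], []
    for chain in model.chains:
        for res in chain.residues:
            mk = (chain.chain_id, res.res_seq, res.ins_code)
            rk = mapping.residue_pairs.get(mk)
            if rk is None:
                continue
            am = res.atoms.get("CA")
            rres = reference.residue(rk)
            ar = rres.atoms.get("CA") if rres is not None else None
            if am is None or ar is None:
                continue
            P.append((am.x, am.y, am.z))
            Q.append((ar.x, ar.y, ar.z))
            keys.append(mk)
    return np.asarray(P, dtype=float), np.asarray(Q, dtype=float), keys


def _fragment_seeds(L: int):
    lengths = sorted({3, max(3, L // 4), max(3, L // 2), L})
    for flen in lengths:
        stride = max(1, (L - flen + 1) // 12)
        for start in range(0, L - flen + 1, stride):
            yield start, flen


def _growth_sizes(L: int):
    if L <= 20:
        return list(range(3, L + 1))
    sizes, k = [], 3
    while k < L:
        sizes.append(k)
        k = max(k + 1, int(k * 1.5))
    sizes.append(L)
    return sizes


def superposition_scan(P, Q, d0: float | None = None):
    """Deterministic fragment-seeded superposition search.

    Rigid fits are seeded from contiguous fragments of lengths
    {3, L/4, L/2, L} and refined by k-nearest inclusion growth: after
    each fit, the k residues closest to their partners are refit for a
    ladder of sizes k, and the best fit by a soft TM-style guide score
    reseeds the next round.  Every visited fit is scored against all GDT
    cutoffs and the TM sum, so one scan serves both metrics.  Problems
    of at most 8 residues are searched exhaustively over every residue
    subset.  Ties keep the first-found fit: the scan is reproducible.

    Returns (gdt_counts per cutoff, tm_best).
    """
    L = len(P)
    if d0 is None:
        d0 = tm_d0(L)
    gdt_best = {c: 0 for c in GDT_CUTOFFS}
    tm_best = 0.0

    def visit(sup):
        nonlocal tm_best
        d = np.linalg.norm(sup.apply(P) - Q, axis=1)
        for c in GDT_CUTOFFS:
            n = int(np.count_nonzero(d <= c))
            if n > gdt_best[c]:
                gdt_best[c] = n
        tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)
        if tm > tm_best:
            tm_best = tm
        return tm, d

    if L <= 8:
        import itertools

        for r in range(3, L + 1):
            for subset in itertools.combinations(range(L), r):
                idx = np.asarray(subset)
                try:
                    visit(kabsch(P[idx], Q[idx]))
                except DegenerateInputError:
                    continue
        return gdt_best, tm_best

    sizes = _growth_sizes(L)
    for start, flen in _fragment_seeds(L):
        try:
            sup = kabsch(P[start : start + flen], Q[start : start + flen])
        except DegenerateInputError:
            continue
        _, d = visit(sup)
        for _ in range(2):
            order = np.argsort(d, kind="stable")
            round_best, round_d = -np.inf, None
            for k in sizes:
                idx = np.sort(order[:k])
                try:
                    cand = kabsch(P[idx], Q[idx])
                except DegenerateInputError:
                    continue
                guide, cand_d = visit(cand)
                if guide > round_best:
                    round_best, round_d = guide, cand_d
            if round_d is None:
                break
            d = round_d
    return gdt_best, tm_best


def gdt_ts(model: Structure, reference: Structure,
           mapping: ChainMapping) -> GlobalScore:
    """Mean over {1,2,4,8} A cutoffs of the max superposable CA fraction."""
    P, Q, _ = mapped_ca_coords(model, reference, mapping)
    L = len(P)
    if L < 3:
        raise MappingError("need at least 3 mapped CA pairs for GDT_TS")
    gdt_best, _ = superposition_scan(P, Q)
    return GlobalScore(
        "GDT_TS", float(np.mean([gdt_best[c] / L for c in GDT_CUTOFFS])), L
    )


def tm_d0(L: int) -> float:
    """Standard TM-score distance scale, clamped below at 0.5 A."""
    if L < 16:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def tm_score(model: Structure, reference: Structure,
             mapping: ChainMapping) -> GlobalScore:
    """Assembly TM-score: one superposition, one d0 from total mapped length."""
    P, Q, _ = mapped_ca_coords(model, reference, mapping)
    L = len(P)
    if L < 3:
        raise MappingError("need at least 3 mapped CA pairs for TM-score")
    _, tm_best = superposition_scan(P, Q)
    return GlobalScore("TM", tm_best, L)


# ---------------------------------------------------------------------------
# lDDT


def _mapped_atom_tables(model: Structure, reference: Structure,
                        mapping: ChainMapping):
    """Reference heavy atoms of mapped residues with model counterparts.

    Returns (ref_coords, model_coords-with-NaN, residue index array,
    model residue keys).  A NaN row marks an atom missing from the model.
    """
    rev = mapping.reverse_residue_pairs
    ref_xyz, mod_xyz, res_idx = [], [], []
    model_keys: list = []
    key_index: dict = {}
    for chain in reference.chains:
        for res in chain.residues:
            rk = (chain.chain_id, res.res_seq, res.ins_code)
            mk = rev.get(rk)
            if mk is None:
                continue
            if mk not in key_index:
                key_index[mk] = len(model_keys)
                model_keys.append(mk)
            ridx = key_index[mk]
            mres = model.residue(mk)
            for name, atom in res.atoms.items():
                ref_xyz.append((atom.x, atom.y, atom.z))
                res_idx.append(ridx)
                matom = mres.atoms.get(name) if mres is not None else None
                if matom is None:
                    mod_xyz.append((np.nan, np.nan, np.nan))
                else:
                    mod_xyz.append((matom.x, matom.y, matom.z))
    return (
        np.asarray(ref_xyz, dtype=float),
        np.asarray(mod_xyz, dtype=float),
        np.asarray(res_idx, dtype=int),
        model_keys,
    )


def lddt(
    model: Structure,
    reference: Structure,
    mapping: ChainMapping,
    inclusion: float = LDDT_INCLUSION,
    thresholds: tuple = LDDT_THRESHOLDS,
) -> tuple[GlobalScore, LocalScoreTrack]:
    """Superposition-free local distance difference test, heavy atoms only.

    The pair list comes from the reference: all heavy-atom pairs within
    the inclusion radius whose atoms lie in distinct (mapped) residues.
    A pair is preserved at threshold t when the model reproduces its
    distance within t; model-absent atoms are unpreserved at every
    threshold.  Local scores are keyed by model residues.
    """
    ref_xyz, mod_xyz, res_idx, model_keys = _mapped_atom_tables(
        model, reference, mapping
    )
    track = LocalScoreTrack()
    if len(ref_xyz) == 0:
        return GlobalScore("lDDT", None, 0), track

    tree = cKDTree(ref_xyz)
    raw_pairs = tree.query_pairs(inclusion, output_type="ndarray")
    if len(raw_pairs):
        distinct = res_idx[raw_pairs[:, 0]] != res_idx[raw_pairs[:, 1]]
        pairs = raw_pairs[distinct]
    else:
        pairs = raw_pairs
    n_res = len(model_keys)
    if len(pairs) == 0:
        for mk in model_keys:
            track[mk] = None
        return GlobalScore("lDDT", None, n_res), track

    dr = np.linalg.norm(ref_xyz[pairs[:, 0]] - ref_xyz[pairs[:, 1]], axis=1)
    dm = np.linalg.norm(mod_xyz[pairs[:, 0]] - mod_xyz[pairs[:, 1]], axis=1)
    delta = np.abs(dm - dr)  # NaN when a model atom is missing

    thr = np.asarray(thresholds, dtype=float)
    # preserved[p, t]; NaN comparisons are False, so missing atoms fail all t
    with np.errstate(invalid="ignore"):
        preserved = delta[:, None] <= thr[None, :]

    global_score = float(preserved.mean())

    pres_per_pair = preserved.sum(axis=1).astype(float)
    total_per_res = np.zeros(n_res)
    pres_per_res = np.zeros(n_res)
    for col in (0, 1):
        np.add.at(total_per_res, res_idx[pairs[:, col]], len(thr))
        np.add.at(pres_per_res, res_idx[pairs[:, col]], pres_per_pair)
    for i, mk in enumerate(model_keys):
        if total_per_res[i] == 0:
            track[mk] = None
        else:
            track[mk] = float(pres_per_res[i] / total_per_res[i])
    return GlobalScore("lDDT", global_score, n_res), track
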