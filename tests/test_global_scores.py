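"""Superposition, GDT_TS, TM-score and lDDT against independent oracles."""

import itertools

import numpy as np
import pytest

from dockjury.errors import DegenerateInputError
from dockjury.global_scores import (
    gdt_ts,
    kabsch,
    lddt,
    mapped_ca_coords,
    tm_d0,
    tm_score,
)

from conftest import (
    ca_chain,
    random_rigid_transform,
    structure_from_ca,
    transform_structure,
)


def quaternion_superposition_rmsd(P, Q):
    """Independent oracle: quaternion characteristic-matrix method.

    Largest eigenvalue of the 4x4 key matrix gives the maximal correlation;
    rmsd^2 = (G_P + G_Q - 2*lambda_max) / N.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    M = Pc.T @ Qc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((Pc**2).sum() + (Qc**2).sum() - 2 * lam) / len(P)
    return float(np.sqrt(max(msd, 0.0)))


class TestKabsch:
    def test_pure_translation_zero_rmsd(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        res = kabsch(P, P + np.array([1.0, 0, 0]))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_rotation_90deg_zero_rmsd(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 2]], float)
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        res = kabsch(P, P @ R.T)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_matches_quaternion_oracle(self):
        P = np.array([[0, 0, 0], [2, 0, 0], [0, 3, 0], [1, 1, 4]], float)
        Q = P.copy()
        Q[3] += np.array([1.5, -0.5, 0.7])
        assert kabsch(P, Q).rmsd == pytest.approx(
            quaternion_superposition_rmsd(P, Q), abs=1e-9
        )

    def test_random_inputs_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            P = rng.normal(size=(7, 3)) * 5
            Q = rng.normal(size=(7, 3)) * 5
            assert kabsch(P, Q).rmsd == pytest.approx(
                quaternion_superposition_rmsd(P, Q), abs=1e-9
            )

    def test_reflection_not_allowed(self):
        # mirrored set must not reach rmsd 0 via an improper rotation
        P = np.array([[0, 0, 0], [2, 0, 0], [0, 3, 0], [1, 1, 4]], float)
        Q = P * np.array([1, 1, -1])
        res = kabsch(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)
        assert res.rmsd > 0.5

    @pytest.mark.parametrize(
        "P", [np.zeros((2, 3)), np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                                         float)]
    )
    def test_degenerate_inputs(self, P):
        with pytest.raises(DegenerateInputError):
            kabsch(P, P + 1.0)


def brute_force_best_superposition(P, Q, score_of_distances):
    """Score max over superpositions seeded on every residue subset >=3."""
    n = len(P)
    best = -np.inf
    for r in range(3, n + 1):
        for subset in itertools.combinations(range(n), r):
            idx = np.asarray(subset)
            try:
                sup = kabsch(P[idx], Q[idx])
            except DegenerateInputError:
                continue
            d = np.linalg.norm(sup.apply(P) - Q, axis=1)
            best = max(best, score_of_distances(d))
    return best


class TestGDT:
    def test_identity(self, a2_reference, identity_mapping):
        m = identity_mapping(a2_reference)
        assert gdt_ts(a2_reference, a2_reference, m).value == 1.0

    def test_rigid_motion_invariance(self, a2_reference, identity_mapping):
        rng = np.random.default_rng(0)
        moved = transform_structure(a2_reference, *random_rigid_transform(rng))
        m = identity_mapping(a2_reference)
        assert gdt_ts(moved, a2_reference, m).value == pytest.approx(1.0, abs=1e-9)

    def test_half_displaced_toy(self, identity_mapping):
        # 4 residues exact; 4 displaced far enough (25 A) that no compromise
        # fit can cover any of them within the largest (8 A) cutoff
        good = [(0.0, 0.0, 0.0), (3.8, 0.0, 0.0), (1.9, 3.3, 0.0),
                (1.9, 1.1, 3.1)]
        rest = [(7.6, 1.0, 0.5), (11.4, 0.0, 1.0), (9.5, 3.3, 1.5),
                (9.5, 1.1, 4.0)]
        ref = structure_from_ca("ref", ca_chain("A", good + rest))
        model = structure_from_ca(
            "mod", ca_chain("A", good + [(x, y + 25.0, z) for x, y, z in rest])
        )
        m = identity_mapping(ref)
        assert gdt_ts(model, ref, m).value == pytest.approx(0.5)

    def test_matches_brute_force_on_toys(self, identity_mapping):
        rng = np.random.default_rng(42)
        for _ in range(5):
            coords = rng.uniform(0, 15, size=(7, 3))
            noise = coords + rng.normal(scale=1.5, size=coords.shape)
            ref = structure_from_ca("ref", ca_chain("A", coords))
            model = structure_from_ca("mod", ca_chain("A", noise))
            m = identity_mapping(ref)
            got = gdt_ts(model, ref, m).value
            P, Q, _ = mapped_ca_coords(model, ref, m)
            fractions = [
                brute_force_best_superposition(
                    P, Q, lambda d, c=c: np.mean(d <= c)
                )
                for c in (1.0, 2.0, 4.0, 8.0)
            ]
            assert got == pytest.approx(np.mean(fractions), abs=1e-9)


class TestTM:
    def test_identity(self, a3_reference, identity_mapping):
        m = identity_mapping(a3_reference)
        assert tm_score(a3_reference, a3_reference, m).value == 1.0

    def test_d0_formula(self):
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-6)
        assert tm_d0(15) == 0.5  # clamped
        assert tm_d0(19) == 0.5  # formula below the clamp floor

    def test_all_atoms_at_d0_gives_half(self, identity_mapping):
        # ring of residues displaced radially by exactly d0 under the best fit
        n = 20
        d0 = tm_d0(n)
        angles = 2 * np.pi * np.arange(n) / n
        ref_xy = np.column_stack(
            [10 * np.cos(angles), 10 * np.sin(angles), np.zeros(n)]
        )
        model_xy = np.column_stack(
            [(10 + d0) * np.cos(angles), (10 + d0) * np.sin(angles), np.zeros(n)]
        )
        # radial expansion: optimal superposition is identity by symmetry,
        # each residue exactly d0 from its partner
        ref = structure_from_ca("ref", ca_chain("A", ref_xy))
        model = structure_from_ca("mod", ca_chain("A", model_xy))
        m = identity_mapping(ref)
        assert tm_score(model, ref, m).value == pytest.approx(0.5, abs=1e-3)

    def test_matches_brute_force_on_toys(self, identity_mapping):
        rng = np.random.default_rng(7)
        for _ in range(5):
            coords = rng.uniform(0, 15, size=(8, 3))
            noise = coords + rng.normal(scale=2.0, size=coords.shape)
            ref = structure_from_ca("ref", ca_chain("A", coords))
            model = structure_from_ca("mod", ca_chain("A", noise))
            m = identity_mapping(ref)
            got = tm_score(model, ref, m).value
            P, Q, _ = mapped_ca_coords(model, ref, m)
            d0 = tm_d0(len(P))
            oracle = brute_force_best_superposition(
                P, Q, lambda d: np.mean(1.0 / (1.0 + (d / d0) ** 2))
            )
            assert got == pytest.approx(oracle, abs=1e-9)


class TestLDDT:
    def test_identity_global_and_local(self, a2_reference, identity_mapping):
        m = identity_mapping(a2_reference)
        g, track = lddt(a2_reference, a2_reference, m)
        assert g.value == 1.0
        assert all(v == 1.0 for _, v in track.scored_items())

    def test_superposition_free(self, ca_line_trio, identity_mapping):
        model, ref = ca_line_trio
        rng = np.random.default_rng(1)
        moved = transform_structure(model, *random_rigid_transform(rng))
        m = identity_mapping(ref)
        assert lddt(moved, ref, m)[0].value == pytest.approx(
            lddt(model, ref, m)[0].value
        )

    def test_three_atom_line_hand_enumeration(self, ca_line_trio,
                                              identity_mapping):
        """3 pairs x 4 thresholds; displacement of atom 3 by 3 A.

        AB: delta 0 -> 4/4; BC: delta 3 -> 1/4; AC: delta 3 -> 1/4.
        Global 6/12 = 0.5; locals A 5/8, B 5/8, C 2/8.
        """
        model, ref = ca_line_trio
        m = identity_mapping(ref)
        g, track = lddt(model, ref, m)
        assert g.value == pytest.approx(0.5)
        assert track[("A", 1, " ")] == pytest.approx(0.625)
        assert track[("A", 2, " ")] == pytest.approx(0.625)
        assert track[("A", 3, " ")] == pytest.approx(0.25)

    def test_missing_model_atom_counts_unpreserved(self, ca_line_trio,
                                                   identity_mapping):
        model, ref = ca_line_trio
        model = model.copy()
        model.chains[0].residues[2].atoms.clear()
        model.chains[0].residues[2].atoms  # residue kept, atom gone
        m = identity_mapping(ref)
        g, track = lddt(model, ref, m)
        assert g.value == pytest.approx(4 / 12)
        assert track[("A", 3, " ")] == pytest.approx(0.0)

    def test_asymmetric_direction_pairs_from_reference(self, identity_mapping):
        # reference atoms within inclusion; model spreads them beyond 15 A
        ref = structure_from_ca("ref", ca_chain("A", [(0, 0, 0), (4, 0, 0),
                                                      (8, 0, 0)]))
        model = structure_from_ca("mod", ca_chain("A", [(0, 0, 0), (40, 0, 0),
                                                        (80, 0, 0)]))
        m = identity_mapping(ref)
        g_fwd, _ = lddt(model, ref, m)
        g_bwd, _ = lddt(ref, model, m)
        # forward: all reference pairs exist but none preserved
        assert g_fwd.value == pytest.approx(0.0)
        # backward: the model-as-reference has no pairs within 15 A
        assert g_bwd.value is None
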