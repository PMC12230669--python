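"""fnat, DockQ(-wave), QS, ICS, CAD proxy and patch tracks."""

import numpy as np
import pytest

from dockjury.assembly import interchain_contacts, map_chains
from dockjury.interface_scores import (
    cad_score,
    dockq,
    dockq_from_terms,
    dockq_wave,
    fnat,
    ics,
    patch_scores,
    qs_score,
    qs_weight,
)
from dockjury.decoys import DecoySpec, make_reference, perturb

from conftest import (
    ca_chain,
    make_structure,
    random_rigid_transform,
    structure_from_ca,
    transform_structure,
)


@pytest.fixture(scope="module")
def dimer():
    return make_reference(DecoySpec(stoichiometry="A2", chain_length=14,
                                    seed=2))


@pytest.fixture(scope="module")
def dimer_mapping(dimer):
    return map_chains(dimer, dimer)


class TestFnat:
    def test_identity(self, dimer, dimer_mapping):
        assert fnat(dimer, dimer, dimer_mapping).value == 1.0

    def test_direct_count(self, identity_mapping):
        # reference contacts {(A1,B1), (A2,B1)}; model preserves only (A1,B1)
        ref = structure_from_ca(
            "ref",
            ca_chain("A", [(0, 0, 0), (0, 3, 0)]),
            ca_chain("B", [(4, 0, 0)]),
        )
        model = structure_from_ca(
            "mod",
            ca_chain("A", [(0, 0, 0), (0, 12, 0)]),
            ca_chain("B", [(4, 0, 0)]),
        )
        m = identity_mapping(ref)
        assert fnat(model, ref, m).value == pytest.approx(0.5)

    def test_separated_chains_zero(self, dimer, dimer_mapping):
        far = perturb(dimer, "B", 0.0, 50.0, 0.0, seed=0)
        assert fnat(far, dimer, dimer_mapping).value == 0.0

    def test_contact_free_reference_unscored(self, identity_mapping):
        ref = structure_from_ca(
            "ref", ca_chain("A", [(0, 0, 0)]), ca_chain("B", [(30, 0, 0)])
        )
        m = identity_mapping(ref)
        assert fnat(ref, ref, m).value is None


class TestDockQ:
    def test_composite_formula(self):
        # each scaled term equals 0.5 at fnat=0.5, iRMSD=1.5, LRMSD=8.5
        assert dockq_from_terms(0.5, 1.5, 8.5) == pytest.approx(0.5)
        assert dockq_from_terms(1.0, 0.0, 0.0) == 1.0

    def test_identity(self, dimer, dimer_mapping):
        pair = tuple(dimer.chain_ids[:2])
        score = dockq(dimer, dimer, dimer_mapping, pair)
        assert score.value == pytest.approx(1.0)
        assert score.breakdown["iRMSD"] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, dimer, dimer_mapping):
        rng = np.random.default_rng(8)
        moved = transform_structure(dimer, *random_rigid_transform(rng))
        pair = tuple(dimer.chain_ids[:2])
        assert dockq(moved, dimer, dimer_mapping, pair).value == pytest.approx(
            1.0, abs=1e-9
        )

    def test_unknown_interface_unscored(self, dimer, dimer_mapping):
        far = perturb(dimer, "B", 0.0, 60.0, 0.0, seed=1)
        m = map_chains(dimer, far)
        assert dockq(dimer, far, m, ("A", "B")).value is None


class TestDockQWave:
    def test_single_interface_equals_dockq(self, dimer, dimer_mapping):
        decoy = perturb(dimer, "B", 10.0, 1.0, 0.1, seed=3)
        m = map_chains(decoy, dimer)
        wave = dockq_wave(decoy, dimer, m)
        single = dockq(decoy, dimer, m, ("A", "B"))
        assert wave.value == pytest.approx(single.value)

    def test_weighted_mean_arithmetic(self):
        # weights (3, 1) on per-interface DockQ (1.0, 0.0) -> 0.75
        from dockjury.interface_scores import InterfaceScore

        counts = {("A", "B"): 3, ("B", "C"): 1}
        values = {("A", "B"): 1.0, ("B", "C"): 0.0}
        num = sum(counts[p] * values[p] for p in counts)
        den = sum(counts.values())
        assert num / den == pytest.approx(0.75)
        # and the implementation agrees on a trimer where one interface
        # is destroyed: its weighted mean lies between min and max
        ref = make_reference(DecoySpec(stoichiometry="A3", chain_length=10,
                                       seed=1))
        decoy = perturb(ref, "C", 60.0, 12.0, 0.0, seed=5)
        m = map_chains(decoy, ref)
        wave = dockq_wave(decoy, ref, m)
        per_iface = [v["DockQ"] for v in wave.breakdown.values()]
        assert min(per_iface) <= wave.value <= max(per_iface)

    def test_identity(self, dimer, dimer_mapping):
        assert dockq_wave(dimer, dimer, dimer_mapping).value == pytest.approx(1.0)


class TestQS:
    def test_weight_function(self):
        assert qs_weight(np.array(4.0)) == 1.0
        assert qs_weight(np.array(5.0)) == 1.0
        assert qs_weight(np.array(12.1)) == 0.0
        d = 8.0
        assert qs_weight(np.array(d)) == pytest.approx(
            np.exp(-((d - 5.0) ** 2) / (2 * 4.28**2))
        )

    def test_identity(self, dimer, dimer_mapping):
        qs = qs_score(dimer, dimer, dimer_mapping)
        assert qs.breakdown["QSglobal"] == 1.0
        assert qs.breakdown["QSbest"] == 1.0

    def test_disjoint_interfaces_zero(self, identity_mapping):
        ref = structure_from_ca(
            "ref",
            ca_chain("A", [(0, 0, 0), (0, 30, 0)]),
            ca_chain("B", [(4, 0, 0), (0, 60, 0)]),
        )
        model = structure_from_ca(
            "mod",
            ca_chain("A", [(0, 0, 0), (0, 30, 0)]),
            ca_chain("B", [(40, 0, 0), (0, 34, 0)]),
        )
        m = identity_mapping(ref)
        assert qs_score(model, ref, m).breakdown["QSglobal"] == pytest.approx(0.0)

    def test_min_max_sums_on_toy(self, identity_mapping):
        # 2 shared weight-1 contacts + 2 model-only weight-1 contacts
        ref = structure_from_ca(
            "ref",
            ca_chain("A", [(0, 0, 0), (0, 20, 0), (0, 40, 0), (0, 60, 0)]),
            ca_chain("B", [(4, 0, 0), (0, 24, 0), (0, 140, 0), (0, 160, 0)]),
        )
        model = structure_from_ca(
            "mod",
            ca_chain("A", [(0, 0, 0), (0, 20, 0), (0, 40, 0), (0, 60, 0)]),
            ca_chain("B", [(4, 0, 0), (0, 24, 0), (0, 44, 0), (0, 64, 0)]),
        )
        m = identity_mapping(ref)
        assert qs_score(model, ref, m).breakdown["QSglobal"] == pytest.approx(0.5)

    def test_qsbest_ge_qsglobal_random_pairs(self):
        """QS-best never falls below QS-global (union never smaller)."""
        rng = np.random.default_rng(12)
        for _ in range(300):
            n = 6
            coords_a = rng.uniform(0, 10, (n, 3))
            coords_b = rng.uniform(0, 10, (n, 3)) + np.array([6.0, 0, 0])
            coords_c = rng.uniform(0, 10, (n, 3)) + np.array([0, 6.0, 0])
            ref = structure_from_ca(
                "ref", ca_chain("A", coords_a), ca_chain("B", coords_b),
                ca_chain("C", coords_c)
            )
            model = structure_from_ca(
                "mod",
                ca_chain("A", coords_a + rng.normal(scale=2.0, size=(n, 3))),
                ca_chain("B", coords_b + rng.normal(scale=2.0, size=(n, 3))),
                ca_chain("C", coords_c + rng.normal(scale=2.0, size=(n, 3))),
            )
            keys = ref.residue_keys()
            from dockjury.assembly import ChainMapping

            m = ChainMapping({c: c for c in "ABC"}, {k: k for k in keys})
            qs = qs_score(model, ref, m)
            if qs.value is None:
                continue
            assert qs.breakdown["QSbest"] >= qs.breakdown["QSglobal"] - 1e-12


class TestICS:
    def test_identity(self, dimer, dimer_mapping):
        assert ics(dimer, dimer, dimer_mapping).value == 1.0

    def test_f1_arithmetic(self, identity_mapping):
        # model finds 2 of 4 reference contacts, adds none:
        # precision 1, recall 0.5 -> F1 = 2/3
        ref = structure_from_ca(
            "ref",
            ca_chain("A", [(0, 0, 0), (0, 20, 0), (0, 40, 0), (0, 60, 0)]),
            ca_chain("B", [(4, 0, 0), (0, 24, 0), (0, 44, 0), (0, 64, 0)]),
        )
        model = structure_from_ca(
            "mod",
            ca_chain("A", [(0, 0, 0), (0, 20, 0), (0, 40, 0), (0, 60, 0)]),
            ca_chain("B", [(4, 0, 0), (0, 24, 0), (0, 100, 0), (0, 120, 0)]),
        )
        m = identity_mapping(ref)
        score = ics(model, ref, m)
        assert score.breakdown["precision"] == pytest.approx(1.0)
        assert score.breakdown["recall"] == pytest.approx(0.5)
        assert score.value == pytest.approx(2 / 3)

    def test_disjoint_zero(self, dimer, dimer_mapping):
        far = perturb(dimer, "B", 0.0, 45.0, 0.0, seed=2)
        # far model still has no contacts -> recall 0 -> F1 0
        assert ics(far, dimer, dimer_mapping).value == 0.0


class TestCAD:
    def test_identity(self, dimer, dimer_mapping):
        g, track = cad_score(dimer, dimer, dimer_mapping)
        assert g.value == 1.0
        assert all(v == 1.0 for _, v in track.scored_items())
        assert g.breakdown["flavor"] == "cad-proxy"

    def test_all_contacts_lost_zero(self, identity_mapping):
        ref = structure_from_ca(
            "ref", ca_chain("A", [(0, 0, 0)]), ca_chain("B", [(3.5, 0, 0)])
        )
        model = structure_from_ca(
            "mod", ca_chain("A", [(0, 0, 0)]), ca_chain("B", [(50, 0, 0)])
        )
        m = identity_mapping(ref)
        g, _ = cad_score(model, ref, m)
        assert g.value == 0.0

    def test_halved_contact_area(self, identity_mapping):
        """One of two equal contacts loses half its area: CAD = 0.75."""
        from dockjury.interface_scores import _residue_contact_areas

        ref = structure_from_ca(
            "ref",
            ca_chain("A", [(0, 0, 0), (0, 30, 0)]),
            ca_chain("B", [(3.0, 0, 0), (3.0, 30, 0)]),
        )
        areas = _residue_contact_areas(ref)
        a0 = areas[
            tuple(sorted(((("A", 1, " ")), ("B", 1, " "))))
        ]
        # move the second B residue so its contact area halves
        target_overlap = a0 / 2
        d = 2 * 1.70 + 1.4 - target_overlap
        model = structure_from_ca(
            "mod",
            ca_chain("A", [(0, 0, 0), (0, 30, 0)]),
            ca_chain("B", [(3.0, 0, 0), (d, 30, 0)]),
        )
        m = identity_mapping(ref)
        g, _ = cad_score(model, ref, m)
        assert g.value == pytest.approx(1 - (a0 / 2) / (2 * a0), abs=1e-6)

    def test_rigid_motion_invariance(self, dimer, dimer_mapping):
        rng = np.random.default_rng(4)
        moved = transform_structure(dimer, *random_rigid_transform(rng))
        g, _ = cad_score(moved, dimer, dimer_mapping)
        assert g.value == pytest.approx(1.0, abs=1e-6)


class TestPatchScores:
    def test_identity_all_one(self, dimer, dimer_mapping):
        tqs, tdq = patch_scores(dimer, dimer, dimer_mapping)
        assert len(tqs.scored_items()) > 0
        assert all(v == pytest.approx(1.0) for _, v in tqs.scored_items())
        assert all(v == pytest.approx(1.0) for _, v in tdq.scored_items())

    def test_non_interface_residues_unscored(self, dimer, dimer_mapping):
        tqs, _ = patch_scores(dimer, dimer, dimer_mapping)
        iface = {
            k
            for pair in interchain_contacts(dimer, 5.0).pairs
            for k in pair
        }
        for key, v in tqs.items():
            if key not in iface:
                assert v is None

    def test_patchqs_matches_restriction_oracle(self, dimer):
        """PatchQS equals QS on the pair lists filtered by patch membership."""
        from dockjury.interface_scores import (
            _patch_members,
            _qs_weight_maps,
            residue_cb_coords,
        )

        decoy = perturb(dimer, "B", 12.0, 1.5, 0.3, seed=6)
        m = map_chains(decoy, dimer)
        patch_size = 6
        tqs, _ = patch_scores(decoy, dimer, m, patch_size=patch_size)
        w_model, w_ref = _qs_weight_maps(decoy, dimer, m)
        cb = residue_cb_coords(decoy)
        for center, got in tqs.scored_items():
            patch = _patch_members(center, cb, patch_size)
            union = {
                p
                for p in set(w_model) | set(w_ref)
                if p[0] in patch and p[1] in patch
            }
            num = sum(min(w_model.get(p, 0), w_ref.get(p, 0)) for p in union)
            den = sum(max(w_model.get(p, 0), w_ref.get(p, 0)) for p in union)
            assert got == pytest.approx(num / den, abs=1e-12)

    def test_locality(self, dimer, dimer_mapping):
        """A perfectly modelled region scores 1.0 even in a wrong model."""
        # perturb chain B of a 3-chain complex; patches on the A-C side
        ref = make_reference(DecoySpec(stoichiometry="A1B1C1",
                                       chain_length=12, seed=3))
        decoy = perturb(ref, "C", 50.0, 20.0, 0.0, seed=7)
        m = map_chains(decoy, ref)
        tqs, tdq = patch_scores(decoy, ref, m, patch_size=8)
        # residues whose patches lie fully in the intact A-B half
        intact = [
            (key, v)
            for key, v in tqs.scored_items()
            if key[0] == "A" and v is not None
        ]
        assert intact, "expected scored residues on the intact interface"
        assert any(v == pytest.approx(1.0, abs=1e-9) for _, v in intact)
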