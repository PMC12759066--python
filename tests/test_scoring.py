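"""Contact detection, confidence filtering, canonical restriction and the
*average models* score.

The independent oracle for contact detection is an exhaustive loop over
all non-hydrogen atom pairs; the oracle for the score is per-contact
model counting done by hand over explicit membership maps.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afmetrics.fixtures import FixtureSpec, build_multimer, expected_average_models
from afmetrics.scoring import (
    average_models,
    detect_contacts,
    filter_contacts,
    interface_pae,
    restrict_canonical,
    score_target,
)
from afmetrics.types import (
    ConfidenceBundle,
    DomainRange,
    ResidueContact,
    ScoreConfig,
)

from conftest import make_two_chain_model, random_toy_model


def brute_force_contacts(model, chain_a, chain_b, cutoff=8.0):
    """All-pairs enumeration over non-hydrogen atoms, strict < cutoff."""
    pairs = set()
    for res_a in model.chain(chain_a).residues:
        for res_b in model.chain(chain_b).residues:
            hit = False
            for atom_a in res_a.atoms:
                if atom_a.is_hydrogen:
                    continue
                for atom_b in res_b.atoms:
                    if atom_b.is_hydrogen:
                        continue
                    d = math.dist(
                        (atom_a.x, atom_a.y, atom_a.z),
                        (atom_b.x, atom_b.y, atom_b.z),
                    )
                    if d < cutoff:
                        hit = True
            if hit:
                pairs.add((res_a.index, res_b.index))
    return pairs


def contact(ra, rb, pae_ab=5.0, pae_ba=5.0, plddt=90.0, dist=5.0):
    return ResidueContact(
        chain_a_res=("A", ra), chain_b_res=("B", rb),
        min_distance=dist, pae_ab=pae_ab, pae_ba=pae_ba, min_plddt=plddt,
    )


class TestDetectContacts:
    def test_residues_five_angstroms_apart_are_contacts(self):
        model = make_two_chain_model([(0, 0, 0)], [(0, 5.0, 0)])
        contacts = detect_contacts(model, ("A", "B"))
        assert {c.pair_id for c in contacts} == {(("A", 1), ("B", 1))}

    def test_exactly_eight_angstroms_is_not_a_contact(self):
        # strict inequality: atoms at exactly the cutoff distance miss
        model = make_two_chain_model([(0.7, 0, 0)], [(0.7, 0, 0)])
        # nearest heavy atoms: chain A "C" at x=1.4 vs chain B "N" at x=0;
        # rebuild so the minimal non-H distance is exactly 8.0
        from conftest import make_residue
        from afmetrics.types import ChainRecord, PredictedModel

        a = ChainRecord("A", [make_residue(1, (0, 0, 0), with_hydrogen=False)])
        b = ChainRecord("B", [make_residue(1, (9.4, 0, 0), with_hydrogen=False)])
        model = PredictedModel("m", [a, b])
        # A's rightmost heavy atom at x=0.7; B's leftmost at x=8.7 -> 8.0
        assert detect_contacts(model, ("A", "B")) == set()
        b2 = ChainRecord("B", [make_residue(1, (9.35, 0, 0), with_hydrogen=False)])
        model2 = PredictedModel("m2", [a, b2])
        assert len(detect_contacts(model2, ("A", "B"))) == 1

    def test_hydrogen_only_proximity_is_not_a_contact(self):
        from conftest import make_residue
        from afmetrics.types import Atom, ChainRecord, PredictedModel, Residue

        a = ChainRecord("A", [make_residue(1, (0, 0, 0), with_hydrogen=False)])
        # hydrogen 2 Å away, heavy atoms 20 Å away
        res_b = Residue(
            1, "ALA",
            [Atom("H1", "H", 2.0, 0, 0), Atom("CA", "C", 20.0, 0, 0)],
            90.0,
        )
        model = PredictedModel("m", [a, ChainRecord("B", [res_b])])
        assert detect_contacts(model, ("A", "B")) == set()

    def test_unknown_chain_errors(self):
        model = make_two_chain_model([(0, 0, 0)], [(0, 5, 0)])
        with pytest.raises(KeyError):
            detect_contacts(model, ("A", "Z"))

    def test_matches_brute_force_on_random_toys(self, rng):
        for _ in range(25):
            model = random_toy_model(rng, n_a=20, n_b=20, box=30.0)
            got = {
                (c.chain_a_res[1], c.chain_b_res[1])
                for c in detect_contacts(model, ("A", "B"))
            }
            assert got == brute_force_contacts(model, "A", "B")

    def test_min_distance_is_minimum_over_atom_pairs(self, rng):
        model = random_toy_model(rng, n_a=10, n_b=10, box=20.0)
        for c in detect_contacts(model, ("A", "B")):
            res_a = next(
                r for r in model.chain("A").residues
                if r.index == c.chain_a_res[1]
            )
            res_b = next(
                r for r in model.chain("B").residues
                if r.index == c.chain_b_res[1]
            )
            dists = [
                math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
                for a in res_a.atoms if not a.is_hydrogen
                for b in res_b.atoms if not b.is_hydrogen
            ]
            assert c.min_distance == pytest.approx(min(dists))


def toy_model_and_conf(plddt_a=90.0, plddt_b=90.0, pae=5.0, n=2):
    model = make_two_chain_model(
        [(i * 20.0, 0, 0) for i in range(n)],
        [(0, 5.0, 0)],
        plddt=plddt_a,
    )
    for res in model.chain("B").residues:
        res.plddt = plddt_b
    conf = ConfidenceBundle(pae=np.full((n + 1, n + 1), pae))
    return model, conf


class TestFilterContacts:
    def test_plddt_49_9_removed(self):
        model, conf = toy_model_and_conf(plddt_b=49.9)
        raw = detect_contacts(model, ("A", "B"))
        assert raw
        assert filter_contacts(raw, model, conf) == set()

    def test_plddt_exactly_50_kept(self):
        model, conf = toy_model_and_conf(plddt_b=50.0)
        raw = detect_contacts(model, ("A", "B"))
        assert len(filter_contacts(raw, model, conf)) == len(raw)

    def test_pae_16_removed_15_kept(self):
        model, conf = toy_model_and_conf(pae=16.0)
        raw = detect_contacts(model, ("A", "B"))
        assert filter_contacts(raw, model, conf) == set()
        model2, conf2 = toy_model_and_conf(pae=15.0)
        raw2 = detect_contacts(model2, ("A", "B"))
        assert len(filter_contacts(raw2, model2, conf2)) == len(raw2)

    def test_clean_confidences_leave_set_unchanged(self):
        model, conf = toy_model_and_conf(plddt_a=90.0, pae=5.0)
        raw = detect_contacts(model, ("A", "B"))
        filtered = filter_contacts(raw, model, conf)
        assert {c.pair_id for c in filtered} == {c.pair_id for c in raw}

    def test_pae_direction_combination_modes(self):
        model, _ = toy_model_and_conf()
        n = model.n_residues
        pae = np.zeros((n, n))
        ia = model.concat_index("A", 1)
        ib = model.concat_index("B", 1)
        pae[ia, ib], pae[ib, ia] = 12.0, 20.0  # mean 16 > 15; min 12 <= 15
        conf = ConfidenceBundle(pae=pae)
        raw = detect_contacts(model, ("A", "B"))
        assert filter_contacts(raw, model, conf, ScoreConfig()) == set()
        keep_min = ScoreConfig(pae_combine="min")
        assert len(filter_contacts(raw, model, conf, keep_min)) == 1
        drop_max = ScoreConfig(pae_combine="max")
        assert filter_contacts(raw, model, conf, drop_max) == set()

    def test_filter_monotone_in_thresholds(self, rng):
        spec = FixtureSpec(
            interface_pairs=[(2, 3), (5, 7), (8, 11)],
            plddt_decoy_pairs=[(12, 15)],
            pae_interface=10.0,
        )
        prediction = build_multimer(spec)
        model, conf = prediction.models[0]
        raw = detect_contacts(model, ("A", "B"))
        sizes = []
        for plddt_min in (30.0, 50.0, 95.0):
            cfg = ScoreConfig(plddt_min=plddt_min)
            sizes.append(len(filter_contacts(raw, model, conf, cfg)))
        assert sizes == sorted(sizes, reverse=True)
        sizes = []
        for pae_max in (20.0, 10.0, 5.0):
            cfg = ScoreConfig(pae_max=pae_max)
            sizes.append(len(filter_contacts(raw, model, conf, cfg)))
        assert sizes == sorted(sizes, reverse=True)


class TestRestrictCanonical:
    def test_contact_at_domain_residue_kept(self):
        domain = DomainRange("t", "ORC6_BD", 5, 10)
        kept = restrict_canonical([contact(7, 3)], domain, "A")
        assert len(kept) == 1

    def test_contact_outside_domain_removed(self):
        domain = DomainRange("t", "ORC6_BD", 5, 10)
        assert restrict_canonical([contact(2, 3)], domain, "A") == set()

    def test_absent_domain_empty_set(self):
        domain = DomainRange.make_absent("t", "ORC6_BD")
        assert restrict_canonical([contact(7, 3)], domain, "A") == set()


class TestAverageModels:
    def test_five_identical_nonempty_sets_score_one(self):
        sets = [{contact(1, 1), contact(2, 5)} for _ in range(5)]
        assert average_models(sets) == 1.0

    def test_five_empty_sets_score_zero(self):
        assert average_models([set() for _ in range(5)]) == 0.0

    def test_shared_plus_singleton_hand_value(self):
        # one contact in all 5 models, one in exactly 1: (5+1)/2/5 = 0.6
        sets = [{contact(1, 1)} for _ in range(5)]
        sets[2] = {contact(1, 1), contact(9, 9)}
        assert average_models(sets) == pytest.approx(0.6)

    def test_wrong_number_of_sets_errors(self):
        with pytest.raises(ValueError, match="expected 5"):
            average_models([set(), set()])

    @given(
        membership=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=12),
                st.sets(st.integers(min_value=0, max_value=4), min_size=1),
            ),
            max_size=10,
            unique_by=lambda t: t[0],
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_per_contact_counting_oracle(self, membership):
        """Score equals (sum of per-contact model counts) / (|U| * 5)."""
        sets = [set() for _ in range(5)]
        for residue, models in membership:
            for m in models:
                sets[m].add(contact(residue, residue))
        got = average_models(sets)
        if not membership:
            assert got == 0.0
        else:
            want = sum(len(m) for _, m in membership) / (len(membership) * 5)
            assert got == pytest.approx(want)
            assert 1 / 5 <= got <= 1.0

    def test_permutation_invariance(self, rng):
        sets = [
            {contact(int(r), int(r)) for r in rng.integers(1, 15, size=6)}
            for _ in range(5)
        ]
        base = average_models(sets)
        for perm in itertools.islice(itertools.permutations(range(5)), 10):
            assert average_models([sets[p] for p in perm]) == pytest.approx(base)

    def test_adding_shared_contact_never_decreases_score(self, rng):
        sets = [{contact(1, 1)} for _ in range(5)]
        sets[0].add(contact(3, 3))
        before = average_models(sets)
        richer = [s | {contact(7, 7)} for s in sets]
        assert average_models(richer) >= before

    def test_adding_singleton_dilutes_score(self):
        sets = [{contact(1, 1)} for _ in range(5)]
        before = average_models(sets)
        sets[0].add(contact(9, 9))
        assert average_models(sets) < before


class TestInterfacePae:
    def test_single_contact_mean_is_its_pae(self):
        sets = [set() for _ in range(5)]
        sets[0] = {contact(1, 1, pae_ab=3.0, pae_ba=3.0)}
        assert interface_pae(sets) == pytest.approx(3.0)

    def test_two_contacts_arithmetic_mean(self):
        sets = [set() for _ in range(5)]
        sets[0] = {contact(1, 1, pae_ab=4.0, pae_ba=4.0)}
        sets[1] = {contact(2, 2, pae_ab=8.0, pae_ba=8.0)}
        assert interface_pae(sets) == pytest.approx(6.0)

    def test_no_contacts_undefined(self):
        assert interface_pae([set() for _ in range(5)]) is None

    def test_instance_pooling_weights_recurring_pairs(self):
        # a pair present in all 5 models contributes 5 instances
        shared = contact(1, 1, pae_ab=2.0, pae_ba=2.0)
        single = contact(2, 2, pae_ab=8.0, pae_ba=8.0)
        sets = [{shared} for _ in range(5)]
        sets[0] = {shared, single}
        pooled = interface_pae(sets, ScoreConfig(pae_pool="instances"))
        assert pooled == pytest.approx((5 * 2.0 + 8.0) / 6)
        unique = interface_pae(sets, ScoreConfig(pae_pool="union"))
        assert unique == pytest.approx((2.0 + 8.0) / 2)


class TestScoreTarget:
    DOMAIN = DomainRange("t", "ORC6_BD", 1, 30)

    def test_shared_fixture_scores_one_and_confident(self, shared_spec):
        prediction = build_multimer(shared_spec)
        score = score_target(prediction, self.DOMAIN)
        assert score.average_models == 1.0
        assert score.confident and score.canonical
        assert score.n_contacts_per_model == [6] * 5
        assert score.n_union_contacts == 6
        assert score.interface_pae == pytest.approx(shared_spec.pae_interface)
        assert score.iptm_best == shared_spec.iptm

    def test_decoy_only_fixture_scores_zero(self):
        spec = FixtureSpec(
            interface_pairs=[],
            plddt_decoy_pairs=[(2, 3), (5, 7)],
            shared_fraction=1.0,
        )
        score = score_target(build_multimer(spec), self.DOMAIN)
        assert score.average_models == 0.0
        assert not score.confident
        assert not score.canonical
        assert score.interface_pae is None

    def test_disjoint_fixture_scores_point_two(self):
        spec = FixtureSpec(
            interface_pairs=[(2, 3), (5, 7), (8, 11), (12, 14), (15, 20)],
            shared_fraction=0.0,
        )
        score = score_target(build_multimer(spec), self.DOMAIN)
        assert score.average_models == pytest.approx(0.2)
        assert not score.confident
        assert score.canonical  # contacts exist, just inconsistent

    def test_decoys_never_change_the_filtered_score(self, shared_spec):
        clean = score_target(build_multimer(shared_spec), self.DOMAIN)
        spec = FixtureSpec(
            interface_pairs=shared_spec.interface_pairs,
            shared_fraction=1.0,
            seed=shared_spec.seed,
            plddt_decoy_pairs=[(25, 28), (28, 30)],
            target_id=shared_spec.target_id,
        )
        noisy_pred = build_multimer(spec)
        # decoys do add raw contacts...
        raw = detect_contacts(noisy_pred.models[0][0], ("A", "B"))
        assert len(raw) == len(shared_spec.interface_pairs) + 2
        # ...but the filtered score is bit-identical
        noisy = score_target(noisy_pred, self.DOMAIN)
        assert noisy.average_models == clean.average_models
        assert noisy.n_union_contacts == clean.n_union_contacts

    def test_domain_restriction_drops_outside_contacts(self):
        spec = FixtureSpec(
            interface_pairs=[(2, 3), (25, 20)], shared_fraction=1.0
        )
        narrow = DomainRange("t", "ORC6_BD", 1, 10)
        score = score_target(build_multimer(spec), narrow)
        assert score.n_union_contacts == 1
        assert score.average_models == 1.0

    def test_ground_truth_recovery_formula(self):
        pairs = [(2 * i, 3 * i % 30 + 1) for i in range(1, 11)]
        # distinct a/b residues required; construct disjoint pairs instead
        pairs = [(i, i + 10) for i in range(1, 11)]
        for fraction in (0.0, 0.2, 0.6, 1.0):
            spec = FixtureSpec(
                interface_pairs=pairs, shared_fraction=fraction, seed=9
            )
            score = score_target(build_multimer(spec), self.DOMAIN)
            assert score.average_models == pytest.approx(
                expected_average_models(spec)
            )
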