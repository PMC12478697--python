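"""Batched identity evaluation and full discovery."""

import numpy as np
import pytest

from crnsubnet.core import NetworkDims, parse_reaction_string
from crnsubnet.identity import (
    MappingPair,
    brute_force_sis_pairs,
    evaluate_batch,
    find_subnets,
)
from crnsubnet.randnet import make_embedded_pair

from conftest import random_net


def identity_pair(net):
    return MappingPair(
        species={s: s for s in net.species_names},
        reactions={r: r for r in net.reaction_names},
    )


class TestEvaluateBatch:
    @pytest.mark.parametrize("mode", ["strong", "weak"])
    def test_identity_mapping_verifies(self, chain_net, mode):
        ok = evaluate_batch(chain_net, chain_net, [identity_pair(chain_net)], mode)
        assert ok.tolist() == [True]

    def test_forced_wrong_type_fails(self):
        ref = parse_reaction_string("R: A -> C", name="ref")
        tgt = parse_reaction_string("Rp: Ap + Bp -> Cp", name="tgt")
        pair = MappingPair(species={"A": "Ap", "C": "Cp"}, reactions={"R": "Rp"})
        for mode in ("strong", "weak"):
            assert not evaluate_batch(ref, tgt, [pair], mode)[0]

    def test_weak_true_strong_false(self):
        """A->B inside A+C->B+C: same standard column, different reactants."""
        ref = parse_reaction_string("R: A -> B", name="ref")
        tgt = parse_reaction_string("T: A + C -> B + C", name="tgt")
        pair = MappingPair(species={"A": "A", "B": "B"}, reactions={"R": "T"})
        assert evaluate_batch(ref, tgt, [pair], "weak")[0]
        assert not evaluate_batch(ref, tgt, [pair], "strong")[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_batch_equals_per_pair(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_net(3, 3, seed=seed)
        tgt = random_net(5, 5, seed=seed + 50)
        pairs = []
        for _ in range(20):
            srows = rng.permutation(5)[:3]
            cols = rng.permutation(5)[:3]
            pairs.append(
                MappingPair(
                    species={
                        ref.species_names[i]: tgt.species_names[srows[i]]
                        for i in range(3)
                    },
                    reactions={
                        ref.reaction_names[j]: tgt.reaction_names[cols[j]]
                        for j in range(3)
                    },
                )
            )
        for mode in ("strong", "weak"):
            batch = evaluate_batch(ref, tgt, pairs, mode)
            single = [evaluate_batch(ref, tgt, [p], mode)[0] for p in pairs]
            assert batch.tolist() == single

    def test_unknown_element_names_error_with_index(self, chain_net):
        bad = MappingPair(species={"A": "A", "B": "B", "C": "nope"},
                          reactions={"R1": "R1", "R2": "R2"})
        with pytest.raises(ValueError, match="pair 1"):
            evaluate_batch(chain_net, chain_net, [identity_pair(chain_net), bad])

    def test_non_injective_mapping_rejected(self):
        with pytest.raises(ValueError, match="injective"):
            MappingPair(species={"A": "X", "B": "X"}, reactions={})

    def test_empty_batch(self, chain_net):
        assert evaluate_batch(chain_net, chain_net, []).size == 0


class TestFindSubnets:
    def test_network_in_itself(self, chain_net):
        res = find_subnets(chain_net, chain_net)
        assert identity_pair(chain_net) in res.sis_mapping_pairs
        assert not res.truncated

    def test_pruned_negative_example_evaluates_nothing(self):
        ref = parse_reaction_string("R: A -> C", name="ref")
        tgt = parse_reaction_string("Rp: Ap + Bp -> Cp", name="tgt")
        res = find_subnets(ref, tgt)
        assert not res.is_subnet
        assert res.num_pairs_evaluated == 0
        assert res.log10_pair_estimate == float("-inf")

    @pytest.mark.parametrize("seed", range(20))
    def test_embedded_ground_truth_recovered(self, seed, small_dist):
        pair = make_embedded_pair(
            NetworkDims(4, 4), NetworkDims(10, 10), dist=small_dist, seed=seed
        )
        res = find_subnets(pair.reference, pair.target, max_mapping_pairs=1e9)
        assert pair.ground_truth in res.sis_mapping_pairs
        assert not res.truncated

    def test_empty_network_rejected(self, chain_net):
        import numpy as np
        from crnsubnet.core import Network

        empty = Network("e", ["A"], [], np.zeros((1, 0)), np.zeros((1, 0)))
        with pytest.raises(ValueError, match="empty"):
            find_subnets(empty, chain_net)
        with pytest.raises(ValueError, match="empty"):
            find_subnets(chain_net, empty)

    def test_budget_truncation(self):
        ref = parse_reaction_string("R: A -> B", name="ref")
        tgt = parse_reaction_string("T1: A -> B\nT2: C -> D", name="tgt")
        res = find_subnets(ref, tgt, max_mapping_pairs=1)
        assert res.truncated
        assert res.num_pairs_evaluated <= 1
        full = find_subnets(ref, tgt, max_mapping_pairs=1e6)
        assert not full.truncated
        assert len(full.sis_mapping_pairs) == 2

    def test_first_only_stops_early(self, chain_net):
        tgt = parse_reaction_string(
        "R1: A -> B\nR2: B -> C\nR3: C -> A", name="cycle"
        )
        res = find_subnets(chain_net, tgt, first_only=True)
        assert len(res.sis_mapping_pairs) == 1
        full = find_subnets(chain_net, tgt)
        assert res.sis_mapping_pairs[0] == full.sis_mapping_pairs[0]

    @pytest.mark.parametrize("seed", range(4))
    def test_batch_size_invariance(self, seed, small_dist):
        pair = make_embedded_pair(
            NetworkDims(3, 3), NetworkDims(7, 7), dist=small_dist, seed=seed
        )
        results = [
            find_subnets(pair.reference, pair.target, batch_size=b)
            for b in (1, 7, 1000)
        ]
        for other in results[1:]:
            assert other.sis_mapping_pairs == results[0].sis_mapping_pairs
            assert other.num_pairs_evaluated == results[0].num_pairs_evaluated
            assert other.truncated == results[0].truncated

    def test_process_count_invariance(self, small_dist):
        pair = make_embedded_pair(
            NetworkDims(4, 4), NetworkDims(9, 9), dist=small_dist, seed=11
        )
        serial = find_subnets(pair.reference, pair.target, batch_size=5)
        parallel = find_subnets(
            pair.reference, pair.target, batch_size=5, num_processes=2
        )
        assert serial.sis_mapping_pairs == parallel.sis_mapping_pairs
        assert serial.num_pairs_evaluated == parallel.num_pairs_evaluated

    @pytest.mark.parametrize("mode", ["strong", "weak"])
    @pytest.mark.parametrize("seed", range(15))
    def test_oracle_equivalence_small_networks(self, seed, mode, small_dist):
        """Constrained discovery == exhaustive no-constraint enumeration."""
        ref = random_net(3, 3, seed=seed, dist=small_dist)
        tgt = random_net(4, 4, seed=seed + 500, dist=small_dist)
        res = find_subnets(ref, tgt, mode=mode, max_mapping_pairs=1e9)
        assert set(res.sis_mapping_pairs) == set(brute_force_sis_pairs(ref, tgt, mode))

    def test_strong_implies_weak(self, small_dist):
        for seed in range(10):
            pair = make_embedded_pair(
                NetworkDims(3, 3), NetworkDims(8, 8), dist=small_dist, seed=seed
            )
            strong = find_subnets(pair.reference, pair.target, mode="strong",
                                  max_mapping_pairs=1e9)
            for mp in strong.sis_mapping_pairs:
                assert evaluate_batch(pair.reference, pair.target, [mp], "weak")[0]

    def test_target_relabeling_invariance(self, small_dist):
        from crnsubnet.core import Network

        pair = make_embedded_pair(
            NetworkDims(3, 3), NetworkDims(7, 7), dist=small_dist, seed=5
        )
        tgt = pair.target
        rng = np.random.default_rng(0)
        sperm, rperm = rng.permutation(tgt.num_species), rng.permutation(tgt.num_reactions)
        s_new = {tgt.species_names[i]: f"Z{k}" for k, i in enumerate(sperm)}
        r_new = {tgt.reaction_names[j]: f"W{k}" for k, j in enumerate(rperm)}
        relabeled = Network(
            "relabeled",
            [s_new[tgt.species_names[i]] for i in sperm],
            [r_new[tgt.reaction_names[j]] for j in rperm],
            tgt.reactant[np.ix_(sperm, rperm)],
            tgt.product[np.ix_(sperm, rperm)],
        )
        base = find_subnets(pair.reference, tgt, max_mapping_pairs=1e9)
        relab = find_subnets(pair.reference, relabeled, max_mapping_pairs=1e9)
        mapped = {
            MappingPair(
                species={a: s_new[b] for a, b in mp.species.items()},
                reactions={a: r_new[b] for a, b in mp.reactions.items()},
            )
            for mp in base.sis_mapping_pairs
        }
        assert mapped == set(relab.sis_mapping_pairs)

    def test_mode_validation(self, chain_net):
        with pytest.raises(ValueError, match="identity mode"):
            find_subnets(chain_net, chain_net, mode="loose")
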