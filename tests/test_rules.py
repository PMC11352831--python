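"""Rule sampling, enumeration, bias, canalization depth, consistency."""

import numpy as np
import pytest

from irrnet.network import SignedNetwork
from irrnet.rules import (OP_AND, OP_NEST, OP_OR, BooleanRule, EnsembleParams,
                          canalization_depths, check_consistency,
                          ensure_root_selfloop, enumerate_rules,
                          enumerate_rulesets, rule_bias, sample_ruleset)
from irrnet.synth import SynthNetworkParams, generate_network


def chain_rule(k, ops, pols=None):
    pols = pols or [1] * k
    return BooleanRule.from_chain(
        "z", [(f"i{j}", p) for j, p in enumerate(pols)], ops)


class TestSampling:
    def three_input_net(self):
        return SignedNetwork([("a", "z", 1), ("b", "z", 1), ("c", "z", 1),
                              ("z", "a", 1), ("z", "b", 1), ("z", "c", 1)])

    def test_r1_gives_nested_and(self):
        net = self.three_input_net()
        rs = sample_ruleset(net, EnsembleParams(r=1, s=0.5, M=1))
        rule = rs.rules["z"]
        assert rule.ops == (OP_NEST, OP_NEST)
        # y1*(y2*(y3 is the conjunction of all three literals
        assert rule.truth_table.sum() == 1 and rule.truth_table[7] == 1

    def test_r0_s1_gives_or(self):
        net = self.three_input_net()
        rs = sample_ruleset(net, EnsembleParams(r=0, s=1, M=1))
        rule = rs.rules["z"]
        assert rule.ops == (OP_OR, OP_OR)
        assert rule.truth_table.sum() == 7 and rule.truth_table[0] == 0

    def test_single_input_rule_is_literal(self):
        net = SignedNetwork([("a", "b", -1), ("b", "a", 1)])
        rs = sample_ruleset(net, EnsembleParams(r=0.5, s=0.5, M=1))
        assert list(rs.rules["b"].truth_table) == [1, 0]  # negated literal
        assert list(rs.rules["a"].truth_table) == [0, 1]

    def test_determinism_same_seed(self):
        net = generate_network(SynthNetworkParams(n=10, edge_prob=0.3, seed=4))
        net = ensure_root_selfloop(net)
        p = EnsembleParams(r=0.4, s=0.7, seed=99, M=2)
        a = sample_ruleset(net, p, realization=1)
        b = sample_ruleset(net, p, realization=1)
        assert all(np.array_equal(a.rules[u].truth_table,
                                  b.rules[u].truth_table) for u in net.nodes)
        c = sample_ruleset(net, p, realization=2)
        assert any(not np.array_equal(a.rules[u].truth_table,
                                      c.rules[u].truth_table)
                   for u in net.nodes)

    def test_zero_indegree_node_rejected(self):
        net = SignedNetwork([("a", "b", 1)])
        with pytest.raises(ValueError, match="ensure_root_selfloop"):
            sample_ruleset(net, EnsembleParams(r=0.5, s=0.5, M=1))

    def test_unique_rule_corner_forces_M1(self):
        assert EnsembleParams(r=1, s=0.3, M=20).M == 1
        assert EnsembleParams(r=0.3, s=0, M=20).M == 1
        assert EnsembleParams(r=0, s=1, M=20).M == 1
        assert EnsembleParams(r=0.5, s=1, M=20).M == 20


class TestEnsureRootSelfloop:
    def test_adds_positive_selfloop(self):
        net = SignedNetwork([("1", "2", 1)])
        fixed = ensure_root_selfloop(net)
        assert ("1", "1", 1) in fixed.edges

    def test_noop_and_idempotent(self):
        net = SignedNetwork([("a", "b", 1), ("b", "a", 1)])
        assert ensure_root_selfloop(net) == net
        once = ensure_root_selfloop(SignedNetwork([("1", "2", 1)]))
        assert ensure_root_selfloop(once) == once


class TestEnumeration:
    def test_k2_exactly_and_or(self):
        dist = enumerate_rules(2, [1, 1], EnsembleParams(r=0.5, s=0.5, M=1))
        assert dist.n_distinct == 2
        assert sorted(dist.biases) == [0.25, 0.75]

    @pytest.mark.parametrize("k", range(2, 8))
    def test_distinct_count_lower_bound_and_prob_sum(self, k):
        dist = enumerate_rules(k, [1] * k, EnsembleParams(r=0.3, s=0.6, M=1))
        assert dist.n_distinct >= 2 ** (k - 1)
        assert sum(dist.probabilities) == pytest.approx(1.0, abs=1e-12)
        for r in (0.0, 0.25, 0.9):
            for s in (0.0, 0.5, 1.0):
                assert dist.probabilities_at(r, s).sum() == pytest.approx(
                    1.0, abs=1e-12)

    @pytest.mark.parametrize("k", range(2, 8))
    def test_bias_corners(self, k):
        dist = enumerate_rules(k, [1] * k, EnsembleParams(r=0.5, s=0.5, M=1))
        assert dist.mean_bias_at(0.0, 1.0) == pytest.approx(1 - 2.0 ** -k)
        for r in (0.0, 0.4, 1.0):
            assert dist.mean_bias_at(r, 0.0) == pytest.approx(2.0 ** -k)
        for s in (0.0, 0.5, 1.0):
            assert dist.mean_bias_at(1.0, s) == pytest.approx(2.0 ** -k)

    @pytest.mark.parametrize("k", range(3, 8))
    def test_depth_surface_max_at_half_one(self, k):
        dist = enumerate_rules(k, [1] * k, EnsembleParams(r=0.5, s=0.5, M=1))
        grid = np.linspace(0, 1, 5)
        vals = [dist.mean_depth_at(r, s) for r in grid for s in grid]
        assert dist.mean_depth_at(0.5, 1.0) == pytest.approx(max(vals),
                                                             abs=1e-9)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_rules(11, [1] * 11, EnsembleParams(r=0.5, s=0.5, M=1))


class TestBias:
    def test_and_or_corners(self):
        assert rule_bias(chain_rule(3, (OP_AND, OP_AND))) == 0.125
        assert rule_bias(chain_rule(3, (OP_OR, OP_OR))) == 0.875

    def test_nested_example(self):
        assert rule_bias(chain_rule(3, (OP_NEST, OP_OR))) == 0.375


class TestDepths:
    def test_and_pair_fully_canalizing(self):
        depths, avg = canalization_depths(chain_rule(2, (OP_AND,)))
        assert depths == [1, 1] and avg == 1.0

    def test_nested_example(self):
        depths, avg = canalization_depths(chain_rule(3, (OP_NEST, OP_OR)))
        assert depths == [1, 2, 2]
        assert avg == pytest.approx(5 / 3)

    def test_single_literal(self):
        depths, avg = canalization_depths(chain_rule(1, ()))
        assert depths == [1] and avg == 1.0


class TestConsistency:
    def test_two_activators_or_passes(self):
        net = SignedNetwork([("a", "z", 1), ("b", "z", 1), ("z", "a", 1),
                             ("z", "b", 1)])
        rule = BooleanRule.from_chain("z", [("a", 1), ("b", 1)], (OP_OR,))
        assert check_consistency(rule, net).ok

    def test_missing_edge_fails(self):
        net = SignedNetwork([("a", "z", 1), ("b", "z", 1), ("z", "a", 1),
                             ("z", "b", 1)])
        rule = BooleanRule.from_chain("z", [("a", 1)], ())
        rep = check_consistency(rule, net)
        assert not rep.ok and any("edge consistency" in v for v in rep.violations)

    def test_nonessential_input_flagged(self):
        net = SignedNetwork([("a", "z", 1), ("b", "z", 1), ("z", "a", 1),
                             ("z", "b", 1)])
        # hand-built table that ignores input b
        tt = np.array([0, 1, 0, 1], dtype=np.uint8)
        rule = BooleanRule(target="z", inputs=[("a", 1), ("b", 1)],
                           ops=(OP_AND,), truth_table=tt,
                           silenced=[False, False])
        rep = check_consistency(rule, net)
        assert not rep.ok and any("essentiality" in v for v in rep.violations)

    def test_sign_violation_flagged(self):
        net = SignedNetwork([("a", "z", -1), ("z", "a", 1)])
        tt = np.array([0, 1], dtype=np.uint8)  # increasing in a repressor
        rule = BooleanRule(target="z", inputs=[("a", -1)], ops=(),
                           truth_table=tt, silenced=[False])
        rep = check_consistency(rule, net)
        assert not rep.ok and any("sign" in v for v in rep.violations)

    def test_autorepression_conjoined_partner_exempt(self):
        # z represses itself; rule y_a x ~y_z is constant 0 under silencing
        net = SignedNetwork([("a", "z", 1), ("z", "z", -1), ("z", "a", 1)])
        rule = BooleanRule.from_chain("z", [("a", 1), ("z", -1)], (OP_AND,))
        assert rule.truth_table.sum() == 0
        rep = check_consistency(rule, net)
        assert rep.ok and len(rep.exemptions) == 2

    def test_autorepression_own_monomial_self_exempt(self):
        net = SignedNetwork([("a", "z", 1), ("z", "z", -1), ("z", "a", 1)])
        rule = BooleanRule.from_chain("z", [("a", 1), ("z", -1)], (OP_OR,))
        # the self monomial vanishes from the sum: rule reduces to y_a
        assert list(rule.truth_table) == [0, 1, 0, 1]
        rep = check_consistency(rule, net)
        assert rep.ok and len(rep.exemptions) == 1

    @pytest.mark.parametrize("r,s", [(0, 1), (1, 0.5), (0.5, 0.5), (0.2, 0.8),
                                     (0.8, 0.2), (0.5, 1), (0, 0)])
    def test_sampled_rules_always_consistent(self, r, s):
        for seed in range(5):
            net = generate_network(SynthNetworkParams(
                n=8, edge_prob=0.3, repression_fraction=0.4, seed=seed))
            net = ensure_root_selfloop(net)
            params = EnsembleParams(r=r, s=s, M=1, seed=seed)
            rs = sample_ruleset(net, params)
            for u in net.nodes:
                assert check_consistency(rs.rules[u], net).ok


class TestEnumerateRulesets:
    def test_product_of_distinct_functions(self):
        net = SignedNetwork([("a", "b", 1), ("b", "a", 1),
                             ("a", "c", 1), ("b", "c", 1), ("c", "a", 1)])
        sets = list(enumerate_rulesets(net))
        # a and c have 2 inputs (AND, OR each); b has 1 input (1 rule)
        assert len(sets) == 4

    def test_cap_enforced(self):
        net = generate_network(SynthNetworkParams(n=8, edge_prob=0.5, seed=0))
        net = ensure_root_selfloop(net)
        with pytest.raises(RuntimeError, match="cap"):
            list(enumerate_rulesets(net, cap=2))
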