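"""Transient perturbation protocol, classification, aggregation, convergence."""

import math

import numpy as np
import pandas as pd
import pytest

from irrnet.dynamics import AttractorSet, basin_map, find_attractors
from irrnet.network import decompose_sccs
from irrnet.perturb import (Perturbation, apply_transient_perturbation,
                            classify_gene, convergence, ensemble_rmsd,
                            irreversibility_profile, iter_perturbation_outcomes,
                            verify_conditions)
from irrnet.rules import EnsembleParams, ensure_root_selfloop
from irrnet.synth import SynthNetworkParams, fixtures, generate_network


def attractor_with_state(atts, state):
    return next(a for a in atts.attractors if state in a)


class TestProtocol:
    def test_mutual_activation_oe_is_irreversible(self, toy):
        rules = toy["T1"].rules
        atts = find_attractors(rules)
        A = attractor_with_state(atts, 0)
        out = apply_transient_perturbation(rules, atts, A, 0,
                                           Perturbation("a", "OE"))
        assert out.applicable and out.irreversible
        assert out.x_q == 3          # clamped fixed point (1,1)
        assert out.x_r == 2          # release: (0,1)
        assert out.final_attractor.period == 2
        assert out.changed_set == {"b"}

    def test_three_gene_exemplar_turns_genes_on(self, toy):
        rules = toy["T2"].rules
        atts = find_attractors(rules)
        A = attractor_with_state(atts, 0)
        out = apply_transient_perturbation(rules, atts, A, 0,
                                           Perturbation("g1", "OE"))
        assert out.irreversible
        # final attractor: g2 and g3 on, g1 restored off
        assert out.final_attractor.states == (6,)
        assert out.response_genes == {"g2", "g3"}

    def test_inapplicable_returns_flag_not_exception(self, toy):
        rules = toy["T1"].rules
        atts = find_attractors(rules)
        A = attractor_with_state(atts, 0)
        out = apply_transient_perturbation(rules, atts, A, 0,
                                           Perturbation("a", "KO"))
        assert not out.applicable and not out.irreversible

    def test_single_attractor_network_all_reversible(self, toy):
        for name in ("T3", "T4"):
            rules = toy[name].rules
            atts = find_attractors(rules)
            for out in iter_perturbation_outcomes(rules, atts):
                assert not out.irreversible


class TestClassification:
    def test_three_gene_exemplar_probabilities(self, toy):
        rules = toy["T2"].rules
        atts = find_attractors(rules)
        c = classify_gene(rules, atts, "g1")
        assert c.q == pytest.approx(0.25)
        assert c.p_oe == pytest.approx(2 / 3)
        assert c.p_ko == 0.0

    def test_mutual_activation_q(self, toy):
        rules = toy["T1"].rules
        atts = find_attractors(rules)
        c = classify_gene(rules, atts, "a")
        assert c.q == pytest.approx(2 / 3)

    def test_unknown_gene_raises(self, toy):
        rules = toy["T1"].rules
        atts = find_attractors(rules)
        with pytest.raises(KeyError):
            classify_gene(rules, atts, "zz")


class TestProfile:
    def test_exemplar_p_hat(self, toy):
        net = toy["T2"].network
        # unique-rule corner (r, s) = (0, 1) reproduces the exemplar rules
        table = irreversibility_profile(net, EnsembleParams(r=0, s=1, M=1))
        assert table.p_hat()["g1"] == pytest.approx(0.5)

    def test_single_attractor_profile_is_zero(self, toy):
        table = irreversibility_profile(toy["T3"].network,
                                        EnsembleParams(r=0, s=1, M=1))
        assert (table.p_hat() == 0).all()

    def test_p_hat_reproducible_from_components(self):
        net = ensure_root_selfloop(generate_network(
            SynthNetworkParams(n=7, edge_prob=0.3, two_cycles=1, seed=5)))
        table = irreversibility_profile(net, EnsembleParams(r=0.5, s=0.8,
                                                            M=4, seed=5))
        df = table.frame
        manual = (df["p_ko"] * df["q"] + df["p_oe"] * (1 - df["q"])) \
            .groupby(df["gene"]).mean()
        assert np.allclose(manual.sort_index(), table.p_hat(), atol=1e-12)

    def test_basin_weighting_runs_and_bounded(self, toy):
        table = irreversibility_profile(toy["T2"].network,
                                        EnsembleParams(r=0, s=1, M=1),
                                        weighting="basin")
        assert table.p_hat().between(0, 1).all()


class TestConditions:
    def test_worked_example(self, toy):
        rules = toy["T1"].rules
        bm = basin_map(rules)
        atts = AttractorSet(attractors=bm.attractors, mode="exhaustive",
                            n_nodes=2)
        A = attractor_with_state(atts, 0)
        out = apply_transient_perturbation(rules, atts, A, 0,
                                           Perturbation("a", "OE"))
        rep = verify_conditions(out, bm)
        assert rep.necessary_holds and rep.sufficient_consistent
        assert not rep.violations

    def test_reversible_outcome_vacuously_passes(self, toy):
        rules = toy["T3"].rules
        bm = basin_map(rules)
        atts = AttractorSet(attractors=bm.attractors, mode="exhaustive",
                            n_nodes=2)
        for out in iter_perturbation_outcomes(rules, atts):
            rep = verify_conditions(out, bm)
            assert not rep.violations

    def test_no_violations_on_random_networks(self):
        for seed in range(10):
            net = ensure_root_selfloop(generate_network(SynthNetworkParams(
                n=7, edge_prob=0.3, repression_fraction=0.3, two_cycles=1,
                seed=seed)))
            from irrnet.rules import sample_ruleset
            rules = sample_ruleset(net, EnsembleParams(r=0.5, s=0.5, M=1,
                                                       seed=seed))
            bm = basin_map(rules)
            atts = AttractorSet(attractors=bm.attractors, mode="exhaustive",
                                n_nodes=len(net))
            for out in iter_perturbation_outcomes(rules, atts):
                assert not verify_conditions(out, bm).violations


class TestNoCycleReachability:
    @pytest.mark.parametrize("seed", range(8))
    def test_genes_reaching_no_scc_are_reversible(self, seed):
        """A gene that cannot reach any nontrivial SCC cannot be irreversible:
        its perturbation never feeds back, so the network relaxes to the
        initial attractor."""
        net = ensure_root_selfloop(generate_network(SynthNetworkParams(
            n=8, edge_prob=0.25, two_cycles=1, seed=seed)))
        scc = decompose_sccs(net)
        import networkx as nx
        nontrivial_nodes = set().union(*(
            c for c, nt in zip(scc.components, scc.nontrivial) if nt)) \
            if any(scc.nontrivial) else set()
        table = irreversibility_profile(net, EnsembleParams(r=0.5, s=0.5,
                                                            M=2, seed=seed))
        p_hat = table.p_hat()
        for u in net.nodes:
            reach = nx.descendants(net.graph, u) | {u}
            if not (reach & nontrivial_nodes):
                assert p_hat[u] == 0.0


class TestRmsdAndConvergence:
    def test_identical_profiles_zero(self):
        a = pd.Series({"x": 0.2, "y": 0.8})
        assert ensemble_rmsd(a, a.copy()) == 0.0

    def test_opposite_profiles_one(self):
        a = pd.Series({"x": 0.0, "y": 0.0})
        b = pd.Series({"x": 1.0, "y": 1.0})
        assert ensemble_rmsd(a, b) == 1.0

    def test_formula_arithmetic(self):
        a = pd.Series({"x": 0.1, "y": 0.0})
        b = pd.Series({"x": 0.0, "y": 0.0})
        assert ensemble_rmsd(a, b) == pytest.approx(math.sqrt(0.005))

    def test_node_set_mismatch(self):
        with pytest.raises(ValueError):
            ensemble_rmsd(pd.Series({"x": 0.1}), pd.Series({"y": 0.1}))

    def test_pair_counts_and_nonnegative(self):
        net = ensure_root_selfloop(generate_network(
            SynthNetworkParams(n=6, edge_prob=0.35, two_cycles=1, seed=9)))
        table = irreversibility_profile(net, EnsembleParams(r=0.5, s=0.8,
                                                            M=6, seed=9))
        rep = convergence(table, [1, 2, 3], seed=1)
        assert rep.n_pairs[1] == 30           # C(6,1)*C(5,1)
        assert rep.n_pairs[2] == 90           # C(6,2)*C(4,2)
        assert rep.n_pairs[3] == 20           # C(6,3)*C(3,3)
        for m in (1, 2, 3):
            assert (rep.rmsd[m] >= 0).all()

    def test_mprime_too_large(self):
        net = ensure_root_selfloop(generate_network(
            SynthNetworkParams(n=5, edge_prob=0.4, seed=2)))
        table = irreversibility_profile(net, EnsembleParams(r=0.5, s=0.8,
                                                            M=4, seed=2))
        with pytest.raises(ValueError):
            convergence(table, [3])
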