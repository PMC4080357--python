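"""Extreme-ray enumeration, classification, the brute-force oracle, decomposition."""

import json
from pathlib import Path

import numpy as np
import pytest

import expanet as ex
from expanet.cone import _extreme_rays

DATA = Path(__file__).parent / "data"


class TestSplitReversible:
    def test_pair_columns_are_exact_negations(self, fixture_nets):
        net = fixture_nets["reversible_pair"]
        sp = ex.split_reversible(net)
        assert sp.n_reactions == net.n_reactions + 1
        f = sp.reaction_index("r1_fwd")
        b = sp.reaction_index("r1_bwd")
        assert (sp.S[:, f] == -sp.S[:, b]).all()
        assert not sp.has_reversible()

    def test_irreversible_network_unchanged(self, fixture_nets):
        net = fixture_nets["chain"]
        assert ex.split_reversible(net) is net


class TestEnumerate:
    def test_chain_has_single_full_route(self, fixture_nets):
        expas = ex.enumerate_extreme_pathways(fixture_nets["chain"])
        assert len(expas) == 1
        assert expas.pathways[0].flux == (1, 1, 1)

    def test_diamond_has_two_routes(self, fixture_nets):
        expas = ex.enumerate_extreme_pathways(fixture_nets["diamond"])
        assert expas.vectors() == {(1, 1, 0, 1), (1, 0, 1, 1)}

    def test_reversible_split_two_cycle_suppressed(self, fixture_nets):
        sp = ex.split_reversible(fixture_nets["reversible_pair"])
        expas = ex.enumerate_extreme_pathways(sp)
        assert len(expas) == 1
        assert expas.pathways[0].flux[sp.reaction_index("r1_bwd")] == 0

    def test_reversible_network_rejected(self, fixture_nets):
        with pytest.raises(ValueError, match="split_reversible"):
            ex.enumerate_extreme_pathways(fixture_nets["reversible_pair"])

    def test_empty_network_empty_set(self):
        net = ex.StoichiometricNetwork(np.zeros((2, 0), dtype=np.int64), ["A", "B"], [])
        assert len(ex.enumerate_extreme_pathways(net)) == 0

    def test_steady_state_and_gcd_invariants(self, fixture_nets):
        for name, net in fixture_nets.items():
            sp = ex.split_reversible(net)
            for p in ex.enumerate_extreme_pathways(sp):
                flux = np.array(p.flux)
                assert (sp.S @ flux == 0).all(), name
                assert np.gcd.reduce(flux[flux > 0]) == 1, name

    def test_support_minimality_pairwise(self, fixture_nets):
        for name, net in fixture_nets.items():
            sp = ex.split_reversible(net)
            paths = ex.enumerate_extreme_pathways(sp).pathways
            for p in paths:
                for q in paths:
                    if p is not q:
                        assert not p.support < q.support, name

    def test_row_and_column_permutation_invariance(self):
        net = ex.random_network(seed=7)
        rng = np.random.default_rng(3)
        rperm = rng.permutation(net.n_species)
        cperm = rng.permutation(net.n_reactions)
        shuffled = ex.StoichiometricNetwork(
            net.S[np.ix_(rperm, cperm)],
            [net.species[i] for i in rperm],
            [net.reactions[j] for j in cperm],
        )
        base = ex.enumerate_extreme_pathways(net).vectors()
        inv = {int(c): j for j, c in enumerate(cperm)}
        relabeled = {
            tuple(v[inv[j]] for j in range(net.n_reactions))
            for v in ex.enumerate_extreme_pathways(shuffled).vectors()
        }
        assert base == relabeled

    def test_row_processing_order_does_not_change_result(self):
        net = ex.random_network(seed=11)
        S = net.S.tolist()
        natural = {tuple(v) for v in _extreme_rays(S, row_order=list(range(net.n_species)))}
        reversed_order = {
            tuple(v) for v in _extreme_rays(S, row_order=list(range(net.n_species))[::-1])
        }
        heuristic = {tuple(v) for v in _extreme_rays(S)}
        assert natural == reversed_order == heuristic


class TestClassify:
    def test_pure_internal_cycle_detected_and_removed(self, fixture_nets):
        raw = ex.enumerate_extreme_pathways(fixture_nets["cycle"])
        assert len(raw) == 1
        assert raw.pathways[0].expa_class == "III"
        kept = ex.classify_pathways(raw)
        assert len(kept) == 0 and kept.n_class3_removed == 1

    def test_chain_with_cycle_keeps_only_the_chain(self, fixture_nets):
        kept = ex.classify_pathways(
            ex.enumerate_extreme_pathways(fixture_nets["chain_cycle"])
        )
        assert len(kept) == 1
        assert kept.pathways[0].support_ids(fixture_nets["chain_cycle"]) == {
            "Ein", "r1", "Eout",
        }


class TestOracle:
    def test_matches_enumerator_on_committed_fixture_sets(self, fixture_nets):
        stored = json.loads((DATA / "fixture_expas.json").read_text())
        for name, net in fixture_nets.items():
            sp = ex.split_reversible(net)
            enum = sorted(list(p.flux) for p in ex.enumerate_extreme_pathways(sp))
            oracle = sorted(list(p.flux) for p in ex.brute_force_elementary_modes(sp))
            assert enum == oracle == stored[name]["expas"], name
            assert sp.reaction_ids == stored[name]["reactions"], name

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumerator_on_random_networks(self, seed):
        sp = ex.split_reversible(ex.random_network(seed=seed))
        assert (
            ex.enumerate_extreme_pathways(sp).vectors()
            == ex.brute_force_elementary_modes(sp).vectors()
        )

    def test_size_guard(self):
        net = ex.random_network(seed=0, n_species=5, n_internal=13, n_exchange=3)
        with pytest.raises(ValueError, match="limited"):
            ex.brute_force_elementary_modes(net)


class TestDecompose:
    def test_known_conic_combination_recovered(self, fixture_nets):
        net = fixture_nets["diamond"]
        expas = ex.classify_pathways(ex.enumerate_extreme_pathways(net))
        p1, p2 = (np.array(p.flux) for p in expas.pathways)
        ok, alpha = ex.decompose_flux(net, 2 * p1 + 3 * p2, expas)
        assert ok
        recon = np.array([p.flux for p in expas.pathways]).T @ alpha
        assert np.allclose(recon, 2 * p1 + 3 * p2)

    def test_zero_flux_is_feasible_with_zero_coefficients(self, fixture_nets):
        net = fixture_nets["chain"]
        expas = ex.enumerate_extreme_pathways(net)
        ok, alpha = ex.decompose_flux(net, np.zeros(net.n_reactions, dtype=int), expas)
        assert ok and np.allclose(alpha, 0)

    def test_random_conic_points_always_decompose(self, fixture_nets):
        rng = np.random.default_rng(42)
        for name in ("diamond", "parallel_chains", "chain_cycle"):
            net = fixture_nets[name]
            expas = ex.enumerate_extreme_pathways(net)
            P = np.array([p.flux for p in expas.pathways])
            for _ in range(20):
                coeff = rng.integers(0, 5, size=len(P))
                ok, _ = ex.decompose_flux(net, coeff @ P, expas)
                assert ok, name

    def test_non_steady_state_vector_rejected(self, fixture_nets):
        net = fixture_nets["chain"]
        expas = ex.enumerate_extreme_pathways(net)
        with pytest.raises(ValueError, match="steady-state"):
            ex.decompose_flux(net, [1, 0, 0], expas)
        with pytest.raises(ValueError, match="nonnegative"):
            ex.decompose_flux(net, [-1, -1, -1], expas)
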