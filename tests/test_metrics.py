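"""Pathway metrics: lengths, participation, CoSets, crosstalk, unused reactions."""

import math

import numpy as np
import pytest

import expanet as ex
from expanet.metrics import participation_matrix


class TestLengths:
    def test_chain_pathway_length_counts_exchanges(self, fixture_nets):
        expas = ex.enumerate_extreme_pathways(fixture_nets["chain"])
        stats = ex.pathway_lengths(expas)
        assert stats.max == stats.min == 3

    def test_toy_minimum_length_is_three(self, toy_expas):
        # shortest regulatory pathway: stimulus input + rule + product export
        stats = ex.pathway_lengths(toy_expas)
        assert stats.min == 3
        assert stats.lr_percent == pytest.approx(100 * stats.avg / 18)

    def test_histogram_matches_recount_from_flux_vectors(self, toy_expas):
        stats = ex.pathway_lengths(toy_expas)
        recount = {}
        for p in toy_expas.pathways:
            ln = sum(1 for v in p.flux if v)
            recount[ln] = recount.get(ln, 0) + 1
        assert stats.histogram == recount
        assert sum(stats.histogram.values()) == len(toy_expas.pathways)

    def test_mode_tie_breaks_to_smallest_length(self, toy_expas):
        stats = ex.pathway_lengths(toy_expas)
        best = max(stats.histogram.values())
        assert stats.mode == min(k for k, v in stats.histogram.items() if v == best)

    def test_empty_set_flagged_not_crashing(self, fixture_nets):
        empty = ex.ExPaSet(fixture_nets["chain"], [])
        stats = ex.pathway_lengths(empty)
        assert stats.empty and math.isnan(stats.avg)


class TestParticipation:
    def test_pr_ratio_definition(self, toy_expas):
        assert ex.pr_ratio(toy_expas) == pytest.approx(6 / 18)

    def test_rpr_equals_column_mean_of_participation_matrix(self, toy_expas):
        rpr = ex.reaction_participation(toy_expas)
        part = participation_matrix(toy_expas)
        recount = part.sum(axis=0) / part.shape[0] * 100
        by_id = dict(zip(toy_expas.network.reaction_ids, recount))
        for _, row in rpr.iterrows():
            assert row["rpr"] == pytest.approx(by_id[row["reaction"]])
        assert (rpr["rpr"].to_numpy()[:-1] >= rpr["rpr"].to_numpy()[1:]).all()

    def test_reaction_in_every_pathway_scores_100(self, fixture_nets):
        expas = ex.enumerate_extreme_pathways(fixture_nets["diamond"])
        rpr = ex.reaction_participation(expas)
        assert set(rpr[rpr["rpr"] == 100.0]["reaction"]) == {"Ein", "Eout"}

    def test_pr_ratio_rejects_empty_network(self):
        net = ex.StoichiometricNetwork(np.zeros((1, 0), dtype=np.int64), ["A"], [])
        with pytest.raises(ValueError):
            ex.pr_ratio(ex.ExPaSet(net, []))


class TestUnused:
    def test_contradictory_rule_reported_type_two(self):
        model = ex.parse_rule_text("stimuli: X\nP <- X AND NOT X\n")
        u = ex.compute_trn_expa_set(model)
        report = ex.unused_reactions(u.as_expa_set())
        types = {r.reaction: r.type for r in report}
        assert types["P_1"] == "II"
        assert types["Ex_P"] == "II"  # exported state only produced contradictorily

    def test_missing_producer_reported_type_one(self):
        # Q consumes P's absence state, but nothing ever produces Q's substrate
        # state NOT_P except the converse of P itself; cutting the stimulus link
        # leaves dead wiring: model P from an undriven internal component.
        model = ex.parse_rule_text("stimuli: A\nTF <- A\nG <- TF AND NOT A\n")
        u = ex.compute_trn_expa_set(model)
        report = ex.unused_reactions(u.as_expa_set())
        # G needs TF present and A absent, but TF requires A present: dead rule
        assert {r.reaction for r in report} >= {"G_1"}
        assert all(r.type == "I" for r in report if r.reaction == "G_1")

    def test_fully_connected_toy_has_empty_report(self, toy_expas):
        assert ex.unused_reactions(toy_expas) == []


class TestCoSets:
    def test_linear_chain_internal_reactions_form_one_trivial_coset(self, fixture_nets):
        expas = ex.enumerate_extreme_pathways(fixture_nets["chain"])
        report = ex.find_cosets(expas)
        assert len(report.cosets) == 1
        assert set(report.cosets[0].members) == {"Ein", "r1", "Eout"}
        assert report.cosets[0].trivial
        assert report.adjacent_ratio == 100.0

    def test_coupled_parallel_chains_yield_nontrivial_coset(self, fixture_nets):
        # Eout_B always fires with Ein/split/r2/Eout_D but shares no species
        # with any of them, so the CoSet's adjacency graph is disconnected
        net = fixture_nets["parallel_chains"]
        expas = ex.enumerate_extreme_pathways(net)
        assert len(expas) == 2
        report = ex.find_cosets(expas)
        [coset] = report.cosets
        assert set(coset.members) == {"Ein", "split", "r2", "Eout_B", "Eout_D"}
        assert not coset.trivial
        assert report.adjacent_ratio == 0.0

    def test_members_share_identical_rpr(self, toy_expas):
        report = ex.find_cosets(toy_expas)
        rpr = ex.reaction_participation(toy_expas).set_index("reaction")["rpr"]
        for coset in report.cosets:
            values = {round(rpr[m], 9) for m in coset.members}
            assert len(values) == 1

    def test_cosets_partition_shared_signatures(self, toy_expas):
        report = ex.find_cosets(toy_expas)
        seen = [m for c in report.cosets for m in c.members]
        assert len(seen) == len(set(seen))
        part = participation_matrix(toy_expas)
        ids = toy_expas.network.reaction_ids
        sig_of = {rid: tuple(part[:, j]) for j, rid in enumerate(ids)}
        grouped = {m for c in report.cosets for m in c.members}
        for rid in ids:
            twins = [o for o in ids if o != rid and sig_of[o] == sig_of[rid]]
            if any(sig_of[rid]) and twins:
                assert rid in grouped


class TestCrosstalk:
    def test_pair_of_identical_pathway_copies(self, fixture_nets):
        net = fixture_nets["chain"]
        single = ex.enumerate_extreme_pathways(net).pathways[0]
        expas = ex.ExPaSet(net, [single, single])
        m = ex.crosstalk_matrix(expas, exclude_top_exchange_fraction=0.0)
        assert m.counts[0, 0] == 1 and m.counts.sum() == 1

    def test_counts_sum_to_all_pairs_and_percentages_to_100(self, toy_expas):
        m = ex.crosstalk_matrix(toy_expas, exclude_top_exchange_fraction=0.0)
        n = len(toy_expas.pathways)
        assert m.counts.sum() == n * (n - 1) // 2
        assert m.percentages.sum() == pytest.approx(100.0)

    def test_redundant_routes_count_as_identical_identical(self, fixture_nets):
        expas = ex.enumerate_extreme_pathways(fixture_nets["diamond"])
        m = ex.crosstalk_matrix(expas, exclude_top_exchange_fraction=0.0)
        assert m.counts[0, 0] == 1  # same input, same output, different interior

    def test_exclusion_removes_top_exchange_reactions(self, toy_expas):
        m = ex.crosstalk_matrix(toy_expas, exclude_top_exchange_fraction=0.20)
        n_exch = len(toy_expas.network.exchange_columns)
        assert len(m.excluded_reactions) == math.ceil(0.20 * n_exch)

    def test_needs_two_pathways(self, fixture_nets):
        expas = ex.enumerate_extreme_pathways(fixture_nets["chain"])
        with pytest.raises(ValueError, match="two"):
            ex.crosstalk_matrix(expas)


class TestReport:
    def test_report_fields_cross_check_individual_ops(self, toy_expas):
        report = ex.metrics_report(toy_expas)
        assert report.n_expas == len(toy_expas.pathways)
        assert report.pr_ratio == pytest.approx(ex.pr_ratio(toy_expas))
        assert report.lengths.histogram == ex.pathway_lengths(toy_expas).histogram
        assert report.crosstalk.counts.sum() == 15
        assert report.unused == []

    def test_empty_set_flags_instead_of_crash(self, fixture_nets):
        report = ex.metrics_report(ex.ExPaSet(fixture_nets["chain"], []))
        assert report.flags and report.lengths.empty

    def test_report_is_deterministic(self, tmp_path):
        model = ex.random_trn(ex.GeneratorConfig(seed=5))
        outs = []
        for run in ("a", "b"):
            u = ex.compute_trn_expa_set(model)
            report = ex.metrics_report(u.as_expa_set())
            d = tmp_path / run
            report.write(d)
            outs.append((d / "report.json").read_bytes())
        assert outs[0] == outs[1]
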