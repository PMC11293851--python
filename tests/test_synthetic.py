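"""The synthetic transect and campaign generator: planted, seeded, valid."""

import numpy as np
import pytest
from scipy.stats import chisquare

from benthicnet.synthetic import (
    CampaignDesign,
    PlantedTruth,
    SiteSpec,
    make_community,
    planted_campaign_design,
    sample_contact_graph,
    score_recovery,
    simulate_campaign,
    simulate_transect,
)
from benthicnet.transect import network_from_record, run_length_encode


class TestMakeCommunity:
    def test_neutral_default_affinity_is_ones(self):
        model = make_community(5, seed=0)
        assert (model.affinity == 1.0).all()
        assert model.abundance.sum() == pytest.approx(1.0)

    def test_planted_pair_set_symmetrically(self):
        model = make_community(6, planted_pairs=[(0, 1, 10.0)], seed=0)
        assert model.affinity[0, 1] == model.affinity[1, 0] == 10.0

    def test_deterministic_under_seed(self):
        a = make_community(8, seed=5)
        b = make_community(8, seed=5)
        np.testing.assert_array_equal(a.abundance, b.abundance)
        assert a.phylum == b.phylum

    def test_bad_pair_rejected(self):
        with pytest.raises(ValueError):
            make_community(4, planted_pairs=[(0, 9, 5.0)])
        with pytest.raises(ValueError):
            make_community(4, planted_pairs=[(0, 1, -2.0)])


class TestSimulateTransect:
    def test_two_species_alternate(self):
        model = make_community(2, seed=1)
        record = simulate_transect(model, seed=2)
        runs = run_length_encode(record)
        assert all(a.species != b.species for a, b in zip(runs, runs[1:]))
        net = network_from_record(record)
        assert net.n_simple_edges == 1

    def test_length_and_determinism(self):
        model = make_community(10, seed=3)
        a = simulate_transect(model, seed=4)
        b = simulate_transect(model, seed=4)
        assert a.length == 500
        assert a.codes == b.codes

    def test_neutral_successor_frequencies_proportional_to_abundance(self):
        """Oracle: closed-form multinomial for the next-species draw."""
        n = 5
        model = make_community(n, seed=6, run_mean=1.0, transect_length=40)
        counts = np.zeros(n)
        prev_target = model.species[int(np.argmax(model.abundance))]
        for seed in range(400):
            record = simulate_transect(model, seed=seed)
            runs = run_length_encode(record)
            for a, b in zip(runs, runs[1:]):
                if a.species == prev_target:
                    counts[model.species.index(b.species)] += 1
        expected = model.abundance.copy()
        expected[model.species.index(prev_target)] = 0.0
        expected /= expected.sum()
        mask = expected > 0
        stat = chisquare(counts[mask], counts[mask].sum() * expected[mask])
        assert stat.pvalue > 1e-3

    def test_planted_affinity_raises_pair_multiplicity(self):
        """Phi = 50 pair abuts far more often than under the neutral model."""
        neutral = make_community(8, seed=7)
        planted = make_community(8, planted_pairs=[(0, 1, 50.0)], seed=7)

        def pair_multiplicity(model, seed):
            net = network_from_record(simulate_transect(model, seed=seed))
            g = net.graph
            if g.has_edge("SP00", "SP01"):
                return g["SP00"]["SP01"]["multiplicity"]
            return 0

        neutral_mean = np.mean([pair_multiplicity(neutral, s) for s in range(30)])
        exceed = [pair_multiplicity(planted, s) > neutral_mean for s in range(30)]
        assert np.mean(exceed) >= 0.95

    def test_generated_transects_satisfy_network_invariants(self):
        model = make_community(20, seed=8)
        record = simulate_transect(model, seed=9)
        runs = run_length_encode(record)
        net = network_from_record(record)
        assert sum(r.length for r in runs) == record.length
        assert sum(d["size"] for _, d in net.graph.nodes(data=True)) == record.length
        assert sum(d["count"] for _, d in net.graph.nodes(data=True)) == len(runs)
        assert net.n_multi_edges == len(runs) - 1


class TestContactGraph:
    def test_contact_graph_is_symmetric_with_planted_edges(self):
        A = sample_contact_graph(20, 1.0, seed=3, planted_edges=[(0, 1)])
        assert (A == A.T).all()
        assert not A.diagonal().any()
        assert A[0, 1]

    def test_mean_degree_calibrated_across_triad_levels(self):
        # the estimable latent range: beyond ~1.5 the family is degenerate
        for coef in (0.0, 1.2):
            A = sample_contact_graph(30, coef, seed=4, target_degree=3.5)
            assert 2.0 <= A.sum() / 30 <= 6.5

    def test_contact_restricts_observed_edges(self):
        model = make_community(20, seed=10)
        contact = sample_contact_graph(20, 0.0, seed=11)
        restricted = model.with_overrides(contact=contact)
        net = network_from_record(simulate_transect(restricted, seed=12))
        index = {s: k for k, s in enumerate(model.species)}
        off_graph = sum(
            0 if contact[index[u], index[v]] else d["multiplicity"]
            for u, v, d in net.graph.edges(data=True)
        )
        assert off_graph <= 0.1 * net.n_multi_edges


class TestSimulateCampaign:
    def test_survey_roster_size(self):
        model = make_community(15, seed=1)
        records, truth = simulate_campaign(
            planted_campaign_design(17), model, seed=2, latent_contact=False
        )
        assert len(records) == 85
        assert len(truth.site_triad) == 17

    def test_single_site_single_depth(self):
        design = CampaignDesign(sites=(SiteSpec(name="X"),), depths=(7.0,))
        model = make_community(10, seed=1)
        records, _ = simulate_campaign(design, model, seed=3, latent_contact=False)
        assert len(records) == 1

    def test_bit_identical_under_same_master_seed(self):
        model = make_community(12, seed=4)
        design = planted_campaign_design(3)
        a, _ = simulate_campaign(design, model, seed=5)
        b, _ = simulate_campaign(design, model, seed=5)
        assert [r.codes for r in a] == [r.codes for r in b]

    def test_planted_truth_records_pairs_and_sites(self):
        model = make_community(12, planted_pairs=[(0, 1, 50.0)], seed=4)
        _, truth = simulate_campaign(
            planted_campaign_design(4), model, seed=5, latent_contact=False
        )
        assert truth.planted_species == {"SP00", "SP01"}
        assert set(truth.site_triad.values()) == {0.0, 0.3}


class TestScoreRecovery:
    def test_truth_against_itself_is_perfect(self):
        truth = PlantedTruth(
            species=("A", "B", "C", "D"),
            planted_pairs=(("A", "B", 50.0),),
            site_triad={"S1": 0.3, "S2": 0.0, "S3": 0.1},
        )
        scores = score_recovery(
            truth,
            preferential={"A", "B"},
            site_scores={"S1": 0.3, "S2": 0.0, "S3": 0.1},
            influence_shares={"site": 60.0, "depth": 10.0},
        )
        assert scores["sensitivity"] == 1.0
        assert scores["specificity"] == 1.0
        assert scores["site_rank_correlation"] == pytest.approx(1.0)
        assert scores["top_predictor_is_site"]

    def test_mismatched_species_rejected(self):
        truth = PlantedTruth(species=("A", "B"), planted_pairs=(), site_triad={})
        with pytest.raises(ValueError, match="not in the planted community"):
            score_recovery(truth, preferential={"Z"})


class TestMonotonicity:
    def test_latent_triad_coefficient_recovered_in_order(self):
        """Stronger planted triad propensity -> larger fitted gwesp coefficient."""
        from benthicnet.ergm import mcmle, model1
        from benthicnet.ergm.fit import McmcControl

        model = make_community(35, seed=2)
        means = []
        for pi in (0.0, 0.3):
            design = CampaignDesign(
                sites=tuple(
                    SiteSpec(name=f"P{k}", triad_propensity=pi) for k in range(3)
                ),
                depths=(2.0, 7.0, 23.0),
            )
            records, _ = simulate_campaign(design, model, seed=11)
            coefs = []
            for rec in records:
                net = network_from_record(rec)
                fit = mcmle(net, model1(), McmcControl(seed=13, n_samples=400))
                if fit.converged:
                    coefs.append(fit.coef("gwesp"))
            means.append(np.mean(coefs))
        assert means[1] > means[0]
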