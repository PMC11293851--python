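"""Estimation: exact enumeration oracles, pseudolikelihood, sampler, MC-MLE."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.special import expit, logsumexp

from benthicnet.ergm import (
    ErgmError,
    compute_statistics,
    exact_loglik,
    exact_mle,
    information_criteria,
    mcmle,
    model1,
    model1A,
    mple,
    null_loglik,
    parse_formula,
    sample_networks,
)
from benthicnet.ergm.fit import ErgmFit, McmcControl

from conftest import random_attr_graph


def enumerate_graphs(nodes):
    """Independent enumerator: all simple graphs on the vertex set."""
    dyads = list(itertools.combinations(nodes, 2))
    for mask in range(1 << len(dyads)):
        g = nx.empty_graph(nodes)
        for d, (u, v) in enumerate(dyads):
            if (mask >> d) & 1:
                g.add_edge(u, v)
        yield g


class TestExactLikelihood:
    def test_null_model_is_uniform(self):
        g = nx.empty_graph(["A", "B", "C"])
        g.add_edge("A", "B")
        # theta = 0: every one of the 8 graphs has probability 1/8
        assert exact_loglik(g, parse_formula("edges"), [0.0]) == pytest.approx(math.log(1 / 8))
        assert null_loglik(3) == pytest.approx(-3 * math.log(2))

    def test_one_edge_mle_closed_form(self):
        g = nx.empty_graph(["A", "B", "C"])
        g.add_edge("A", "B")
        fit = exact_mle(g, parse_formula("edges"))
        assert fit.theta[0] == pytest.approx(math.log((1 / 3) / (2 / 3)), abs=1e-5)
        assert fit.method == "exact"

    @pytest.mark.parametrize("seed", [0, 1])
    def test_normalization_sums_to_one(self, seed):
        """Sum over all graphs of Pr(Y=y) must be 1 for random theta."""
        rng = np.random.default_rng(seed)
        theta = rng.normal(scale=0.7, size=2)
        spec = parse_formula("edges + gwesp(0.25, fixed)")
        nodes = [f"v{k}" for k in range(4)]
        total = 0.0
        for g in enumerate_graphs(nodes):
            total += math.exp(exact_loglik(g, spec, theta))
        assert total == pytest.approx(1.0, rel=1e-8)

    def test_exact_mle_agrees_with_independent_enumerator(self):
        """Second enumeration path: log k from itertools + per-graph stats."""
        spec = parse_formula("edges + gwesp(0.25, fixed)")
        g = nx.relabel_nodes(nx.gnp_random_graph(5, 0.5, seed=7), str)
        fit = exact_mle(g, spec)
        etas = []
        for h in enumerate_graphs(sorted(g.nodes)):
            etas.append(float(fit.theta @ compute_statistics(h, spec)))
        log_k = logsumexp(etas)
        obs = compute_statistics(g, spec)
        assert fit.log_likelihood == pytest.approx(float(fit.theta @ obs) - log_k, abs=1e-6)
        # at the MLE the expected statistics match the observed ones
        w = np.exp(np.asarray(etas) - log_k)
        G = np.array([compute_statistics(h, spec) for h in enumerate_graphs(sorted(g.nodes))])
        np.testing.assert_allclose(w @ G, obs, atol=1e-4)

    def test_enumeration_limit(self):
        g = nx.relabel_nodes(nx.empty_graph(9), str)
        g.add_edge("0", "1")
        with pytest.raises(ErgmError, match="mcmle"):
            exact_mle(g, parse_formula("edges"))

    def test_likelihood_invariant_to_relabeling(self):
        spec = parse_formula("edges + gwesp(0.25, fixed)")
        g = nx.relabel_nodes(nx.gnp_random_graph(5, 0.5, seed=3), str)
        ll = exact_loglik(g, spec, [-0.5, 0.3])
        relabeled = nx.relabel_nodes(g, {n: f"z{9 - int(n)}" for n in g.nodes})
        assert exact_loglik(relabeled, spec, [-0.5, 0.3]) == pytest.approx(ll)


class TestMple:
    def test_edges_only_equals_logit_density(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(8, 0.4, seed=2), str)
        d = g.number_of_edges() / 28
        fit = mple(g, parse_formula("edges"))
        assert fit.theta[0] == pytest.approx(math.log(d / (1 - d)), abs=1e-4)
        assert fit.method == "mple"

    def test_complete_graph_flags_separation(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        fit = mple(g, parse_formula("edges"))
        assert fit.notes.get("separation")
        assert not fit.estimable
        assert "+inf" in fit.notes["divergence"].values()

    def test_dyad_independent_mple_equals_exact_mle(self):
        g = random_attr_graph(6, 0.5, seed=5)
        spec = parse_formula("edges + nodecov(size)")
        pseudo = mple(g, spec)
        exact = exact_mle(g, spec)
        np.testing.assert_allclose(pseudo.theta, exact.theta, atol=1e-4)
        assert pseudo.log_likelihood == pytest.approx(exact.log_likelihood, abs=1e-5)

    def test_z_values_are_theta_over_se(self):
        g = random_attr_graph(7, 0.5, seed=8)
        fit = mple(g, parse_formula("edges + nodecov(size)"))
        np.testing.assert_allclose(fit.z_values, fit.theta / fit.standard_errors)


class TestSampler:
    def test_uniform_model_mean_edges(self):
        _, stats = sample_networks(
            parse_formula("edges"), [0.0], n_vertices=10,
            n_samples=400, seed=1, return_stats=True,
        )
        mean, se = stats[:, 0].mean(), stats[:, 0].std(ddof=1) / math.sqrt(len(stats))
        assert abs(mean - 22.5) < 3 * max(se, 0.3)

    def test_strongly_negative_theta_gives_empty_graphs(self):
        graphs = sample_networks(
            parse_formula("edges"), [-50.0], n_vertices=6, n_samples=20, seed=3
        )
        assert all(g.number_of_edges() == 0 for g in graphs)

    def test_dyad_marginals_match_logistic_closed_form(self):
        graphs = sample_networks(
            parse_formula("edges"), [-1.0], n_vertices=8,
            n_samples=600, thin=60, seed=5,
        )
        freq = np.mean([g.number_of_edges() / 28 for g in graphs])
        p = expit(-1.0)
        se = math.sqrt(p * (1 - p) / (600 * 28)) * 6  # generous: correlated draws
        assert abs(freq - p) < max(3 * se, 0.02)

    def test_reproducible_under_seed(self):
        kw = dict(n_vertices=6, n_samples=5, seed=11)
        a = sample_networks(parse_formula("edges"), [-0.3], **kw)
        b = sample_networks(parse_formula("edges"), [-0.3], **kw)
        assert all(set(x.edges) == set(y.edges) for x, y in zip(a, b))

    def test_detailed_balance_against_exact_enumeration(self):
        """Empirical graph distribution on n=4 matches exact probabilities."""
        spec = parse_formula("edges + gwesp(0.25, fixed)")
        theta = np.array([-0.4, 0.5])
        nodes = [f"v{k}" for k in range(4)]
        # exact distribution over the 64 graphs, keyed by edge set
        probs = {}
        for g in enumerate_graphs(nodes):
            key = frozenset(frozenset(e) for e in g.edges)
            probs[key] = math.exp(exact_loglik(g, spec, theta))
        graphs = sample_networks(spec, theta, n_vertices=4, n_samples=4000,
                                 thin=12, burn_in=200, seed=9)
        counts = {}
        for g in graphs:
            key = frozenset(frozenset((f"v{int(u[1:])}", f"v{int(v[1:])}")) for u, v in g.edges)
            counts[key] = counts.get(key, 0) + 1
        tv = 0.5 * sum(
            abs(counts.get(k, 0) / len(graphs) - p) for k, p in probs.items()
        )
        assert tv < 0.08


class TestMcmle:
    def test_dyad_independent_spec_short_circuits_to_exact(self):
        g = random_attr_graph(6, 0.5, seed=5)
        fit = mcmle(g, model1A())
        exact = exact_mle(g, model1A())
        np.testing.assert_allclose(fit.theta, exact.theta, atol=5e-3)
        assert fit.method == "mple"  # no chain was run

    def test_matches_exact_mle_with_gwesp(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(6, 0.5, seed=3), str)
        spec = parse_formula("edges + gwesp(0.25, fixed)")
        exact = exact_mle(g, spec)
        fit = mcmle(g, spec, McmcControl(seed=5, n_samples=3000, thin=80, t_tol=0.04))
        assert fit.converged
        np.testing.assert_allclose(fit.theta, exact.theta, atol=0.05)
        assert fit.log_likelihood == pytest.approx(exact.log_likelihood, abs=0.25)

    def test_serialization_round_trip(self, tmp_path):
        g = random_attr_graph(6, 0.5, seed=5)
        fit = mcmle(g, model1A())
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = ErgmFit.from_json(path)
        np.testing.assert_allclose(back.theta, fit.theta)
        assert back.labels == fit.labels
        assert back.method == fit.method
        assert back.aic == pytest.approx(fit.aic)


class TestInformationCriteria:
    def test_closed_form_one_edge_network(self):
        g = nx.empty_graph(["A", "B", "C"])
        g.add_edge("A", "B")
        fit = exact_mle(g, parse_formula("edges"))
        ll = math.log((1 / 3) * (2 / 3) ** 2)
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(2 - 2 * ll, abs=1e-4)
        assert bic == pytest.approx(math.log(3) - 2 * ll, abs=1e-4)

    def test_triad_model_beats_restriction_on_planted_triads(self):
        """Graphs sampled at strong gwesp theta prefer the triad model by AIC."""
        rng = np.random.default_rng(4)
        cov = {
            f"v{k:02d}": {"size": float(rng.integers(2, 40)), "count": float(rng.integers(1, 9))}
            for k in range(12)
        }
        graphs = sample_networks(
            model1(), [-3.0, 1.5, 0.0, 0.0], covariates=cov,
            n_samples=8, thin=800, burn_in=8000, seed=21,
        )
        wins = losses = 0
        for k, g in enumerate(graphs):
            full = mcmle(g, model1(), McmcControl(seed=100 + k, n_samples=2000))
            restricted = mcmle(g, model1A())
            if not (full.converged and restricted.estimable):
                continue
            if full.log_likelihood is None or restricted.log_likelihood is None:
                continue
            wins += full.aic < restricted.aic
            losses += full.aic >= restricted.aic
        assert wins > losses
        assert wins >= 4


class TestFallbackInit:
    def test_quasi_separated_mple_still_yields_converged_mcmle(self):
        # dense small graph where the gwesp pseudolikelihood separates
        g = nx.relabel_nodes(nx.gnp_random_graph(6, 0.5, seed=3), str)
        spec = parse_formula("edges + gwesp(0.25, fixed)")
        init = mple(g, spec)
        fit = mcmle(g, spec, McmcControl(seed=2, n_samples=2000))
        assert fit.converged
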