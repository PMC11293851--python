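"""Cross-survey aggregation into species, phylum, site and diversity summaries."""

import numpy as np
import pytest

from benthicnet.diversity import (
    classify_preferences,
    collect_species_effects,
    diversity_proportions,
    phylum_aggregate,
    site_gwesp_summary,
)
from benthicnet.ergm.fit import ErgmFit
from benthicnet.ergm.model import model1, model2
from benthicnet.gof import FitBundle, GofReport
from benthicnet.transect import SpeciesAttributeTable


def fake_model2_fit(species_z: dict[str, tuple[float, float]]) -> ErgmFit:
    """A species-factor fit with given (coefficient, z) per non-reference species.

    Standard errors are back-computed as |theta / z|, so the fit's z_values
    reproduce the requested magnitudes (signs follow the coefficients).
    """
    labels = ["edges"] + [f"nodefactor.vertex.names.{s}" for s in sorted(species_z)]
    theta = np.array([-1.0] + [species_z[s][0] for s in sorted(species_z)])
    z = np.array([1.0] + [species_z[s][1] for s in sorted(species_z)])
    se = np.abs(theta) / np.maximum(np.abs(z), 1e-9)
    se[np.abs(theta) < 1e-12] = 1e6  # zero coefficient: huge uncertainty
    return ErgmFit(
        spec=model2(),
        labels=tuple(labels),
        theta=theta,
        standard_errors=se,
        observed_stats=np.zeros(len(labels)),
        n_vertices=len(species_z) + 1,
        log_likelihood=-10.0,
        log_normalizer=0.0,
        converged=True,
        method="mple",
    )


def fake_model1_fit(gwesp_coef: float) -> ErgmFit:
    labels = ("edges", "gwesp.fixed.0.25", "nodecov.size", "nodecov.count")
    return ErgmFit(
        spec=model1(),
        labels=labels,
        theta=np.array([-2.0, gwesp_coef, 0.01, 0.1]),
        standard_errors=np.ones(4),
        observed_stats=np.array([50.0, 60.0, 500.0, 100.0]),
        n_vertices=16,
        log_likelihood=-40.0,
        log_normalizer=5.0,
        converged=True,
        method="mcmle",
    )


def fake_gof(labels, p_values, seed=0) -> GofReport:
    p = np.asarray(p_values, dtype=float)
    return GofReport(
        labels=tuple(labels),
        observed=np.zeros(len(p)),
        sim_mean=np.zeros(len(p)),
        sim_sd=np.ones(len(p)),
        p_values=p,
        n_sim=100,
        seed=seed,
    )


def make_bundle(
    site: str,
    species: list[str],
    species_z: dict[str, tuple[float, float]],
    gwesp_coef: float | None = 0.5,
    gof_edges_p: float = 0.9,
    gof_gwesp_p: float = 0.9,
    seed: int = 0,
) -> FitBundle:
    fallback = gwesp_coef is None
    cov_fit = fake_model1_fit(gwesp_coef) if not fallback else None
    gof_reports = {}
    if not fallback:
        gof_reports["model1"] = fake_gof(
            cov_fit.labels, [gof_edges_p, gof_gwesp_p, 0.9, 0.9], seed
        )
    m2 = fake_model2_fit(species_z)
    return FitBundle(
        metadata={"survey_id": site, "site": site, "depth": 7.0,
                  "aspect": "photophilous", "species": species},
        n_vertices=len(species),
        n_simple_edges=30,
        n_multi_edges=150,
        covariate_fit=cov_fit,
        fallback=fallback,
        model2_fit=m2,
        gof_reports=gof_reports,
        degeneracy=None,
        mcmc=None,
        seed=seed,
    )


SPECIES = [f"S{k}" for k in range(8)]


def standard_bundles(n=10):
    """n bundles where S1 is consistently near-zero-z and S2 is noisy."""
    bundles = []
    for k in range(n):
        z = {
            "S1": (2.0, 0.01 if k % 2 == 0 else -0.02),
            "S2": (0.5, 0.8 + 0.1 * k),
            "S3": (-1.5, -0.4),
        }
        bundles.append(make_bundle(f"SITE{k % 3}", SPECIES, z, gwesp_coef=0.4 - 0.1 * k, seed=k))
    return bundles


class TestCollectSpeciesEffects:
    def test_occurrence_threshold_excludes_rare_species(self):
        bundles = standard_bundles(4)
        # S9 occurs in only 3 networks
        for b in bundles[:3]:
            b.metadata["species"] = b.metadata["species"] + ["S9"]
        table = collect_species_effects(bundles, min_occurrences=5)
        assert "S9" not in table.effects
        assert table.all_species["S9"] == 3

    def test_effects_pooled_per_species(self):
        table = collect_species_effects(standard_bundles(10), min_occurrences=5)
        assert table.effects["S1"].n_networks == 10
        assert len(table.effects["S1"].z_values) == 10
        assert table.effects["S1"].median_abs_z < 0.05
        assert table.effects["S2"].median_abs_z > 0.5

    def test_empty_bundle_list_rejected(self):
        with pytest.raises(ValueError, match="model-2"):
            collect_species_effects([])

    def test_order_invariance(self):
        bundles = standard_bundles(8)
        t1 = collect_species_effects(bundles)
        t2 = collect_species_effects(list(reversed(bundles)))
        assert t1.to_frame().sort_values("code").reset_index(drop=True).equals(
            t2.to_frame().sort_values("code").reset_index(drop=True)
        )


class TestClassifyPreferences:
    def test_low_z_with_positive_coefficient_is_homophily(self):
        table = classify_preferences(collect_species_effects(standard_bundles(10)))
        assert table.effects["S1"].label == "positive homophily"
        assert table.effects["S2"].label == "none"

    def test_negative_coefficient_low_z_is_avoidance(self):
        bundles = [
            make_bundle(f"X{k}", SPECIES, {"S1": (-2.0, 0.001), "S2": (0.1, 1.0)}, seed=k)
            for k in range(8)
        ]
        table = classify_preferences(collect_species_effects(bundles))
        assert table.effects["S1"].label == "negative/avoidance"

    def test_wald_rule_flags_large_z(self):
        bundles = [
            make_bundle(f"X{k}", SPECIES, {"S1": (2.0, 3.0), "S2": (0.1, 0.5)}, seed=k)
            for k in range(8)
        ]
        table = classify_preferences(collect_species_effects(bundles), rule="wald")
        assert table.effects["S1"].label == "positive homophily"
        assert table.effects["S2"].label == "none"

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            classify_preferences(collect_species_effects(standard_bundles(6)), rule="x")


class TestPhylumAggregate:
    def test_unweighted_means(self):
        bundles = [
            make_bundle(f"X{k}", SPECIES, {"S1": (-2.0, 0.1), "S2": (-6.0, 0.3)}, seed=k)
            for k in range(8)
        ]
        attrs = SpeciesAttributeTable(
            [("S1", "s1", "Porifera", None), ("S2", "s2", "Porifera", None)]
        )
        table = collect_species_effects(bundles)
        summary = phylum_aggregate(table, attrs).to_frame().set_index("phylum")
        assert summary.loc["Porifera", "mean_coefficient"] == pytest.approx(-4.0)
        assert summary.loc["Porifera", "n_species"] == 2

    def test_species_without_phylum_grouped_unknown(self):
        bundles = standard_bundles(8)
        table = collect_species_effects(bundles)
        summary = phylum_aggregate(table, SpeciesAttributeTable()).to_frame()
        assert list(summary["phylum"]) == ["unknown"]


class TestDiversityProportions:
    def test_counts_follow_qualification_rule(self):
        bundles = []
        # 68 qualifying, 10 failing GoF, 7 fallback -> 68/85
        for k in range(68):
            bundles.append(make_bundle(f"A{k}", SPECIES, {"S1": (1.0, 0.5)}, seed=k))
        for k in range(10):
            bundles.append(
                make_bundle(f"B{k}", SPECIES, {"S1": (1.0, 0.5)}, gof_gwesp_p=0.01, seed=k)
            )
        for k in range(7):
            bundles.append(
                make_bundle(f"C{k}", SPECIES, {"S1": (1.0, 0.5)}, gwesp_coef=None, seed=k)
            )
        table = classify_preferences(collect_species_effects(bundles))
        report = diversity_proportions(bundles, table)
        assert report.n_networks == 85
        assert report.n_networks_with_triad_support == 68
        assert report.proportion == pytest.approx(0.8)

    def test_all_fallback_gives_zero_proportion(self):
        bundles = [
            make_bundle(f"C{k}", SPECIES, {"S1": (1.0, 0.5)}, gwesp_coef=None, seed=k)
            for k in range(9)
        ]
        table = classify_preferences(collect_species_effects(bundles))
        report = diversity_proportions(bundles, table)
        assert report.proportion == 0.0

    def test_proportions_bounded_and_counts_consistent(self):
        bundles = standard_bundles(12)
        table = classify_preferences(collect_species_effects(bundles))
        report = diversity_proportions(bundles, table)
        assert 0.0 <= report.proportion <= 1.0
        assert 0.0 <= report.proportion_species_preferential <= 1.0
        assert report.n_species_preferential_strict <= report.n_species_preferential
        assert report.n_species_total == len(table.all_species)


class TestSiteGwespSummary:
    def test_site_medians_and_signs(self):
        bundles = (
            [make_bundle("HI", SPECIES, {"S1": (1.0, 0.5)}, gwesp_coef=0.8, seed=k) for k in range(3)]
            + [make_bundle("LO", SPECIES, {"S1": (1.0, 0.5)}, gwesp_coef=-0.6, seed=k) for k in range(3)]
        )
        summary = site_gwesp_summary(bundles)
        assert summary["HI"]["median"] == pytest.approx(0.8)
        assert summary["LO"]["median"] == pytest.approx(-0.6)
        assert summary["HI"]["n_positive"] == 3

    def test_fallback_only_site_has_empty_list(self):
        bundles = [
            make_bundle("OK", SPECIES, {"S1": (1.0, 0.5)}, gwesp_coef=0.3),
            make_bundle("NA", SPECIES, {"S1": (1.0, 0.5)}, gwesp_coef=None),
        ]
        summary = site_gwesp_summary(bundles)
        assert summary["NA"]["coefficients"] == []
        assert summary["NA"]["median"] is None

    def test_single_network_site(self):
        bundles = [make_bundle("ONE", SPECIES, {"S1": (1.0, 0.5)}, gwesp_coef=0.3)]
        summary = site_gwesp_summary(bundles)
        assert summary["ONE"]["n"] == 1

    def test_no_triad_fits_rejected(self):
        bundles = [make_bundle("NA", SPECIES, {"S1": (1.0, 0.5)}, gwesp_coef=None)]
        with pytest.raises(ValueError):
            site_gwesp_summary(bundles)
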