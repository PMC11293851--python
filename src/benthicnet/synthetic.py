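"""Synthetic transects and survey campaigns with planted, known structure.

The generator emulates the study setting — 500 one-centimetre observation
points per transect, a survey design of sites x five depths x reef-wall
aspects, run-length-structured species sequences — while planting the
statistical signals the pipeline is meant to recover: pairwise affinities
(homophily), per-site triangle-closing propensity, and site/depth effects.
Everything is driven by a master seed through stable per-record hashing, so
campaigns are bit-reproducible and insertion-order independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .transect import SpeciesAttributeTable, TransectRecord

__all__ = [
    "CommunityModel",
    "SiteSpec",
    "CampaignDesign",
    "PlantedTruth",
    "make_community",
    "sample_contact_graph",
    "simulate_transect",
    "simulate_campaign",
    "planted_campaign_design",
    "score_recovery",
    "derive_seed",
]

DEFAULT_DEPTHS = (2.0, 4.0, 7.0, 14.0, 23.0)
_PHYLA = (
    "Porifera",
    "Cnidaria",
    "Bryozoa",
    "Chordata",
    "Echinodermata",
    "Annelida",
    "Rhodophyta",
)


def derive_seed(master: int, *keys) -> int:
    """Stable child seed from a master seed and hashable key parts."""
    tag = "|".join(str(k) for k in keys).encode()
    return (zlib.crc32(tag) ^ (int(master) * 2654435761)) % (2**31)


@dataclass
class CommunityModel:
    """Generative model of one transect community.

    ``affinity`` is a symmetric positive matrix: 1 is neutral, >1 attracts
    (the pair abuts more than abundance predicts), <1 avoids; the diagonal
    is ignored (a run never borders itself).  ``triad_propensity`` is the
    probability that the next run closes a triangle with the last two
    distinct species.  Run lengths are geometric with mean ``run_mean`` cm.
    """

    species: tuple[str, ...]
    abundance: np.ndarray
    affinity: np.ndarray
    triad_propensity: float = 0.0
    run_mean: float = 3.0
    transect_length: int = 500
    phylum: dict[str, str] = field(default_factory=dict)
    # optional latent contact graph: which species pairs can share a boundary.
    # None = all pairs.  Off-graph transitions are damped to contact_leak.
    contact: np.ndarray | None = None
    contact_leak: float = 0.005

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.affinity = np.asarray(self.affinity, dtype=float)
        if not np.isclose(self.abundance.sum(), 1.0):
            raise ValueError("abundances must sum to 1")
        if (self.affinity <= 0).any():
            raise ValueError("affinities must be positive")
        if not np.allclose(self.affinity, self.affinity.T):
            raise ValueError("affinity matrix must be symmetric")
        if not (0.0 <= self.triad_propensity < 1.0):
            raise ValueError("triad propensity must be in [0, 1)")
        if self.run_mean < 1.0:
            raise ValueError("mean run length must be >= 1 cm")

    def with_overrides(
        self,
        triad_propensity: float | None = None,
        planted_pairs: Sequence[tuple[str, str, float]] | None = None,
        contact: np.ndarray | None = None,
    ) -> "CommunityModel":
        affinity = self.affinity.copy()
        new_contact = contact if contact is not None else (
            None if self.contact is None else self.contact.copy()
        )
        index = {s: k for k, s in enumerate(self.species)}
        if planted_pairs:
            for a, b, strength in planted_pairs:
                affinity[index[a], index[b]] = strength
                affinity[index[b], index[a]] = strength
                if new_contact is not None:  # a planted pair is always in contact
                    new_contact[index[a], index[b]] = True
                    new_contact[index[b], index[a]] = True
        return CommunityModel(
            species=self.species,
            abundance=self.abundance.copy(),
            affinity=affinity,
            triad_propensity=(
                self.triad_propensity if triad_propensity is None else triad_propensity
            ),
            run_mean=self.run_mean,
            transect_length=self.transect_length,
            phylum=dict(self.phylum),
            contact=new_contact,
            contact_leak=self.contact_leak,
        )

    def attribute_table(self) -> SpeciesAttributeTable:
        return SpeciesAttributeTable(
            (code, code, self.phylum.get(code, "unknown"), None) for code in self.species
        )


def make_community(
    n_species: int = 35,
    planted_pairs: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    *,
    triad_propensity: float = 0.0,
    run_mean: float = 3.0,
    transect_length: int = 500,
    dirichlet_concentration: float = 0.2,
) -> CommunityModel:
    """Draw a community: Dirichlet abundances plus planted pair affinities.

    The low default concentration gives the strongly skewed abundances of
    real benthic pools: a 35-species pool then shows roughly 14-27 species
    on any one 500 cm transect, the rest being too rare to appear.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    species = tuple(f"SP{k:02d}" for k in range(n_species))
    abundance = rng.dirichlet(np.full(n_species, dirichlet_concentration))
    affinity = np.ones((n_species, n_species))
    for i, j, strength in planted_pairs:
        if not (0 <= i < n_species and 0 <= j < n_species) or i == j:
            raise ValueError(f"planted pair ({i}, {j}) out of range")
        if strength <= 0:
            raise ValueError("planted strengths must be positive")
        affinity[i, j] = strength
        affinity[j, i] = strength
    phylum = {code: _PHYLA[rng.integers(len(_PHYLA))] for code in species}
    return CommunityModel(
        species=species,
        abundance=abundance,
        affinity=affinity,
        triad_propensity=triad_propensity,
        run_mean=run_mean,
        transect_length=transect_length,
        phylum=phylum,
    )


def sample_contact_graph(
    n_species: int,
    triad_coef: float,
    seed: int,
    *,
    target_degree: float = 3.5,
    planted_edges: Sequence[tuple[int, int]] = (),
    n_adapt: int = 6,
) -> np.ndarray:
    """Draw a latent contact graph from an edges + gwesp(0.25) graph model.

    The contact graph encodes which species pairs can share a boundary at a
    site; its triad coefficient is the planted truth the fitting stage
    should recover.  The edges coefficient is calibrated by a short seeded
    adaptation so the mean degree lands near ``target_degree`` regardless
    of ``triad_coef``.  Planted pair edges are forced on afterwards.
    """
    from .ergm.fit import sample_networks
    from .ergm.model import EdgesTerm, GwespTerm, ModelSpec

    spec = ModelSpec((EdgesTerm(), GwespTerm(0.25)))
    # beyond ~1.5 the edges+gwesp(0.25) family is degenerate (bimodal
    # near-empty/near-complete) and no edges coefficient reaches the
    # target density, so the planted coefficient is capped there
    triad_coef = min(max(float(triad_coef), 0.0), 1.5)
    n = n_species
    D = n * (n - 1) / 2.0
    target_edges = target_degree * n / 2.0
    d0 = min(max(target_edges / D, 0.01), 0.99)
    theta_e = float(np.log(d0 / (1.0 - d0)))
    A = None
    # start each chain at the target density: under strong triad
    # coefficients the edge distribution is bimodal and a cold (empty)
    # start can stay trapped in the near-empty mode
    import networkx as nx

    init = nx.gnm_random_graph(n, int(round(target_edges)), seed=seed % (2**31))
    init = nx.relabel_nodes(init, lambda k: f"v{k:02d}")
    for it in range(n_adapt):
        graphs, stats = sample_networks(
            spec,
            [theta_e, triad_coef],
            covariates={f"v{k:02d}": {} for k in range(n)},
            n_samples=16,
            burn_in=int(20 * D),
            thin=int(2 * D),
            seed=derive_seed(seed, "contact", it),
            initial=init,
            return_stats=True,
        )
        mean_edges = float(stats[:, 0].mean())
        # at strong triad coefficients the edge distribution is bimodal;
        # keep the sampled graph closest to the target edge count
        best = int(np.argmin(np.abs(stats[:, 0] - target_edges)))
        A = np.zeros((n, n), dtype=bool)
        for u, v in graphs[best].edges():
            i, j = int(u[1:]), int(v[1:])
            A[i, j] = A[j, i] = True
        if abs(mean_edges - target_edges) <= 0.1 * target_edges:
            break
        theta_e += float(np.log((target_edges + 1.0) / (mean_edges + 1.0)))
    assert A is not None
    for i, j in planted_edges:
        A[i, j] = A[j, i] = True
    return A


def simulate_transect(
    model: CommunityModel,
    seed: int = 0,
    *,
    survey_id: str = "SYN",
    site: str = "SYN",
    depth: float = 7.0,
    aspect: str = "photophilous",
) -> TransectRecord:
    """Generate one per-centimetre transect from the community model.

    Sequential process: draw the first species by abundance; draw each run
    length geometric(mean ``run_mean``) truncated to the remaining tape;
    choose the next species with probability proportional to
    abundance x affinity to the previous species — except that, with
    probability ``triad_propensity``, the next run instead closes a
    triangle: it is drawn uniformly from the species already adjacent (so
    far along the tape) to BOTH of the last two distinct species, when any
    exist.
    """
    rng = np.random.default_rng(seed)
    n = len(model.species)
    index = {s: k for k, s in enumerate(model.species)}
    codes: list[str] = []
    adjacent: set[frozenset[int]] = set()
    prev: int | None = None
    prev2: int | None = None
    p_run = 1.0 / model.run_mean
    remaining = model.transect_length
    while remaining > 0:
        if prev is None:
            current = int(rng.choice(n, p=model.abundance))
        else:
            current = None
            if prev2 is not None and rng.random() < model.triad_propensity:
                # close a triangle: the next run must create a NEW adjacency
                # (k, prev) while k already borders the previous-but-one
                # species, completing the triangle k - prev - prev2
                closers = [
                    k
                    for k in range(n)
                    if k != prev
                    and k != prev2
                    and frozenset((k, prev2)) in adjacent
                    and frozenset((k, prev)) not in adjacent
                    and (model.contact is None or model.contact[k, prev])
                ]
                if closers:
                    current = int(closers[rng.integers(len(closers))])
            if current is None:
                weights = model.abundance * model.affinity[prev]
                if model.contact is not None:
                    damp = np.where(model.contact[prev], 1.0, model.contact_leak)
                    weights = weights * damp
                weights[prev] = 0.0
                total = weights.sum()
                if total <= 0:  # degenerate affinities: fall back to uniform
                    weights = np.ones(n)
                    weights[prev] = 0.0
                    total = weights.sum()
                current = int(rng.choice(n, p=weights / total))
            adjacent.add(frozenset((current, prev)))
        length = min(int(rng.geometric(p_run)), remaining)
        codes.extend([model.species[current]] * length)
        remaining -= length
        prev2, prev = prev, current
    return TransectRecord(
        survey_id=survey_id,
        site=site,
        depth=depth,
        aspect=aspect,
        codes=tuple(codes),
    )


@dataclass
class SiteSpec:
    """One survey site: label, aspect, and its planted overrides."""

    name: str
    aspect: str = "photophilous"
    triad_propensity: float | None = None
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    n_surveys: int = 1


@dataclass
class CampaignDesign:
    """A survey campaign: sites x depths, with per-site planted structure."""

    sites: tuple[SiteSpec, ...]
    depths: tuple[float, ...] = DEFAULT_DEPTHS

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("campaign needs at least one site")
        if any(d <= 0 for d in self.depths):
            raise ValueError("depths must be positive")

    @property
    def n_records(self) -> int:
        return sum(s.n_surveys for s in self.sites) * len(self.depths)


@dataclass
class PlantedTruth:
    """Ground truth of a simulated campaign, for recovery scoring."""

    species: tuple[str, ...]
    planted_pairs: tuple[tuple[str, str, float], ...]
    site_triad: dict[str, float]
    depth_trend: float = 0.0

    @property
    def planted_species(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.planted_pairs:
            out.update((a, b))
        return out


def planted_campaign_design(
    n_surveys: int = 17,
    *,
    triad_propensity: float = 0.3,
    triad_fraction: float = 0.5,
    depths: Sequence[float] = DEFAULT_DEPTHS,
) -> CampaignDesign:
    """The default planted design: half the sites triad-rich, half neutral.

    Mirrors the study layout of one transect per (survey, depth) with five
    depths; survey sites alternate sunlit and shaded aspects.
    """
    sites = []
    n_triad = round(n_surveys * triad_fraction)
    for k in range(n_surveys):
        sites.append(
            SiteSpec(
                name=f"SITE{k:02d}",
                aspect="photophilous" if k % 2 == 0 else "sciaphilous",
                triad_propensity=triad_propensity if k < n_triad else 0.0,
            )
        )
    return CampaignDesign(sites=tuple(sites), depths=tuple(depths))


def simulate_campaign(
    design: CampaignDesign,
    model: CommunityModel,
    seed: int = 0,
    *,
    latent_contact: bool = True,
    obligate_pairs: bool = False,
    gwesp_scale: float = 4.0,
    target_degree: float = 3.5,
    pair_abundance_boost: float = 5.0,
    site_abundance_sigma: float = 0.3,
) -> tuple[list[TransectRecord], PlantedTruth]:
    """Generate one record per (site, survey, depth) with planted truth.

    With ``latent_contact`` (the default), each site receives a latent
    contact graph drawn from an edges + gwesp(0.25) graph model whose triad
    coefficient is ``gwesp_scale`` times the site's triad propensity — the
    quantity the fitting stage should recover — while the mean contact
    degree is held near ``target_degree`` across sites.  With
    ``obligate_pairs``, planted pairs additionally behave as obligate
    associates (epibiont-style): their contact rows are restricted to the
    partner and their abundance is floored at ``pair_abundance_boost``
    times the pool mean.  This sharpens the species-level signature but
    shrinks and distorts the networks, so it is off by default.
    ``site_abundance_sigma`` applies a persistent log-normal per-site
    jitter to species abundances (beta diversity between sites), which is
    what makes site identity a genuine driver of between-network
    differences.
    Per-record seeds are derived by stable hashing of (site, survey, depth)
    from the master seed, so the output does not depend on iteration order
    and identical seeds give bit-identical campaigns.
    """
    records: list[TransectRecord] = []
    site_triad: dict[str, float] = {}
    planted: dict[tuple[str, str], float] = {}
    index = {s: k for k, s in enumerate(model.species)}
    n_sp = len(model.species)
    base_planted_idx = [
        (i, j)
        for i in range(n_sp)
        for j in range(i + 1, n_sp)
        if model.affinity[i, j] != 1.0
    ]
    partner_of: dict[int, int] = {}
    for i, j in base_planted_idx:
        partner_of[i] = j
        partner_of[j] = i
    if obligate_pairs and partner_of:
        abundance = model.abundance.copy()
        floor = pair_abundance_boost * abundance.mean()
        for i in partner_of:
            abundance[i] = max(abundance[i], floor)
        model = CommunityModel(
            species=model.species,
            abundance=abundance / abundance.sum(),
            affinity=model.affinity.copy(),
            triad_propensity=model.triad_propensity,
            run_mean=model.run_mean,
            transect_length=model.transect_length,
            phylum=dict(model.phylum),
            contact=model.contact,
            contact_leak=model.contact_leak,
        )
    for site in design.sites:
        contact = None
        pi_site = (
            site.triad_propensity
            if site.triad_propensity is not None
            else model.triad_propensity
        )
        if latent_contact:
            forced = base_planted_idx + [
                tuple(sorted((index[a], index[b]))) for a, b, _ in site.planted_pairs
            ]
            contact = sample_contact_graph(
                n_sp,
                gwesp_scale * pi_site,
                derive_seed(seed, "site-contact", site.name),
                target_degree=target_degree,
                planted_edges=forced,
            )
            if obligate_pairs:
                for i, j in partner_of.items():
                    contact[i, :] = False
                    contact[:, i] = False
                for i, j in partner_of.items():
                    contact[i, j] = contact[j, i] = True
        site_model = model.with_overrides(
            triad_propensity=site.triad_propensity,
            planted_pairs=site.planted_pairs or None,
            contact=contact,
        )
        if site_abundance_sigma > 0:
            rng = np.random.default_rng(derive_seed(seed, "abundance", site.name))
            jitter = np.exp(site_abundance_sigma * rng.standard_normal(n_sp))
            abundance = site_model.abundance * jitter
            site_model.abundance = abundance / abundance.sum()
        site_triad[site.name] = site_model.triad_propensity
        for a, b, strength in site.planted_pairs:
            planted[tuple(sorted((a, b)))] = strength
        for survey in range(site.n_surveys):
            survey_id = site.name if site.n_surveys == 1 else f"{site.name}.{survey}"
            for depth in design.depths:
                records.append(
                    simulate_transect(
                        site_model,
                        seed=derive_seed(seed, site.name, survey, depth),
                        survey_id=survey_id,
                        site=site.name,
                        depth=depth,
                        aspect=site.aspect,
                    )
                )
    # globally planted pairs (present in the base model) are part of truth too
    base_pairs = []
    idx = {k: s for k, s in enumerate(model.species)}
    n = len(model.species)
    for i in range(n):
        for j in range(i + 1, n):
            if model.affinity[i, j] != 1.0:
                base_pairs.append((idx[i], idx[j], float(model.affinity[i, j])))
    for a, b, strength in base_pairs:
        planted.setdefault(tuple(sorted((a, b))), strength)
    truth = PlantedTruth(
        species=model.species,
        planted_pairs=tuple((a, b, s) for (a, b), s in sorted(planted.items())),
        site_triad=site_triad,
    )
    return records, truth


def score_recovery(
    truth: PlantedTruth,
    *,
    preferential: set[str] | None = None,
    species_table=None,
    site_scores: Mapping[str, float] | None = None,
    site_gwesp: Mapping[str, Mapping] | None = None,
    influence_shares: Mapping[str, float] | None = None,
) -> dict:
    """Score pipeline output against the planted truth.

    ``preferential`` (or the labels of a classified species-effect table)
    is compared against the planted-pair species for sensitivity and
    specificity; ``site_scores`` (or the medians of a site gwesp summary)
    is rank-correlated with the planted per-site triad propensities; the
    argmax of ``influence_shares`` is checked against "site".
    """
    out: dict = {}
    if species_table is not None and preferential is None:
        preferential = {
            code for code, eff in species_table.effects.items() if eff.label != "none"
        }
    if preferential is not None:
        unknown = preferential - set(truth.species)
        if unknown:
            raise ValueError(f"species not in the planted community: {sorted(unknown)}")
        positives = truth.planted_species
        negatives = set(truth.species) - positives
        tp = len(preferential & positives)
        tn = len(negatives - preferential)
        out["sensitivity"] = tp / len(positives) if positives else float("nan")
        out["specificity"] = tn / len(negatives) if negatives else float("nan")
    if site_gwesp is not None and site_scores is None:
        site_scores = {
            site: d["median"]
            for site, d in site_gwesp.items()
            if d.get("median") is not None
        }
    if site_scores is not None:
        common = sorted(set(site_scores) & set(truth.site_triad))
        if len(common) >= 2:
            rho = spearmanr(
                [truth.site_triad[s] for s in common],
                [site_scores[s] for s in common],
            ).statistic
            out["site_rank_correlation"] = float(rho)
    if influence_shares is not None:
        top = max(influence_shares, key=influence_shares.__getitem__)
        out["top_predictor"] = top
        out["top_predictor_is_site"] = top == "site"
    return out


def records_to_csv(records: Sequence[TransectRecord], path) -> None:
    """Write records in the long observation-table format the parser reads."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["survey_id", "site", "depth_m", "aspect", "position_cm", "species_code"]
        )
        for rec in records:
            for pos, code in enumerate(rec.codes, start=1):
                writer.writerow([rec.survey_id, rec.site, rec.depth, rec.aspect, pos, code])
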