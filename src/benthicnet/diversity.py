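"""Cross-survey aggregation: species preferences, phyla, sites, diversity.

Each fitted network contributes species-factor coefficients and z-values
(from the species model) and a shared-partner coefficient and its
goodness-of-fit p-value (from the triad model).  Aggregating across the
survey campaign yields:

- a species effect table: per-species distributions of coefficients and
  z-values with a preference classification,
- phylum-level means,
- per-site distributions of the shared-partner (triad) coefficient, and
- the co-occurrence social-diversity proportion: the fraction of networks
  whose formation is jointly captured by the edge and triad terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gof import FitBundle
from .transect import SpeciesAttributeTable

__all__ = [
    "SpeciesEffectTable",
    "PhylumSummary",
    "DiversityReport",
    "collect_species_effects",
    "classify_preferences",
    "phylum_aggregate",
    "diversity_proportions",
    "site_gwesp_summary",
]

_FACTOR_PREFIX = "nodefactor.vertex.names."


@dataclass
class SpeciesEffect:
    code: str
    n_networks: int  # networks in which the species occurs
    coefficients: list[float] = field(default_factory=list)
    z_values: list[float] = field(default_factory=list)
    label: str = "unclassified"

    @property
    def median_z(self) -> float:
        return float(np.median(self.z_values)) if self.z_values else float("nan")

    @property
    def median_abs_z(self) -> float:
        return float(np.median(np.abs(self.z_values))) if self.z_values else float("nan")

    @property
    def mean_coefficient(self) -> float:
        return float(np.mean(self.coefficients)) if self.coefficients else float("nan")

    @property
    def median_coefficient(self) -> float:
        return float(np.median(self.coefficients)) if self.coefficients else float("nan")


@dataclass
class SpeciesEffectTable:
    """Per-species model-2 effect distributions across the campaign."""

    effects: dict[str, SpeciesEffect]
    n_bundles_used: int
    n_bundles_skipped: int
    min_occurrences: int
    all_species: dict[str, int]  # every observed species -> occurrence count

    def __len__(self) -> int:
        return len(self.effects)

    def species(self) -> list[str]:
        return sorted(self.effects)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in self.species():
            e = self.effects[code]
            rows.append(
                {
                    "code": code,
                    "n_networks": e.n_networks,
                    "mean_coefficient": e.mean_coefficient,
                    "median_coefficient": e.median_coefficient,
                    "median_z": e.median_z,
                    "median_abs_z": e.median_abs_z,
                    "label": e.label,
                }
            )
        return pd.DataFrame(rows)


def collect_species_effects(
    bundles: Sequence[FitBundle],
    attrs: SpeciesAttributeTable | None = None,
    min_occurrences: int = 5,
) -> SpeciesEffectTable:
    """Gather species-factor coefficients and z-values per species.

    A species contributes from every network where it occurs AND carries a
    factor coefficient (the per-network reference species has none).
    Species occurring in no more than ``min_occurrences`` networks are
    excluded from the reported table; occurrence counts for every species
    are kept in ``all_species``.  Bundles without an estimable species-model
    fit are skipped and counted.
    """
    occurrences: dict[str, int] = {}
    pooled: dict[str, SpeciesEffect] = {}
    used = 0
    skipped = 0
    for bundle in bundles:
        species = bundle.metadata.get("species", [])
        for code in species:
            occurrences[code] = occurrences.get(code, 0) + 1
        fit = bundle.model2_fit
        if fit is None or not fit.estimable:
            skipped += 1
            continue
        used += 1
        z = fit.z_values
        for lab, coef, zval in zip(fit.labels, fit.theta, z):
            if not lab.startswith(_FACTOR_PREFIX):
                continue
            code = lab[len(_FACTOR_PREFIX) :]
            eff = pooled.setdefault(code, SpeciesEffect(code=code, n_networks=0))
            eff.coefficients.append(float(coef))
            if np.isfinite(zval):
                eff.z_values.append(float(zval))
    if used == 0:
        raise ValueError("no estimable model-2 fits among the supplied bundles")
    for code, eff in pooled.items():
        eff.n_networks = occurrences.get(code, len(eff.coefficients))
    effects = {
        code: eff
        for code, eff in pooled.items()
        if occurrences.get(code, 0) > min_occurrences and eff.z_values
    }
    return SpeciesEffectTable(
        effects=effects,
        n_bundles_used=used,
        n_bundles_skipped=skipped,
        min_occurrences=min_occurrences,
        all_species=occurrences,
    )


def classify_preferences(
    table: SpeciesEffectTable,
    z_threshold: float = 0.05,
    rule: str = "low-z",
) -> SpeciesEffectTable:
    """Label each species by the consistency of its attachment preference.

    Under the default ``low-z`` rule a species is preferential when the
    median |z| of its factor coefficient across networks falls below
    ``z_threshold`` — a near-zero z marks coefficients the fits place at the
    boundary of the parameter space, i.e. species whose neighbourhoods are
    so consistent the model cannot trade them off.  The sign of the median
    coefficient splits "positive homophily" from "negative/avoidance".  The
    conventional Wald reading (|z| > 1.96 significant) is available as
    ``rule="wald"``.
    """
    if not table.effects:
        raise ValueError("empty species effect table")
    for eff in table.effects.values():
        if rule == "low-z":
            preferential = eff.median_abs_z < z_threshold
        elif rule == "wald":
            preferential = eff.median_abs_z > 1.96
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if preferential:
            eff.label = (
                "positive homophily" if eff.median_coefficient > 0 else "negative/avoidance"
            )
        else:
            eff.label = "none"
    return table


@dataclass
class PhylumSummary:
    rows: pd.DataFrame  # phylum, mean_coefficient, mean_z, n_species

    def to_frame(self) -> pd.DataFrame:
        return self.rows


def phylum_aggregate(
    table: SpeciesEffectTable, attrs: SpeciesAttributeTable
) -> PhylumSummary:
    """Unweighted per-phylum means of species-level mean coefficient and z."""
    rows = []
    for code in table.species():
        eff = table.effects[code]
        rows.append(
            {
                "phylum": attrs.phylum(code),
                "code": code,
                "mean_coefficient": eff.mean_coefficient,
                "mean_z": float(np.mean(eff.z_values)) if eff.z_values else np.nan,
            }
        )
    if not rows:
        raise ValueError("no species with phylum information")
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("phylum")
        .agg(
            mean_coefficient=("mean_coefficient", "mean"),
            mean_z=("mean_z", "mean"),
            n_species=("code", "nunique"),
        )
        .reset_index()
    )
    return PhylumSummary(rows=agg)


@dataclass
class DiversityReport:
    """Campaign-level co-occurrence social-diversity summary."""

    n_networks: int
    n_networks_with_triad_support: int
    proportion: float
    n_species_total: int
    n_species_preferential: int
    n_species_preferential_strict: int
    proportion_species_preferential: float
    site_gwesp: dict  # site -> {"coefficients": [...], "median": float, ...}

    def to_dict(self) -> dict:
        return {
            "n_networks": self.n_networks,
            "n_networks_with_triad_support": self.n_networks_with_triad_support,
            "proportion": self.proportion,
            "n_species_total": self.n_species_total,
            "n_species_preferential": self.n_species_preferential,
            "n_species_preferential_strict": self.n_species_preferential_strict,
            "proportion_species_preferential": self.proportion_species_preferential,
            "site_gwesp": self.site_gwesp,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _triad_supported(bundle: FitBundle, gof_p_threshold: float) -> bool:
    """Does the triad model capture this network's formation?

    True iff the covariate model is the full triad model (no fallback), it
    converged, and both the edges and gwesp goodness-of-fit p-values exceed
    the threshold.
    """
    if bundle.fallback or bundle.covariate_fit is None:
        return False
    if not (bundle.covariate_fit.converged and bundle.covariate_fit.estimable):
        return False
    report = bundle.gof_reports.get("model1")
    if report is None:
        return False
    try:
        return (
            report.p_value("edges") > gof_p_threshold
            and report.p_value("gwesp") > gof_p_threshold
        )
    except KeyError:
        return False


def site_gwesp_summary(bundles: Sequence[FitBundle]) -> dict:
    """Per-site distribution of the shared-partner (triad) coefficient.

    Positive coefficients indicate a preference for triangle formation at
    the site, negative ones an aversion; sites where every fit fell back to
    the no-triad model are reported with an empty coefficient list.
    """
    if not any(not b.fallback and b.covariate_fit is not None for b in bundles):
        raise ValueError("no triad-model fits among the supplied bundles")
    sites: dict[str, list[float]] = {}
    for bundle in bundles:
        site = str(bundle.metadata.get("site", ""))
        sites.setdefault(site, [])
        coef = bundle.gwesp_coefficient()
        if coef is not None and np.isfinite(coef):
            sites[site].append(float(coef))
    out = {}
    for site in sorted(sites):
        coefs = sites[site]
        out[site] = {
            "coefficients": coefs,
            "n": len(coefs),
            "median": float(np.median(coefs)) if coefs else None,
            "n_positive": int(sum(c > 0 for c in coefs)),
            "n_negative": int(sum(c < 0 for c in coefs)),
        }
    return out


def diversity_proportions(
    bundles: Sequence[FitBundle],
    species_table: SpeciesEffectTable,
    gof_p_threshold: float = 0.05,
    strict_z: float = 0.005,
) -> DiversityReport:
    """Campaign-level proportions of structured networks and species.

    A network counts toward co-occurrence social diversity when the triad
    model (not the fallback) converged and both its edge and shared-partner
    terms pass goodness-of-fit.  The species proportion uses the loose
    preferential count; a strict count additionally requires positive
    homophily with median |z| below ``strict_z``.
    """
    if not bundles:
        raise ValueError("no bundles supplied")
    supported = sum(_triad_supported(b, gof_p_threshold) for b in bundles)
    labels = [table_eff.label for table_eff in species_table.effects.values()]
    if any(lab == "unclassified" for lab in labels):
        classify_preferences(species_table)
    preferential = [
        e for e in species_table.effects.values() if e.label != "none"
    ]
    strict = [
        e
        for e in preferential
        if e.label == "positive homophily" and e.median_abs_z <= strict_z
    ]
    n_total = len(species_table.all_species)
    try:
        site_summary = site_gwesp_summary(bundles)
    except ValueError:
        site_summary = {}
    return DiversityReport(
        n_networks=len(bundles),
        n_networks_with_triad_support=int(supported),
        proportion=supported / len(bundles),
        n_species_total=n_total,
        n_species_preferential=len(preferential),
        n_species_preferential_strict=len(strict),
        proportion_species_preferential=len(preferential) / n_total if n_total else 0.0,
        site_gwesp=site_summary,
    )
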