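"""Simulation-based goodness-of-fit, degeneracy detection, and fallback fits.

A fitted model is judged by simulating networks at the fitted coefficients
and comparing their statistics with the observed network.  Each term gets a
two-sided Monte-Carlo p-value with add-one correction,

    r = (1 + #{simulated >= observed}) / (n_sim + 1),  p = min(1, 2 min(r, 1-r)),

so p is never exactly 0 and a HIGH p means the simulated distribution is
centred on the observed value, i.e. the term captures how the network
formed.  Degenerate fits (mass piled on near-empty or near-complete graphs)
are detected and trigger the fallback from the triad model to its
no-triad restriction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .transect import BenthicNetwork
from .ergm.fit import ErgmFit, McmcControl, mcmle, mple, simulate_statistics
from .ergm.model import ModelSpec, model1, model1A, model2

__all__ = [
    "GofReport",
    "DegeneracyDiagnostics",
    "McmcDiagnostics",
    "FitBundle",
    "gof",
    "detect_degeneracy",
    "mcmc_diagnostics",
    "fit_with_fallback",
]


def _degree_counts(A: np.ndarray) -> np.ndarray:
    deg = A.sum(axis=1)
    return np.bincount(deg.astype(int), minlength=A.shape[0])


def _esp_counts(A: np.ndarray) -> np.ndarray:
    """Edgewise shared-partner histogram: entry k = edges with k common nbrs."""
    n = A.shape[0]
    out = np.zeros(max(n - 1, 1), dtype=int)
    Af = A.astype(np.int64)
    common = Af @ Af
    ii, jj = np.nonzero(np.triu(A, 1))
    for i, j in zip(ii, jj):
        out[common[i, j]] += 1
    return out


@dataclass
class GofReport:
    """Per-term Monte-Carlo goodness-of-fit for one fitted model."""

    labels: tuple[str, ...]
    observed: np.ndarray
    sim_mean: np.ndarray
    sim_sd: np.ndarray
    p_values: np.ndarray
    n_sim: int
    seed: int
    degree_observed: list[int] = field(default_factory=list)
    degree_sim_mean: list[float] = field(default_factory=list)
    esp_observed: list[int] = field(default_factory=list)
    esp_sim_mean: list[float] = field(default_factory=list)

    def p_value(self, label_prefix: str) -> float:
        for lab, p in zip(self.labels, self.p_values):
            if lab.startswith(label_prefix):
                return float(p)
        raise KeyError(f"no term labelled {label_prefix!r} in {self.labels}")

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "observed": [float(v) for v in self.observed],
            "sim_mean": [float(v) for v in self.sim_mean],
            "sim_sd": [float(v) for v in self.sim_sd],
            "p_values": [float(v) for v in self.p_values],
            "n_sim": self.n_sim,
            "seed": self.seed,
            "degree_observed": list(map(int, self.degree_observed)),
            "degree_sim_mean": [float(v) for v in self.degree_sim_mean],
            "esp_observed": list(map(int, self.esp_observed)),
            "esp_sim_mean": [float(v) for v in self.esp_sim_mean],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GofReport":
        return cls(
            labels=tuple(d["labels"]),
            observed=np.asarray(d["observed"], float),
            sim_mean=np.asarray(d["sim_mean"], float),
            sim_sd=np.asarray(d["sim_sd"], float),
            p_values=np.asarray(d["p_values"], float),
            n_sim=int(d["n_sim"]),
            seed=int(d["seed"]),
            degree_observed=list(d.get("degree_observed", [])),
            degree_sim_mean=list(d.get("degree_sim_mean", [])),
            esp_observed=list(d.get("esp_observed", [])),
            esp_sim_mean=list(d.get("esp_sim_mean", [])),
        )


def gof(
    fit: ErgmFit,
    network: BenthicNetwork,
    n_sim: int = 100,
    seed: int = 0,
    *,
    burn_in: int | None = None,
    thin: int | None = None,
) -> GofReport:
    """Simulate ``n_sim`` networks at the fitted theta and compare terms."""
    if n_sim < 1:
        raise ValueError(f"n_sim must be >= 1, got {n_sim}")
    stats, graphs = simulate_statistics(
        fit, network, n_sim, seed, burn_in=burn_in, thin=thin, collect_graphs=True
    )
    obs = fit.observed_stats
    r = (1.0 + np.sum(stats >= obs[None, :], axis=0)) / (n_sim + 1.0)
    p = np.minimum(1.0, 2.0 * np.minimum(r, 1.0 - r))

    from .ergm.stats import adjacency_matrix, network_arrays

    expanded, A_obs = network_arrays(network, fit.spec)
    deg_obs = _degree_counts(A_obs)
    esp_obs = _esp_counts(A_obs)
    deg_sim = np.zeros_like(deg_obs, dtype=float)
    esp_sim = np.zeros_like(esp_obs, dtype=float)
    for k in range(graphs.shape[0]):
        deg_sim += _degree_counts(graphs[k])
        esp_sim += _esp_counts(graphs[k])
    deg_sim /= max(graphs.shape[0], 1)
    esp_sim /= max(graphs.shape[0], 1)
    return GofReport(
        labels=fit.labels,
        observed=obs,
        sim_mean=stats.mean(axis=0),
        sim_sd=stats.std(axis=0, ddof=1) if n_sim > 1 else np.zeros_like(obs),
        p_values=p,
        n_sim=n_sim,
        seed=seed,
        degree_observed=list(deg_obs),
        degree_sim_mean=list(deg_sim),
        esp_observed=list(esp_obs),
        esp_sim_mean=list(esp_sim),
    )


@dataclass
class DegeneracyDiagnostics:
    degenerate: bool
    reasons: list[str]
    edge_fraction: float | None
    max_t_ratio: float

    def to_dict(self) -> dict:
        return {
            "degenerate": self.degenerate,
            "reasons": self.reasons,
            "edge_fraction": self.edge_fraction,
            "max_t_ratio": self.max_t_ratio,
        }


def detect_degeneracy(
    sample: np.ndarray,
    observed: Sequence[float],
    n_vertices: int,
    labels: Sequence[str] | None = None,
) -> DegeneracyDiagnostics:
    """Flag fits whose simulated networks collapse away from the data.

    Degenerate iff (a) the mean simulated simple-edge count falls below 2%
    or above 98% of the dyad count, (b) any per-term t-ratio
    |observed - mean| / sd exceeds 4, or (c) a simulated statistic has zero
    variance yet its mean misses the observed value.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim == 1:
        sample = sample[:, None]
    if sample.size == 0:
        raise ValueError("empty simulated sample")
    observed = np.asarray(observed, dtype=float)
    D = max(1, n_vertices * (n_vertices - 1) // 2)
    labels = list(labels) if labels is not None else [f"t{k}" for k in range(sample.shape[1])]
    reasons: list[str] = []
    edge_fraction = None
    edge_col = next((k for k, lab in enumerate(labels) if lab == "edges"), None)
    if edge_col is not None:
        edge_fraction = float(sample[:, edge_col].mean() / D)
        if edge_fraction < 0.02:
            reasons.append(f"mean simulated density {edge_fraction:.3f} < 0.02")
        elif edge_fraction > 0.98:
            reasons.append(f"mean simulated density {edge_fraction:.3f} > 0.98")
    mean = sample.mean(axis=0)
    sd = sample.std(axis=0, ddof=1) if len(sample) > 1 else np.zeros_like(mean)
    max_t = 0.0
    for k, lab in enumerate(labels):
        if sd[k] > 0:
            t = abs(observed[k] - mean[k]) / sd[k]
            max_t = max(max_t, t)
            if t > 4.0:
                reasons.append(f"{lab}: t-ratio {t:.2f} > 4")
        elif not np.isclose(mean[k], observed[k]):
            max_t = np.inf
            reasons.append(f"{lab}: zero simulated variance away from observed")
    return DegeneracyDiagnostics(
        degenerate=bool(reasons),
        reasons=reasons,
        edge_fraction=edge_fraction,
        max_t_ratio=float(max_t),
    )


@dataclass
class McmcDiagnostics:
    labels: tuple[str, ...]
    centred_mean: np.ndarray  # trace mean minus observed statistic
    trace_sd: np.ndarray
    lag1_autocorr: np.ndarray
    geweke_z: np.ndarray
    passed: bool
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "centred_mean": [float(v) for v in self.centred_mean],
            "trace_sd": [float(v) for v in self.trace_sd],
            "lag1_autocorr": [float(v) for v in self.lag1_autocorr],
            "geweke_z": [float(v) for v in self.geweke_z],
            "passed": self.passed,
            "warnings": self.warnings,
        }


def mcmc_diagnostics(
    trace: np.ndarray,
    observed: Sequence[float],
    labels: Sequence[str] | None = None,
) -> McmcDiagnostics:
    """Stationarity checks on a statistic trace from the sampler.

    Reports the trace mean centred on the observed statistic, lag-1
    autocorrelation, and a Geweke-style z comparing the first 10% of the
    trace with the last 50%; |z| > 2 on any term raises a warning flag.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim == 1:
        trace = trace[:, None]
    if len(trace) < 10:
        raise ValueError("trace must have length >= 10")
    observed = np.asarray(observed, dtype=float)
    labels = tuple(labels) if labels is not None else tuple(f"t{k}" for k in range(trace.shape[1]))
    S, p = trace.shape
    mean = trace.mean(axis=0)
    sd = trace.std(axis=0, ddof=1)
    lag1 = np.zeros(p)
    for k in range(p):
        x = trace[:, k]
        if sd[k] > 0:
            lag1[k] = np.corrcoef(x[:-1], x[1:])[0, 1]
    head = trace[: max(2, S // 10)]
    tail = trace[S // 2 :]

    def batch_mean_var(x: np.ndarray) -> float:
        """Autocorrelation-robust variance of the mean via batch means."""
        n_batches = max(2, min(10, len(x) // 5))
        batches = np.array_split(x, n_batches)
        means = np.array([b.mean() for b in batches])
        return float(means.var(ddof=1) / n_batches)

    gz = np.zeros(p)
    warnings = []
    for k in range(p):
        v = batch_mean_var(head[:, k]) + batch_mean_var(tail[:, k])
        if v > 0:
            gz[k] = (head[:, k].mean() - tail[:, k].mean()) / np.sqrt(v)
        if abs(gz[k]) > 2.0:
            warnings.append(f"{labels[k]}: Geweke z = {gz[k]:.2f}")
    return McmcDiagnostics(
        labels=labels,
        centred_mean=mean - observed,
        trace_sd=sd,
        lag1_autocorr=lag1,
        geweke_z=gz,
        passed=not warnings,
        warnings=warnings,
    )


@dataclass
class FitBundle:
    """All fits and diagnostics for one network.

    Exactly one of the covariate models is present: the triad model
    (``model1``) when it converged without degeneracy, otherwise its
    no-triad restriction (``model1A``, ``fallback=True``).  The species
    factor model (``model2``) is fitted independently.
    """

    metadata: dict
    n_vertices: int
    n_simple_edges: int
    n_multi_edges: int
    covariate_fit: ErgmFit | None
    fallback: bool
    model2_fit: ErgmFit | None
    gof_reports: dict  # model name -> GofReport
    degeneracy: DegeneracyDiagnostics | None
    mcmc: McmcDiagnostics | None
    seed: int
    estimable: bool = True

    @property
    def covariate_model_name(self) -> str:
        return "model1A" if self.fallback else "model1"

    def gwesp_coefficient(self) -> float | None:
        if self.fallback or self.covariate_fit is None:
            return None
        try:
            return self.covariate_fit.coef("gwesp")
        except KeyError:
            return None

    def gwesp_gof_p(self) -> float | None:
        report = self.gof_reports.get("model1")
        if report is None:
            return None
        try:
            return report.p_value("gwesp")
        except KeyError:
            return None

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "n_vertices": self.n_vertices,
            "n_simple_edges": self.n_simple_edges,
            "n_multi_edges": self.n_multi_edges,
            "covariate_model": self.covariate_model_name if self.covariate_fit else None,
            "covariate_fit": self.covariate_fit.to_dict() if self.covariate_fit else None,
            "fallback": self.fallback,
            "model2_fit": self.model2_fit.to_dict() if self.model2_fit else None,
            "gof": {k: v.to_dict() for k, v in self.gof_reports.items()},
            "degeneracy": self.degeneracy.to_dict() if self.degeneracy else None,
            "mcmc": self.mcmc.to_dict() if self.mcmc else None,
            "seed": self.seed,
            "estimable": self.estimable,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitBundle":
        deg = d.get("degeneracy")
        return cls(
            metadata=dict(d["metadata"]),
            n_vertices=int(d["n_vertices"]),
            n_simple_edges=int(d["n_simple_edges"]),
            n_multi_edges=int(d["n_multi_edges"]),
            covariate_fit=ErgmFit.from_dict(d["covariate_fit"]) if d["covariate_fit"] else None,
            fallback=bool(d["fallback"]),
            model2_fit=ErgmFit.from_dict(d["model2_fit"]) if d["model2_fit"] else None,
            gof_reports={k: GofReport.from_dict(v) for k, v in d.get("gof", {}).items()},
            degeneracy=DegeneracyDiagnostics(
                degenerate=deg["degenerate"],
                reasons=list(deg["reasons"]),
                edge_fraction=deg["edge_fraction"],
                max_t_ratio=deg["max_t_ratio"],
            )
            if deg
            else None,
            mcmc=None,
            seed=int(d["seed"]),
            estimable=bool(d.get("estimable", True)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitBundle":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_with_fallback(
    network: BenthicNetwork,
    control: McmcControl | None = None,
    n_sim: int = 100,
    seed: int = 0,
    decay: float = 0.25,
) -> FitBundle:
    """Fit the triad model with automatic fallback, plus the species model.

    The triad model (edges + gwesp + size + count) is fitted by MC-MLE; if
    it fails to converge or its final simulated sample is degenerate, the
    no-triad restriction is fitted instead and flagged.  The species-factor
    model is fitted independently (it is dyad-independent and needs no
    chain).  Goodness-of-fit with ``n_sim`` simulated networks is attached
    to every estimable fit.  Degeneracy never raises.
    """
    meta = network.metadata()
    meta["species"] = network.species()
    base = dict(
        metadata=meta,
        n_vertices=network.n_vertices,
        n_simple_edges=network.n_simple_edges,
        n_multi_edges=network.n_multi_edges,
        seed=seed,
    )
    if not network.fittable:
        return FitBundle(
            covariate_fit=None,
            fallback=False,
            model2_fit=None,
            gof_reports={},
            degeneracy=None,
            mcmc=None,
            estimable=False,
            **base,
        )
    control = control or McmcControl()
    control = McmcControl(
        burn_in=control.burn_in,
        thin=control.thin,
        n_samples=control.n_samples,
        seed=seed,
        max_iter=control.max_iter,
        t_tol=control.t_tol,
        step_max=control.step_max,
        bridge_points=control.bridge_points,
        bridge_samples=control.bridge_samples,
    )
    fit1 = mcmle(network, model1(decay=decay), control)
    degeneracy = None
    mcmc = None
    if fit1.sample is not None:
        degeneracy = detect_degeneracy(
            fit1.sample, fit1.observed_stats, network.n_vertices, fit1.labels
        )
        if len(fit1.sample) >= 10:
            mcmc = mcmc_diagnostics(fit1.sample, fit1.observed_stats, fit1.labels)
    use_fallback = (
        not fit1.estimable
        or not fit1.converged
        or (degeneracy is not None and degeneracy.degenerate)
    )
    if use_fallback:
        covariate_fit = mple(network, model1A())
        fallback = True
    else:
        covariate_fit = fit1
        fallback = False
    fit2 = mcmle(network, model2(), control)

    gof_reports: dict[str, GofReport] = {}
    if covariate_fit.estimable:
        name = "model1A" if fallback else "model1"
        gof_reports[name] = gof(covariate_fit, network, n_sim=n_sim, seed=seed + 17)
    if fit2.estimable:
        gof_reports["model2"] = gof(fit2, network, n_sim=n_sim, seed=seed + 29)
    return FitBundle(
        covariate_fit=covariate_fit if covariate_fit.estimable else covariate_fit,
        fallback=fallback,
        model2_fit=fit2,
        gof_reports=gof_reports,
        degeneracy=degeneracy,
        mcmc=mcmc,
        estimable=covariate_fit.estimable or fit2.estimable,
        **base,
    )
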