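"""Model specifications: term types, formula parsing, and expansion.

A :class:`ModelSpec` is an ordered list of terms.  ``nodefactor`` terms
expand to one statistic per non-reference level, with levels discovered from
the data and the lexicographically first level taken as the (omitted)
reference.  Expansion maps a spec onto a concrete vertex set, producing the
flat arrays the numerical kernels consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EdgesTerm",
    "GwespTerm",
    "NodeCovTerm",
    "NodeFactorTerm",
    "ModelSpec",
    "ExpandedModel",
    "parse_formula",
    "model1",
    "model1A",
    "model2",
]

# kernel term kinds
KIND_EDGES = 0
KIND_GWESP = 1
KIND_NODECOV = 2
KIND_NODEFACTOR = 3


@dataclass(frozen=True)
class EdgesTerm:
    name: str = "edges"


@dataclass(frozen=True)
class GwespTerm:
    """Geometrically weighted edgewise shared partners with fixed decay.

    The statistic is ``e^tau * sum_k [1 - (1 - e^-tau)^k] * EP_k`` where
    ``EP_k`` counts edges whose endpoints share exactly ``k`` neighbours.
    """

    decay: float = 0.25
    fixed: bool = True

    def __post_init__(self) -> None:
        if self.decay < 0:
            raise ValueError(f"gwesp decay must be >= 0, got {self.decay}")
        if not self.fixed:
            raise NotImplementedError("curved (estimated-decay) gwesp is not supported")

    @property
    def name(self) -> str:
        return f"gwesp({self.decay:g})"


@dataclass(frozen=True)
class NodeCovTerm:
    """Quantitative vertex covariate: sum of endpoint values over edges."""

    attribute: str

    @property
    def name(self) -> str:
        return f"nodecov({self.attribute})"


@dataclass(frozen=True)
class NodeFactorTerm:
    """Categorical vertex attribute: per-level count of edge endpoints.

    ``vertex.names`` (the species identities themselves) is allowed as the
    attribute, matching the species-factor model.  ``reference=None`` selects
    the lexicographically first observed level.
    """

    attribute: str
    reference: str | None = None

    @property
    def name(self) -> str:
        return f"nodefactor({self.attribute})"


Term = EdgesTerm | GwespTerm | NodeCovTerm | NodeFactorTerm


@dataclass(frozen=True)
class ModelSpec:
    """Ordered list of ERGM terms."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        keys = [t.name for t in self.terms]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate terms in model spec: {keys}")

    @property
    def dyad_independent(self) -> bool:
        """True when no term couples dyads (no gwesp): MPLE equals MLE."""
        return not any(isinstance(t, GwespTerm) for t in self.terms)

    @property
    def gwesp_decay(self) -> float | None:
        for t in self.terms:
            if isinstance(t, GwespTerm):
                return t.decay
        return None

    def __str__(self) -> str:
        return " + ".join(t.name for t in self.terms)

    def expand(self, nodes: Sequence[str], node_attrs: dict[str, dict]) -> "ExpandedModel":
        """Expand onto a concrete vertex set (order defines vertex indices)."""
        n = len(nodes)
        kinds: list[int] = []
        labels: list[str] = []
        vecs: list[np.ndarray] = []
        decay = 0.0
        for term in self.terms:
            if isinstance(term, EdgesTerm):
                kinds.append(KIND_EDGES)
                labels.append("edges")
                vecs.append(np.zeros(n))
            elif isinstance(term, GwespTerm):
                kinds.append(KIND_GWESP)
                labels.append(f"gwesp.fixed.{term.decay:g}")
                vecs.append(np.zeros(n))
                decay = term.decay
            elif isinstance(term, NodeCovTerm):
                vals = []
                for node in nodes:
                    attrs = node_attrs.get(node, {})
                    if term.attribute not in attrs:
                        raise KeyError(
                            f"vertex {node!r} is missing attribute {term.attribute!r}"
                        )
                    vals.append(float(attrs[term.attribute]))
                kinds.append(KIND_NODECOV)
                labels.append(f"nodecov.{term.attribute}")
                vecs.append(np.asarray(vals, dtype=float))
            elif isinstance(term, NodeFactorTerm):
                if term.attribute == "vertex.names":
                    levels_by_node = {node: str(node) for node in nodes}
                else:
                    levels_by_node = {}
                    for node in nodes:
                        attrs = node_attrs.get(node, {})
                        if term.attribute not in attrs:
                            raise KeyError(
                                f"vertex {node!r} is missing attribute {term.attribute!r}"
                            )
                        levels_by_node[node] = str(attrs[term.attribute])
                levels = sorted(set(levels_by_node.values()))
                reference = term.reference if term.reference is not None else levels[0]
                for level in levels:
                    if level == reference:
                        continue
                    indicator = np.array(
                        [1.0 if levels_by_node[node] == level else 0.0 for node in nodes]
                    )
                    kinds.append(KIND_NODEFACTOR)
                    labels.append(f"nodefactor.{term.attribute}.{level}")
                    vecs.append(indicator)
            else:  # pragma: no cover - exhaustive over Term
                raise TypeError(f"unknown term {term!r}")
        return ExpandedModel(
            spec=self,
            nodes=tuple(nodes),
            kinds=np.asarray(kinds, dtype=np.int64),
            vectors=np.vstack(vecs) if vecs else np.zeros((0, n)),
            labels=tuple(labels),
            decay=decay,
        )


@dataclass(frozen=True)
class ExpandedModel:
    """A ModelSpec bound to a vertex set: flat arrays for the kernels."""

    spec: ModelSpec
    nodes: tuple[str, ...]
    kinds: np.ndarray  # (p,) int64 term kinds
    vectors: np.ndarray  # (p, n) float64 per-vertex values (zeros for edges/gwesp)
    labels: tuple[str, ...]
    decay: float

    @property
    def n_params(self) -> int:
        return len(self.labels)

    @property
    def n_vertices(self) -> int:
        return len(self.nodes)


_TERM_RE = re.compile(r"^\s*(\w+)\s*(?:\(([^)]*)\))?\s*$")


def parse_formula(formula: str) -> ModelSpec:
    """Parse a model mini-language string into a :class:`ModelSpec`.

    Examples: ``"edges"``, ``"edges + gwesp(0.25, fixed) + nodecov(size) +
    nodecov(count)"``, ``"edges + nodefactor(vertex.names)"``.  The preset
    names ``model1``, ``model1A`` and ``model2`` are also accepted.
    """
    presets = {"model1": model1, "model1a": model1A, "model2": model2}
    key = formula.strip().lower()
    if key in presets:
        return presets[key]()
    terms: list[Term] = []
    for chunk in formula.split("+"):
        m = _TERM_RE.match(chunk)
        if not m:
            raise ValueError(f"cannot parse model term {chunk!r}")
        name, args = m.group(1).lower(), m.group(2)
        argv = [a.strip().strip("'\"") for a in args.split(",")] if args else []
        if name == "edges":
            terms.append(EdgesTerm())
        elif name == "gwesp":
            decay = float(argv[0]) if argv else 0.25
            terms.append(GwespTerm(decay=decay))
        elif name == "nodecov":
            if len(argv) != 1:
                raise ValueError(f"nodecov takes one attribute name: {chunk!r}")
            terms.append(NodeCovTerm(argv[0]))
        elif name == "nodefactor":
            if not argv:
                raise ValueError(f"nodefactor takes an attribute name: {chunk!r}")
            ref = argv[1] if len(argv) > 1 else None
            terms.append(NodeFactorTerm(argv[0].replace("vertex.names", "vertex.names"), ref))
        else:
            raise ValueError(f"unknown model term {name!r}")
    if not terms:
        raise ValueError("empty model formula")
    return ModelSpec(tuple(terms))


def model1(decay: float = 0.25) -> ModelSpec:
    """Edges + gwesp(decay, fixed) + nodecov(size) + nodecov(count)."""
    return ModelSpec(
        (EdgesTerm(), GwespTerm(decay=decay), NodeCovTerm("size"), NodeCovTerm("count"))
    )


def model1A() -> ModelSpec:
    """Edges + nodecov(size) + nodecov(count): the no-triad fallback model."""
    return ModelSpec((EdgesTerm(), NodeCovTerm("size"), NodeCovTerm("count")))


def model2() -> ModelSpec:
    """Edges + nodefactor(vertex.names): the species-preference model."""
    return ModelSpec((EdgesTerm(), NodeFactorTerm("vertex.names")))
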