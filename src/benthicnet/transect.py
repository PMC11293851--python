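"""Benthic transect records and species co-occurrence networks.

A line-intercept transect is recorded as one species code per centimetre.
Collapsing the sequence into maximal same-species runs and connecting
adjacent runs yields an undirected co-occurrence network: vertices are
species, edges are shared boundaries, and edge multiplicity counts how
often two species abut along the tape.  Vertex covariates record the total
cover (``size``, cm) and the number of runs (``count``) of each species.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "TransectRecord",
    "RunSegment",
    "SpeciesAttributeTable",
    "BenthicNetwork",
    "TransectDataError",
    "TransectConfigError",
    "parse_transect_table",
    "run_length_encode",
    "build_network",
    "write_network",
    "read_network",
]

ASPECTS = ("photophilous", "sciaphilous", "unknown")

DEFAULT_COLUMNS = {
    "survey_id": "survey_id",
    "site": "site",
    "depth": "depth_m",
    "aspect": "aspect",
    "position": "position_cm",
    "species_code": "species_code",
}


class TransectDataError(ValueError):
    """Malformed transect or network data (gaps, duplicates, bad values)."""


class TransectConfigError(ValueError):
    """Unresolvable configuration, e.g. a missing required column."""


@dataclass(frozen=True)
class TransectRecord:
    """One transect survey: metadata plus the per-centimetre species codes.

    ``codes[k]`` is the observation at centimetre ``k + 1`` (positions are
    1-based and inclusive).
    """

    survey_id: str
    site: str
    depth: float
    aspect: str
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.codes:
            raise TransectDataError(f"transect {self.survey_id}: empty code sequence")
        if any(not c for c in self.codes):
            raise TransectDataError(f"transect {self.survey_id}: empty species token")
        if self.aspect not in ASPECTS:
            object.__setattr__(self, "aspect", "unknown")
        if self.depth <= 0:
            raise TransectDataError(
                f"transect {self.survey_id}: depth must be positive, got {self.depth}"
            )

    @property
    def length(self) -> int:
        return len(self.codes)

    @property
    def label(self) -> str:
        return f"{self.survey_id}@{self.depth:g}m"


@dataclass(frozen=True)
class RunSegment:
    """A maximal run of one species: code, 1-based start, length in cm."""

    species: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise TransectDataError(f"run of {self.species}: length {self.length} < 1")


class SpeciesAttributeTable:
    """Lookup of species code -> (full name, phylum, category group)."""

    def __init__(self, rows: Iterable[tuple[str, str, str, str | None]] = ()):
        self._rows: dict[str, tuple[str, str, str | None]] = {}
        for code, name, phylum, category in rows:
            code = code.strip()
            if code in self._rows:
                raise TransectDataError(f"duplicate species code {code!r}")
            self._rows[code] = (name, phylum or "unknown", category)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesAttributeTable":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise TransectDataError(f"{path}: empty species file")
            rows = []
            for row in reader:
                rows.append(
                    (
                        row["code"],
                        row.get("name", row["code"]),
                        row.get("phylum", "unknown"),
                        row.get("category"),
                    )
                )
        return cls(rows)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "name", "phylum", "category"])
            for code, (name, phylum, category) in sorted(self._rows.items()):
                writer.writerow([code, name, phylum, category or ""])

    def __contains__(self, code: str) -> bool:
        return code in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def codes(self) -> list[str]:
        return list(self._rows)

    def name(self, code: str) -> str:
        return self._rows[code][0] if code in self._rows else code

    def phylum(self, code: str) -> str:
        return self._rows[code][1] if code in self._rows else "unknown"

    def category(self, code: str) -> str | None:
        return self._rows[code][2] if code in self._rows else None


@dataclass
class BenthicNetwork:
    """Undirected species co-occurrence network for one transect.

    Wraps a :class:`networkx.Graph` whose nodes carry ``size`` (total cm),
    ``count`` (number of runs) and ``phylum`` attributes and whose edges
    carry a ``multiplicity`` attribute (number of distinct adjacency
    observations).  The exponential random graph machinery operates on the
    simple graph; multiplicities only enter summaries and vertex covariates.
    """

    graph: nx.Graph
    survey_id: str = ""
    site: str = ""
    depth: float = 0.0
    aspect: str = "unknown"

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_simple_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_multi_edges(self) -> int:
        """Multiplicity-weighted edge count (= number of runs - 1 on a line)."""
        return sum(d["multiplicity"] for _, _, d in self.graph.edges(data=True))

    @property
    def fittable(self) -> bool:
        """At least two species, hence at least one dyad to model."""
        return self.n_vertices >= 2

    @property
    def label(self) -> str:
        return f"{self.survey_id}@{self.depth:g}m"

    def species(self) -> list[str]:
        return sorted(self.graph.nodes)

    def metadata(self) -> dict:
        return {
            "survey_id": self.survey_id,
            "site": self.site,
            "depth": self.depth,
            "aspect": self.aspect,
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BenthicNetwork):
            return NotImplemented
        if self.metadata() != other.metadata():
            return False
        if dict(self.graph.nodes(data=True)) != dict(other.graph.nodes(data=True)):
            return False
        mine = {frozenset(e): d for *e, d in self.graph.edges(data=True)}
        theirs = {frozenset(e): d for *e, d in other.graph.edges(data=True)}
        return mine == theirs


def parse_transect_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[TransectRecord]:
    """Read a long-format observation CSV into one record per (survey, depth).

    The file must have a header row; ``columns`` maps the logical names
    (survey_id, site, depth, aspect, position, species_code) onto the file's
    column names, defaulting to survey_id/site/depth_m/aspect/position_cm/
    species_code.  Positions within each (survey, depth) must be consecutive
    integers starting at 1.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TransectDataError(f"{path}: empty file")
        for logical, actual in colmap.items():
            if actual not in reader.fieldnames:
                raise TransectConfigError(
                    f"{path}: required column {actual!r} (for {logical}) not found; "
                    f"available: {reader.fieldnames}"
                )
        groups: dict[tuple[str, float], dict] = {}
        for row in reader:
            survey = row[colmap["survey_id"]].strip()
            depth = float(row[colmap["depth"]])
            key = (survey, depth)
            grp = groups.setdefault(
                key,
                {
                    "site": row[colmap["site"]].strip(),
                    "aspect": row[colmap["aspect"]].strip() or "unknown",
                    "obs": {},
                },
            )
            pos = int(row[colmap["position"]])
            if pos in grp["obs"]:
                raise TransectDataError(
                    f"survey {survey} depth {depth:g}: duplicate position {pos}"
                )
            grp["obs"][pos] = row[colmap["species_code"]].strip()
    if not groups:
        raise TransectDataError(f"{path}: no observation rows")

    records = []
    for (survey, depth), grp in groups.items():
        positions = sorted(grp["obs"])
        expected = list(range(1, len(positions) + 1))
        if positions != expected:
            missing = sorted(set(expected) - set(positions))
            where = missing[0] if missing else positions[-1]
            raise TransectDataError(
                f"survey {survey} depth {depth:g}: positions are not consecutive "
                f"from 1 (first problem at position {where})"
            )
        codes = tuple(grp["obs"][p] for p in positions)
        records.append(
            TransectRecord(
                survey_id=survey,
                site=grp["site"],
                depth=depth,
                aspect=grp["aspect"] if grp["aspect"] in ASPECTS else "unknown",
                codes=codes,
            )
        )
    records.sort(key=lambda r: (r.survey_id, r.depth))
    return records


def run_length_encode(record: TransectRecord) -> list[RunSegment]:
    """Collapse the per-centimetre codes into maximal same-species runs."""
    runs: list[RunSegment] = []
    start = 1
    prev = record.codes[0]
    length = 1
    for code in record.codes[1:]:
        if code == prev:
            length += 1
        else:
            runs.append(RunSegment(prev, start, length))
            start += length
            prev = code
            length = 1
    runs.append(RunSegment(prev, start, length))
    return runs


def build_network(
    runs: Sequence[RunSegment],
    attrs: SpeciesAttributeTable | None = None,
    metadata: Mapping | None = None,
    non_species: Iterable[str] = (),
) -> BenthicNetwork:
    """Build the co-occurrence network from a transect's run list.

    Each pair of adjacent runs contributes one adjacency observation to the
    edge between their two species; repeated pairs accumulate multiplicity.
    Vertex ``size`` is the species' total run length, ``count`` its number of
    runs.  Tokens in ``non_species`` (e.g. bare substrate markers) are not
    vertices and break adjacency: runs on either side of them are NOT
    connected.  The default is the empty set, i.e. every recorded category is
    a vertex.
    """
    if not runs:
        raise TransectDataError("empty run list")
    skip = {s.strip() for s in non_species}
    graph = nx.Graph()
    for run in runs:
        if run.species in skip:
            continue
        if run.species in graph:
            graph.nodes[run.species]["size"] += run.length
            graph.nodes[run.species]["count"] += 1
        else:
            graph.add_node(run.species, size=run.length, count=1)
    prev: str | None = None
    for run in runs:
        if run.species in skip:
            prev = None  # a non-species gap is not a shared boundary
            continue
        if prev is not None and prev != run.species:
            if graph.has_edge(prev, run.species):
                graph[prev][run.species]["multiplicity"] += 1
            else:
                graph.add_edge(prev, run.species, multiplicity=1)
        prev = run.species
    for node in graph.nodes:
        graph.nodes[node]["phylum"] = attrs.phylum(node) if attrs else "unknown"
    meta = dict(metadata or {})
    return BenthicNetwork(
        graph=graph,
        survey_id=str(meta.get("survey_id", "")),
        site=str(meta.get("site", "")),
        depth=float(meta.get("depth", 0.0) or 0.0),
        aspect=str(meta.get("aspect", "unknown")),
    )


def network_from_record(
    record: TransectRecord,
    attrs: SpeciesAttributeTable | None = None,
    non_species: Iterable[str] = (),
) -> BenthicNetwork:
    """Convenience: run-length encode a record and build its network."""
    return build_network(
        run_length_encode(record),
        attrs=attrs,
        metadata={
            "survey_id": record.survey_id,
            "site": record.site,
            "depth": record.depth,
            "aspect": record.aspect,
        },
        non_species=non_species,
    )


_META_KEYS = ("survey_id", "site", "depth", "aspect")


def write_network(network: BenthicNetwork, path: str | Path, format: str = "graphml") -> None:
    """Serialize a network as GraphML or as paired vertex/edge CSVs.

    For ``edge-csv`` the path is treated as a stem: ``<stem>.vertices.csv``
    and ``<stem>.edges.csv`` are written.
    """
    path = Path(path)
    if format == "graphml":
        g = network.graph.copy()
        for key in _META_KEYS:
            g.graph[key] = getattr(network, key)
        nx.write_graphml(g, path)
    elif format == "edge-csv":
        stem = path.with_suffix("") if path.suffix == ".csv" else path
        with open(f"{stem}.vertices.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "size", "count", "phylum"] + list(_META_KEYS))
            meta = [network.survey_id, network.site, network.depth, network.aspect]
            for node, data in sorted(network.graph.nodes(data=True)):
                writer.writerow([node, data["size"], data["count"], data["phylum"]] + meta)
        with open(f"{stem}.edges.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["u", "v", "multiplicity"])
            for u, v, data in sorted(network.graph.edges(data=True), key=lambda e: (e[0], e[1])):
                writer.writerow([u, v, data["multiplicity"]])
    else:
        raise TransectConfigError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> BenthicNetwork:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        graph = nx.Graph()
        for node, data in g.nodes(data=True):
            graph.add_node(
                node,
                size=int(data["size"]),
                count=int(data["count"]),
                phylum=str(data.get("phylum", "unknown")),
            )
        for u, v, data in g.edges(data=True):
            mult = int(data["multiplicity"])
            if mult < 1:
                raise TransectDataError(f"{path}: edge {u}-{v} has multiplicity {mult}")
            graph.add_edge(u, v, multiplicity=mult)
        return BenthicNetwork(
            graph=graph,
            survey_id=str(g.graph.get("survey_id", "")),
            site=str(g.graph.get("site", "")),
            depth=float(g.graph.get("depth", 0.0)),
            aspect=str(g.graph.get("aspect", "unknown")),
        )
    if format == "edge-csv":
        stem = path.with_suffix("") if path.suffix == ".csv" else path
        graph = nx.Graph()
        meta: dict = {}
        with open(f"{stem}.vertices.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                graph.add_node(
                    row["code"],
                    size=int(row["size"]),
                    count=int(row["count"]),
                    phylum=row["phylum"],
                )
                meta = {k: row[k] for k in _META_KEYS}
        with open(f"{stem}.edges.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                mult = int(row["multiplicity"])
                if mult < 1:
                    raise TransectDataError(
                        f"{stem}.edges.csv: edge {row['u']}-{row['v']} has "
                        f"multiplicity {mult}"
                    )
                graph.add_edge(row["u"], row["v"], multiplicity=mult)
        return BenthicNetwork(
            graph=graph,
            survey_id=meta.get("survey_id", ""),
            site=meta.get("site", ""),
            depth=float(meta.get("depth", 0.0) or 0.0),
            aspect=meta.get("aspect", "unknown"),
        )
    raise TransectConfigError(f"unknown network format {format!r}")
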