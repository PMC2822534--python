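"""Gene-interaction network sieving and normalized expression ratios.

Two interaction networks — one built from alignment-derived miRNA targets,
one from sequence-based target predictions — are intersected ("sieved") for
common nodes; genes present and well-connected in both are candidate
downstream targets.  For a candidate gene set, group-wise expression ratios
are computed after within-sample normalization by a housekeeping gene
(typically GAPDH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ConfigurationError, DataError, ParseError

__all__ = [
    "InteractionNetwork",
    "ExpressionMatrix",
    "HubReport",
    "read_edge_list",
    "common_nodes",
    "normalized_group_ratio",
    "direction_concordance",
]

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "source", "target", "node1", "node2", "gene_a", "gene_b", "from", "to",
    "gene1", "gene2", "a", "b",
}


@dataclass
class InteractionNetwork:
    """Undirected, unweighted gene-symbol network."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    label: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], label: str = ""
    ) -> "InteractionNetwork":
        g = nx.Graph()
        for a, b in edges:
            a, b = a.strip().upper(), b.strip().upper()
            if a == b:
                logger.warning("self-loop on %s dropped", a)
                continue
            g.add_edge(a, b)
        return cls(graph=g, label=label)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with groups and a housekeeping gene."""

    values: pd.DataFrame  # genes (index) x samples (columns)
    groups: dict[str, str]  # sample -> group label
    housekeeping_gene: str

    def __post_init__(self) -> None:
        if self.housekeeping_gene not in self.values.index:
            raise DataError(
                f"housekeeping gene {self.housekeeping_gene!r} absent from matrix"
            )
        hk = self.values.loc[self.housekeeping_gene]
        if (hk.isna() | (hk <= 0)).any():
            raise DataError("housekeeping gene must be positive in every sample")
        unknown = set(self.values.columns) - set(self.groups)
        if unknown:
            raise ConfigurationError(f"samples without a group label: {sorted(unknown)}")

    def group_samples(self, group: str) -> list[str]:
        samples = [s for s in self.values.columns if self.groups.get(s) == group]
        if not samples:
            raise ConfigurationError(f"group {group!r} has no samples")
        return samples


@dataclass
class HubReport:
    """Common nodes of two networks with per-network degrees."""

    common_nodes: set[str]
    degrees_a: dict[str, int]
    degrees_b: dict[str, int]
    shared_hubs: list[str]  # descending min-degree, ties lexicographic


def read_edge_list(path: str | Path, label: str = "") -> InteractionNetwork:
    """Read a two-column TSV edge list into an undirected network.

    Symbols are uppercased and trimmed; duplicate and reversed-duplicate
    edges collapse; self-loops are dropped with a warning.  A first row made
    of common header tokens (source/target/...) is skipped.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}: row {lineno}: expected two gene symbols")
            if lineno == 1 and {fields[0].lower(), fields[1].lower()} <= _HEADER_TOKENS:
                continue
            edges.append((fields[0], fields[1]))
    return InteractionNetwork.from_edges(edges, label=label or str(path))


def common_nodes(net_a: InteractionNetwork, net_b: InteractionNetwork) -> HubReport:
    """Sieve two networks for shared nodes, ranked by min-degree across both."""
    common = net_a.nodes & net_b.nodes
    degrees_a = {v: net_a.degree(v) for v in common}
    degrees_b = {v: net_b.degree(v) for v in common}
    hubs = sorted(common, key=lambda v: (-min(degrees_a[v], degrees_b[v]), v))
    return HubReport(
        common_nodes=common,
        degrees_a=degrees_a,
        degrees_b=degrees_b,
        shared_hubs=hubs,
    )


def normalized_group_ratio(
    expr: ExpressionMatrix,
    genes: Iterable[str],
    group_num: str,
    group_den: str,
) -> dict[str, float]:
    """Housekeeping-normalized group-mean expression ratio per gene.

    Each sample's values are divided by that sample's housekeeping value;
    the normalized values are averaged within the numerator and denominator
    groups (missing gene-sample cells excluded, not imputed); the ratio of
    the two means is returned.  Genes absent from the matrix are reported
    and skipped; zero denominator means are flagged and excluded.
    """
    samples_num = expr.group_samples(group_num)
    samples_den = expr.group_samples(group_den)
    hk = expr.values.loc[expr.housekeeping_gene]
    normalized = expr.values.div(hk, axis=1)
    ratios: dict[str, float] = {}
    for gene in sorted(set(genes)):
        if gene not in normalized.index:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        mean_num = normalized.loc[gene, samples_num].mean(skipna=True)
        mean_den = normalized.loc[gene, samples_den].mean(skipna=True)
        if pd.isna(mean_num) or pd.isna(mean_den):
            logger.warning("gene %s has no values in a group; skipped", gene)
            continue
        if mean_den == 0:
            logger.warning("gene %s: zero denominator group mean; undefined", gene)
            continue
        ratios[gene] = float(mean_num / mean_den)
    return ratios


def direction_concordance(
    ratios: Mapping[str, float], expected_direction: str
) -> float:
    """Fraction of genes whose ratio falls on the expected side of 1.

    ``expected_direction`` is ">1" or "<1"; ratios exactly 1 count as
    discordant.
    """
    if expected_direction not in (">1", "<1"):
        raise ConfigurationError("expected_direction must be '>1' or '<1'")
    if not ratios:
        raise DataError("empty ratio map")
    if expected_direction == ">1":
        hits = sum(1 for r in ratios.values() if r > 1)
    else:
        hits = sum(1 for r in ratios.values() if r < 1)
    return hits / len(ratios)
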