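"""Hypergeometric over-representation against GMT gene sets and pathway graphs.

Over-representation follows the MSigDB-style k/K convention: for a query of
``n`` genes drawn from a universe of ``M`` genes, a set of size ``K``
(restricted to the universe) overlapping the query in ``k`` genes gets the
upper-tail hypergeometric p-value ``P(X >= k)``; q-values are BH across the
collection. The pathway-overlap graph connects two enriched sets when they
share at least a configurable fraction of genes (default 10%, denominator
= size of the smaller set) *and* at least one query/signature gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .io import ParseError

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "overlap_ratio",
    "format_ratio",
    "format_percent",
    "hypergeom_ora",
    "build_pathway_graph",
    "write_graph_edges_tsv",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (order-preserving, deduplicated) with descriptions."""

    sets: dict = field(default_factory=dict)  #: name -> list of gene ids
    descriptions: dict = field(default_factory=dict)
    universe: list | None = None  #: optional explicit background

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> list:
        seen: dict = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)


def read_gmt(path) -> GeneSetCollection:
    """Parse a standard GMT file (name, description, member genes...).

    Duplicate genes within a set are counted once (a warning reports how
    many were dropped); a line with fewer than three tab-separated fields is
    a parse error carrying the line number.
    """
    sets: dict = {}
    descriptions: dict = {}
    n_dup = 0
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description, >=1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ParseError(f"{path}: duplicate set name {name!r} at line {lineno}")
            uniq: dict = {}
            for g in genes:
                uniq.setdefault(g, None)
            n_dup += len(genes) - len(uniq)
            if not uniq:
                raise ParseError(f"{path}: set {name!r} at line {lineno} has no genes")
            sets[name] = list(uniq)
            descriptions[name] = desc
    if n_dup:
        warnings.warn(f"{path}: dropped {n_dup} duplicate gene entries within sets")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def overlap_ratio(k: int, K: int) -> float:
    """The k/K overlap ratio of over-representation tables."""
    if K <= 0:
        raise ValueError("K must be positive")
    if not 0 <= k <= K:
        raise ValueError(f"need 0 <= k <= K, got k={k}, K={K}")
    return k / K


def format_ratio(k: int, K: int) -> str:
    """k/K rounded to 4 decimals, trailing zeros trimmed (``0.0857``, ``0.1``)."""
    return f"{round(overlap_ratio(k, K), 4):g}"


def format_percent(k: int, K: int) -> str:
    """k/K as a percentage with one decimal (``7.3%``)."""
    return f"{overlap_ratio(k, K) * 100:.1f}%"


def hypergeom_ora(
    query,
    collection: GeneSetCollection,
    universe=None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query signature in each set.

    Parameters
    ----------
    query
        Iterable of gene ids, or a :class:`~synerseq.synergy.SignatureSet`.
    collection
        The gene-set collection; each set is intersected with the universe
        before its size ``K`` is taken.
    universe
        Background gene ids. Defaults to the collection's explicit universe
        when present, otherwise to the union of all its sets. Query genes
        outside the universe are dropped with a warning.

    Returns a DataFrame sorted by (q, p, set name) with columns
    ``set_name, K, k, k_over_K, p_value, q_value, genes`` (semicolon-joined
    sorted overlap).
    """
    if hasattr(query, "genes"):
        query = list(query.genes)
    query = list(dict.fromkeys(query))
    if universe is None:
        universe = collection.universe or collection.all_genes()
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    dropped = [g for g in query if g not in universe_set]
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped "
            f"(e.g. {dropped[:5]})"
        )
    query_set = set(query) & universe_set
    if not query_set:
        raise ValueError("empty query after restriction to universe")

    M, n = len(universe_set), len(query_set)
    rows = []
    for name, genes in collection.sets.items():
        members = set(genes) & universe_set
        K = len(members)
        overlap = sorted(members & query_set)
        k = len(overlap)
        # Upper tail including the observed overlap: P(X >= k).
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "K": K,
                "k": k,
                "k_over_K": overlap_ratio(k, K) if K else float("nan"),
                "p_value": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    records = pd.DataFrame(rows)
    records["q_value"] = bh_fdr(records["p_value"].to_numpy())
    records = records.sort_values(
        ["q_value", "p_value", "set_name"], kind="stable"
    ).reset_index(drop=True)
    return records[["set_name", "K", "k", "k_over_K", "p_value", "q_value", "genes"]]


_DENOMINATORS = ("min", "union", "mean")


def build_pathway_graph(
    records: pd.DataFrame,
    collection: GeneSetCollection,
    query,
    overlap_threshold: float = 0.10,
    q_threshold: float = 0.05,
    denominator: str = "min",
) -> nx.Graph:
    """Pathway-overlap network over the significantly enriched sets.

    Nodes are sets with ``q <= q_threshold`` (attributes ``size`` and
    ``q_value``); an undirected edge joins two sets when their shared-gene
    fraction reaches ``overlap_threshold`` (inclusive) *and* they share at
    least one query/signature gene. Edge attributes: ``n_shared_total``,
    ``n_shared_query``, ``overlap_fraction``. Node/edge insertion order is
    deterministic (sorted names), so the graph is invariant to the input
    ordering of records.
    """
    if denominator not in _DENOMINATORS:
        raise ValueError(f"denominator must be one of {_DENOMINATORS}")
    if hasattr(query, "genes"):
        query = list(query.genes)
    query_set = set(query)

    graph = nx.Graph()
    if records is None or records.empty:
        return graph
    enriched = records[records["q_value"] <= q_threshold]
    names = sorted(enriched["set_name"])
    meta = enriched.set_index("set_name")
    for name in names:
        graph.add_node(
            name,
            size=len(collection.sets[name]),
            q_value=float(meta.loc[name, "q_value"]),
        )
    for i, a in enumerate(names):
        set_a = set(collection.sets[a])
        for b in names[i + 1 :]:
            set_b = set(collection.sets[b])
            shared = set_a & set_b
            if not shared:
                continue
            if denominator == "min":
                denom = min(len(set_a), len(set_b))
            elif denominator == "union":
                denom = len(set_a | set_b)
            else:
                denom = (len(set_a) + len(set_b)) / 2
            frac = len(shared) / denom
            n_query = len(shared & query_set)
            if frac >= overlap_threshold and n_query >= 1:
                graph.add_edge(
                    a,
                    b,
                    n_shared_total=len(shared),
                    n_shared_query=n_query,
                    overlap_fraction=frac,
                )
    return graph


def write_graph_edges_tsv(graph: nx.Graph, path) -> None:
    rows = [
        {
            "source": a,
            "target": b,
            "n_shared_total": data["n_shared_total"],
            "n_shared_query": data["n_shared_query"],
            "overlap_fraction": data["overlap_fraction"],
        }
        for a, b, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "n_shared_total", "n_shared_query", "overlap_fraction"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
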