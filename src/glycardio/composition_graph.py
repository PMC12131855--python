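"""Composition relatedness graph of glycan libraries.

Observed N-glycan compositions form a natural graph in which two
compositions are adjacent when they differ by exactly one monosaccharide
(Manhattan distance 1 over the H/N/F/S counts).  Because N-glycan
biosynthesis adds or removes one residue at a time, connectedness of this
graph is a completeness check on a glycan library, and node membership
colours (present in one sample type, the other, or both) visualise library
overlap.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .glycan_core import (
    GlycanComposition,
    composition_property,
    parse_composition,
)

__all__ = [
    "build_graph",
    "graph_summary",
    "compare_libraries",
    "write_graphml",
    "write_edge_list",
    "write_node_table",
]

MEMBERSHIPS = ("A-only", "B-only", "both")


def _as_composition(c) -> GlycanComposition:
    return parse_composition(c) if isinstance(c, str) else c


def build_graph(
    compositions: Iterable,
    memberships: Optional[Mapping] = None,
    provenance: tuple[str, str] = ("A", "B"),
) -> nx.Graph:
    """Build the composition graph: one node per unique composition, an
    undirected edge wherever two compositions differ by one residue.

    ``memberships`` optionally maps composition (string or object) to one
    of ``A-only``/``B-only``/``both``.  Brute-force all-pairs comparison;
    libraries are small (~10²) so O(n²) is fine.
    """
    comps = sorted({_as_composition(c) for c in compositions})
    g = nx.Graph(provenance=",".join(provenance))
    member_by_str = {}
    if memberships:
        member_by_str = {str(_as_composition(k)): v for k, v in memberships.items()}
        bad = set(member_by_str.values()) - set(MEMBERSHIPS)
        if bad:
            raise ValueError(f"unknown membership labels: {sorted(bad)}")
    for c in comps:
        g.add_node(
            str(c),
            membership=member_by_str.get(str(c), "both"),
            property=composition_property(c),
        )
    for i, u in enumerate(comps):
        for v in comps[i + 1:]:
            if u.distance(v) == 1:
                g.add_edge(str(u), str(v))
    return g


def graph_summary(g: nx.Graph) -> dict:
    """Deterministic summary: node/edge/component counts plus node tallies
    by membership and by composition property."""
    by_membership = {m: 0 for m in MEMBERSHIPS}
    by_property: dict[str, int] = {}
    for _, data in g.nodes(data=True):
        by_membership[data.get("membership", "both")] = (
            by_membership.get(data.get("membership", "both"), 0) + 1
        )
        prop = data.get("property", "neutral")
        by_property[prop] = by_property.get(prop, 0) + 1
    return {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
        "connected_components": nx.number_connected_components(g) if g else 0,
        "by_membership": by_membership,
        "by_property": dict(sorted(by_property.items())),
    }


def compare_libraries(
    lib_a: pd.DataFrame, lib_b: pd.DataFrame, level: str = "structure"
) -> tuple[set, set, set]:
    """Partition two library tables into (shared, A-only, B-only) identity
    sets.

    At ``structure`` level identity is the (canonical composition,
    structure serialization) pair; at ``composition`` level it is the
    canonical composition string.
    """
    if level not in ("structure", "composition"):
        raise ValueError(f"level must be 'structure' or 'composition', got {level!r}")

    def keys(df: pd.DataFrame, name: str) -> set:
        if level == "composition":
            return {str(parse_composition(c)) for c in df["composition"]}
        out = [
            (str(parse_composition(c)), s)
            for c, s in zip(df["composition"], df["structure"])
        ]
        if len(out) != len(set(out)):
            seen: set = set()
            dups = [k for k in out if k in seen or seen.add(k)]
            raise ValueError(f"duplicate structures within library {name}: {dups}")
        return set(out)

    a, b = keys(lib_a, "A"), keys(lib_b, "B")
    return a & b, a - b, b - a


def membership_map(shared: set, a_only: set, b_only: set) -> dict[str, str]:
    """Composition-level membership labels for build_graph from a
    compare_libraries partition (composition level)."""
    out = {}
    for k in a_only:
        out[k] = "A-only"
    for k in b_only:
        out[k] = "B-only"
    for k in shared:
        out[k] = "both"
    return out


# -- exports ----------------------------------------------------------------

def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_edge_list(g: nx.Graph, path) -> None:
    """Two-column TSV edge list, lexicographically sorted."""
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def write_node_table(g: nx.Graph, path) -> None:
    """Node attribute TSV: composition, membership, property."""
    rows = [
        {"composition": n, "membership": d.get("membership", "both"),
         "property": d.get("property", "")}
        for n, d in sorted(g.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["composition", "membership", "property"]).to_csv(
        path, sep="\t", index=False
    )
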