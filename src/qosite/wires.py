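"""Q_o_-site contact graph and proton-wire enumeration.

Nodes are proton donors (the quinol oxygens), relay groups (side chains,
which can accept and re-donate a proton along a Grotthuss chain) and release
groups (groups in contact with bulk solvent, where a transported proton can
leave).  Edges carry the mechanisms by which the two groups connect: a direct
H-bond or a bridge of one or two waters.  Connections needing more than two
bridging waters are never admitted: the stability of a wire is expected to
fall quickly with the number of mobile waters that must align simultaneously.

A wire is a simple donor -> ... -> release path in which release groups are
terminal sinks.  Wires are distinguished by their node sequence only; the
mechanisms available on each hop are reported alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .geometry import ValidationError

__all__ = [
    "MECHANISMS",
    "QO_SITE_EDGES",
    "QO_SITE_ROLES",
    "Wire",
    "WireGraph",
    "build_graph",
    "enumerate_wires",
    "load_edge_list",
    "qo_site_graph",
    "wire_report",
]

#: Admissible edge mechanisms, by number of bridging waters.
MECHANISMS = ("direct", "1-water", "2-water")
_WATER_COUNT = {"direct": 0, "1-water": 1, "2-water": 2}

#: Node roles of the Q_o_-site instance.
QO_SITE_ROLES: dict[str, str] = {
    "Q_O1": "donor",
    "Q_O4": "donor",
    "Y147": "relay",
    "E295": "relay",
    "Y297": "relay",
    "H276": "relay",
    "H152": "release",
    "PRA_bL": "release",
    "D278": "release",
}

#: Contact-network edge list of the Q_o_ site: (node, node, mechanisms,
#: occupancy per mechanism or None when only qualitative).  The weakest
#: admitted bridge (Y297 to the heme propionate) runs at 16% occupancy.
QO_SITE_EDGES: list[tuple[str, str, tuple[str, ...], dict[str, float] | None]] = [
    ("Q_O4", "H152", ("direct", "1-water"), None),
    ("Q_O1", "Y147", ("direct", "1-water"), None),
    ("Y147", "E295", ("direct", "1-water"), None),
    ("Y147", "Y297", ("direct",), None),
    ("E295", "PRA_bL", ("1-water",), None),
    ("Y297", "PRA_bL", ("1-water",), {"1-water": 0.16}),
    ("Y147", "PRA_bL", ("2-water",), None),
    ("E295", "H276", ("direct",), None),
    ("H276", "D278", ("direct", "1-water", "2-water"), None),
]


@dataclass
class WireGraph:
    """Undirected contact graph with node roles and per-edge mechanisms."""

    graph: nx.Graph

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["role"] == role)

    def mechanisms(self, a: str, b: str) -> dict[str, float | None]:
        return self.graph.edges[a, b]["mechanisms"]


def build_graph(
    edges: Iterable[tuple],
    roles: Mapping[str, str] = QO_SITE_ROLES,
    theta_min: float = 0.05,
    declared: bool = True,
) -> WireGraph:
    """Assemble a WireGraph from an edge list or contact-occupancy summaries.

    Each edge is (nodeA, nodeB, mechanisms, occupancies) where ``mechanisms``
    is a sequence of mechanism names and ``occupancies`` maps mechanism ->
    occupancy fraction (or is None).  Mechanisms with more than two bridging
    waters are rejected with a warning regardless of occupancy.  When
    ``declared`` is False, an edge is admitted only if some mechanism's
    occupancy reaches ``theta_min``; a declared edge list bypasses the
    threshold.
    """
    g = nx.Graph()
    for node, role in roles.items():
        if role not in ("donor", "relay", "release"):
            raise ValidationError(f"unknown role {role!r} for node {node}")
        g.add_node(node, role=role)
    for entry in edges:
        a, b, mechs, occ = entry
        for node in (a, b):
            if node not in g:
                raise ValidationError(f"edge names unknown node {node!r}")
        occ = dict(occ) if occ else {}
        kept: dict[str, float | None] = {}
        for m in mechs:
            if m not in _WATER_COUNT:
                warnings.warn(
                    f"edge {a}-{b}: mechanism {m!r} needs more than two bridging waters "
                    "(or is unrecognised); rejected",
                    stacklevel=2,
                )
                continue
            kept[m] = occ.get(m)
        if not kept:
            continue
        if not declared:
            known = [v for v in kept.values() if v is not None]
            for v in known:
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"edge {a}-{b}: occupancy {v} outside [0, 1]")
            if not known or max(known) < theta_min:
                continue
        g.add_edge(a, b, mechanisms=kept)
    return WireGraph(g)


def qo_site_graph() -> WireGraph:
    """The Q_o_-site contact graph (declared edge list shipped with the package)."""
    return build_graph(QO_SITE_EDGES)


def load_edge_list(path: str | Path, roles: Mapping[str, str] | None = None, **kwargs) -> WireGraph:
    """Read an edge list from TSV (nodeA nodeB mechanism occupancy) or JSON."""
    path = Path(path)
    edges: dict[tuple[str, str], tuple[list[str], dict[str, float]]] = {}
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        roles = roles or data.get("roles") or QO_SITE_ROLES
        rows = data["edges"]
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        rows = df.to_dict("records")
        roles = roles or QO_SITE_ROLES
    for row in rows:
        key = (str(row["nodeA"]), str(row["nodeB"]))
        mechs, occ = edges.setdefault(key, ([], {}))
        m = str(row["mechanism"])
        mechs.append(m)
        v = row.get("occupancy")
        if v is not None and not (isinstance(v, float) and pd.isna(v)):
            occ[m] = float(v)
    entries = [(a, b, tuple(mechs), occ or None) for (a, b), (mechs, occ) in edges.items()]
    return build_graph(entries, roles=roles, **kwargs)


@dataclass(frozen=True)
class Wire:
    """An ordered donor -> release proton pathway."""

    path: tuple[str, ...]
    mechanisms: tuple[tuple[str, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise ValidationError("a wire needs at least donor and release")
        if len(set(self.path)) != len(self.path):
            raise ValidationError("wire path must be simple")

    @property
    def donor(self) -> str:
        return self.path[0]

    @property
    def release(self) -> str:
        return self.path[-1]


def enumerate_wires(graph: WireGraph) -> list[Wire]:
    """All simple donor -> release paths with release nodes as terminal sinks.

    Output order is deterministic: by donor name, then path length, then
    lexicographic node sequence.
    """
    g = graph.graph
    donors = graph.nodes_with_role("donor")
    releases = set(graph.nodes_with_role("release"))
    if not donors or not releases:
        raise ValidationError("graph needs at least one donor and one release node")
    wires: list[Wire] = []

    def dfs(path: list[str]) -> None:
        tail = path[-1]
        if tail in releases:
            mechs = tuple(tuple(sorted(graph.mechanisms(u, v))) for u, v in zip(path, path[1:]))
            wires.append(Wire(path=tuple(path), mechanisms=mechs))
            return  # release nodes are sinks: never extended
        for nxt in sorted(g.neighbors(tail)):
            if nxt not in path:
                dfs(path + [nxt])

    for donor in donors:
        for nxt in sorted(g.neighbors(donor)):
            dfs([donor, nxt])
    wires.sort(key=lambda w: (w.donor, len(w.path), w.path))
    return wires


def wire_report(wires: Sequence[Wire], graph: WireGraph) -> pd.DataFrame:
    """Per-wire report ranked by bottleneck (minimum edge occupancy), descending.

    An edge's occupancy is the best over its mechanisms; wires containing an
    edge with no measured occupancy get an unknown bottleneck and rank last.
    """
    rows = []
    for w in wires:
        edge_occs = []
        mech_desc = []
        for u, v in zip(w.path, w.path[1:]):
            mechs = graph.mechanisms(u, v)
            mech_desc.append("/".join(sorted(mechs)))
            known = [x for x in mechs.values() if x is not None]
            edge_occs.append(max(known) if known else None)
        bottleneck = None if any(o is None for o in edge_occs) else min(edge_occs)
        rows.append(
            {
                "donor": w.donor,
                "release": w.release,
                "path": "->".join(w.path),
                "mechanisms": ";".join(mech_desc),
                "bottleneck": bottleneck,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            by=["bottleneck", "path"],
            ascending=[False, True],
            na_position="last",
            kind="mergesort",
        ).reset_index(drop=True)
    return df
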