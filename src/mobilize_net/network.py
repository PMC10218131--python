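"""Typed two-role network: container, synthetic generator and file I/O.

Nodes carry a role — ``GRS`` (government resource subject) or ``SRS``
(social resource subject) — and edges are undirected cooperative ties.
Cross-role ties carry the stage game; same-role ties carry learning only
(see :mod:`mobilize_net.engine`).

The case network studied here (built from news coverage of a COVID-19
response in a Chinese city) comprised 19 GRSs and 49 SRSs with both
cross-type and same-type ties; its exact topology is not published, so
:func:`generate_network` produces synthetic networks that emulate its
size, two-type composition, mixing and connectedness.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "TypedNetwork",
    "GeneratorConfig",
    "generate_network",
    "read_network",
    "write_network",
]


class Role(enum.Enum):
    GRS = "GRS"
    SRS = "SRS"

    @classmethod
    def coerce(cls, value: Union["Role", str]) -> "Role":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).upper()]
        except KeyError:
            raise ValueError(
                f"unknown role label {value!r}: expected 'GRS' or 'SRS'"
            ) from None


class TypedNetwork:
    """Undirected network whose nodes carry an immutable role.

    Node ids are opaque strings; iteration order is sorted id order so
    that runs are reproducible.  No self-loops, no duplicate edges, and
    every edge endpoint must be a declared node.
    """

    def __init__(
        self,
        nodes: Iterable[Tuple[str, Union[Role, str]]],
        edges: Iterable[Tuple[str, str]],
    ):
        roles: Dict[str, Role] = {}
        for node_id, role in nodes:
            node_id = str(node_id)
            if node_id in roles:
                raise ValueError(f"duplicate node id {node_id!r}")
            roles[node_id] = Role.coerce(role)
        g = nx.Graph()
        for node_id in sorted(roles):
            g.add_node(node_id, role=roles[node_id].value)
        seen = set()
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on node {a!r} is not allowed")
            for end in (a, b):
                if end not in roles:
                    raise ValueError(
                        f"edge ({a!r}, {b!r}) references unknown node {end!r}"
                    )
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise ValueError(f"duplicate edge ({a!r}, {b!r})")
            seen.add(key)
            g.add_edge(*key)
        self._g = g

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (roles as the ``role`` node attr)."""
        return self._g

    @property
    def node_ids(self) -> List[str]:
        return sorted(self._g.nodes)

    def role(self, node_id: str) -> Role:
        return Role(self._g.nodes[node_id]["role"])

    @property
    def roles(self) -> Dict[str, Role]:
        return {n: Role(d["role"]) for n, d in self._g.nodes(data=True)}

    def nodes_with_role(self, role: Union[Role, str]) -> List[str]:
        role = Role.coerce(role)
        return [n for n in self.node_ids if self.role(n) is role]

    @property
    def n_grs(self) -> int:
        return len(self.nodes_with_role(Role.GRS))

    @property
    def n_srs(self) -> int:
        return len(self.nodes_with_role(Role.SRS))

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    def neighbors(self, node_id: str) -> List[str]:
        return sorted(self._g.neighbors(node_id))

    def is_connected(self) -> bool:
        return len(self) > 0 and nx.is_connected(self._g)

    def same_type_edge_fraction(self) -> float:
        edges = self.edges
        if not edges:
            return float("nan")
        same = sum(1 for a, b in edges if self.role(a) is self.role(b))
        return same / len(edges)

    def validation_report(self) -> Dict[str, object]:
        """Structural summary: counts, connectivity, mixing, isolates."""
        return {
            "n_nodes": len(self),
            "n_grs": self.n_grs,
            "n_srs": self.n_srs,
            "n_edges": self._g.number_of_edges(),
            "connected": self.is_connected(),
            "same_type_edge_fraction": self.same_type_edge_fraction(),
            "isolated_nodes": sorted(nx.isolates(self._g)),
        }


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic network generator.

    Defaults emulate the case network: 19 GRSs and 49 SRSs, connected,
    with cross-type ties dominant (``p_same_type=0.3``) at mean degree 4.
    """

    n_grs: int = 19
    n_srs: int = 49
    mean_degree: float = 4.0
    p_same_type: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_grs < 1 or self.n_srs < 1:
            raise ValueError("n_grs and n_srs must each be at least 1")
        if not 0.0 <= self.p_same_type <= 1.0:
            raise ValueError(f"p_same_type must be in [0, 1], got {self.p_same_type}")
        n = self.n_grs + self.n_srs
        lower = 2.0 * (1.0 - 1.0 / n)  # mean degree of a spanning tree
        if self.mean_degree < lower:
            raise ValueError(
                f"mean_degree {self.mean_degree} is below the connectivity "
                f"bound {lower:.4f} for {n} nodes"
            )


def generate_network(config: GeneratorConfig = GeneratorConfig()) -> TypedNetwork:
    """Generate a connected two-role network.

    Construction: a random spanning tree over all nodes guarantees
    connectivity — each node (in shuffled order) attaches to a previously
    placed anchor node — after which additional random edges are drawn
    until the target edge count ``round(mean_degree * n / 2)`` is met,
    clamped to the number of distinct node pairs.  The same-type /
    cross-type mixture is applied by quota: exactly
    ``round(p_same_type * target)`` edges are earmarked same-role (the
    earmarks shuffled across tree and extra edges), so the realized
    mixing fraction concentrates tightly on ``p_same_type``.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    grs_ids = [f"G{i:02d}" for i in range(config.n_grs)]
    srs_ids = [f"S{i:02d}" for i in range(config.n_srs)]
    all_ids = grs_ids + srs_ids
    role_of = {n: Role.GRS for n in grs_ids}
    role_of.update({n: Role.SRS for n in srs_ids})

    n = len(all_ids)
    max_pairs = n * (n - 1) // 2
    target = min(max(n - 1, int(round(config.mean_degree * n / 2.0))), max_pairs)

    # earmark exactly round(p_same_type*target) edges as same-role
    n_same = int(round(config.p_same_type * target))
    earmarks = np.zeros(target, dtype=bool)
    earmarks[:n_same] = True
    rng.shuffle(earmarks)

    order = list(rng.permutation(all_ids))
    edges = set()

    def add_edge(a: str, b: str) -> None:
        edges.add((a, b) if a <= b else (b, a))

    # random spanning tree with earmark-driven anchor choice
    placed = [order[0]]
    for node, want_same in zip(order[1:], earmarks):
        same = [p for p in placed if role_of[p] is role_of[node]]
        cross = [p for p in placed if role_of[p] is not role_of[node]]
        pool = same if (want_same and same) else (cross or same)
        anchor = pool[rng.integers(len(pool))]
        add_edge(node, anchor)
        placed.append(node)

    same_pools = {Role.GRS: grs_ids, Role.SRS: srs_ids}
    for want_same in earmarks[n - 1 :]:
        for attempt in range(10000):
            if want_same:
                pool = same_pools[
                    Role.GRS if rng.random() < config.n_grs / n else Role.SRS
                ]
                if len(pool) < 2:
                    continue
                a, b = (
                    pool[i] for i in rng.choice(len(pool), size=2, replace=False)
                )
            else:
                a = grs_ids[rng.integers(len(grs_ids))]
                b = srs_ids[rng.integers(len(srs_ids))]
            key = (a, b) if a <= b else (b, a)
            if key not in edges:
                add_edge(a, b)
                break
        else:
            raise RuntimeError(
                "edge target could not be reached; the requested mixture "
                "leaves too few free node pairs"
            )
    return TypedNetwork([(i, role_of[i]) for i in all_ids], sorted(edges))


# -- file I/O ----------------------------------------------------------------


def write_network(
    net: TypedNetwork,
    node_file: Union[str, Path],
    edge_file: Union[str, Path, None] = None,
) -> None:
    """Write a network to CSV node/edge files, or to GraphML.

    If ``node_file`` ends in ``.graphml`` a single GraphML file with a
    ``role`` node attribute is written and ``edge_file`` is ignored;
    otherwise two CSVs with columns (id, role) and (source, target).
    """
    node_file = Path(node_file)
    if node_file.suffix == ".graphml":
        nx.write_graphml(net.graph, node_file)
        return
    if edge_file is None:
        raise ValueError("edge_file is required for CSV output")
    pd.DataFrame(
        [(n, net.role(n).value) for n in net.node_ids], columns=["id", "role"]
    ).to_csv(node_file, index=False)
    pd.DataFrame(net.edges, columns=["source", "target"]).to_csv(
        Path(edge_file), index=False
    )


def read_network(
    node_file: Union[str, Path],
    edge_file: Union[str, Path, None] = None,
) -> TypedNetwork:
    """Read a network from CSV node/edge files or a GraphML file.

    Raises ValueError naming the offending row for unknown roles,
    duplicate ids, or edges referencing missing nodes.
    """
    node_file = Path(node_file)
    if node_file.suffix == ".graphml":
        g = nx.read_graphml(node_file)
        nodes = []
        for n, data in g.nodes(data=True):
            if "role" not in data:
                raise ValueError(f"node {n!r} is missing the 'role' attribute")
            nodes.append((n, data["role"]))
        return TypedNetwork(nodes, list(g.edges))
    if edge_file is None:
        raise ValueError("edge_file is required for CSV input")
    node_df = pd.read_csv(node_file, dtype=str)
    for col in ("id", "role"):
        if col not in node_df.columns:
            raise ValueError(f"node file {node_file} lacks required column {col!r}")
    try:
        edge_df = pd.read_csv(Path(edge_file), dtype=str)
    except pd.errors.EmptyDataError:
        edge_df = pd.DataFrame(columns=["source", "target"])
    for col in ("source", "target"):
        if col not in edge_df.columns:
            raise ValueError(f"edge file {edge_file} lacks required column {col!r}")
    return TypedNetwork(
        list(zip(node_df["id"], node_df["role"])),
        list(zip(edge_df["source"], edge_df["target"])),
    )
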