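"""Random directed signed networks with an embedded mutually repressing motif.

A toggle switch (TS) is two genes that mutually inhibit each other; a toggle
triad (TT) is three genes in which every ordered pair is an inhibition.  The
``-SA`` / ``-SI`` variants add one self-activation / self-inhibition loop per
motif node.  A motif is embedded in a random background of ``order_n`` extra
nodes by adding ``connectivity_x * order_n`` randomly placed signed edges, so
the whole network has mean connectivity E:xN.  Generated networks are simple
(at most one edge per ordered node pair), contain no self-loops outside the
SA/SI motif variants, and are connected when viewed as undirected graphs;
candidates violating connectivity are regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

ACTIVATION = 1
INHIBITION = -1

#: .topo file column encoding (RACIPE convention).
_TOPO_TYPE = {ACTIVATION: 1, INHIBITION: 2}
_TOPO_SIGN = {1: ACTIVATION, 2: INHIBITION}

MOTIF_NAMES = ("TS", "TT", "TS-SA", "TS-SI", "TT-SA", "TT-SI")

Edge = tuple[str, str, int]


@dataclass(frozen=True)
class MotifSpec:
    """A mutually repressing motif: ordered node labels and signed edges."""

    name: str
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_motif(name: str) -> MotifSpec:
    """Construct one of the six supported motifs.

    ``TS``: A and B mutually inhibit each other (2 inhibitory edges).
    ``TT``: A, B, C with all 6 ordered inter-node inhibitions.
    ``-SA`` / ``-SI`` variants add one self-activation / self-inhibition
    edge on every motif node.
    """
    if name not in MOTIF_NAMES:
        raise ValueError(
            f"unknown motif {name!r}; expected one of {', '.join(MOTIF_NAMES)}"
        )
    base = name.split("-")[0]
    nodes = ("A", "B") if base == "TS" else ("A", "B", "C")
    edges = [
        (s, t, INHIBITION)
        for s in nodes
        for t in nodes
        if s != t
    ]
    if name.endswith("-SA"):
        edges += [(x, x, ACTIVATION) for x in nodes]
    elif name.endswith("-SI"):
        edges += [(x, x, INHIBITION) for x in nodes]
    return MotifSpec(name=name, nodes=nodes, edges=tuple(edges))


@dataclass(frozen=True)
class NetworkTopology:
    """A directed signed network, optionally with an identified embedded motif.

    Motif nodes come first in ``nodes`` (A, B[, C]), then background nodes
    n1..nN.  ``order_n`` is the number of background nodes and
    ``connectivity_x`` the number of random edges added per background node.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    motif: Optional[MotifSpec] = None
    order_n: int = 0
    connectivity_x: int = 0
    seed: Optional[int] = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(source_idx, target_idx, sign) as integer arrays in edge order."""
        idx = self.node_index()
        src = np.array([idx[s] for s, _, _ in self.edges], dtype=np.int64)
        tgt = np.array([idx[t] for _, t, _ in self.edges], dtype=np.int64)
        sgn = np.array([g for _, _, g in self.edges], dtype=np.int64)
        return src, tgt, sgn

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.edges:
            g.add_edge(s, t, sign=sign)
        return g


def motif_topology(motif: MotifSpec | str) -> NetworkTopology:
    """The stand-alone (isolated) topology of a motif: no background nodes."""
    if isinstance(motif, str):
        motif = build_motif(motif)
    return NetworkTopology(
        nodes=motif.nodes, edges=motif.edges, motif=motif,
        order_n=0, connectivity_x=0,
    )


def is_connected(topology: NetworkTopology) -> bool:
    """True iff the underlying undirected graph has a single component."""
    if topology.n_nodes == 0:
        raise ValueError("topology has no nodes")
    return nx.is_connected(topology.to_graph().to_undirected())


def generate_embedded_network(
    motif: MotifSpec | str,
    order_n: int,
    connectivity_x: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 10_000,
) -> NetworkTopology:
    """Embed ``motif`` in a random connected background network.

    ``connectivity_x * order_n`` random signed edges are placed uniformly over
    the empty off-diagonal cells of the adjacency matrix (so a random edge can
    neither duplicate a motif edge nor create a self-loop), each activating or
    inhibiting with probability 1/2.  Whole candidates failing the undirected
    connectivity check are regenerated, up to ``max_attempts`` times.
    """
    if isinstance(motif, str):
        motif = build_motif(motif)
    if order_n < 1:
        raise ValueError("order_n must be >= 1")
    if connectivity_x < 1:
        raise ValueError("connectivity_x must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    nodes = motif.nodes + tuple(f"n{i + 1}" for i in range(order_n))
    n_random = connectivity_x * order_n
    taken = {(s, t) for s, t, _ in motif.edges}
    cells = [
        (s, t)
        for s in nodes
        for t in nodes
        if s != t and (s, t) not in taken
    ]
    if n_random > len(cells):
        raise ValueError(
            f"cannot place {n_random} random edges: only {len(cells)} free "
            f"ordered node pairs exist for order_n={order_n}"
        )

    for _ in range(max_attempts):
        chosen = rng.choice(len(cells), size=n_random, replace=False)
        signs = rng.integers(0, 2, size=n_random)
        random_edges = tuple(
            (cells[c][0], cells[c][1], ACTIVATION if b else INHIBITION)
            for c, b in zip(chosen, signs)
        )
        topo = NetworkTopology(
            nodes=nodes,
            edges=motif.edges + random_edges,
            motif=motif,
            order_n=order_n,
            connectivity_x=connectivity_x,
            seed=seed,
        )
        if is_connected(topo):
            return topo
    raise RuntimeError(
        f"no connected network found in {max_attempts} attempts "
        f"(order_n={order_n}, connectivity_x={connectivity_x})"
    )


def generate_network_batch(
    motif: MotifSpec | str,
    order_n: int,
    connectivity_x: int,
    count: int,
    seed: Optional[int] = None,
    max_attempts: int = 10_000,
) -> list[NetworkTopology]:
    """Generate ``count`` pairwise distinct connected embedded networks.

    Two networks are duplicates when their signed edge sets are identical;
    duplicates are replaced by freshly generated networks, mirroring the
    replacement rule used for disconnected candidates.
    """
    if isinstance(motif, str):
        motif = build_motif(motif)
    if count < 1:
        raise ValueError("count must be >= 1")
    master = np.random.default_rng(seed)
    seen: set[frozenset] = set()
    batch: list[NetworkTopology] = []
    attempts = 0
    while len(batch) < count:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not assemble {count} unique networks in "
                f"{max_attempts} attempts ({len(batch)} found); the space of "
                "simple graphs for these dimensions may be exhausted"
            )
        net_seed = int(master.integers(2**31))
        try:
            topo = generate_embedded_network(
                motif, order_n, connectivity_x, seed=net_seed
            )
        except RuntimeError:
            continue
        key = frozenset(topo.edges)
        if key in seen:
            continue
        seen.add(key)
        batch.append(topo)
    return batch


def add_self_regulation(topology: NetworkTopology,
                        kind: str) -> NetworkTopology:
    """Turn a plain-motif embedded network into its SA/SI variant in place.

    Adds one self-activation (``kind='SA'``) or self-inhibition
    (``kind='SI'``) loop per motif node on the *same* background network —
    the matched design for comparing a motif against its self-regulating
    variants without background-to-background variability.  Random edges
    never occupy diagonal cells, so the loops cannot collide.
    """
    if kind not in ("SA", "SI"):
        raise ValueError("kind must be 'SA' or 'SI'")
    if topology.motif is None or "-" in topology.motif.name:
        raise ValueError("need a topology with a plain (TS/TT) motif")
    new_motif = build_motif(f"{topology.motif.name}-{kind}")
    sign = ACTIVATION if kind == "SA" else INHIBITION
    loops = tuple((n, n, sign) for n in topology.motif.nodes)
    return NetworkTopology(
        nodes=topology.nodes, edges=topology.edges + loops,
        motif=new_motif, order_n=topology.order_n,
        connectivity_x=topology.connectivity_x, seed=topology.seed,
    )


def in_degree_profile(topology: NetworkTopology) -> dict[str, int]:
    """In-degree descriptors of the motif nodes.

    Counts *all* incoming edges, including the motif-internal inhibitions, so
    an isolated TS has in_A = in_B = 1.  ``in_motif`` is the sum over motif
    nodes; activating/inhibiting splits are reported per node.
    """
    if topology.motif is None:
        raise ValueError("topology has no identified motif")
    counts = {n: {"in": 0, "act": 0, "inh": 0} for n in topology.motif.nodes}
    for _, t, sign in topology.edges:
        if t in counts:
            counts[t]["in"] += 1
            counts[t]["act" if sign == ACTIVATION else "inh"] += 1
    prof: dict[str, int] = {}
    for n in topology.motif.nodes:
        prof[f"in_{n}"] = counts[n]["in"]
        prof[f"act_in_{n}"] = counts[n]["act"]
        prof[f"inh_in_{n}"] = counts[n]["inh"]
    prof["in_motif"] = sum(counts[n]["in"] for n in topology.motif.nodes)
    return prof


def batch_manifest(batch: Sequence[NetworkTopology],
                   network_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Tabulate a batch: id, motif, class, seed and in-degree profile."""
    rows = []
    for i, topo in enumerate(batch):
        row = {
            "network_id": network_ids[i] if network_ids else f"net{i:04d}",
            "motif": topo.motif.name if topo.motif else "",
            "order_N": topo.order_n,
            "connectivity_x": topo.connectivity_x,
            "seed": topo.seed,
        }
        prof = in_degree_profile(topo)
        row["in_A"] = prof.get("in_A")
        row["in_B"] = prof.get("in_B")
        row["in_C"] = prof.get("in_C", 0)
        row["in_motif"] = prof.get("in_motif")
        rows.append(row)
    return pd.DataFrame(rows)


def write_topo(topology: NetworkTopology, path: str | Path) -> None:
    """Write the RACIPE ``.topo`` format: header ``Source Target Type``,
    then one whitespace-separated edge per line (1=activation, 2=inhibition)."""
    lines = ["Source Target Type"]
    for s, t, sign in topology.edges:
        lines.append(f"{s} {t} {_TOPO_TYPE[sign]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_topo(path: str | Path,
              motif: Optional[MotifSpec | str] = None) -> NetworkTopology:
    """Read a ``.topo`` file; nodes are ordered by first appearance, except
    that motif nodes (when ``motif`` is given) are always listed first."""
    if isinstance(motif, str):
        motif = build_motif(motif)
    edges: list[Edge] = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        if ln == 1:
            if line.split() != ["Source", "Target", "Type"]:
                raise ValueError(
                    f"{path}:1: expected header 'Source Target Type', got {line!r}"
                )
            continue
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 fields, got {len(parts)}")
        s, t, typ = parts
        if typ not in ("1", "2"):
            raise ValueError(f"{path}:{ln}: Type must be 1 or 2, got {typ!r}")
        edges.append((s, t, _TOPO_SIGN[int(typ)]))
    seen_nodes: list[str] = list(motif.nodes) if motif else []
    for s, t, _ in edges:
        for n in (s, t):
            if n not in seen_nodes:
                seen_nodes.append(n)
    order_n = len(seen_nodes) - (motif.n_nodes if motif else 0)
    return NetworkTopology(
        nodes=tuple(seen_nodes), edges=tuple(edges), motif=motif,
        order_n=order_n if motif else 0, connectivity_x=0,
    )
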