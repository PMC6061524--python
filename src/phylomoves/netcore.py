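"""Rooted binary phylogenetic networks: data model, validation, tier
arithmetic, isomorphism, canonical forms, ancestry queries and I/O.

A rooted binary phylogenetic network is a DAG without parallel arcs whose
leaves (indegree 1, outdegree 0) are bijectively labelled, with a unique
root of indegree 0 and outdegree 1, and all remaining nodes either tree
nodes (1 in, 2 out) or reticulations (2 in, 1 out).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx

Node = str
Arc = Tuple[Node, Node]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or unknown nodes/arcs."""


@dataclass(frozen=True)
class TierSignature:
    """Leaf count, reticulation number and the node/edge counts they fix.

    For a binary network with n leaves and k reticulations,
    ``|V| = 2n + 2k`` and ``|E| = 2n + 3k - 1``.
    """

    n_leaves: int
    k: int
    n_nodes: int
    n_edges: int

    def __post_init__(self) -> None:
        if self.n_nodes != 2 * self.n_leaves + 2 * self.k:
            raise NetworkError(
                f"node count {self.n_nodes} inconsistent with "
                f"n={self.n_leaves}, k={self.k}"
            )
        if self.n_edges != 2 * self.n_leaves + 3 * self.k - 1:
            raise NetworkError(
                f"edge count {self.n_edges} inconsistent with "
                f"n={self.n_leaves}, k={self.k}"
            )


@dataclass(frozen=True)
class IsomorphismResult:
    """Outcome of an isomorphism test; ``mapping`` is None when absent."""

    mapping: Optional[Dict[Node, Node]]

    def __bool__(self) -> bool:
        return self.mapping is not None


class RootedNetwork:
    """A rooted binary phylogenetic network.

    Node ids are opaque strings; equality of networks is by structure and
    leaf labels (see :func:`is_isomorphic` / :func:`canonical_form`), never
    by node ids.
    """

    __slots__ = ("_g", "leaf_labels", "_canon")

    def __init__(
        self,
        arcs: Iterable[Arc],
        leaf_labels: Dict[Node, str],
        nodes: Optional[Iterable[Node]] = None,
    ) -> None:
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from(arcs)
        self._g = g
        self.leaf_labels = dict(leaf_labels)
        self._canon: Optional[tuple] = None

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> List[Node]:
        return list(self._g.nodes)

    @property
    def arcs(self) -> List[Arc]:
        return list(self._g.edges)

    @property
    def digraph(self) -> nx.DiGraph:
        return self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def has_node(self, u: Node) -> bool:
        return self._g.has_node(u)

    def has_arc(self, u: Node, v: Node) -> bool:
        return self._g.has_edge(u, v)

    def parents(self, u: Node) -> List[Node]:
        self._require(u)
        return sorted(self._g.predecessors(u))

    def children(self, u: Node) -> List[Node]:
        self._require(u)
        return sorted(self._g.successors(u))

    def indeg(self, u: Node) -> int:
        return self._g.in_degree(u)

    def outdeg(self, u: Node) -> int:
        return self._g.out_degree(u)

    def _require(self, u: Node) -> None:
        if not self._g.has_node(u):
            raise NetworkError(f"unknown node {u!r}")

    @property
    def root(self) -> Node:
        for u in self._g.nodes:
            if self._g.in_degree(u) == 0:
                return u
        raise NetworkError("no root (indegree-0 node) found")

    @property
    def root_arc(self) -> Arc:
        r = self.root
        return (r, next(iter(self._g.successors(r))))

    def leaves(self) -> List[Node]:
        return sorted(self.leaf_labels)

    def labels(self) -> Set[str]:
        return set(self.leaf_labels.values())

    def is_leaf(self, u: Node) -> bool:
        return u in self.leaf_labels

    def is_reticulation(self, u: Node) -> bool:
        return self._g.in_degree(u) == 2 and self._g.out_degree(u) == 1

    def is_tree_node(self, u: Node) -> bool:
        return self._g.in_degree(u) == 1 and self._g.out_degree(u) == 2

    def reticulations(self) -> List[Node]:
        return sorted(u for u in self._g.nodes if self.is_reticulation(u))

    def tree_nodes(self) -> List[Node]:
        return sorted(u for u in self._g.nodes if self.is_tree_node(u))

    def copy(self) -> "RootedNetwork":
        return RootedNetwork(self.arcs, self.leaf_labels, nodes=self.nodes)

    def fresh_node(self, prefix: str = "_v") -> Node:
        i = 0
        while f"{prefix}{i}" in self._g:
            i += 1
        return f"{prefix}{i}"

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"RootedNetwork({len(self)} nodes, labels={sorted(self.labels())})"


# -- validation -------------------------------------------------------------


def validate_rooted(net: RootedNetwork) -> List[str]:
    """Return a list of violation messages; empty means valid."""
    g = net.digraph
    problems: List[str] = []
    if g.number_of_nodes() == 0:
        return ["empty graph"]
    if not nx.is_directed_acyclic_graph(g):
        problems.append("cycle: graph contains a directed cycle")
    roots = [u for u in g.nodes if g.in_degree(u) == 0]
    if len(roots) != 1:
        problems.append(f"root: expected exactly one indegree-0 node, found {len(roots)}")
    else:
        if g.out_degree(roots[0]) != 1:
            problems.append(
                f"root: root {roots[0]!r} has outdegree {g.out_degree(roots[0])}, expected 1"
            )
    for u in g.nodes:
        din, dout = g.in_degree(u), g.out_degree(u)
        if din == 0:
            continue  # root handled above
        if (din, dout) not in ((1, 0), (1, 2), (2, 1)):
            problems.append(f"degree: node {u!r} has (in,out)=({din},{dout})")
        if din == 1 and dout == 0 and u not in net.leaf_labels:
            problems.append(f"label: leaf {u!r} is unlabelled")
    labelled = set(net.leaf_labels)
    actual_leaves = {u for u in g.nodes if g.in_degree(u) == 1 and g.out_degree(u) == 0}
    for u in labelled - actual_leaves:
        problems.append(f"label: labelled node {u!r} is not a leaf")
    vals = list(net.leaf_labels.values())
    if len(set(vals)) != len(vals):
        problems.append("label: leaf labels are not distinct")
    # parallel arcs cannot be stored in a DiGraph; detect 2-cycles explicitly
    for u, v in g.edges:
        if g.has_edge(v, u):
            problems.append(f"parallel/cycle: arcs both ways between {u!r} and {v!r}")
    if nx.number_weakly_connected_components(g) > 1:
        problems.append("connected: graph is not weakly connected")
    return problems


def assert_valid(net: RootedNetwork) -> None:
    problems = validate_rooted(net)
    if problems:
        raise NetworkError("; ".join(problems))


def tier_signature(net: RootedNetwork) -> TierSignature:
    assert_valid(net)
    n = len(net.leaf_labels)
    v = net.digraph.number_of_nodes()
    e = net.digraph.number_of_edges()
    k = e - v + 1
    return TierSignature(n_leaves=n, k=k, n_nodes=v, n_edges=e)


# -- ancestry ---------------------------------------------------------------


def is_above(net: RootedNetwork, u: Node, v: Node) -> bool:
    """Reflexive reachability u -> v in the DAG."""
    net._require(u)
    net._require(v)
    return u == v or nx.has_path(net.digraph, u, v)


def lca_set(net: RootedNetwork, u: Node, v: Node) -> Set[Node]:
    """All minimal common ancestors of u and v (nonempty; root qualifies)."""
    net._require(u)
    net._require(v)
    g = net.digraph
    anc_u = nx.ancestors(g, u) | {u}
    anc_v = nx.ancestors(g, v) | {v}
    common = anc_u & anc_v
    # minimal = no proper descendant inside `common` is also a common ancestor
    minimal = {
        a for a in common if not any(c in common for c in g.successors(a))
    }
    return minimal


# -- isomorphism and canonical form ----------------------------------------


def _node_match(a: dict, b: dict) -> bool:
    return a.get("label") == b.get("label")


def _labelled(net: RootedNetwork) -> nx.DiGraph:
    g = net.digraph.copy()
    for u, lab in net.leaf_labels.items():
        g.nodes[u]["label"] = lab
    return g


def is_isomorphic(a: RootedNetwork, b: RootedNetwork) -> IsomorphismResult:
    """Arc-direction- and leaf-label-preserving isomorphism, or absent."""
    if a.labels() != b.labels():
        return IsomorphismResult(None)
    if len(a) != len(b) or a.digraph.number_of_edges() != b.digraph.number_of_edges():
        return IsomorphismResult(None)
    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        _labelled(a), _labelled(b), node_match=_node_match
    )
    if matcher.is_isomorphic():
        return IsomorphismResult(dict(matcher.mapping))
    return IsomorphismResult(None)


def _refine(colors: Dict[Node, int], g: nx.DiGraph) -> Dict[Node, int]:
    """Iterated in/out-neighbourhood colour refinement to a stable partition."""
    while True:
        sigs = {}
        for u in g.nodes:
            sigs[u] = (
                colors[u],
                tuple(sorted(colors[w] for w in g.predecessors(u))),
                tuple(sorted(colors[w] for w in g.successors(u))),
            )
        # re-intern signatures as small ints
        order = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
        new = {u: order[sigs[u]] for u in g.nodes}
        if len(set(new.values())) == len(set(colors.values())):
            return new
        colors = new


def _canonical_token(g: nx.DiGraph, colors: Dict[Node, int]) -> tuple:
    colors = _refine(colors, g)
    cells: Dict[int, List[Node]] = {}
    for u, c in colors.items():
        cells.setdefault(c, []).append(u)
    non_singleton = sorted(
        (c for c, members in cells.items() if len(members) > 1)
    )
    if not non_singleton:
        idx = {u: colors[u] for u in g.nodes}
        edges = tuple(sorted((idx[u], idx[v]) for u, v in g.edges))
        color_seq = tuple(sorted(idx.values()))
        return (color_seq, edges)
    # individualise each member of the first non-singleton cell, recurse,
    # keep the lexicographically least token
    target = non_singleton[0]
    best = None
    ncolors = len(set(colors.values()))
    for u in cells[target]:
        child = dict(colors)
        child[u] = ncolors  # new distinct colour
        tok = _canonical_token(g, child)
        if best is None or tok < best:
            best = tok
    return best


def canonical_form(net: RootedNetwork) -> tuple:
    """A hashable token equal for two networks iff they are isomorphic."""
    if net._canon is not None:
        return net._canon
    g = net.digraph
    base: Dict[Node, tuple] = {}
    for u in g.nodes:
        lab = net.leaf_labels.get(u)
        base[u] = (g.in_degree(u), g.out_degree(u), lab if lab is not None else "")
    order = {s: i for i, s in enumerate(sorted(set(base.values())))}
    colors = {u: order[base[u]] for u in g.nodes}
    tok = ("rooted", tuple(sorted(net.labels())), _canonical_token(g, colors))
    net._canon = tok
    return tok


# -- extended Newick I/O ----------------------------------------------------


class ParseError(ValueError):
    def __init__(self, msg: str, pos: int) -> None:
        super().__init__(f"{msg} (at position {pos})")
        self.pos = pos


def _tokenize(text: str) -> Iterator[Tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "(),;":
            yield c, c, i
            i += 1
            continue
        j = i
        while j < n and text[j] not in "(),;" and not text[j].isspace():
            j += 1
        yield "name", text[i:j], i
        i = j


def read_enewick(text: str) -> RootedNetwork:
    """Parse extended Newick with ``#H`` hybrid tags into a network.

    Each hybrid node appears exactly twice: once with its subtree and once
    as a bare tag. Branch lengths and internal labels are discarded.
    """
    tokens = list(_tokenize(text))
    pos = 0

    counter = [0]
    arcs: List[Arc] = []
    labels: Dict[Node, str] = {}
    hybrids: Dict[str, Node] = {}

    def fresh() -> Node:
        counter[0] += 1
        return f"n{counter[0]}"

    def peek():
        return tokens[pos] if pos < len(tokens) else ("eof", "", len(text))

    def parse_clade() -> Node:
        nonlocal pos
        kind, val, at = peek()
        children: List[Node] = []
        if kind == "(":
            pos += 1
            children.append(parse_clade())
            while peek()[0] == ",":
                pos += 1
                children.append(parse_clade())
            if peek()[0] != ")":
                raise ParseError("expected ')'", peek()[2])
            pos += 1
        name = ""
        kind, val, at = peek()
        if kind == "name":
            name = val
            pos += 1
        # strip branch length / internal decorations
        if ":" in name:
            name = name.split(":", 1)[0]
        hybrid_tag = None
        if "#" in name:
            name, _, hybrid_tag = name.partition("#")
        if hybrid_tag is not None:
            if hybrid_tag in hybrids:
                node = hybrids[hybrid_tag]
            else:
                node = fresh()
                hybrids[hybrid_tag] = node
            if name and not children and node not in labels:
                labels[node] = name
        else:
            node = fresh()
            if children and name:
                pass  # internal label, discard
            elif name:
                labels[node] = name
        for c in children:
            arcs.append((node, c))
        if not children and not name and hybrid_tag is None:
            raise ParseError("empty clade", at)
        return node

    top = parse_clade()
    if peek()[0] != ";":
        raise ParseError("expected ';'", peek()[2])
    # wrap in an explicit root of outdegree 1 unless the top node already
    # has a single child (the conventional unary wrapper)
    g = nx.DiGraph(arcs)
    g.add_node(top)
    if g.out_degree(top) == 1:
        root = top
        net = RootedNetwork(arcs, labels, nodes=g.nodes)
    else:
        root = "n0"
        net = RootedNetwork(arcs + [(root, top)], labels, nodes=list(g.nodes) + [root])
    problems = validate_rooted(net)
    if problems:
        raise NetworkError("parsed graph is not a valid network: " + "; ".join(problems))
    return net


def write_enewick(net: RootedNetwork) -> str:
    """Serialise to extended Newick; hybrid nodes tagged #H1..#Hk."""
    assert_valid(net)
    g = net.digraph
    rets = net.reticulations()
    tag = {r: f"H{i+1}" for i, r in enumerate(rets)}
    done: Set[Node] = set()

    def emit(u: Node) -> str:
        if u in tag:
            if u in done:
                return f"#{tag[u]}"
            done.add(u)
            inner = emit(net.children(u)[0])
            return f"({inner})#{tag[u]}"
        if net.is_leaf(u):
            return net.leaf_labels[u]
        parts = [emit(c) for c in net.children(u)]
        return "(" + ",".join(parts) + ")"

    root = net.root
    child = net.children(root)[0]
    return f"({emit(child)});"


# -- JSON I/O ---------------------------------------------------------------


def to_json(net: RootedNetwork) -> str:
    payload = {
        "nodes": sorted(net.nodes),
        "arcs": sorted([list(a) for a in net.arcs]),
        "labels": dict(sorted(net.leaf_labels.items())),
    }
    return json.dumps(payload)


def from_json(text: str) -> RootedNetwork:
    payload = json.loads(text)
    return RootedNetwork(
        [tuple(a) for a in payload["arcs"]],
        payload["labels"],
        nodes=payload["nodes"],
    )
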