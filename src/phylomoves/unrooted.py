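"""Unrooted binary networks: SPR moves, rootability, bipolar orientation,
redundant terminal components, and SPR connectivity.

An unrooted network is a connected simple graph whose leaves (degree 1)
are bijectively labelled and whose internal nodes have degree 3; its
reticulation number is |E| - |V| + 1.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import networkx as nx

from .netcore import (
    NetworkError,
    Node,
    RootedNetwork,
    is_isomorphic,
    tier_signature,
    validate_rooted,
)
from .moves import Move, MoveSequence
from .headsim import TierMismatch
from .connect import AlgorithmError, init_frontier, run_frontier

Edge = Tuple[Node, Node]

ROOT_LABEL = "ρ"


class NotRootable(ValueError):
    pass


class NoTerminalComponent(ValueError):
    pass


class InvalidSPRMove(ValueError):
    pass


def _edge(u: Node, v: Node) -> Edge:
    return (u, v) if u <= v else (v, u)


class UnrootedNetwork:
    """Connected simple graph; leaves labelled, internal nodes degree 3."""

    __slots__ = ("_g", "leaf_labels", "_canon")

    def __init__(
        self,
        edges: Iterable[Edge],
        leaf_labels: Dict[Node, str],
        nodes: Optional[Iterable[Node]] = None,
    ) -> None:
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        self._g = g
        self.leaf_labels = dict(leaf_labels)
        self._canon = None

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> List[Node]:
        return list(self._g.nodes)

    @property
    def edges(self) -> List[Edge]:
        return [_edge(u, v) for u, v in self._g.edges]

    def neighbors(self, u: Node) -> List[Node]:
        return sorted(self._g.neighbors(u))

    def degree(self, u: Node) -> int:
        return self._g.degree(u)

    def has_edge(self, u: Node, v: Node) -> bool:
        return self._g.has_edge(u, v)

    def labels(self) -> Set[str]:
        return set(self.leaf_labels.values())

    def leaves(self) -> List[Node]:
        return sorted(self.leaf_labels)

    def copy(self) -> "UnrootedNetwork":
        return UnrootedNetwork(self.edges, self.leaf_labels, nodes=self.nodes)

    def fresh_node(self, prefix: str = "_v") -> Node:
        i = 0
        while f"{prefix}{i}" in self._g:
            i += 1
        return f"{prefix}{i}"

    @property
    def reticulation_number(self) -> int:
        return self._g.number_of_edges() - self._g.number_of_nodes() + 1

    def __repr__(self) -> str:  # pragma: no cover
        return f"UnrootedNetwork({len(self._g)} nodes, labels={sorted(self.labels())})"


def validate_unrooted(u_net: UnrootedNetwork) -> List[str]:
    g = u_net.graph
    problems: List[str] = []
    if g.number_of_nodes() == 0:
        return ["empty graph"]
    if not nx.is_connected(g):
        problems.append("connected: graph is not connected")
    for u in g.nodes:
        d = g.degree(u)
        if d == 1:
            if u not in u_net.leaf_labels:
                problems.append(f"label: leaf {u!r} is unlabelled")
        elif d != 3:
            problems.append(f"degree: internal node {u!r} has degree {d}")
    for u in u_net.leaf_labels:
        if not g.has_node(u) or g.degree(u) != 1:
            problems.append(f"label: labelled node {u!r} is not a leaf")
    vals = list(u_net.leaf_labels.values())
    if len(set(vals)) != len(vals):
        problems.append("label: leaf labels are not distinct")
    if len(vals) < 2:
        problems.append("label: fewer than two leaves")
    if g.number_of_edges() - g.number_of_nodes() + 1 < 0:
        problems.append("structure: negative reticulation number")
    return problems


def assert_valid_unrooted(u_net: UnrootedNetwork) -> None:
    problems = validate_unrooted(u_net)
    if problems:
        raise NetworkError("; ".join(problems))


# -- isomorphism -----------------------------------------------------------


def _node_match(a: dict, b: dict) -> bool:
    return a.get("label") == b.get("label")


def is_isomorphic_unrooted(a: UnrootedNetwork, b: UnrootedNetwork) -> Optional[Dict]:
    if a.labels() != b.labels():
        return None
    ga, gb = a.graph.copy(), b.graph.copy()
    for u, lab in a.leaf_labels.items():
        ga.nodes[u]["label"] = lab
    for u, lab in b.leaf_labels.items():
        gb.nodes[u]["label"] = lab
    matcher = nx.algorithms.isomorphism.GraphMatcher(ga, gb, node_match=_node_match)
    if matcher.is_isomorphic():
        return dict(matcher.mapping)
    return None


def _refine_undirected(colors: Dict[Node, int], g: nx.Graph) -> Dict[Node, int]:
    while True:
        sigs = {
            u: (colors[u], tuple(sorted(colors[w] for w in g.neighbors(u))))
            for u in g.nodes
        }
        order = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
        new = {u: order[sigs[u]] for u in g.nodes}
        if len(set(new.values())) == len(set(colors.values())):
            return new
        colors = new


def _canon_token_undirected(g: nx.Graph, colors: Dict[Node, int]) -> tuple:
    colors = _refine_undirected(colors, g)
    cells: Dict[int, List[Node]] = {}
    for u, c in colors.items():
        cells.setdefault(c, []).append(u)
    non_singleton = sorted(c for c, m in cells.items() if len(m) > 1)
    if not non_singleton:
        idx = {u: colors[u] for u in g.nodes}
        edges = tuple(sorted(tuple(sorted((idx[u], idx[v]))) for u, v in g.edges))
        return (tuple(sorted(idx.values())), edges)
    target = non_singleton[0]
    best = None
    ncolors = len(set(colors.values()))
    for u in cells[target]:
        child = dict(colors)
        child[u] = ncolors
        tok = _canon_token_undirected(g, child)
        if best is None or tok < best:
            best = tok
    return best


def canonical_form_unrooted(u_net: UnrootedNetwork) -> tuple:
    if u_net._canon is not None:
        return u_net._canon
    g = u_net.graph
    base = {
        u: (g.degree(u), u_net.leaf_labels.get(u, "")) for u in g.nodes
    }
    order = {s: i for i, s in enumerate(sorted(set(base.values())))}
    colors = {u: order[base[u]] for u in g.nodes}
    tok = ("unrooted", tuple(sorted(u_net.labels())), _canon_token_undirected(g, colors))
    u_net._canon = tok
    return tok


# -- decomposition ---------------------------------------------------------


def cut_edges(u_net: UnrootedNetwork) -> List[Edge]:
    return sorted(_edge(u, v) for u, v in nx.bridges(u_net.graph))


def blobs(u_net: UnrootedNetwork) -> List[FrozenSet[Node]]:
    """Non-trivial biconnected components (those containing a cycle)."""
    out = [
        frozenset(c)
        for c in nx.biconnected_components(u_net.graph)
        if len(c) >= 3
    ]
    return sorted(out, key=lambda c: sorted(c))


def redundant_cut_edges(u_net: UnrootedNetwork) -> List[Edge]:
    """Bridges one of whose sides contains no leaf."""
    g = u_net.graph
    leaves = set(u_net.leaf_labels)
    out = []
    for u, v in nx.bridges(g):
        h = g.copy()
        h.remove_edge(u, v)
        side_u = nx.node_connected_component(h, u)
        side_v = nx.node_connected_component(h, v)
        if not (side_u & leaves) or not (side_v & leaves):
            out.append(_edge(u, v))
    return sorted(out)


@dataclass(frozen=True)
class TerminalComponent:
    nodes: FrozenSet[Node]
    edges: FrozenSet[Edge]  # all edges with an endpoint inside, incl. the cut-edge
    cut_edge: Edge

    @property
    def excess(self) -> int:
        return len(self.edges) - len(self.nodes)


def terminal_components(u_net: UnrootedNetwork) -> List[TerminalComponent]:
    """Blobs incident to exactly one cut-edge (necessarily redundant)."""
    g = u_net.graph
    bridges = set(_edge(u, v) for u, v in nx.bridges(g))
    out = []
    for comp in blobs(u_net):
        incident = [
            e for e in bridges if (e[0] in comp) != (e[1] in comp)
        ]
        if len(incident) == 1:
            edges = frozenset(
                _edge(u, v) for u, v in g.edges if u in comp or v in comp
            )
            out.append(
                TerminalComponent(nodes=comp, edges=edges, cut_edge=incident[0])
            )
    return sorted(out, key=lambda t: sorted(t.nodes))


def is_rootable(u_net: UnrootedNetwork) -> bool:
    return not redundant_cut_edges(u_net)


# -- bipolar orientation ---------------------------------------------------


def _bipolar_order(g: nx.Graph, comp: FrozenSet[Node], s: Node, t: Node) -> List[Node]:
    """An ordering of `comp` beginning with s and ending with t such that
    orienting every edge from earlier to later yields a single-source,
    single-sink acyclic orientation; built by open ear decomposition."""
    sub = g.subgraph(comp)
    seq: List[Node] = list(nx.shortest_path(sub, s, t))
    placed = set(seq)
    while len(placed) < len(comp):
        ear = None
        for a in sorted(placed):
            for w in sorted(sub.neighbors(a)):
                if w in placed:
                    continue
                # path from w to another placed node, avoiding a
                h = sub.subgraph([n for n in comp if n != a])
                prev = {w: None}
                q = deque([w])
                end = None
                while q:
                    cur = q.popleft()
                    if cur in placed:
                        end = cur
                        break
                    for nb in sorted(h.neighbors(cur)):
                        if nb not in prev:
                            prev[nb] = cur
                            q.append(nb)
                if end is None:
                    continue
                path = [end]
                while prev[path[-1]] is not None:
                    path.append(prev[path[-1]])
                path.reverse()  # w .. end
                ear = [a] + path
                break
            if ear:
                break
        if not ear:
            raise AlgorithmError("no open ear found; component not biconnected?")
        a, b = ear[0], ear[-1]
        internals = ear[1:-1]
        ia, ib = seq.index(a), seq.index(b)
        if ia < ib:
            insert_at, chain = ia + 1, internals
        else:
            insert_at, chain = ib + 1, list(reversed(internals))
        for off, w in enumerate(chain):
            seq.insert(insert_at + off, w)
        placed.update(internals)
    return seq


def orient(u_net: UnrootedNetwork, root_leaf: str) -> RootedNetwork:
    """Orient a rootable network as a rooted network with the given leaf
    (by label) as root: cut-edges point away from the root, each blob gets
    a bipolar orientation from its entry to a chosen exit."""
    assert_valid_unrooted(u_net)
    if not is_rootable(u_net):
        raise NotRootable("network has a redundant cut-edge")
    rev = {lab: node for node, lab in u_net.leaf_labels.items()}
    if root_leaf not in rev:
        raise NetworkError(f"unknown leaf label {root_leaf!r}")
    r = rev[root_leaf]
    g = u_net.graph
    dist = nx.single_source_shortest_path_length(g, r)
    arcs: List[Edge] = []
    bridge_set = set(_edge(u, v) for u, v in nx.bridges(g))
    for e in bridge_set:
        u, v = e
        # direct away from r: the endpoint closer to r is the tail
        h = g.copy()
        h.remove_edge(u, v)
        if r in nx.node_connected_component(h, u):
            arcs.append((u, v))
        else:
            arcs.append((v, u))
    for comp in blobs(u_net):
        entry = min(comp, key=lambda n: (dist[n], n))
        external = sorted(
            n
            for n in comp
            if n != entry
            and any(nb not in comp for nb in g.neighbors(n))
        )
        if not external:
            raise NotRootable("blob with no exit (redundant terminal component)")
        exit_node = external[0]
        order = _bipolar_order(g, comp, entry, exit_node)
        pos = {n: i for i, n in enumerate(order)}
        for u, v in g.subgraph(comp).edges:
            arcs.append((u, v) if pos[u] < pos[v] else (v, u))
    labels = {n: lab for n, lab in u_net.leaf_labels.items() if n != r}
    net = RootedNetwork(arcs, labels, nodes=u_net.nodes)
    problems = validate_rooted(net)
    if problems:
        raise AlgorithmError(f"orientation produced invalid network: {problems}")
    return net


def underlying(net: RootedNetwork, root_label: str = ROOT_LABEL) -> UnrootedNetwork:
    """Forget directions; the root becomes a leaf carrying root_label."""
    labels = dict(net.leaf_labels)
    labels[net.root] = root_label
    return UnrootedNetwork(
        [_edge(u, v) for u, v in net.arcs], labels, nodes=net.nodes
    )


# -- SPR moves -------------------------------------------------------------


@dataclass(frozen=True)
class SPRMove:
    """Relocate the ``end``-end of edge {end, other} onto ``target``."""

    end: Node
    other: Node
    target: Edge

    def to_json(self) -> dict:
        return {
            "kind": "spr",
            "end": self.end,
            "edge": sorted([self.end, self.other]),
            "target": list(self.target),
        }


@dataclass
class SPRApplication:
    network: UnrootedNetwork
    created: Node
    suppressed: Node
    restored_edge: Edge


def apply_spr(
    u_net: UnrootedNetwork, move: SPRMove, check: bool = True
) -> SPRApplication:
    g = u_net.graph
    end, other = move.end, move.other
    a, b = move.target
    if not g.has_edge(end, other):
        raise InvalidSPRMove(f"edge {{{end},{other}}} not in network")
    if not g.has_edge(a, b):
        raise InvalidSPRMove(f"target {{{a},{b}}} not in network")
    if _edge(end, other) == _edge(a, b):
        raise InvalidSPRMove("target equals moving edge")
    if g.degree(end) != 3:
        raise InvalidSPRMove("relocated end must be an internal (degree-3) node")
    h = g.copy()
    new = u_net.fresh_node()
    parallel = False
    h.remove_edge(a, b)  # subdivide target
    h.add_edge(a, new)
    h.add_edge(new, b)
    h.remove_edge(end, other)  # remove moving edge
    nbrs = sorted(h.neighbors(end))  # suppress end
    if len(nbrs) != 2:
        raise InvalidSPRMove("cannot suppress relocated end")
    p, c = nbrs
    h.remove_node(end)
    if h.has_edge(p, c):
        parallel = True
    h.add_edge(p, c)
    if h.has_edge(new, other):
        parallel = True
    h.add_edge(new, other)
    result = UnrootedNetwork(h.edges, u_net.leaf_labels, nodes=h.nodes)
    if check:
        if parallel:
            raise InvalidSPRMove("move creates parallel edges")
        problems = validate_unrooted(result)
        if problems:
            raise InvalidSPRMove("; ".join(problems))
    return SPRApplication(
        result, created=new, suppressed=end, restored_edge=_edge(p, c)
    )


def check_spr(u_net: UnrootedNetwork, move: SPRMove) -> Optional[str]:
    try:
        apply_spr(u_net, move, check=True)
    except InvalidSPRMove as exc:
        return str(exc)
    return None


def invert_spr(app: SPRApplication, move: SPRMove) -> SPRMove:
    return SPRMove(end=app.created, other=move.other, target=app.restored_edge)


def enumerate_spr(u_net: UnrootedNetwork) -> List[SPRMove]:
    out = []
    edges = sorted(u_net.edges)
    for u, v in edges:
        for end, other in ((u, v), (v, u)):
            for t in edges:
                if t == _edge(u, v):
                    continue
                m = SPRMove(end=end, other=other, target=t)
                if check_spr(u_net, m) is None:
                    out.append(m)
    return out


def apply_spr_sequence(
    u_net: UnrootedNetwork, seq: Iterable[SPRMove]
) -> UnrootedNetwork:
    cur = u_net
    for m in seq:
        cur = apply_spr(cur, m).network
    return cur


def project_move(move: Move) -> SPRMove:
    """The SPR move induced on the underlying graph by a rooted move."""
    u, v = move.moving_edge
    end, other = (u, v) if move.kind == "tail" else (v, u)
    return SPRMove(end=end, other=other, target=_edge(*move.target_edge))


def exact_spr_distance(
    u_a: UnrootedNetwork, u_b: UnrootedNetwork, cap: int
) -> Optional[int]:
    """Exact SPR distance by breadth-first search with canonical-form
    deduplication; None if not reached within cap moves."""
    if u_a.labels() != u_b.labels():
        raise TierMismatch("label sets differ")
    target = canonical_form_unrooted(u_b)
    if canonical_form_unrooted(u_a) == target:
        return 0
    seen = {canonical_form_unrooted(u_a)}
    queue = deque([(u_a, 0)])
    while queue:
        cur, d = queue.popleft()
        if d >= cap:
            continue
        for m in enumerate_spr(cur):
            res = apply_spr(cur, m, check=False).network
            tok = canonical_form_unrooted(res)
            if tok == target:
                return d + 1
            if tok not in seen:
                seen.add(tok)
                queue.append((res, d + 1))
    return None


# -- terminal-component removal --------------------------------------------


def strip_terminal_component(
    u_net: UnrootedNetwork,
) -> Tuple[UnrootedNetwork, SPRMove]:
    comps = terminal_components(u_net)
    if not comps:
        raise NoTerminalComponent("network has no redundant terminal component")
    comp = comps[0]
    cu, cv = comp.cut_edge
    v = cv if cv in comp.nodes else cu  # component-side end of the cut-edge
    u = cu if v == cv else cv
    x, y = sorted(n for n in u_net.neighbors(v) if n != u)
    leaf_edges = sorted(
        _edge(leaf, u_net.neighbors(leaf)[0]) for leaf in u_net.leaves()
    )
    before = len(comps)
    for le in leaf_edges:
        m = SPRMove(end=v, other=x, target=le)
        if check_spr(u_net, m) is not None:
            continue
        app = apply_spr(u_net, m)
        after = len(terminal_components(app.network))
        if after < before:
            return app.network, m
    raise AlgorithmError("no leaf edge accepted the strip move")


def make_rootable(
    u_net: UnrootedNetwork,
) -> Tuple[UnrootedNetwork, List[SPRMove]]:
    cur, moves = u_net, []
    k = u_net.reticulation_number
    while terminal_components(cur):
        cur, m = strip_terminal_component(cur)
        moves.append(m)
    if len(moves) > k // 3:
        raise AlgorithmError(
            f"{len(moves)} strip moves exceed the k/3 = {k // 3} bound"
        )
    return cur, moves


def _make_rootable_tracked(
    u_net: UnrootedNetwork,
) -> Tuple[UnrootedNetwork, List[Tuple[SPRMove, SPRApplication]]]:
    cur, events = u_net, []
    while terminal_components(cur):
        nxt, m = strip_terminal_component(cur)
        app = apply_spr(cur, m)
        events.append((m, app))
        cur = app.network
    return cur, events


# -- SPR connectivity -------------------------------------------------------


def spr_connect(
    u_a: UnrootedNetwork, u_b: UnrootedNetwork
) -> List[SPRMove]:
    """SPR sequence from u_a to u_b of length at most n + (8/3)k: strip
    both networks to rootable form, orient them at a common leaf, run the
    frontier construction with triangle re-orientation, and project the
    rooted moves back down."""
    assert_valid_unrooted(u_a)
    assert_valid_unrooted(u_b)
    if u_a.labels() != u_b.labels():
        raise TierMismatch("label sets differ")
    if (
        u_a.graph.number_of_nodes() != u_b.graph.number_of_nodes()
        or u_a.graph.number_of_edges() != u_b.graph.number_of_edges()
    ):
        raise TierMismatch("tier (node/edge counts) differs")
    if is_isomorphic_unrooted(u_a, u_b):
        return []
    stripped_a, strips_a = _make_rootable_tracked(u_a)
    stripped_b, strips_b = _make_rootable_tracked(u_b)
    r = min(u_a.labels())
    rooted_a = orient(stripped_a, r)
    rooted_b = orient(stripped_b, r)
    state = init_frontier(
        rooted_a, rooted_b, use_head=True, allow_reorient=True, check_exclusion=False
    )
    rooted_seq = run_frontier(state)
    out: List[SPRMove] = [m for m, _ in strips_a]
    out.extend(project_move(m) for m in rooted_seq)

    # unwind the strips applied to u_b, translated onto the evolved a side
    final_rooted = state.a.net
    iso = is_isomorphic(rooted_b, final_rooted)
    if not iso:
        raise AlgorithmError("frontier finished but oriented networks differ")
    psi = dict(iso.mapping)
    cur = underlying(final_rooted, root_label=r)
    for mv, app in reversed(strips_b):
        inv = invert_spr(app, mv)
        translated = SPRMove(
            end=psi[inv.end],
            other=psi[inv.other],
            target=_edge(psi[inv.target[0]], psi[inv.target[1]]),
        )
        app2 = apply_spr(cur, translated)
        cur = app2.network
        out.append(translated)
        psi = {n: psi[n] for n in app.network.nodes if n != app.created}
        psi[app.suppressed] = app2.created

    n = len(u_a.labels())
    k = u_a.reticulation_number
    if 3 * len(out) > 3 * n + 8 * k:
        raise AlgorithmError(
            f"emitted {len(out)} SPR moves, bound is n + 8k/3 = {n + 8 * k / 3:.2f}"
        )
    return out


# -- exhaustive terminal-component candidates --------------------------------


def _graphs_with_degrees(degrees: List[int]):
    """All simple labelled graphs on nodes 0..n-1 realising the degree
    sequence, by backtracking (each graph yielded exactly once)."""
    n = len(degrees)
    rem = list(degrees)
    adj: Set[Tuple[int, int]] = set()
    from itertools import combinations

    def rec():
        u = next((i for i in range(n) if rem[i] > 0), None)
        if u is None:
            yield frozenset(adj)
            return
        partners = [
            v
            for v in range(n)
            if v != u and rem[v] > 0 and (u, v) not in adj and (v, u) not in adj
        ]
        if len(partners) < rem[u]:
            return
        for chosen in combinations(partners, rem[u]):
            for v in chosen:
                adj.add((u, v))
                rem[v] -= 1
            saved, rem[u] = rem[u], 0
            yield from rec()
            rem[u] = saved
            for v in chosen:
                adj.discard((u, v))
                rem[v] += 1

    yield from rec()


def enumerate_terminal_component_candidates(
    n_nodes: int, limit: Optional[int] = None
) -> List[nx.Graph]:
    """Simple connected biconnected graphs on n_nodes in which one node has
    degree 2 (the attachment point of the single cut-edge) and all others
    degree 3 — the shapes a redundant terminal component can take.

    With ``limit`` the search stops after that many survivors; the search is
    exhaustive either way when it returns fewer (in particular, an empty
    result is a proof of emptiness).
    """
    if n_nodes < 1:
        return []
    degrees = [2] + [3] * (n_nodes - 1)
    if sum(degrees) % 2 == 1:
        return []
    out: List[nx.Graph] = []
    for edge_set in _graphs_with_degrees(degrees):
        g = nx.Graph(sorted(edge_set))
        if g.number_of_nodes() != n_nodes or not nx.is_connected(g):
            continue
        if n_nodes >= 3 and not nx.is_biconnected(g):
            continue
        out.append(g)
        if limit is not None and len(out) >= limit:
            break
    return out


# -- edge-list I/O ----------------------------------------------------------


def read_edgelist(text: str) -> UnrootedNetwork:
    """Parse the plain text format: one ``u v`` pair per line, label
    headers as ``#label NODE TAXON``."""
    edges: List[Edge] = []
    labels: Dict[Node, str] = {}
    nodes: List[Node] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#label"):
            parts = line.split()
            if len(parts) != 3:
                raise NetworkError(f"bad label line: {raw!r}")
            labels[parts[1]] = parts[2]
            continue
        if line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise NetworkError(f"bad edge line: {raw!r}")
        edges.append(_edge(parts[0], parts[1]))
        nodes.extend(parts)
    return UnrootedNetwork(edges, labels, nodes=nodes)


def write_graphml(u_net: UnrootedNetwork) -> str:
    g = u_net.graph.copy()
    for node, taxon in u_net.leaf_labels.items():
        g.nodes[node]["label"] = taxon
    return "\n".join(nx.generate_graphml(g))


def write_edgelist(u_net: UnrootedNetwork) -> str:
    lines = [
        f"#label {node} {taxon}"
        for node, taxon in sorted(u_net.leaf_labels.items())
    ]
    lines.extend(f"{u} {v}" for u, v in sorted(u_net.edges))
    return "\n".join(lines) + "\n"
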