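"""Tail and head moves on rooted binary phylogenetic networks.

A tail move of arc e=(u,v) to arc f=(s,t) deletes e, subdivides f with a
new node u', suppresses the now indegree-1/outdegree-1 node u, and adds
(u',v).  A head move of e=(u,v) to f does the same with the roles of the
endpoints swapped: v is suppressed and the new arc is (u,v').  Head moves
only apply to reticulation edges (head is a reticulation).

Moves are addressed by arcs of the host network; the nodes created and
suppressed during application never appear in user-facing descriptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx

from .netcore import (
    Arc,
    NetworkError,
    Node,
    RootedNetwork,
    canonical_form,
    is_above,
    lca_set,
    validate_rooted,
)


class InvalidMove(ValueError):
    """Raised when a move violates the validity conditions."""


@dataclass(frozen=True)
class Move:
    kind: str  # "tail" | "head"
    moving_edge: Arc
    target_edge: Arc

    def __post_init__(self) -> None:
        if self.kind not in ("tail", "head"):
            raise ValueError(f"unknown move kind {self.kind!r}")
        if self.moving_edge == self.target_edge:
            raise ValueError("moving edge and target edge must differ")

    def to_json(self) -> dict:
        return {
            "kind": self.kind,
            "edge": list(self.moving_edge),
            "target": list(self.target_edge),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "Move":
        return cls(payload["kind"], tuple(payload["edge"]), tuple(payload["target"]))


@dataclass(frozen=True)
class Triangle:
    """Nodes x,u,y with arcs (x,u),(u,y),(x,y); (x,y) is the long edge."""

    top: Node
    side: Node
    bottom_head: Node

    @property
    def long_edge(self) -> Arc:
        return (self.top, self.bottom_head)

    @property
    def bottom_edge(self) -> Arc:
        return (self.side, self.bottom_head)


@dataclass
class MoveApplication:
    """Result of applying a move plus bookkeeping needed for inversion."""

    network: RootedNetwork
    created: Node  # subdivision node placed on the target edge
    suppressed: Node  # tail (tail move) or head (head move) of the moving edge
    restored_arc: Arc  # arc created by suppressing the degree-2 node


MoveSequence = List[Move]


def _require_arc(net: RootedNetwork, e: Arc) -> None:
    if not net.has_arc(*e):
        raise NetworkError(f"arc {e} not in network")


# -- movability and triangles ----------------------------------------------


def find_triangles(net: RootedNetwork) -> List[Triangle]:
    out = []
    g = net.digraph
    for x, u in g.edges:
        for y in g.successors(u):
            if g.has_edge(x, y):
                out.append(Triangle(top=x, side=u, bottom_head=y))
    return sorted(out, key=lambda t: (t.top, t.side, t.bottom_head))


def is_movable(net: RootedNetwork, e: Arc) -> Tuple[bool, Optional[str]]:
    """Whether the tail of e can be detached without breaking the network."""
    _require_arc(net, e)
    u, v = e
    if net.indeg(u) == 0:
        return False, "root-tail"
    if net.is_reticulation(u):
        return False, "reticulation-tail"
    # removal of e followed by suppressing u creates parallel arcs iff the
    # parent of u and the other child of u are already joined by an arc
    (p,) = net.parents(u)
    others = [c for c in net.children(u) if c != v]
    for c in others:
        if net.has_arc(p, c):
            return False, "triangle-parallel"
    return True, None


# -- tail moves -------------------------------------------------------------


def check_tail_move(net: RootedNetwork, e: Arc, f: Arc) -> Optional[str]:
    """None if moving the tail of e to f is valid, else a violation string."""
    _require_arc(net, e)
    _require_arc(net, f)
    if e == f:
        return "target equals moving edge"
    u, v = e
    s, t = f
    ok, reason = is_movable(net, e)
    if not ok:
        return f"not movable: {reason}"
    if is_above(net, v, s):  # f below v (tail of f at or below v) => cycle
        return "cycle: target edge is below the moving head"
    if t == v:
        return "parallel: target edge ends at the moving head"
    return None


def apply_tail_move(
    net: RootedNetwork, move: Move, check: bool = True
) -> MoveApplication:
    if move.kind != "tail":
        raise InvalidMove(f"expected a tail move, got {move.kind}")
    e, f = move.moving_edge, move.target_edge
    if check:
        violation = check_tail_move(net, e, f)
        if violation is not None:
            raise InvalidMove(f"tail move {e}->{f}: {violation}")
    u, v = e
    s, t = f
    g = net.digraph.copy()
    new = net.fresh_node()
    g.remove_edge(u, v)  # 1. delete e
    g.remove_edge(s, t)  # 2. subdivide f
    g.add_edge(s, new)
    g.add_edge(new, t)
    (p,) = g.predecessors(u)  # 3. suppress u
    (c,) = g.successors(u)
    g.remove_node(u)
    g.add_edge(p, c)
    g.add_edge(new, v)  # 4. add (u', v)
    result = RootedNetwork(g.edges, net.leaf_labels, nodes=g.nodes)
    return MoveApplication(result, created=new, suppressed=u, restored_arc=(p, c))


def invert_tail_move(app: MoveApplication, move: Move) -> Move:
    """The tail move that undoes `move` when applied to `app.network`."""
    _, v = move.moving_edge
    return Move("tail", (app.created, v), app.restored_arc)


# -- head moves -------------------------------------------------------------


def check_head_move(net: RootedNetwork, e: Arc, f: Arc) -> Optional[str]:
    """None if moving the head of e to f is valid, else a violation string.

    The closed-form conditions below were derived by case analysis; the
    test suite verifies that they agree with the apply-and-validate oracle
    on every arc pair of every network in the enumerated tiers.
    """
    _require_arc(net, e)
    _require_arc(net, f)
    if e == f:
        return "target equals moving edge"
    u, v = e
    s, t = f
    if not net.is_reticulation(v):
        return "not a reticulation edge"
    if s == u:
        return "parallel: target edge starts at the moving tail"
    if is_above(net, t, u):  # path t => u plus new arc (u, v') => cycle
        return "cycle: target edge is above the moving tail"
    # suppression of v joins its other parent w to its child c
    (w,) = [p for p in net.parents(v) if p != u] or [None]
    if w is None:
        return "not a reticulation edge"
    (c,) = net.children(v)
    # when f is incident to v, or f is the long edge (w, c) itself, the
    # subdivision step removes the adjacency before suppression recreates it
    if f not in ((w, v), (v, c), (w, c)):
        if net.has_arc(w, c):
            return "parallel: suppressing the head joins already-adjacent nodes"
    return None


def apply_head_move(
    net: RootedNetwork, move: Move, check: bool = True
) -> MoveApplication:
    if move.kind != "head":
        raise InvalidMove(f"expected a head move, got {move.kind}")
    e, f = move.moving_edge, move.target_edge
    if check:
        violation = check_head_move(net, e, f)
        if violation is not None:
            raise InvalidMove(f"head move {e}->{f}: {violation}")
    u, v = e
    s, t = f
    g = net.digraph.copy()
    new = net.fresh_node()
    g.remove_edge(u, v)  # 1. delete e
    g.remove_edge(s, t)  # 2. subdivide f
    g.add_edge(s, new)
    g.add_edge(new, t)
    (w,) = g.predecessors(v)  # 3. suppress v
    (c,) = g.successors(v)
    g.remove_node(v)
    g.add_edge(w, c)
    g.add_edge(u, new)  # 4. add (u, v')
    result = RootedNetwork(g.edges, net.leaf_labels, nodes=g.nodes)
    return MoveApplication(result, created=new, suppressed=v, restored_arc=(w, c))


def invert_head_move(app: MoveApplication, move: Move) -> Move:
    u, _ = move.moving_edge
    return Move("head", (u, app.created), app.restored_arc)


# -- generic application ----------------------------------------------------


def apply_move(net: RootedNetwork, move: Move, check: bool = True) -> MoveApplication:
    if move.kind == "tail":
        return apply_tail_move(net, move, check=check)
    return apply_head_move(net, move, check=check)


def check_move(net: RootedNetwork, move: Move) -> Optional[str]:
    if move.kind == "tail":
        return check_tail_move(net, move.moving_edge, move.target_edge)
    return check_head_move(net, move.moving_edge, move.target_edge)


def invert_move(app: MoveApplication, move: Move) -> Move:
    if move.kind == "tail":
        return invert_tail_move(app, move)
    return invert_head_move(app, move)


def apply_sequence(net: RootedNetwork, seq: Iterable[Move]) -> RootedNetwork:
    """Replay a move sequence; every prefix must be valid."""
    cur = net
    for m in seq:
        cur = apply_move(cur, m).network
    return cur


# -- distance ---------------------------------------------------------------


def move_distance(net: RootedNetwork, move: Move) -> int:
    """d where d+1 is the undirected shortest-path length, after deleting the
    moving edge and subdividing the target, between the relocated endpoint
    and the subdivision node."""
    violation = check_move(net, move)
    if violation is not None:
        raise InvalidMove(violation)
    u, v = move.moving_edge
    s, t = move.target_edge
    g = net.digraph.copy()
    g.remove_edge(u, v)
    g.remove_edge(s, t)
    new = net.fresh_node()
    g.add_edge(s, new)
    g.add_edge(new, t)
    anchor = u if move.kind == "tail" else v
    d = nx.shortest_path_length(g.to_undirected(as_view=False), anchor, new)
    return d - 1


# -- enumeration ------------------------------------------------------------

_CLASSES = ("tail", "tail1", "head", "head1", "rnni", "rspr")


def enumerate_moves(
    net: RootedNetwork, cls: str = "rspr", nontrivial: bool = False
) -> List[Move]:
    """All valid moves of the class, in canonical arc order.

    With ``nontrivial``, moves whose result is isomorphic to the input are
    dropped.
    """
    if cls not in _CLASSES:
        raise ValueError(f"unknown move class {cls!r}; expected one of {_CLASSES}")
    kinds = []
    if cls in ("tail", "tail1", "rnni", "rspr"):
        kinds.append("tail")
    if cls in ("head", "head1", "rnni", "rspr"):
        kinds.append("head")
    dist1 = cls in ("tail1", "head1", "rnni")
    arcs = sorted(net.arcs)
    out: List[Move] = []
    base_canon = canonical_form(net) if nontrivial else None
    for kind in kinds:
        for e in arcs:
            for f in arcs:
                if e == f:
                    continue
                m = Move(kind, e, f)
                if check_move(net, m) is not None:
                    continue
                if dist1 and move_distance(net, m) != 1:
                    continue
                if nontrivial:
                    res = apply_move(net, m, check=False).network
                    if canonical_form(res) == base_canon:
                        continue
                out.append(m)
    return out


def sequence_to_json(seq: MoveSequence) -> str:
    return json.dumps([m.to_json() for m in seq])


def sequence_from_json(text: str) -> MoveSequence:
    return [Move.from_json(p) for p in json.loads(text)]
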