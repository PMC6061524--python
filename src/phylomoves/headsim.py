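"""Simulation of distance-1 head moves by short tail-move sequences.

Every valid distance-1 head move on a network with at least two leaves can
be replaced by at most four tail moves, except on one exceptional two-leaf
single-reticulation network where no nontrivial tail move exists at all.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .netcore import (
    Arc,
    NetworkError,
    Node,
    RootedNetwork,
    canonical_form,
    tier_signature,
)
from .moves import (
    InvalidMove,
    Move,
    MoveSequence,
    apply_head_move,
    apply_move,
    apply_tail_move,
    check_head_move,
    enumerate_moves,
    move_distance,
)


class ExceptionalNetworkError(RuntimeError):
    """The head move cannot be simulated: no nontrivial tail move exists."""


class TierMismatch(ValueError):
    pass


@dataclass(frozen=True)
class Head1Classification:
    case: str  # one of "a".."f"
    trivial: bool  # result isomorphic to the input network
    flags: Tuple[str, ...]


def classify_head1(net: RootedNetwork, move: Move) -> Head1Classification:
    """Assign a distance-1 head move to its unique local pattern.

    Cases: (a) sideways below a tree node, (b) sideways above a
    reticulation, (c) downward through a tree node, (d) downward through a
    reticulation, (e) upward through a tree node, (f) upward through a
    reticulation.
    """
    if move.kind != "head":
        raise InvalidMove("expected a head move")
    violation = check_head_move(net, move.moving_edge, move.target_edge)
    if violation is not None:
        raise InvalidMove(violation)
    if move_distance(net, move) != 1:
        raise InvalidMove("not a distance-1 head move")
    u, v = move.moving_edge
    s, t = move.target_edge
    (w,) = [p for p in net.parents(v) if p != u]
    (c,) = net.children(v)

    flags: List[str] = []
    if s == w:  # target shares v's other parent
        case = "a" if net.is_tree_node(w) else None
        if case is None:
            raise InvalidMove("unclassifiable sideways move")
        if t == c:
            flags.append("x_eq_y")
        if u in net.parents(w):
            flags.append("u_eq_w")
    elif t == c:  # target enters v's child, which must be a reticulation
        case = "b"
        other = [p for p in net.parents(c) if p != v]
        if other and other[0] == w:
            flags.append("x_eq_y")
    elif s == c:  # target leaves v's child
        case = "c" if net.is_tree_node(c) else "d"
        if case == "d":
            other = [p for p in net.parents(c) if p != v]
            if other and other[0] == u:
                flags.append("u_eq_y")
    elif t == w:  # target enters v's other parent
        case = "e" if net.is_tree_node(w) else "f"
        if case == "f":
            other = [p for p in net.parents(w) if p != s]
            if other and other[0] == u:
                flags.append("u_eq_y")
    else:
        raise InvalidMove("move is not distance-1 (no shared endpoint)")

    res = apply_head_move(net, move).network
    trivial = canonical_form(res) == canonical_form(net)
    return Head1Classification(case=case, trivial=trivial, flags=tuple(flags))


def is_exceptional_two_leaf(net: RootedNetwork) -> bool:
    """Tier (n=2, k=1) network with no nontrivial tail move at all."""
    sig = tier_signature(net)
    if (sig.n_leaves, sig.k) != (2, 1):
        return False
    return not enumerate_moves(net, "tail", nontrivial=True)


def tail_reachable(
    net_a: RootedNetwork, net_b: RootedNetwork, cap: int
) -> Optional[MoveSequence]:
    """Shortest nontrivial-tail-move sequence from a to b within cap moves,
    found by breadth-first search with canonical-form deduplication; None
    if not found within the cap."""
    sig_a, sig_b = tier_signature(net_a), tier_signature(net_b)
    if sig_a != sig_b or net_a.labels() != net_b.labels():
        raise TierMismatch(f"tier/labels differ: {sig_a} vs {sig_b}")
    target = canonical_form(net_b)
    if canonical_form(net_a) == target:
        return []
    seen = {canonical_form(net_a)}
    queue = deque([(net_a, [])])
    while queue:
        cur, seq = queue.popleft()
        if len(seq) >= cap:
            continue
        for m in enumerate_moves(cur, "tail"):
            res = apply_tail_move(cur, m, check=False).network
            tok = canonical_form(res)
            if tok == target:
                return seq + [m]
            if tok in seen:
                continue
            seen.add(tok)
            queue.append((res, seq + [m]))
    return None


def _case_c_shortcut(net: RootedNetwork, move: Move) -> MoveSequence:
    """Single tail move replacing a case (c) head move: with v's child z a
    tree node, move the tail of z's other child edge to v's other parent
    edge."""
    u, v = move.moving_edge
    s, t = move.target_edge
    (w,) = [p for p in net.parents(v) if p != u]
    z = s  # = child of v, a tree node
    (other,) = [x for x in net.children(z) if x != t]
    return [Move("tail", (z, other), (w, v))]


def simulate_head1(
    net: RootedNetwork, move: Move, cap: Optional[int] = None
) -> MoveSequence:
    """Tail-move sequence whose application is isomorphic to the head move.

    Length is at most 4 for networks with at least two leaves; degenerate
    moves whose result is isomorphic to the input yield the empty sequence.
    Raises ExceptionalNetworkError on the exceptional two-leaf tier-1
    network, where the (unique nontrivial) head move has no tail-move
    substitute.
    """
    cls = classify_head1(net, move)
    if cls.trivial:
        return []
    target_net = apply_head_move(net, move).network
    if cls.case == "c":
        seq = _case_c_shortcut(net, move)
        try:
            check = apply_tail_move(net, seq[0]).network
        except InvalidMove:
            pass  # rare degenerate overlap: fall through to BFS
        else:
            if canonical_form(check) == canonical_form(target_net):
                return seq
    if is_exceptional_two_leaf(net):
        raise ExceptionalNetworkError(
            "distance-1 head move on the exceptional two-leaf tier-1 network "
            "cannot be substituted by tail moves"
        )
    n_leaves = len(net.leaf_labels)
    if cap is None:
        cap = 4 if n_leaves >= 2 else 8
    seq = tail_reachable(net, target_net, cap=cap)
    if seq is None and n_leaves < 2:
        seq = tail_reachable(net, target_net, cap=2 * cap)
    if seq is None:
        raise InvalidMove(
            f"no simulating tail sequence found within cap={cap}"
        )
    return seq
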