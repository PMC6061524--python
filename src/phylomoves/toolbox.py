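"""Enumeration, random generation, exact-distance oracles, agreement
forests and named fixtures used throughout the test suite.

The tier enumerator is deliberately redundant: candidates come from
add-reticulation gluings on the tier below, and the set is then closed
under nontrivial rSPR moves, which provably connect every tier.  The two
routes guard each other.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .netcore import (
    NetworkError,
    Node,
    RootedNetwork,
    canonical_form,
    is_isomorphic,
    tier_signature,
    validate_rooted,
)
from .moves import Move, apply_move, enumerate_moves
from .headsim import TierMismatch
from .unrooted import UnrootedNetwork, assert_valid_unrooted


class SizeGuardExceeded(ValueError):
    pass


# -- tree and tier enumeration ----------------------------------------------


def enumerate_trees(labels: Sequence[str]) -> List[RootedNetwork]:
    """All rooted binary trees on the label set (root has outdegree 1)."""
    labels = sorted(labels)
    if not labels:
        raise ValueError("need at least one label")
    first = RootedNetwork([("rho", "L0")], {"L0": labels[0]})
    trees = [first]
    for i, lab in enumerate(labels[1:], start=1):
        nxt: List[RootedNetwork] = []
        for t in trees:
            for s, d in sorted(t.arcs):
                g = t.digraph.copy()
                mid, leaf = f"I{i}_{s}_{d}", f"L{i}"
                g.remove_edge(s, d)
                g.add_edge(s, mid)
                g.add_edge(mid, d)
                g.add_edge(mid, leaf)
                lab_map = dict(t.leaf_labels)
                lab_map[leaf] = lab
                nxt.append(RootedNetwork(g.edges, lab_map, nodes=g.nodes))
        trees = nxt
    return trees


def add_reticulation(
    net: RootedNetwork, e1: Tuple[Node, Node], e2: Tuple[Node, Node]
) -> Optional[RootedNetwork]:
    """Subdivide e1 with the new tail and e2 with the new head and connect
    them; None if the result is not a valid network."""
    if e1 == e2:
        return None
    g = net.digraph.copy()
    a, b = "_ra", "_rb"
    (s1, t1), (s2, t2) = e1, e2
    g.remove_edge(s1, t1)
    g.add_edge(s1, a)
    g.add_edge(a, t1)
    g.remove_edge(s2, t2)
    g.add_edge(s2, b)
    g.add_edge(b, t2)
    g.add_edge(a, b)
    out = RootedNetwork(g.edges, net.leaf_labels, nodes=g.nodes)
    if validate_rooted(out):
        return None
    # normalise node ids so repeated gluings do not collide
    rename = {a: out.fresh_node("_g"), b: out.fresh_node("_h")}
    g2 = nx.relabel_nodes(out.digraph, rename, copy=True)
    return RootedNetwork(g2.edges, net.leaf_labels, nodes=g2.nodes)


def _default_labels(n: int) -> List[str]:
    return [f"t{i}" for i in range(1, n + 1)]


@lru_cache(maxsize=None)
def _enumerate_tier_cached(n: int, k: int, max_nodes: int) -> Tuple[RootedNetwork, ...]:
    if 2 * n + 2 * k > max_nodes:
        raise SizeGuardExceeded(
            f"tier ({n},{k}) has {2 * n + 2 * k} nodes > guard {max_nodes}"
        )
    labels = _default_labels(n)
    if k == 0:
        trees = enumerate_trees(labels)
        uniq: Dict[tuple, RootedNetwork] = {}
        for t in trees:
            uniq.setdefault(canonical_form(t), t)
        return tuple(uniq[c] for c in sorted(uniq))
    below = _enumerate_tier_cached(n, k - 1, max_nodes)
    found: Dict[tuple, RootedNetwork] = {}
    for net in below:
        arcs = sorted(net.arcs)
        for e1 in arcs:
            for e2 in arcs:
                glued = add_reticulation(net, e1, e2)
                if glued is not None:
                    found.setdefault(canonical_form(glued), glued)
    if not found and n == 1 and k == 2:
        # tier (1,1) is empty, so gluing cannot seed tier (1,2); it is
        # nonetheless nonempty (two stacked triangles over a single leaf)
        seed = _stacked_triangles_on(_default_labels(1)[0])
        found[canonical_form(seed)] = seed
    # close under nontrivial rSPR moves: these connect every tier, so the
    # closure is provably the complete tier
    queue = deque(found.values())
    while queue:
        cur = queue.popleft()
        for m in enumerate_moves(cur, "rspr"):
            res = apply_move(cur, m, check=False).network
            tok = canonical_form(res)
            if tok not in found:
                found[tok] = res
                queue.append(res)
    return tuple(found[c] for c in sorted(found))


def enumerate_tier(n: int, k: int, max_nodes: int = 10) -> List[RootedNetwork]:
    """One representative per isomorphism class of the (n, k) tier."""
    return list(_enumerate_tier_cached(n, k, max_nodes))


# -- random generation ------------------------------------------------------


def random_tree(labels: Sequence[str], rng: random.Random) -> RootedNetwork:
    labels = sorted(labels)
    net = RootedNetwork([("rho", "L0")], {"L0": labels[0]})
    for i, lab in enumerate(labels[1:], start=1):
        arcs = sorted(net.arcs)
        s, d = rng.choice(arcs)
        g = net.digraph.copy()
        mid, leaf = f"I{i}", f"L{i}"
        g.remove_edge(s, d)
        g.add_edge(s, mid)
        g.add_edge(mid, d)
        g.add_edge(mid, leaf)
        lab_map = dict(net.leaf_labels)
        lab_map[leaf] = lab
        net = RootedNetwork(g.edges, lab_map, nodes=g.nodes)
    return net


def random_network(
    n: int, k: int, seed: int, labels: Optional[Sequence[str]] = None
) -> RootedNetwork:
    """A valid tier-(n, k) network, deterministic per seed: random tree,
    then k reticulation additions by edge-pair gluing with rejection."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    rng = random.Random(seed)
    labels = list(labels) if labels is not None else _default_labels(n)
    if n == 1 and k == 1:
        raise ValueError("tier (1, 1) is empty")
    if n == 1 and k >= 2:
        net = _stacked_triangles_on(sorted(labels)[0])
        added = 2
        tries = 0
        while added < k:
            tries += 1
            if tries > 10000:
                raise RuntimeError("failed to place reticulations (retry budget)")
            arcs = sorted(net.arcs)
            glued = add_reticulation(net, rng.choice(arcs), rng.choice(arcs))
            if glued is not None:
                net = glued
                added += 1
        return net
    net = random_tree(labels, rng)
    added = 0
    tries = 0
    while added < k:
        tries += 1
        if tries > 10000:
            raise RuntimeError("failed to place reticulations (retry budget)")
        arcs = sorted(net.arcs)
        e1 = rng.choice(arcs)
        e2 = rng.choice(arcs)
        glued = add_reticulation(net, e1, e2)
        if glued is None:
            continue
        net = glued
        added += 1
    return net


# -- exact distances --------------------------------------------------------


@dataclass(frozen=True)
class DistanceResult:
    distance: Optional[int]  # None when not found
    exhausted: bool  # True when the whole component was explored

    @property
    def unreachable(self) -> bool:
        return self.distance is None and self.exhausted


def exact_distance(
    a: RootedNetwork,
    b: RootedNetwork,
    cls: str = "tail",
    cap: int = 10,
    max_states: int = 200_000,
) -> DistanceResult:
    """Exact move distance by BFS with canonical deduplication.

    Returns the distance when found within cap; otherwise reports whether
    the reachable component was exhausted (proving unreachability) or the
    search simply gave up.
    """
    sig_a, sig_b = tier_signature(a), tier_signature(b)
    if sig_a != sig_b or a.labels() != b.labels():
        raise TierMismatch(f"tier/labels differ: {sig_a} vs {sig_b}")
    target = canonical_form(b)
    if canonical_form(a) == target:
        return DistanceResult(0, exhausted=False)
    seen = {canonical_form(a)}
    queue = deque([(a, 0)])
    truncated = False
    while queue:
        cur, d = queue.popleft()
        if d >= cap:
            truncated = True
            continue
        for m in enumerate_moves(cur, cls):
            res = apply_move(cur, m, check=False).network
            tok = canonical_form(res)
            if tok == target:
                return DistanceResult(d + 1, exhausted=False)
            if tok in seen:
                continue
            if len(seen) >= max_states:
                truncated = True
                continue
            seen.add(tok)
            queue.append((res, d + 1))
    return DistanceResult(None, exhausted=not truncated)


# -- restricted trees and agreement forests ---------------------------------

RHO = "ρ"


def _tree_paths_to_root(t: RootedNetwork) -> Dict[Node, List[Node]]:
    out = {}
    for u in t.nodes:
        path = [u]
        while t.parents(path[-1]):
            path.append(t.parents(path[-1])[0])
        out[u] = path
    return out


def _spanning_nodes(t: RootedNetwork, block: FrozenSet[str]) -> Set[Node]:
    """Nodes of t on a path between two members of the block (leaves by
    label, plus the root when RHO is in the block)."""
    rev = {lab: node for node, lab in t.leaf_labels.items()}
    targets = [rev[lab] for lab in block if lab != RHO]
    if RHO in block:
        targets.append(t.root)
    if not targets:
        return set()
    paths = _tree_paths_to_root(t)
    span: Set[Node] = set()
    for a, b in combinations(targets, 2):
        pa, pb = paths[a], paths[b]
        sa, sb = set(pa), set(pb)
        lca = next(x for x in pa if x in sb)
        span.update(pa[: pa.index(lca) + 1])
        span.update(pb[: pb.index(lca) + 1])
    span.update(targets)
    return span


def restrict_tree(t: RootedNetwork, block: Iterable[str]) -> tuple:
    """Canonical shape token of the subtree of t induced by the block
    (a set of leaf labels, optionally including RHO for the root), after
    suppressing degree-two nodes."""
    block = frozenset(block)
    span = _spanning_nodes(t, block)
    if not span:
        return ("empty",)
    sub = t.digraph.subgraph(span)
    rev = {lab: node for node, lab in t.leaf_labels.items()}
    interest = {rev[lab] for lab in block if lab != RHO}
    root_marked = RHO in block

    def shape(u: Node) -> tuple:
        kids = sorted((shape(c) for c in sub.successors(u)), key=repr)
        if u in interest:
            return ("leaf", t.leaf_labels[u])
        if len(kids) == 1:
            return kids[0]  # suppress degree-2 node
        return ("node", tuple(kids))

    top = next(u for u in sub.nodes if sub.in_degree(u) == 0)
    tok = shape(top)
    if root_marked:
        tok = ("rho", tok)
    return tok


def is_agreement_forest(
    trees: Sequence[RootedNetwork], partition: Sequence[Iterable[str]]
) -> bool:
    """Whether the partition of X ∪ {RHO} is an agreement forest: the
    restricted subtrees agree across trees per block and are node-disjoint
    within each tree."""
    blocks = [frozenset(b) for b in partition]
    all_labels = set()
    for b in blocks:
        if all_labels & b:
            return False
        all_labels |= b
    expected = set(trees[0].labels()) | {RHO}
    if all_labels != expected:
        return False
    for b in blocks:
        shapes = {restrict_tree(t, b) for t in trees}
        if len(shapes) != 1:
            return False
    for t in trees:
        spans = [_spanning_nodes(t, b) for b in blocks]
        for s1, s2 in combinations(spans, 2):
            if s1 & s2:
                return False
    return True


def _set_partitions(items: List[str]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def maf_size_exhaustive(t1: RootedNetwork, t2: RootedNetwork) -> int:
    """Size (number of blocks) of a maximum agreement forest, by
    exhaustive search over all partitions of X ∪ {RHO}; |X| <= 6 guard.

    The rSPR distance between the trees equals this size minus one.
    """
    if t1.labels() != t2.labels():
        raise TierMismatch("label sets differ")
    labels = sorted(t1.labels())
    if len(labels) > 6:
        raise SizeGuardExceeded("exhaustive MAF limited to 6 leaves")
    best = None
    for part in _set_partitions(labels + [RHO]):
        if best is not None and len(part) >= best:
            continue
        if is_agreement_forest([t1, t2], part):
            best = len(part)
    if best is None:
        raise RuntimeError("no agreement forest found (singletons must work)")
    return best


# -- mycorrhizal forests ----------------------------------------------------


def build_mycorrhizal(
    trees: Sequence[RootedNetwork], root_component: RootedNetwork
) -> RootedNetwork:
    """Glue tree components onto the leaves of the root component: the root
    edge of the i-th tree is identified with the edge leading to the i-th
    leaf (in label order) of the root component."""
    r_leaves = sorted(root_component.leaf_labels, key=root_component.leaf_labels.get)
    if len(trees) != len(r_leaves):
        raise ValueError("one tree per root-component leaf required")
    g = nx.relabel_nodes(
        root_component.digraph, {u: f"R_{u}" for u in root_component.nodes}, copy=True
    )
    labels: Dict[Node, str] = {}
    for i, (tree, leaf) in enumerate(zip(trees, r_leaves)):
        leaf_r = f"R_{leaf}"
        (p,) = g.predecessors(leaf_r)
        g.remove_node(leaf_r)
        tg = nx.relabel_nodes(
            tree.digraph, {u: f"T{i}_{u}" for u in tree.nodes}, copy=True
        )
        t_root = next(u for u in tg.nodes if tg.in_degree(u) == 0)
        (t_child,) = tg.successors(t_root)
        tg.remove_node(t_root)
        g = nx.union(g, tg)
        g.add_edge(p, t_child)
        for u, lab in tree.leaf_labels.items():
            labels[f"T{i}_{u}"] = lab
    out = RootedNetwork(g.edges, labels, nodes=g.nodes)
    problems = validate_rooted(out)
    if problems:
        raise NetworkError("gluing produced an invalid network: " + "; ".join(problems))
    return out


# -- named fixtures ---------------------------------------------------------


def _triangle_net() -> RootedNetwork:
    arcs = [
        ("rho", "a"),
        ("a", "c"),
        ("a", "l1"),
        ("c", "u"),
        ("c", "r"),
        ("u", "r"),
        ("u", "l2"),
        ("r", "l3"),
    ]
    return RootedNetwork(arcs, {"l1": "t1", "l2": "t2", "l3": "t3"})


def _stacked_triangles_on(label: str) -> RootedNetwork:
    arcs = [
        ("rho", "a"),
        ("a", "b"),
        ("a", "r1"),
        ("b", "r1"),
        ("b", "r2"),
        ("r1", "r2"),
        ("r2", "l"),
    ]
    return RootedNetwork(arcs, {"l": label})


def _stacked_triangles() -> RootedNetwork:
    return _stacked_triangles_on("t1")


def _exceptional_two_leaf() -> RootedNetwork:
    arcs = [
        ("rho", "a"),
        ("a", "b"),
        ("a", "r"),
        ("b", "r"),
        ("b", "x"),
        ("r", "y"),
    ]
    return RootedNetwork(arcs, {"x": "t1", "y": "t2"})


def _exceptional_one_leaf() -> RootedNetwork:
    candidates = [
        net
        for net in enumerate_tier(1, 2)
        if not enumerate_moves(net, "head", nontrivial=True)
    ]
    if len(candidates) != 1:
        raise RuntimeError(
            f"expected a unique one-leaf tier-2 network with only trivial "
            f"head moves, found {len(candidates)}"
        )
    return candidates[0]


def _unrootable_5() -> UnrootedNetwork:
    # minimal redundant terminal component: K4 with one edge subdivided
    # (5 nodes, one of degree 2 that receives the cut-edge), attached to a
    # three-leaf remainder
    edges = [
        ("p", "q"),
        ("p", "r"),
        ("p", "s"),
        ("q", "r"),
        ("q", "s"),
        ("r", "m"),
        ("s", "m"),
        ("m", "v"),  # the cut-edge
        ("v", "w"),
        ("v", "l1"),
        ("w", "l2"),
        ("w", "l3"),
    ]
    u = UnrootedNetwork(edges, {"l1": "t1", "l2": "t2", "l3": "t3"})
    assert_valid_unrooted(u)
    return u


def fixtures() -> Dict[str, object]:
    return {
        "triangle_net": _triangle_net(),
        "stacked_triangles": _stacked_triangles(),
        "exceptional_two_leaf": _exceptional_two_leaf(),
        "exceptional_one_leaf": _exceptional_one_leaf(),
        "unrootable_5": _unrootable_5(),
    }
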