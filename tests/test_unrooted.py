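import random

import pytest

from phylomoves.headsim import TierMismatch
from phylomoves.moves import apply_move, enumerate_moves
from phylomoves.netcore import validate_rooted
from phylomoves.toolbox import random_network
from phylomoves.unrooted import (
    NoTerminalComponent,
    NotRootable,
    SPRMove,
    UnrootedNetwork,
    apply_spr,
    apply_spr_sequence,
    blobs,
    canonical_form_unrooted,
    check_spr,
    cut_edges,
    enumerate_spr,
    exact_spr_distance,
    invert_spr,
    is_isomorphic_unrooted,
    is_rootable,
    make_rootable,
    orient,
    project_move,
    read_edgelist,
    redundant_cut_edges,
    spr_connect,
    strip_terminal_component,
    terminal_components,
    underlying,
    validate_unrooted,
    write_edgelist,
)


@pytest.fixture()
def two_component_net():
    """Two minimal 5-node terminal components hanging off a 3-leaf part."""
    edges = []
    for tag in ("A", "B"):
        p, q, r, s, m = (f"{tag}{x}" for x in "pqrsm")
        edges += [
            (p, q), (p, r), (p, s), (q, r), (q, s), (r, m), (s, m),
        ]
    edges += [
        ("Am", "v"), ("Bm", "w"),
        ("v", "l1"), ("v", "z"),
        ("w", "l2"), ("w", "z"),
        ("z", "l3"),
    ]
    return UnrootedNetwork(edges, {"l1": "t1", "l2": "t2", "l3": "t3"})


class TestValidation:
    def test_single_edge_two_leaves_valid(self):
        u = UnrootedNetwork([("x", "y")], {"x": "a", "y": "b"})
        assert validate_unrooted(u) == []

    def test_degree_violation(self):
        u = UnrootedNetwork([("x", "m"), ("m", "y")], {"x": "a", "y": "b"})
        assert any("degree" in p for p in validate_unrooted(u))

    def test_disconnected(self):
        u = UnrootedNetwork(
            [("x", "y"), ("p", "q")], {"x": "a", "y": "b", "p": "c", "q": "d"}
        )
        assert any("connected" in p for p in validate_unrooted(u))

    def test_k4_with_subdivided_leaf_edge(self):
        # K4 with one edge subdivided twice to hang two leaves is not valid
        # (degree-2 nodes); the proper construction subdivides two distinct
        # edges, giving a valid 2-leaf tier-3 network
        edges = [
            ("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"),
        ]
        edges += [("c", "m1"), ("m1", "d"), ("m1", "x")]  # still deg 2 at m1? no: 3
        u = UnrootedNetwork(edges, {"x": "t1"})
        # single leaf: invalid
        assert validate_unrooted(u)
        edges2 = [
            ("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"),
            ("b", "m2"), ("m2", "d"), ("m2", "y"),
            ("c", "m1"), ("m1", "d"), ("m1", "x"),
        ]
        u2 = UnrootedNetwork(edges2, {"x": "t1", "y": "t2"})
        assert validate_unrooted(u2) == []
        assert u2.reticulation_number == 3  # 10 edges, 8 nodes


class TestDecomposition:
    def test_tree_all_cut_edges_none_redundant(self):
        u = UnrootedNetwork(
            [("x", "m"), ("y", "m"), ("m", "n"), ("n", "z"), ("n", "w")],
            {"x": "a", "y": "b", "z": "c", "w": "d"},
        )
        assert set(cut_edges(u)) == set(u.edges)
        assert redundant_cut_edges(u) == []
        assert blobs(u) == []

    def test_unrootable_fixture(self, named):
        u5 = named["unrootable_5"]
        assert redundant_cut_edges(u5) == [("m", "v")]
        comps = terminal_components(u5)
        assert len(comps) == 1
        assert sorted(comps[0].nodes) == ["m", "p", "q", "r", "s"]
        assert comps[0].excess == 3
        assert not is_rootable(u5)

    def test_underlying_of_rooted_has_no_redundant_cut_edges(self):
        for s in range(20):
            net = random_network(3, 2, seed=s)
            u = underlying(net)
            assert redundant_cut_edges(u) == []
            assert is_rootable(u)

    def test_component_count_bound(self, two_component_net):
        u = two_component_net
        assert validate_unrooted(u) == []
        k = u.reticulation_number
        comps = terminal_components(u)
        assert len(comps) == 2
        assert 3 * len(comps) <= k


class TestOrientation:
    def test_tree_rootable_at_every_leaf(self):
        u = UnrootedNetwork(
            [("x", "m"), ("y", "m"), ("m", "n"), ("n", "z"), ("n", "w")],
            {"x": "a", "y": "b", "z": "c", "w": "d"},
        )
        for lab in sorted(u.labels()):
            net = orient(u, lab)
            assert validate_rooted(net) == []

    def test_unrootable_raises(self, named):
        with pytest.raises(NotRootable):
            orient(named["unrootable_5"], "t1")

    def test_round_trip_50_random(self):
        for s in range(50):
            net = random_network(4, 2, seed=s)
            u = underlying(net, root_label="zz")
            lab = sorted(u.labels())[0]
            r = orient(u, lab)
            assert validate_rooted(r) == []
            back = underlying(r, root_label=lab)
            assert is_isomorphic_unrooted(u, back)

    def test_unknown_leaf_raises(self, named):
        from phylomoves.netcore import NetworkError

        u = underlying(random_network(3, 1, seed=0))
        with pytest.raises(NetworkError):
            orient(u, "no-such-leaf")


class TestSPR:
    def test_reversibility_and_tier(self):
        net = random_network(3, 1, seed=4)
        u = underlying(net)
        nv, ne = len(u.nodes), len(u.edges)
        for m in enumerate_spr(u)[:20]:
            app = apply_spr(u, m)
            assert len(app.network.nodes) == nv
            assert len(app.network.edges) == ne
            inv = invert_spr(app, m)
            back = apply_spr(app.network, inv).network
            assert is_isomorphic_unrooted(back, u), m

    def test_projection_commutes(self):
        cnt = 0
        for s in range(5):
            net = random_network(4, 2, seed=s)
            u = underlying(net)
            rng = random.Random(s)
            moves = enumerate_moves(net, "rspr")
            for m in rng.sample(moves, min(10, len(moves))):
                res = apply_move(net, m).network
                u_res = apply_spr(u, project_move(m)).network
                assert is_isomorphic_unrooted(underlying(res), u_res), (s, m)
                cnt += 1
        assert cnt >= 40

    def test_invalid_moves_rejected(self):
        u = UnrootedNetwork([("x", "y")], {"x": "a", "y": "b"})
        m = SPRMove(end="x", other="y", target=("x", "y"))
        assert check_spr(u, m) is not None


class TestStrip:
    def test_strip_fixture(self, named):
        u5 = named["unrootable_5"]
        u2, mv = strip_terminal_component(u5)
        assert validate_unrooted(u2) == []
        assert len(u2.nodes) == len(u5.nodes)
        assert len(u2.edges) == len(u5.edges)
        assert terminal_components(u2) == []
        assert is_rootable(u2)
        assert exact_spr_distance(u5, u2, cap=2) == 1

    def test_strip_decreases_count(self, two_component_net):
        u = two_component_net
        u2, _ = strip_terminal_component(u)
        assert len(terminal_components(u2)) == 1
        u3, _ = strip_terminal_component(u2)
        assert len(terminal_components(u3)) == 0

    def test_no_component_raises(self):
        u = underlying(random_network(3, 1, seed=0))
        with pytest.raises(NoTerminalComponent):
            strip_terminal_component(u)

    def test_make_rootable_bound(self, two_component_net):
        u = two_component_net
        u2, moves = make_rootable(u)
        assert is_rootable(u2)
        assert len(moves) <= u.reticulation_number // 3
        replay = apply_spr_sequence(u, moves)
        assert is_isomorphic_unrooted(replay, u2)


class TestSprConnect:
    def test_isomorphic_pair(self):
        u = underlying(random_network(3, 1, seed=2))
        assert spr_connect(u, u.copy()) == []

    def test_random_rootable_pairs_tier_4_2(self):
        # unrooted view of tier (4,2) rooted networks: 5 labels, k=2
        for s in range(20):
            a = underlying(random_network(4, 2, seed=s), root_label="zzr")
            b = underlying(random_network(4, 2, seed=s + 999), root_label="zzr")
            seq = spr_connect(a, b)
            n, k = len(a.labels()), a.reticulation_number
            assert 3 * len(seq) <= 3 * n + 8 * k
            final = apply_spr_sequence(a, seq)
            assert is_isomorphic_unrooted(final, b), s

    def test_unrootable_input(self, named):
        u5 = named["unrootable_5"]
        b = underlying(
            random_network(2, 3, seed=1, labels=["t2", "t3"]), root_label="t1"
        )
        seq = spr_connect(u5, b)
        final = apply_spr_sequence(u5, seq)
        assert is_isomorphic_unrooted(final, b)

    def test_bfs_distance_below_emitted(self):
        a = underlying(random_network(3, 1, seed=11), root_label="zzr")
        b = underlying(random_network(3, 1, seed=12), root_label="zzr")
        seq = spr_connect(a, b)
        if seq:
            d = exact_spr_distance(a, b, cap=len(seq))
            assert d is not None and d <= len(seq)

    def test_tier_mismatch(self, named):
        u = underlying(random_network(3, 1, seed=0))
        with pytest.raises(TierMismatch):
            spr_connect(u, named["unrootable_5"])


class TestEdgeListIO:
    def test_round_trip(self, named):
        u5 = named["unrootable_5"]
        text = write_edgelist(u5)
        back = read_edgelist(text)
        assert is_isomorphic_unrooted(u5, back)
        assert write_edgelist(back) == text

    def test_canonical_form_consistency(self, named):
        u5 = named["unrootable_5"]
        renamed = UnrootedNetwork(
            [(f"n_{a}", f"n_{b}") for a, b in u5.edges],
            {f"n_{n}": lab for n, lab in u5.leaf_labels.items()},
        )
        assert canonical_form_unrooted(u5) == canonical_form_unrooted(renamed)
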