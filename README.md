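# phylomoves

Rearrangement moves on binary phylogenetic networks: **tail** and **head**
moves (and the derived rSPR / rNNI classes) on rooted networks, **SPR**
moves on unrooted networks, and constructive algorithms that connect any
two networks of the same *tier* (same leaf set and reticulation number)
with proven length bounds.

Highlights:

- `netcore` — network model, validation, tier arithmetic
  (`|V| = 2n + 2k`, `|E| = 2n + 3k − 1`), leaf-label-preserving
  isomorphism, canonical forms, multi-LCA ancestry queries, extended
  Newick and JSON I/O.
- `moves` — validity, application, inversion, distance classification and
  enumeration of tail/head moves; closed-form validity checks verified
  against an apply-and-validate oracle.
- `headsim` — replaces any valid distance-1 head move by a tail-move
  sequence of length ≤ 4 (two leaves or more), with the single exceptional
  two-leaf network detected structurally.
- `connect` — same-tier connectivity: tail-move sequences of length
  ≤ 3(n + 2k), rSPR sequences ≤ 2n + 3k − 1, and decomposition of one tail
  move into ≤ n + 3k − 1 distance-1 tail moves.
- `unrooted` — rootability via redundant cut-edges, bipolar orientation of
  blobs, redundant terminal components and their removal by single SPR
  moves, and SPR connectivity within n + (8/3)k moves.
- `toolbox` — tier enumeration up to isomorphism (two mutually-guarding
  enumerators), seeded random network generation, exact BFS distance
  oracles, agreement forests / exhaustive MAF at toy scale, mycorrhizal
  forest gluing, named fixtures.

## CLI

```sh
phylomoves validate NET.enwk
phylomoves moves NET.enwk --class tail1 --nontrivial
phylomoves simulate-headmove NET.enwk --edge u,v --target x,y
phylomoves connect A.enwk B.enwk --moves tail --verify [--decompose-d1]
phylomoves spr-connect A.el B.el --verify
phylomoves distance A.enwk B.enwk --class tail --cap 8
phylomoves root U.el --leaf x
phylomoves enumerate --leaves 3 --rets 1
phylomoves random --leaves 4 --rets 2 --seed 7
phylomoves fixtures --name exceptional_two_leaf
```

Rooted networks are read/written as extended Newick (`#H1` hybrid tags) or
JSON; unrooted networks as plain edge lists (`u v` per line, with
`#label NODE TAXON` headers). All sequence-producing commands support
`--verify`, which replays the emitted sequence and checks that the final
network is isomorphic to the target.

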