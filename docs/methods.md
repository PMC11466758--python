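# Methods

## Model and assumptions

The package treats disease biology as a directed, weighted PPI graph in
which signaling flows from molecular initiating events (growth-factor
ligands binding their receptors) to a pathological end point (ECM
protein production). The importance of a protein is operationalized as
the marginal cost its removal imposes on the K cheapest directed paths
between every (start, end) anchor combination. This assumes (a) edge
direction encodes signal flow, (b) path cost is additive over edges, and
(c) therapeutic value correlates with how much a node's removal disrupts
low-cost routes — a topological, not kinetic, notion of importance.

## Network merge

Two sources are combined. Curated edges are directed and trusted as-is;
experimental edges are undirected with a confidence e-score in [0, 1]
and are expanded to both directed edges, since the walks are directional
and no direction information exists for them. "Connected" means degree
≥ 1 in either direction. Rescue of curated-isolated nodes is applied
iteratively to a fixpoint, so a chain of isolated nodes that reaches the
network through one another is rescued as a whole; nodes still isolated
are pruned. On an ordered-pair collision between sources the provenances
are unioned and the experimental e-score kept (the 0.5001 default is a
placeholder for missing evidence, not a measurement). Self-loops are
dropped at load because paths are loopless. The e-score threshold
default is 0.0 inclusive (everything passes); it exists for users who
want a stricter confidence floor.

## Weighting and cost

Node weight is |log2FC| of the F3/F4-vs-F0 contrast; genes without a row
in the expression table weigh 0 rather than being excluded, keeping them
traversable without inventing signal. Edge weight is the e-score plus
the mean endpoint node weight. Three weight→cost transforms ship:

* `identity` (default): cost = weight, the literal "cost is the total
  edge weight" reading;
* `complement`: cost = (W_max + ε) − weight, ε = 1e−9;
* `inverse`: cost = 1 / (weight + ε).

Under `identity`, cheapest paths prefer low-confidence, weakly
dysregulated edges, which arguably inverts the biological intent; the
semantics of "lowest cost" versus "highest relevance" are genuinely
ambiguous in this class of analyses. Rather than guessing, the transform
is explicit, recorded in every run manifest, and defaulted to the
literal reading. All shipped transforms yield non-negative costs; a
negative cost raises.

The DEG filter (p < 0.01, log2FC > 0.5 or < −1, counts > 20; all
strict, asymmetric up/down) is exposed for reporting but never restricts
the network: all measured nodes contribute weights regardless of
significance.

## Path analysis and knockouts

K-shortest loopless paths are computed with Yen's algorithm
(`networkx.shortest_simple_paths`) and post-processed for determinism:
paths are collected until the generator's cost exceeds the K-th best
(with 1e−12 slack for float ties), then sorted by (cost, lexicographic
node sequence) and truncated to K. K defaults to 100.

For a knockout, the node is removed and the K paths recomputed. If m < K
paths survive, the surviving cost sum is compared against the reference
sum truncated to its first m paths — otherwise losing expensive paths
would register as a cost *decrease*, and path scarcity would be
conflated with cost increase. With this rule every delta is ≥ 0 (the
i-th cheapest path after removal costs at least as much as the i-th
cheapest before), and a node absent from all K reference paths of a pair
has delta exactly 0, which the scanner exploits as a behavior-preserving
short-circuit. Note the converse does not hold: a node lying only on the
most expensive reference paths can have delta 0 when its removal leaves
the cheaper paths intact.

A pair with no surviving path is counted as a disconnection. No numeric
cost is defined for disconnection; it is the primary (descending) sort
key, followed by summed finite delta and pairs affected, with identifier
tie-breaks. An optional finite-penalty mode (delta = λ·ref_cost,
λ default 10) is available for a purely numeric reading. Anchor nodes
are knockout candidates for every pair they do not themselves anchor.
Blocklisted generic hubs are flagged after ranking and keep their rank
number, so the shortlist preserves the original ordering with gaps.

## Text mining

Tokenization is a compact regex tokenizer (words, parentheses and
sentence punctuation as tokens) with a rule-based plural lemmatizer
(case-folding; -ies→-y, -es, -s stripping with -ss/-us/-is guards).
This deliberately trades linguistic coverage for zero dependencies and
exact reproducibility; it handles the biomedical noun phrases and gene
symbols the matcher needs, not general English morphology. Term matching
runs over lemmatized n-grams, longest-match-first then leftmost,
non-overlapping. Acronym detection follows the Schwartz–Hearst
constraints (acronym alone in parentheses, 2–10 characters, at least one
letter; definition = shortest preceding span containing the acronym
characters in order, at most min(len+5, 2·len) words) and expansions are
scoped to the defining document to avoid cross-document ambiguity.

Publication-level scoring counts distinct documents with ≥ 1 qualifying
sentence per (protein, cluster); it is therefore idempotent under
sentence duplication and monotone under corpus growth. Measure m₄ counts
distinct publications with a co-occurrence in any cluster; the m₃
denominators are total publications mentioning the protein in any
context and total partners above the interaction-score floor (strictly
> 0.9 by default). Ranking uses dense ranks with boundary ties broken by
descending m₄ then identifier; the year floor (2000) is applied at
corpus load and configurable.

## Synthetic generators

All generators are deterministic in the fixture seed and emit a ground-
truth manifest sufficient to verify downstream output without rerunning.

* **Network, exact-count mode** reproduces a requested (initial,
  connected, rescued) partition: a preferential-attachment curated core
  guarantees each connected node degree ≥ 1, each rescued node gets one
  experimental edge into the network (occasionally into an earlier
  rescued node, exercising iterative rescue), and the remainder stays
  isolated. The default acceptance partition is (1670, 999, 665),
  leaving 6 pruned and 1,664 final nodes.
* **Network, bottleneck mode** (defaults: 50 background nodes, 2 ligand/
  receptor pairs, 2 ECM ends, 4 feeders per side, ~63 nodes total)
  plants a cheap experimental "highway" (e-score 0.01, endpoints
  unmeasured) from every start through one bottleneck to every end, over
  an expensive curated background (default e-score plus dysregulated
  endpoints, cost ≈ 2.5/edge). With 4 feeders each pair has 25 highway
  paths costing ≤ 0.05, so the entire K = 20 reference routes through
  the bottleneck; `bottleneck_route_fraction: 1.0` removes the start→
  background detours so the bottleneck's removal disconnects every pair.
* **Expression** plants |log2FC| ∈ [1, 3] (random sign), p = 10^−U(3,8)
  and counts ∈ [30, 500] for dysregulated genes; background genes get
  |log2FC| < 0.09, uniform p and log-normal counts.
* **Corpus** instantiates template sentences embedding taxonomy surface
  forms, with filler sentences and shuffled order; a fraction of HSC-
  cluster documents introduce the term via a parenthesized acronym
  definition and use the bare acronym in the co-occurring sentence.
  E-scores elsewhere draw from a mixture of a point mass near 0.5 and a
  Beta(4, 1.5) tail, loosely mimicking experimental-score spread.

What the fixtures do **not** emulate: the degree distribution, score
calibration and annotation noise of real interaction databases; the
correlation structure of real transcriptomes; the ambiguity of real
biomedical text (nested entities, hedging, negation). Passing tests
demonstrate algorithmic correctness and bookkeeping fidelity at desk
scale, not biological validity of a ranking on real data.

## Numerical and determinism choices

Edge weights are computed in a fixed operand order so independent
recomputation matches bit-for-bit. All orderings (paths, ranks,
serialized edges) carry lexicographic tie-breaks; identical inputs and
seed give byte-identical outputs. Problem sizes in the test suite
(≤ 8-node graphs for exhaustive path enumeration, ~63-node networks at
K = 20 for the 100-replicate planted-target benchmark, 1,670-node
fixtures for merge bookkeeping) were chosen so exhaustive oracles remain
feasible while preserving the structural features under test.

## Known limitations

* Direction assignment for rescued experimental edges (both directions)
  is a modeling choice, not evidence.
* The 11-entry ECM end-node list is a documented placeholder anchored
  only by COL1A2; override `anchors.yaml` for real analyses.
* The aggregation that turns per-pair deltas into one score has several
  defensible definitions; three are shipped (`default`, `sum_delta`,
  `max_delta`) and the choice is recorded in the run manifest.
* Knockout scans recompute per (node, pair) serially; very large
  networks with K = 100 will be slow in pure Python/networkx.
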