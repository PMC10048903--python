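# Methods

This note records the models, conventions and numerical choices behind
`ppinet`, and what the synthetic study conditions do and do not establish
about real data.

## Topological metrics and fits

All PPI-side computation treats the network as a simple undirected graph;
readers drop self-loops and duplicate edges and record the counts in a
provenance sidecar.

* **Clustering** C(k_i) = 2m_i/(k_i(k_i−1)); nodes of degree < 2 are
  defined to have C = 0.
* **Betweenness** is normalized by (n−1)(n−2)/2 with endpoints excluded, so
  values live in [0, 1] (the interior node of a 3-path scores exactly 1).
* **Closeness** uses the per-component convention
  (reachable − 1)/Σ_j d_ij rather than the textbook N/Σ_j d_ij. The two
  agree up to a constant factor on a connected graph; the per-component
  form stays in [0, 1] on disconnected inputs, which real database exports
  frequently are.
* **Eigenvector centrality** is a deterministic power iteration on A + I
  (the +I shift makes the iteration converge on bipartite components),
  started from the uniform vector, L2-normalized each step, stopping when
  the L2 change between iterates falls below 1e-12 (max 5000 iterations).
  The tight tolerance keeps the iterate error well below the 1e-9 band used
  in the oracle-equivalence tests against a dense eigendecomposition.
* **Power-law fits** are ordinary least squares of log10(mean metric) on
  log10(k), one point per observed degree (not per node), using only
  strictly positive (k, y) pairs; fewer than 3 usable points is an error
  and a constant metric is reported as a degenerate fit (slope 0, r set
  to 0). Regression on log–log axes is the fitting model throughout;
  maximum-likelihood tail estimation is deliberately out of scope.

The unbinned log–log regression of P(k) is known to be biased upward by
sparse-tail noise on small graphs: on preferential-attachment graphs it only
stabilizes (slope ≈ −2.0, within the expected band) from roughly 3000 nodes,
which is the size the tests use.

## Key nodes

Hubs and bottlenecks are strict top-n lists (default n = 10; ties broken by
metric descending, then node id ascending, with no expansion of tied tails).
The bottleneck-hub set is their intersection ordered by hub rank. These are
deliberate conventions: with tied tails a top-n list is otherwise not
well-defined, and the id tie-break makes reruns and relabelings reproducible.

## MCODE

Vertex weight = k_max × density of the k_max-core of the closed neighborhood
(density without self-loops). Seeds are consumed in weight-descending order
(id tie-break); breadth-first expansion admits unassigned neighbors with
weight ≥ seed_weight × (1 − node_score_cutoff) up to max_depth hops; a node
belongs to at most one complex. Post-processing: complexes without a 2-core
are discarded; optional fluff (off by default) admits outside neighbors with
closed-neighborhood density > 0.1 *before* haircut and may create overlap;
haircut iteratively strips degree-1 members. Defaults are the standard tool
defaults: cutoff 0.2, haircut on, fluff off, 2-core filter, depth 100.
Scores are density × node count; the published 31-node/422-edge subnetwork
scores 844/30 = 28.13, which pins down the simple (loop-free) density
convention.

One behavioral consequence worth knowing: two equally dense regions joined
by a *direct* bridge edge merge into one complex, because both bridge
endpoints carry full weight. Separation requires the connection to run
through low-weight intermediaries — which is how the planted-cluster
generator attaches cliques to background, and why planted cliques are
recovered exactly there.

## Crosstalk

Strength counts distinct complex members adjacent to the bottleneck-hub in
the full network, excluding the hub itself (a member of a 31-node complex
can score at most 30 there). Membership alone contributes nothing; hubs
outside a complex score through their edges into it. Row totals rank the
hubs; ties for key mediator break by id.

## Signed regulatory network and motifs

Node roles are induced by edge layers; TF and gene may coexist on one node
(a hub gene acting as a TF), miRNA is exclusive. Duplicate
(source, target, layer) triples collapse; conflicting signs for the same
triple are an error rather than silently resolved. miRNA→target lists
without a sign column default to repression (−1), the dominant mode of
post-transcriptional regulation.

FFL classification follows the sign-product rule — coherent iff the direct
TF→gene sign equals the product of the TF→miRNA and miRNA→gene signs — with
the standard eight-type table (C1: +,+,+; C2: −,+,−; C3: +,−,−; C4: −,−,+;
I1: +,−,+; I2: −,+,+; I3: +,+,−; I4: −,−,−). Triples whose TF and gene are
the same dual-role node are not motifs (that shape is a feedback, not a
feed-forward, pattern). Feedback loops are reciprocal gene↔miRNA pairs;
loop sign is the edge-sign product, so mutual repression is net positive
and activation/repression is negative feedback.

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) per term, Benjamini–Hochberg adjustment
across terms (in place of proprietary server-side corrections), background
defaulting to the union of annotated members. The odds ratio comes from the
2×2 table; the Haldane 0.5 correction is applied only when the ratio is
otherwise undefined (a zero in the denominator), so zero overlap reports an
odds ratio of exactly 0.

## Synthetic study conditions

* **Scale-free**: Barabási–Albert preferential attachment; m is restricted
  to ≤ n − 2 so at least one attachment step occurs.
* **Hierarchical**: the deterministic replica construction — a complete
  base module (default 5 nodes), copied base − 1 times per level with every
  replica-periphery node wired to the central hub — which guarantees the
  C(k) ~ k^(−1) signature. A `copies` parameter lays several disjoint
  blocks side by side. This matters for the null-model diagnostic: a single
  block's central hub (degree 84 in a 125-node block) far exceeds the
  structural cutoff √(N⟨k⟩), so even a degree-preserving rewiring of one
  block shows an artifactual C(k) decay (slope ≈ −0.6). An ensemble of 10
  blocks keeps every degree below the cutoff; there the rewired null is
  flat (slope ≈ −0.15) while the hierarchical graph keeps slope ≈ −1.14,
  making the hierarchy test a test of wiring rather than of degree-sequence
  finite-size effects.
* **Planted clusters**: sparse G(n, p) background (default p = 0.01, 200
  nodes in the recovery tests) with embedded cliques of size ≥ 4 attached
  to background nodes with small Bernoulli probability; ground-truth
  membership is returned, never re-derived.
* **Signed regulatory layers**: per-layer Bernoulli edges over disjoint
  TF/miRNA/gene name pools, TF-edge signs activating with probability 0.5
  by default, miRNA→gene edges repressive; requested FFL types are planted
  on fresh nodes and the returned ground truth is recomputed by an
  independent brute-force triple scan (so it includes incidental motifs).

What these conditions do *not* emulate: database confidence scores and
their thresholding, literature-biased degree inflation of famous genes,
annotation incompleteness, or correlated noise between target-prediction
databases. Passing the recovery tests therefore demonstrates correctness of
the algorithms under clean planted structure, not robustness to curation
artifacts.

## Problem sizes and determinism

The test suite runs everything at desk scale: oracle equivalence on 200
random connected graphs of ≤ 8 nodes against explicit shortest-path
enumeration and dense eigendecomposition (tolerance 1e-9); exponent
recovery on 20-point synthetic laws with 1% multiplicative noise
(tolerance ±0.1); planted-clique recovery at 200 background nodes; motif
enumeration equality on 50 random 12×12×12 tripartite networks; ORA tail
equality against explicit combinatorial sums for backgrounds ≤ 30. Every
source of randomness is seeded; reruns of the pipeline with an identical
config are byte-identical outside the log, and every summary embeds a hash
of its config.

## Known limitations

* MCODE complexes depend on seed order under near-ties; the id tie-break
  makes this deterministic but still a convention.
* The log–log regression slope is a descriptive exponent, not a calibrated
  tail estimate; use it to compare regimes, not to certify power-law-ness.
* Published composite values of the form "exponent ± second number" for
  the CRC network are not reproduced; slope, intercept and r are reported
  separately.
* The replay stages operate on printed summary tables and therefore
  inherit their rounding.
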