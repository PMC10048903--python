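# ppinet

Topological and regulatory-motif analysis of molecular interaction networks,
built around the workflow used to characterize the colorectal-cancer (CRC)
protein–protein interaction (PPI) network: global topology and power-law
fits, bottleneck-hub extraction, dense-complex (subnetwork) detection,
hub–subnetwork crosstalk, and signed TF–miRNA–gene feed-forward-loop
classification.

It is aimed at systems-biology work where the input is an edge list exported
from a database (STRING-style PPI, TransmiR/TRRUST-style signed regulation,
TargetScan/miRDB/miRTarBase-style target lists) and the desired output is a
ranked, reproducible table rather than a GUI session.

## What it computes

**Topology.** For an undirected simple graph, six per-node quantities:
degree *k*; clustering coefficient C(k_i) = 2m_i / (k_i (k_i − 1));
neighborhood connectivity CN (mean neighbor degree); betweenness
C_B(v) = Σ_{i≠j≠v} d_ij(v)/d_ij, normalized by (n−1)(n−2)/2; closeness
(per component, (reachable − 1)/Σ_j d_ij); and eigenvector centrality
(principal eigenvector of the adjacency matrix, L2-normalized). The degree
distribution P(k) = N_k/N and per-degree means of each metric are fitted by
ordinary least squares on log10–log10 axes, so a scale-free network shows
P(k) ~ k^(−γ) as a straight line, and a *hierarchical* network additionally
shows C(k) ~ k^(−1).

**Key nodes.** Hubs are the top-*n* nodes by degree, bottlenecks the top-*n*
by betweenness; their intersection — the *bottleneck-hubs* (Bn-H) — are the
nodes that both concentrate edges and control shortest-path traffic.

**Subnetworks.** A from-scratch implementation of the MCODE algorithm:
vertices are weighted by the density of the highest k-core of their closed
neighborhood, complexes grow from high-weight seeds (admitting neighbors
with weight ≥ seed × (1 − cutoff)), and post-processing applies the 2-core
filter and haircut. Each complex is scored density × node count, so an
n-clique scores n.

**Crosstalk.** The interaction strength of a bottleneck-hub with a
subnetwork is the number of subnetwork members adjacent to it in the full
network (itself excluded); the hub with the largest row total is the *key
mediator*.

**Regulatory motifs.** Signed layers TF→gene, TF→miRNA, miRNA→gene and
gene→miRNA assemble into a tripartite network. Every triple carrying
TF→miRNA (s1), miRNA→gene (s2) and TF→gene (s3) is a feed-forward loop,
*coherent* iff s3 = s1·s2, and labelled C1–C4/I1–I4 by the standard
eight-type sign table. Reciprocal gene↔miRNA pairs are feedback loops with
loop sign s_g·s_m. Consensus miRNA targets across prediction databases and
hypergeometric/BH over-representation analysis round out the pipeline.

## Worked example

The package ships the published CRC summary tables, so the key-node and
crosstalk stages can be replayed directly:

```bash
$ ppinet replay keynodes src/ppinet/data/crc_top10_hubs_bottlenecks.tsv
```

yields the eight bottleneck-hubs, ordered by hub rank:

```
"bottleneck_hubs": ["TP53", "AKT1", "CTNNB1", "EGFR", "HRAS", "JUN", "RHOA", "EGF"]
```

meaning exactly eight proteins sit in both top-10 lists, led by TP53
(degree 1817, betweenness 0.199). Replaying the strength matrix:

```bash
$ ppinet replay crosstalk src/ppinet/data/crc_bnh_subnetwork_strengths.tsv
...
key mediator: HRAS
```

HRAS has the largest row total (216 members adjacent across the five
subnetworks, vs 202 for TP53), making it the key mediator of subnetwork
crosstalk. The published top subnetwork (31 nodes, 422 edges) scores

```python
>>> from ppinet.mcode import cluster_score
>>> round(cluster_score(31, 422), 2)
28.13
```

Everything also runs on synthetic data with planted ground truth:

```bash
$ ppinet simulate hierarchical --levels 3 --base 5 -o demo/
$ ppinet fit demo/network.tsv -o demo/fits.json
```

gives a clustering-vs-degree slope of −1.14 (the hierarchical C(k) ~ k^(−1)
signature) with positive centrality-vs-degree slopes, and

```bash
$ ppinet simulate planted-clusters --n 80 --clique-size 5 --clique-size 6 -o pc/
$ ppinet cluster pc/network.tsv -o pc/complexes.tsv
```

recovers the planted 6-clique (score 6.0) and 5-clique (score 5.0) as the
top-ranked complexes. `ppinet run config.yaml` executes every configured
stage in one shot and writes a summary JSON.

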