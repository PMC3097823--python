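# mlnet — minimal lateral networks for hidden lateral transfer

`mlnet` detects hidden lateral transfer — lexical borrowing between languages,
or horizontal gene transfer between genomes — in binary presence/absence
characters evolving along a rooted reference tree. A character is a cognate
set (COG) or gene family; its presence/absence pattern (PAP) records which
taxa carry it. Patterns that do not map onto a single clade of the tree must
be explained by parallel origin, by loss, or by lateral transfer; `mlnet`
quantifies the minimum amount of transfer required.

## The model

For each character the package infers an origin–loss scenario under a ladder
of *borrowing allowances*:

* **LO** (loss only): the character originates at the root; one loss event is
  placed at the root of every maximal clade from which it is absent.
* **SO** (single origin): the origin moves to the most recent common ancestor
  of the carrier taxa; losses as in LO inside that subtree.
* **BOR1 / BOR3 / BOR7 / BOR15**: up to 2/4/8/16 origins. Starting from the SO
  origin, any origin whose subtree still contains an absent leaf is split —
  while the budget permits — into the MRCAs of the carriers inside its two
  child clades. One origin is primary; every extra origin is a borrowing.

The allowance is chosen by a **uniformitarian criterion**: reconstruct the
inventory size (number of characters present) at every ancestral node and
accept the smallest allowance whose ancestral sizes are statistically
indistinguishable from the contemporary (leaf) sizes under a two-sided
Wilcoxon rank-sum test. Too little borrowing inflates ancestral inventories;
too much shrinks them below modern ones.

The **minimal lateral network (MLN)** is the reference tree plus one lateral
edge for every split performed during inference, linking the two sibling
origins the split produced. Summed lateral edge weight therefore equals the
total number of inferred borrowings. Edges between internal nodes represent
transfers among ancestral lineages; edges at leaves represent recent
borrowing.

The package also builds the shared-character network between taxa (weights =
co-presence counts) and finds its community structure by leading-eigenvector
modularity maximisation, plus a gain–loss–borrowing simulator with full event
ground truth for validation.

## Worked example

Simulate 300 characters on a 16-leaf tree with on average 0.6 borrowing
events per character, then let the package recover the borrowing regime:

```python
from mlnet import dataio
from mlnet.simulate import random_yule_tree, simulate_pap

tree = random_yule_tree(16, 42)
pap, truth = simulate_pap(tree, 300, q=0.05, lam=0.6, seed=42)
dataio.write_newick(tree, "tree.nwk")
dataio.write_pap_matrix(pap, "pap.tsv")
```

```sh
$ mlnet select-model --tree tree.nwk --pap pap.tsv --report models.tsv
BOR1    accepted
$ cat models.tsv
model  p_wilcoxon  iqr_fraction  mean_losses  mean_borrowings  accepted
LO     2.5e-06     3.73          3.63         0.00             False
SO     9.0e-05     1.42          1.32         0.00             False
BOR1   0.607       0.36          0.68         0.50             True
BOR3   0.010       -0.98         0.34         1.09             False
BOR7   2.3e-05     -2.49         0.04         1.60             False
BOR15  9.4e-06     -3.11         0.00         1.66             False
```

Reading the table: under LO the root would hold every character (ancestral
inventories far larger than modern ones, p ≈ 10⁻⁶); BOR1 is the first
allowance whose ancestral sizes match contemporary ones (p = 0.61), and its
inferred 0.50 borrowings per character recovers the simulated rate (true mean
0.45 for this seed); BOR3 and above overshoot, driving ancestral inventories
*below* modern ones (negative interquartile-range fraction). The MLN under
the accepted model:

```sh
$ mlnet mln --tree tree.nwk --pap pap.tsv --model auto --out-prefix run
$ cat run.stats.tsv
statistic                  value
model                      BOR1
lateral_edges              48
lateral_weight             151
connectivity_median        3.0
clustering_coefficient     0.226088
mean_shortest_path         2.35914
single_weight_edges        34
recent_borrowing_pct_mean  3.7284
...
```

i.e. 48 distinct lateral edges carrying 151 borrowing events; most edges
(34/48) share a single character; the tree-plus-lateral union graph is
clustered (0.23) with short paths (2.4) — the small-world signature of
borrowing networks. `run.scenarios.tsv` lists origins, losses and borrowings
per character, `run.mln.graphml` / `run.mln.edges.tsv` export the network.

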