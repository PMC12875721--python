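# Methods

## The model

`axenet` treats a corpus of published axenisation attempts as a set of
*species-level workflow records*: one record per publication × species, each
carrying an ordered list of method codes (from a closed 24-method vocabulary
grouped into Physical, Chemical and Biological modes of action), an outcome
(`success` / `failure` / `partial`), the verification methods used to check
axenicity, antibiotic details and a five-question quality appraisal by three
raters.

For each microalgal division (diatoms, dinoflagellates, green algae, other)
the records are turned into a **weighted directed workflow network**: methods
are nodes, and every ordered transition `m_i -> m_{i+1}` in a record adds one
to the corresponding edge weight; each record's final method additionally
feeds an edge into a reserved *incubation* sink (`INCB`), the terminal step
at which the culture is presumed axenic. Consecutive repeats of a method
yield self-loops. The sink is stored in the graph but excluded from the
method node set and from every statistic, so printed node counts refer to
methods only.

## Network statistics

* **Edge density** is loop-inclusive: distinct realised connections divided
  by the theoretical maximum including self-connections — `n²` for the
  directed convention, `n(n+1)/2` for the undirected one. Published density
  values in this literature rarely state the convention, so both are
  implemented, selectable per call, and the convention used is recorded in
  every report (`directed` is the default).
* **Degree** is total degree (in + out); a self-loop contributes one to each
  of in- and out-degree. The summary statistic is the median over method
  nodes, which produces half-integers at even node counts.
* **Modularity** is Newman–Girvan
  `Q = Σ_c [e_c/m − (d_c/2m)²]` on the undirected weighted projection;
  antiparallel edge pairs collapse with summed weights, and self-loops are
  dropped before clustering by default (`keep_loops` exposes them). `Q` of
  the single-community partition is exactly 0.

## Community detection

Method networks here are small (≤ ~24 nodes), so modularity is maximised
*exactly* by branch-and-bound over restricted-growth assignments. Expanding
`Q` over node pairs gives `Q = C + Σ_{i<j same community} p_ij` with
`p_ij = (w_ij − k_i k_j/2m)/m`, so the search maximises a sum of pair terms.
Nodes are processed in decreasing-degree order (large pair terms early make
the bound bite); a subtree is pruned when the partial score plus the sum of
the remaining positive pair terms cannot beat the incumbent, and the
incumbent bound is seeded just below the greedy solution's score. Because
assignments are enumerated in lexicographic order and replaced only on
strict improvement, the result is the lexicographically first optimal
assignment in that node order — deterministic and independent of node
insertion order. Connected components are solved independently (an optimal
community never spans components); isolated nodes become singleton
communities; an edgeless graph has `Q = 0` by convention.

Components larger than `max_exact_n` (default 20) fall back to greedy
agglomeration (merge the best positive-ΔQ pair until none remains) and the
partition is labelled `greedy`. Exactness at small n is verified against a
brute-force enumeration of all set partitions (Bell numbers), and partition
similarity uses the adjusted Rand index (scikit-learn, cross-checked against
a direct pair-counting formula).

## Cliques

Cliques — methods used in immediate succession with *each other* — are an
unweighted concept: enumeration runs on the simple undirected projection
(no loops, no sink) via Bron–Kerbosch with pivoting (`networkx.find_cliques`),
validated against subset enumeration. Per cluster, all maximum-size cliques
of the induced subgraph are reported in lexicographic order, since real
tables often list several co-maximal cliques.

## Success rates and the representation filter

A method's success rate within a division is
`(# records containing the method with outcome success) / (# records
containing it)`; a method repeated inside one workflow counts once per
record. Rates are only defined when a method appears in **more than six**
records of the division; below that the entry is flagged *below filter
limit* (BFL) rather than reported, to avoid over-reading sparsely used
methods. `partial` outcomes count toward uses but never toward successes — a
deliberately conservative attribution.

## Quality rubric

Five questions (organism source, method reproducibility, medium description,
verification of axenicity, contaminant identification) map to point values
summing to a per-rater total in [−3, 5]. The final score is the rounded mean
of the three rater totals, with ties rounded away from zero; note that with
three integer totals a half-integer mean cannot actually occur, so the
rounding rule only matters if the rater count changes. "Below zero"
classification applies to the final aggregated score.

## Antibiotic summaries

Compounds map to the twelve antibiotic classes through a packaged lookup;
unmapped compounds fall into *Others*. Concentration cells are median
(min–max) in mg/L per class × division over publication-level values (one
value per publication per compound; a publication reporting several values
contributes their median). Cocktail analysis counts, per unordered compound
or class pair, the publications reporting both.

## Synthetic data generator

The generator produces master tables with known ground truth so every stage
is testable without the archived corpus. Defaults emulate the study corpus:

| parameter | default | rationale |
|---|---|---|
| publications | 63 | corpus size |
| species per publication | 1 (54%) or 2–6 uniform | ~half the corpus is single-species |
| division weights | 11 : 15 : 33 : 22 | publication counts per division |
| workflow length | 1–5, continue-prob 0.6 | typical reported workflow depth |
| planted partition | 4 clusters × 6 methods | community structure to recover |
| p_in / p_out | 0.8 / 0.05 | strong within-cluster transition bias |
| start weights | AntB 20, others 1 | ~two-thirds of publications use antibiotics |
| success rule | product of per-method probabilities | independent per-step failure chances |
| poor-reporting share | 0.15 | yields exact P(final score < 0) ≈ 0.107 |

Workflows are random walks: the first method is drawn from the start-weight
distribution, subsequent methods from a row-stochastic transition matrix
whose entries are proportional to `p_in` within a planted cluster (self
included, giving repeat-method loops) and `p_out` across clusters; the walk
stops with probability 0.4 per step after the minimum length and always at
the maximum. Outcomes are Bernoulli with success probability equal to the
product of per-method step probabilities (defaults span 0.55–0.95, precision
isolation methods high). Rubric answers draw from a good or poor
per-publication answer distribution — quality is a property of the
publication, so raters are correlated through it. Randomness is a single
seeded stream with per-publication sub-seeds, making tables reproducible and
insensitive to publication order.

The ledger records the planted partition, per-record success probabilities,
expected per-method rates (the mean per-record success probability over the
records using the method — the exact estimand of the empirical rate) and
true final quality scores. `recovery_report` rebuilds the pooled network,
clusters it, and reports the adjusted Rand index against the planted
partition plus per-method rate errors with 3-standard-error flags.

What the generator does *not* emulate: real method popularity profiles
beyond the antibiotics weighting, correlation between method choice and
division, media/country/habitat structure beyond categorical draws, partial
outcomes, and multi-division publications. Passing recovery tests therefore
demonstrate that the pipeline's estimators and cluster search are correct
and well calibrated under the generative model — not that the published
corpus itself has recoverable structure.

## Problem sizes and numerical choices

The default test corpus is 63 publications (~150 records); recovery checks
use 160 publications (~320 records) for cluster recovery, 200 for rate
calibration, and 5000 (~12 000 records, ~500 uses per method) for the
large-sample limit, where the 0.05 absolute error bound corresponds to more
than 3.5 binomial standard errors per method. Exact clustering is capped at
`max_exact_n = 20` nodes per component; beyond that the greedy path engages.
Modularity comparisons use absolute tolerances of 1e−9 (search vs
brute force) and 1e−12 (implementation vs independent formula). Degenerate
inputs are defined rather than special-cased: empty divisions raise, empty
tables summarise to zeros, edgeless graphs get singleton partitions with
`Q = 0`, and isolated nodes appear as singleton cliques.

## Known limitations

* Exact modularity maximisation is exponential in the worst case; the
  degree-ordered bound is effective on sparse method networks but dense
  graphs near 20 nodes can be slow — `max_exact_n` is the control.
* The success-rate estimator ignores workflow context: a method's rate
  conflates its own effect with that of the methods it co-occurs with.
* Publication-level summaries assume one division per publication when
  derived from synthetic tables; real corpora may span divisions within one
  publication (the data model allows it; the generator does not produce it).
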