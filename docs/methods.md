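# Methods

## Correlation screening

Pairwise association between RNA classes uses the Spearman coefficient,
computed as the Pearson correlation of average (fractional) ranks.  Pairs
with a constant vector have undefined correlation and are excluded rather
than scored zero.  Class-specific retention thresholds follow the sign the
ceRNA mechanism predicts: mRNA–lncRNA pairs are kept at ρ ≥ 0.45
(inclusive), miRNA–mRNA and miRNA–lncRNA pairs at ρ < −0.35 (strict).  The
asymmetry of the two bounds (inclusive vs strict) is deliberate and
matches the retention rule's wording in each direction.

Significance of retained pairs is assessed with a one-sided permutation
test, 1,000 permutations by default, permuting one vector only (equivalent
in distribution to permuting both).  The direction is matched to the class
filter — positive for sponge pairs, negative for miRNA targets — because a
sign-constrained filter makes the opposite tail meaningless.  The empirical
p-value uses add-one smoothing, p = (b + 1)/(n_perm + 1), so it is bounded
below by 1/(n_perm + 1) and never zero; this matters because p later
becomes the edge weight `w` in formulas where w = 0 would be degenerate.
Only ρ gates retention; p is reported, not thresholded.

No multiple-testing correction is applied at this stage, and fiber-type
labels are carried as sample metadata only — the screen never stratifies
by them.

## Quantile normalization

Expression is normalized per RNA class (coding, long non-coding, miRNA
occupy different dynamic ranges).  Within a class stratum, each sample's
values are replaced by the rank-ordered reference distribution (mean of
column-sorted values across samples); tied values receive the mean of the
reference quantiles they span, which keeps the transform idempotent.
Single-gene strata are returned unchanged with a warning.  Missing values
are rejected with a hard error rather than imputed.

## Circuits

Interactions are consumed as TSV exports with a binary evidence label
(`validated`/`predicted`) and a source database name; rows contradicting
the gene catalog are dropped and counted, and duplicates across databases
merge into one record per (miRNA, target, evidence) with concatenated
source names.  Gating keeps exactly the interactions whose pair has a
retained anticorrelation.  Circuit enumeration hashes the retained
mRNA–lncRNA pairs and walks each miRNA's gated adjacency; the output
contract is identical to the cubic brute force over all triples, which the
tests use as the oracle.

A circuit is labeled `validated` only when *both* interaction edges are
validated; any predicted edge makes it `predicted`.  The conservative rule
keeps the validated set pure, which matters because validated circuits are
up-weighted downstream.  When both a validated and a predicted record
exist for the same (miRNA, target) pair, the validated one is used.

Cluster scoping keeps a circuit when at least one of its three members is
in the marker-gene set (configurable to require the mRNA specifically);
when the cluster set defines subgroups (e.g. WT vs DEx51 nuclei), the
per-subgroup circuit lists are computed and kept fully separate.

## Master network

Edges are the union of circuit sides, each remembering its contributing
circuits.  `w` is the permutation p-value of the endpoint correlation —
the only p-value the pipeline computes.  The scale factor defaults to
edge-level counting (edges in ≥ 1 predicted circuit over edges in ≥ 1
validated circuit); circuit-level counting is available behind a flag
since the ratio's denominator is ambiguous between the two readings.  With
zero validated edges the ratio is undefined and sf falls back to 1 with a
prominent warning.

The validated weight formula `wpg = 1 − w·sf` can go negative once
w·sf > 1, which realistic sf values (≫ 1) make common; wpg is therefore
clamped to [1e−6, 1].  Clamping preserves the intended ordering — validated
edges with small w are up-weighted — while keeping all random-walk weights
positive.  Edges belonging to both a validated and a predicted circuit use
the validated formula.  PageRank runs on the undirected graph (each edge as
two arcs of equal weight) with damping 0.85 — a conventional default, made
configurable — and a total-error tolerance of 1e−9.  The minimum spanning
forest uses edge length `w`, so the tree prefers statistically strongest
edges; ties break deterministically by lexicographic edge insertion order.

## Subnetwork extraction

The node-centric procedure composes four steps: (1) induced subgraph of
the two-step unweighted neighborhood; (2) top-30 selection by PageRank
balanced 10 per RNA class, classes with fewer members backfilled by global
PageRank so the displayed size stays stable; (3) greedy circuit
collection — validated circuits strictly before predicted, each round
picking the circuit that de-isolates the most currently edge-less selected
nodes — until no selected node is isolated or no circuit helps; (4)
stitching: repeatedly join the smallest and largest components through the
w-weighted shortest path in the master network between their top-PageRank
nodes (hop-count mode behind a flag), then add one extra node per path
edge where it completes a circuit.  The completion step is a greedy
weighted set cover over candidate third nodes (maximize newly covered path
edges per added node, lexicographic tie-break); an exhaustive solver over
small candidate sets exists for verification.  Nodes already present cover
their edges at no cost.  Components unreachable in the master network are
dropped with a warning, so the output is always a single component.  When
more than two components exist the smallest-into-largest merge order is
applied as stated, although other orders are plausible.

Custom networks skip circuit collection: the induced subgraph on ≤ 30
query nodes is connected along MST paths between component representatives
(the MST path is unique and cheap to reuse), with the same
circuit-completion step on stitched edges.  The 150-node cap evicts
lowest-PageRank circuit-completion nodes first, then path interiors, never
query nodes; the eviction order is this package's choice, since only the
cap itself is specified upstream.  All tie-breaks everywhere are
lexicographic, so identical inputs give identical outputs.

## Pathway enrichment

Pathway topologies are read from a generic node/edge TSV dialect rather
than retrieved from KEGG; extension adds each miRNA with a gated
interaction to a pathway mRNA, and each lncRNA sharing a circuit with such
a miRNA.  Extension affects display only: enrichment is computed on the
original coding membership, because counting regulators as members would
conflate gene-set membership with regulatory reach (a flag overrides
this).  The universe defaults to the union of coding genes across loaded
pathways — the dominant unstated choice, surfaced in the result table as
`universe_size` and overridable with a user background.  Non-coding query
members are excluded from the counts and reported separately.  The test is
the upper-tail hypergeometric probability (scipy's survival function) with
Benjamini–Hochberg step-up adjustment (statsmodels) across pathways.

## Fragmentation index

Per-fragment volume shares are V_S = 100·v_i/Σv; F.I. is the fraction of
fragments with V_S ≤ 20%, cutoff inclusive (the indicator is written with
≤) and exposed as a parameter.  The denominator is the total fragment
count, the only reading that keeps the statistic in [0, 1].  The metric is
scale-free, so volume units are irrelevant.

## Synthetic data

Each planted circuit draws a latent driver z ~ N(0,1) per sample; the
mRNA and lncRNA read out +z and the miRNA −z, plus independent Gaussian
noise.  Monotone links mean the Spearman targets hold regardless of
marginals.  Noise scales come from the bivariate-normal identity
ρ_pearson = 2·sin(πρ_spearman/6): at `noise_sd = 1` planted pairs hit the
requested Spearman targets (defaults 0.8 / −0.7, comfortably inside the
0.45 / −0.35 gates), at `noise_sd = 0` they are exactly ±1.  Remaining
genes are independent N(0,1) background; distractor interactions connect
background genes, so the gates reject them with probability → 1.

Defaults: 40 mRNAs, 20 lncRNAs, 15 miRNAs, 60 samples (ten replicates per
six fiber types, whose labels cycle as pure metadata), 8 planted circuits
half validated, 20 distractor interactions.  These sizes keep the
all-pairs screen (1,700 pairs) plus permutation tests under two seconds
while leaving enough background pairs (~1,670 null pairs) for false
positives to be observable if the gates were mis-specified.

`simulate_master` builds circuit lists directly (synthetic ρ and p drawn
inside the gate-admissible ranges) with a block parameter that forces an
exact number of connected components, for exercising the stitching logic.
Connectivity within a block is guaranteed by adding bridging circuits
between components after sampling.

What the generator does **not** emulate: microarray or snRNA-seq noise
models, count distributions, batch structure, or realistic
interaction-database error rates.  Passing tests therefore demonstrate the
correctness of the algorithms under the stated correlation model, not
performance on real measurements.

## Numerical choices and limitations

* Permutation p-values are Monte-Carlo estimates; tests compare them to
  exhaustive tails within binomial error.
* PageRank is delegated to networkx (power iteration) with the tolerance
  rescaled so it bounds total L1 error; the test oracle is an independent
  dense implementation.
* Spearman comparisons against oracles use 1e−12; a ±1e−12 slack in the
  permutation tail comparison absorbs floating-point ties at |ρ| = 1.
* The greedy set cover in circuit completion is not optimal in general;
  on ≤ 6-candidate instances it matches the exhaustive solver in tests,
  and it never leaves a coverable path edge uncovered.
* Enumeration cost grows with the product of gated adjacencies per miRNA;
  the genome-scale regime (millions of circuits) is out of desk-scale
  scope here, and no attempt is made to reproduce database-dependent
  global counts.
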