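# Methods

## The data model

The unit of evidence is a directed, literature-curated interaction: an input
molecule signals to a target molecule, observed in one model organism
(single-letter codes m, r, h, e, b, g, d for mouse, rat, human, horse, cow,
chicken, zebrafish) at one developmental stage.  The *embryo* stage
deliberately includes fetal-stage reports; *prepubertal* covers early
post-natal life.  Links are typed as *physical* (direct binding) or
*functional* (indirect association), and an optional effect column records
up/down regulation.  Molecule identifiers are normalised to uppercase
symbols with internal whitespace removed; identical symbols are treated as
the same molecule across species.  No orthology mapping is attempted — a
cross-species comparison by shared symbol is exactly that, and molecules
with diverged names in different organisms will not be matched.

Percentage shares in composition summaries are printed to the nearest
integer for shares of at least 2% and to one decimal below that, so small
contributors remain distinguishable from zero.  Under this rule shares need
not sum to exactly 100 (each reported species can lose up to half a point
to rounding).

## Networks and their undirected view

Networks keep the full directed, typed edge set (one edge per distinct
source–target–link-type triple), but every topological quantity — degree,
path statistics, clustering, hubs, MCL — is computed on an *undirected
simple-graph view*: self-loops removed, parallel and antiparallel edges
collapsed to a single pair.  Degree is "the number of other molecules this
molecule touches", which is the convention of the standard network-analysis
tooling this package mirrors, and the only defensible one when curated
edges mix directed regulation with undirected physical binding.  Self-loops
are counted and reported separately.

On disconnected graphs the diameter and characteristic path length are
taken over connected node pairs only, and the radius over the largest
connected component, so they stay finite and comparable across networks
with stray components.  The clustering coefficient is the unweighted mean
of local coefficients, with nodes of degree < 2 contributing 0.

## Scale-free assessment

The degree distribution is fitted by ordinary least squares on
(log10 k, log10 P(k)) over the observed degrees k ≥ 1; the reported γ is
the magnitude of the slope.  A network is flagged scale-free when r² ≥ 0.8
and γ ∈ [1, 4] (both configurable).  The fit is declined outright when
fewer than 3 distinct degrees are observed.

This estimator is simple and matches common interactive tooling, but it is
known to be biased: degrees observed exactly once form a flat tail in the
empirical pmf that drags the slope down, so γ estimates on
preferential-attachment graphs concentrate well below the asymptotic
exponent 3 (typically 1.4–1.9 at a few hundred nodes).  The flag thresholds
are therefore permissive, and γ should be read as a descriptive statistic,
not an estimate of a generative exponent.  Maximum-likelihood tail fitting
was deliberately left out: at literature-corpus scale (tens to a couple of
hundred nodes) it has no power either, and the scale-free statement is
qualitative.

## Hubs

A hub is a node whose degree is at least μ + kσ, where μ and σ are the mean
and standard deviation of the network's degree list and k defaults to 1.
The boundary is inclusive, so a regular graph (σ = 0) makes every node a
hub — the definition degrades transparently rather than arbitrarily.  σ is
the population SD by default; the sample SD is available behind a flag
because the choice moves borderline nodes.  Hub identification requires at
least 2 nodes.

## Markov Cluster Algorithm

MCL is implemented from scratch on dense numpy matrices (the target
networks are far below the scale where sparsity matters).  The adjacency
matrix of the undirected view — optionally score-weighted — receives
self-loops of weight 1 (standard practice: guarantees aperiodicity and
stabilises small graphs), is column-normalised, and is then iterated:

1. *expansion*: matrix power e (default 2) — flow spreads along walks;
2. *inflation*: entrywise power r (default 3) with column re-normalisation
   — strong flows are sharpened, weak ones starved;
3. *pruning*: entries below 1e-5 are zeroed and columns re-normalised.

Iteration stops when the largest entry change falls below 1e-8, or at 100
iterations (the partition is then returned flagged unconverged rather than
raising — a diagnostic, not an error).  Clusters are read off the limit
matrix: rows with positive diagonal are attractors; attractor rows whose
supports share an attractor form one attractor system; a node claimed by
several systems is assigned to the largest (ties to the system containing
the lexicographically smallest symbol), so output is deterministic.  Nodes
orphaned by pruning are attached to the cluster receiving most of their
column flow, or become singletons.  Higher inflation yields finer
partitions; disconnected components can never merge.

Conductance — boundary edges over the smaller of cluster volume and
complement volume — is reported per cluster as a flow-containment score.

## Enrichment and expansion

Term over-representation is the upper-tail hypergeometric probability
P(X ≥ k) for an overlap of k between the query and a term of size K in a
universe of N annotated molecules, computed by exact integer summation of
binomial coefficients.  The background universe is the annotation
collection's universe (not the query network); query symbols outside it are
dropped and logged.  Terms overlapping the effective query by fewer than 2
molecules are not tested by default (singleton overlaps are rarely
interpretable; configurable).  Benjamini–Hochberg adjustment runs over all
tested terms, and significance means q < 0.05.

Network expansion emulates the interactive "add interactors" loop of a
scored interaction service over a local three-column table (scores accepted
on [0,1] or 0–1000, auto-detected).  Per cycle, every non-member linked to
the current node set by a pair scoring ≥ 0.400 is a candidate; candidates
are ranked by (number of qualifying links into the set, summed scores,
symbol) and the top 10 per cycle (configurable) are admitted with all their
qualifying edges.  Three cycles by default.  The ranking depends only on
set contents, so the result is invariant to input row order; raising the
cutoff can only shrink the candidate set.  Term enrichment is *not* re-run
between cycles — cycles add nodes only — though nothing prevents calling
the enrichment step on intermediate networks.  Merged ("enriched")
networks flag each node as literature-only, enriched (new), or common
(curated node also supported by the predicted pair set); predicted edges
never overwrite curated ones.

Significant terms roll up into four macro-categories (growth/
differentiation/survival, morphogenesis and cell motility, nervous system,
endocrine system); terms without one count as "unclassified".

## Comparisons

Venn overlap between two node sets is reported as shared / union
(Jaccard × 100), rounded to the nearest integer — the convention that makes
a 13-node overlap between a 64-node and a 40-node stage network read as
14%.  Layer stratification assigns each node to upstream (ligands,
receptors, transducers), TF, or downstream (ECM and effectors) from an
annotation table and reports, per layer, the fraction of molecules newly
contributed by enrichment.  Percentages here round half *down*
(62.5 → 62), matching how such tables are customarily printed.  Nodes
without a layer annotation are excluded from totals and listed.

## Synthetic data

The generator's defaults are the study conditions: per-(species, stage)
interaction counts of the curated corpus (286 total; 155 embryo / 131
prepubertal; mouse 71/74, rat 0/28, human 9/0, horse 3/25, cow 0/2,
chicken 68/2, zebrafish 4/0), a 52:23:24 upstream:TF:downstream layer
mixture, and preferential-attachment topology.  Counts are met exactly, not
in expectation.  The attachment parameter defaults to m = 1: curated
corpora are sparse and leaf-heavy (most molecules appear in one or two
reports), which m = 1 reproduces — including a monotone degree pmf on which
the log-log fit is well behaved and near-zero clustering — whereas m = 2
produces almost no degree-1 nodes and a non-monotone pmf.  A conserved core
of 4 shared symbols replaces the top-degree nodes of the first 4 populated
species, so cross-species hub conservation is exercised.

Annotation collections place 40 terms of size 10 over a 200-symbol universe
(round-robin across the four macro-categories); planted terms contribute
round(effect × term size) members to a 20-symbol query, with effect 0.8 by
default — strong enough that the planted term is recovered at q < 0.05 in
essentially every replicate, while effect 0 is calibrated at the nominal
type-I level.  Scored sources draw true-pair scores from Beta(8, 2)
(mean 0.8) and background scores from Beta(2, 8) (mean 0.2), separated by
the 0.400 cutoff, and attach 30 novel interactor symbols to random network
nodes so expansion has something real to find.

What the generator does *not* emulate: real gene-symbol vocabularies,
actual pathway content, citation structure, cross-species orthology, or the
reporting biases of curated literature (well-studied molecules attract
edges for sociological as well as biological reasons).  Passing tests
demonstrate that the machinery is correct under the declared statistical
structure, not that any biological conclusion transfers.

All generators fork per-purpose random streams from the single seed by
fixed labels, so adding one generator never shifts another's output and
identical config + seed is byte-identical.

## Pipeline

The orchestrated run builds one network per populated species, and
additionally per-stage networks for every species with at least 10 records
in *each* stage — at corpus-default composition only the mouse qualifies,
which reproduces the usual practice of splitting stages only where the data
can support both.  Analytical constants (hub k = 1, inflation 3, cutoff
0.400, α = 0.05, 3 cycles) live in one config object, are overridable from
a flat YAML file or CLI flags, and are recorded in the run manifest along
with the seed and SHA-256 checksums of every input.  Reports carry no
timestamps, and all iteration orders are sorted, so a rerun with identical
inputs and seed is byte-identical.

Problem sizes throughout the test-suite simulations (≤ 12-node graphs for
exhaustive oracles, 500-replicate property sweeps, 100–200-seed
calibration/power runs, 8-node planted communities) were chosen so each
statistical claim is backed by enough replicates while the whole suite runs
in well under a minute; they are properties of the checks, not of the
method.

## Known limitations

* Betweenness-based bottleneck ranking is intentionally absent: on corpora
  this small the statistic is dominated by noise.
* Cross-species identity is symbol-level only (see above).
* The power-law fit is descriptive (see above).
* MCL overlap resolution is deterministic but arbitrary at exact ties; on
  symmetric graphs the tie-break (largest system, then smallest symbol)
  decides membership.
* The expansion loop models one specific interactive protocol (rank by
  link count, then score sum); services implementing different candidate
  ranking will admit different nodes at the margin.
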