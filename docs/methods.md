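# Methods

This note documents the models and procedures implemented in `mirsignet`,
the parameters that matter, the numerical conventions, and what the
synthetic benchmarks do and do not demonstrate.

## Harmonization model

Association evidence is treated as a set of (miRNA, disease term, source)
assertions. miRNA labels are normalized to miRBase-style canonical form: a
lower-case species prefix (`hsa` by default), the mature-stem casing `miR`
(`let` stays lower-case), and verbatim numeric ids, letter variants,
precursor indices and `-5p`/`-3p` arm suffixes. Precursor-indexed mature
names (`hsa-miR-199a-1-5p` vs `hsa-miR-199a-2-5p`) are distinct miRNAs:
they derive from different loci and association databases list them
separately. Strings without a recognizable `miR`/`let` token are rejected
row-wise with a logged warning rather than failing the whole table.

Disease terms are mapped to a neoplasm-group vocabulary through a supplied
two-column table, with case-, whitespace- and punctuation-insensitive
lookup. The mapping is closed-world: unknown terms map to an `UNMAPPED`
sentinel and are dropped before any network is built; a term whose
normalized key maps to more than one group is ambiguous and is removed at
map-load time. This mirrors manual curation practice, where ambiguous
disease wordings are discarded rather than guessed, and keeps the mapping
fully declarative — the pipeline never invents a group.

Deduplication collapses records to unique (miRNA, group) pairs, merging
the source tags; output order is (group, miRNA)-sorted, making the stage
idempotent and order-independent.

## Consensus targets

Per-tool prediction tables are reduced to distinct (miRNA, gene) pairs per
tool before voting, so duplicated rows in one export cannot inflate
support. A gene is a consensus target of a miRNA when at least
`min_tools` distinct tools predict the pair. The default is 4 of 5 —
"more than three" read literally — and is a configuration knob because
tool panels vary. Raising `min_tools` is monotone (it can only shrink
target sets); at `min_tools = 1` the consensus is the union, at the full
tool count the intersection.

## GO semantic similarity

The ontology is held as a rooted DAG per namespace with `is_a`/`part_of`
parent edges (parsed with `obonet`; obsolete terms excluded; cycles and
rootless namespaces are format errors). Annotations are propagated to all
ancestors (true-path rule) before counting. For a term *t* in namespace
*N*, `p(t)` is the fraction of *N*-annotated genes carrying *t* after
propagation and `IC(t) = −ln p(t)`; the namespace root has IC 0 and IC is
monotone non-decreasing from ancestor to descendant. Natural log is used;
the base only rescales IC and cancels in Lin similarity.

Term similarity is MICA-based. With MICA the common ancestor of maximal
IC:

* `lin(t1, t2) = 2·IC(MICA) / (IC(t1) + IC(t2))` (0 when both IC are 0);
* `resnik(t1, t2) = IC(MICA) / max_IC`, normalized by the largest IC
  observed in the pair's namespace so both measures live on [0, 1] and are
  comparable against the 0.6 edge threshold.

Cross-namespace pairs score 0 (they have no common ancestor); this is a
warning, not an error, so mixed annotation sets degrade gracefully.

Gene similarity is the best-match average (BMA) of the term-similarity
matrix — the mean of row maxima and of column maxima, averaged — computed
per namespace over the *informative* (IC > 0) propagated terms of both
genes, then averaged over the namespaces where both genes have informative
terms. Zero-IC terms (the roots, and any term annotating every gene) are
excluded: they carry no information, and leaving them in would make even a
gene's self-similarity smaller than 1. Lin is the default method because
it is intrinsically bounded in [0, 1].

## miRNA-pair similarity

Two scores per pair, from the consensus target sets:

* **Symmetric** — BMA over the gene-similarity matrix of the two target
  sets. Symmetric by construction; 1.0 for identical target sets.
* **Asymmetric, significance-weighted (`mirgofs_like`)** — term-level
  affinity is the Jaccard index of the two terms' combined
  ancestor+descendant closures, which rewards shared specific ancestry
  *and* shared descendant structure. Each side's terms are weighted by
  enrichment significance in that miRNA's target set: the hypergeometric
  upper-tail p of the term's target overlap is mapped to a weight
  `min(1, −log10 p / log10 N)` where *N* is the annotated-universe size —
  the cap is the magnitude of the smallest achievable single-draw p, so
  one vanishing p-value cannot dominate, and a floor of 1e−6 keeps
  uninformative terms (p = 1) strictly positive as the weight contract
  requires. The directed score S(A→B) is the weighted mean over A's terms
  of each term's best affinity in B's terms; the reported value is the
  mean of the two directions. The directed components are genuinely
  asymmetric (a miRNA whose term set is nested in another's scores a full
  1 in the nested direction). This measure is a declared approximation of
  the MIRGOFS family — it realizes the closure-aware affinity,
  significance weighting and asymmetric comparison, but does not claim to
  reproduce any published tool's numbers, and is isolated behind its own
  function so a faithful port could replace it.

Edges are formed per source first (a pair enters when either score is
**≥ 0.6**, an inclusive cutoff), then merged: one edge per unordered pair
carrying whichever weights passed, with `w_combined` the maximum present.
The union-then-deduplicate rule admits an edge on either source's
strength, and the per-source-then-union order matches how the two sources
are naturally produced independently. Edges are computed only among
miRNAs associated with at least one neoplasm group.

## Networks and pruning

Each group's network restricts the global edge set to the group's
associated miRNAs. Pruning uses the nearest-rank percentile: the cutoff is
the value at ascending rank `⌈(p/100)·E⌉` (no interpolation), and only
edges with combined weight *strictly above* the cutoff survive. With E
distinct weights this retains exactly `E − ⌈(p/100)·E⌉` edges — the
convention is chosen because it reproduces the 2,415 → 241 complete-graph
arithmetic exactly, where interpolated percentiles would give 242. Ties
at the cutoff are all dropped (strictness applies to the value, not the
rank), which makes pruning deterministic and input-order-independent.
Nodes left isolated are removed, which is why pruning reduces node counts
as well as edge counts (70 → 39 in the reference case). Pruning operates
on `w_combined` by default; the weight attribute is configurable.
Re-pruning a pruned network is an error rather than a silent double cut.

Topology reports give the degree histogram, the average local clustering
coefficient (degree < 2 counts 0), the dispersion index (sample
variance/mean of degrees; 0 for regular graphs) and a chi-square
goodness-of-fit p-value against Poisson(mean degree), with adjacent bins
merged inward from both tails until every expected count is ≥ 5 and one
degree of freedom charged for the estimated mean. Graphs too small to
leave a positive degree of freedom report p = 1: the fit is unfalsifiable
at that size, which is reported rather than hidden. Note that
Erdős–Rényi degree sequences are binomial and hence slightly
underdispersed relative to Poisson, so even genuinely "random" graphs
fail this test in a small fraction of seeds at the 0.05 level.

## Signature modules and mutual exclusivity

A candidate module is a maximal clique of ≥ 3 miRNAs in one group's pruned
network, enumerated deterministically (Bron–Kerbosch via networkx, results
totally ordered). Maximal cliques realize both stated properties of a
module — internal density (a clique's internal edge fraction is 1) and
maximality (not contained in a larger dense subgraph) — without a tunable
community-detection step. Pairs (size 2) are excluded by contract.

Mutual exclusivity is a *set-level* property: the census counts networks
in which every member pair is an edge, and a module is exclusive when that
count is 1. Individual miRNAs may appear in many networks and in modules
of several groups; membership alone never breaks exclusivity, only the
full clique reappearing does.

Significance uses a degree-preserving rewiring null: each permutation
replicate rewires every network by attempted double-edge swaps (10·E
attempts per network, preserving all degrees), and a candidate scores a
hit when its member set reappears as a clique in at least one network
other than its host. The add-one estimate `p = (1 + hits)/(n_perm + 1)`
has floor `1/(n_perm + 1)`; `n_perm` defaults to 999 (199 in the
benchmark harness). Benjamini–Hochberg correction is applied across all
tested candidates; modules with q ≤ α (default 0.05) are reported, nested
modules of the same group removed, ranked by (q, −density, −size,
members). All randomness flows from one integer seed; identical seeds
give byte-identical reports.

One calibration caveat, verified empirically: the permutation p-value
estimates each module's reappearance probability under rewiring. Across a
population of candidate cliques that quantity is *not* uniformly
distributed — most specific cliques rarely re-form under degree-preserving
swaps — so the p-values of exclusive candidates in a structureless world
concentrate at small values rather than spreading uniformly. The
procedure's false-positive behaviour should therefore be judged at the
level of the full selection (census + permutation + BH), which the
null-world benchmark below does, not by the marginal p-value histogram.
The test itself is the package's declared choice of exclusivity statistic;
alternatives (e.g. hypergeometric overlap nulls) would plug in at the same
interface.

## Synthetic study conditions

The generator defaults define the benchmark conditions: **10 neoplasm
groups, 60 miRNAs per group, 20 background miRNAs shared by all groups,
one planted exclusive module per group with sizes cycling through 3–6,
199 permutations**, similarity bands module 0.92–0.99, background
0.70–0.90, filler 0.60–0.70 with filler edge density 0.30. Planted module
miRNAs occur only in their group and only score highly with each other;
background miRNAs are fully interconnected in the mid band, so they
straddle each network's decile cutoff; filler edges fall below every
cutoff and are pruned away. Filler edges are drawn as an exact count
rather than Bernoulli so per-network edge totals, and hence cutoff ranks,
are stable; as a consequence, background cliques above the cutoff recur
in several networks and are eliminated by the exclusivity census rather
than surviving as false positives. Association tables are emitted in all
four source dialects with duplicate rows and lower-case `mir` spellings
injected, so deduplication and name normalization are always exercised.

The generator plants similarity *scores* directly (the association world)
and, separately, generates an ontology world — a layered random DAG with
1–2 parents per non-root term and genes annotated to random leaves — that
exercises the full GO route (parsing, propagation, IC, Lin/Resnik, BMA,
enrichment weights). Decoupling the two keeps the module-recovery
benchmark sharp: a recovery failure implicates the network/exclusivity
machinery, not the similarity computation, and vice versa.

What passing these benchmarks shows: the pipeline's bookkeeping,
thresholds, pruning arithmetic and exclusivity logic recover exactly the
structure they are specified to recover, with calibrated nulls. What it
does not show: performance on real association data, where similarity
scores are noisy and correlated with miRNA family structure, group sizes
are wildly unbalanced (39–1,821 miRNAs in the reference tables), and the
"planted module vs background" separation is far less clean. Real-data
module lists additionally depend on the snapshot dates of the upstream
databases and are not reproducible from the package alone; the packaged
report tables are used for structural checks only.

## Problem sizes and determinism

The benchmark harness runs 20 planted worlds and 100 null worlds at the
default conditions (about a minute total on one CPU) — sizes chosen so the
Monte-Carlo error on precision/recall and the null clean-rate is small
relative to the 0.9/0.95 acceptance margins. Rewiring uses
integer-indexed draws from `numpy.random.Generator` exclusively; no
iteration-order-dependent randomness exists, so results are reproducible
across platforms for a fixed seed.

## Known limitations

* The asymmetric similarity is an approximation of the MIRGOFS family,
  not a port; absolute scores are not comparable to the published tool.
* Evidence codes are ignored when reading annotations; all annotations
  count equally.
* Wang's graph-based term similarity is not implemented (Lin/Resnik only).
* The pruning percentile is applied per network on the combined weight;
  pruning on a single source's weight is configurable but untested against
  any external reference.
* `UNMAPPED`/ambiguous disease terms are dropped, not resolved; no fuzzy
  or ontology-driven disease matching is attempted.
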