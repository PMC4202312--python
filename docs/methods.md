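# Methods

## Network model

The similarity network is built from a 12-column tabular hit file (BLAST
outfmt-6 layout; extra trailing columns tolerated). Coordinates are 1-based
inclusive end to end; no half-open conversion is ever serialized. The
network is symmetrized and reduced to at most one edge per unordered pair by
keeping the hit with the best (lowest) E-value; ties go to the higher
bitscore, then to the direction whose query id sorts first, so builds are
deterministic regardless of input order. The edge threshold is a strict
`E < 1e-5`; hits at exactly the threshold are excluded. Self-hits are parsed
(and flagged) but never become edges. Singleton sequences are kept as
nodes so that fractions of "the data set" and of "the network without
singletons" are both computable.

To obtain a hit table from real sequences, the intended recipe is an
all-vs-all BLAST+ with low-complexity softmasking, e.g.

```bash
segmasker -in proteins.fasta -outfmt maskinfo_asn1_bin -out masks.asnb
makeblastdb -in proteins.fasta -dbtype prot -mask_data masks.asnb
blastp -query proteins.fasta -db proteins.fasta -outfmt 6 -evalue 1e-4 \
    -out hits.tsv
```

Running the aligner is deliberately outside the package; the pipeline's
contract starts at the hit table.

## Detection

Candidate enumeration is per node over pairs of its neighbors —
O(Σ deg²), never all n³ triples. Two modes give identical call sets:
the default enumerates all neighbor pairs, which also yields the exact
cumulative funnel of triplet counts per condition (in the order:
non-transitive → overlap ≤ w → stringency); `compute_funnel=False`
restricts enumeration to stringent neighbors, trading exact stage-i/ii
counts for speed on high-degree graphs. The per-call evidence list is a
sample (default 50 triplets) but supporting-triplet counts are always
exact, and the full passing-evidence list is returned separately because
the safest filters need it uncapped.

The overlap between the two candidate edges is measured on the candidate's
own coordinates using the single retained best hit per edge. Condition
thresholds (`build 1e-5`, `stringency 1e-10`, `w = 20 aa`) are parameters;
calls are monotone non-decreasing in both `w` and the stringency
threshold, which the test suite verifies. No attempt is made to
distinguish fusion from fission: both leave the same network signature.

Multicomposite detection re-evaluates the three conditions inside the
subgraph induced by composite calls, with non-transitivity judged by edge
absence within that subgraph. This recovers both planted double fusions and
the directly-connected-composites pattern (composites drawing on
overlapping combinations of a shared segment pool).

## Safest filters

"Embedded" is operationalized as: the component shares the candidate's
genome and the retained hit covers ≥ 95% (`embedding_coverage_fraction`)
of the component's length. Gene-coordinate overlap on the genome would be
the more literal reading, but the data model is protein-only; sequence
containment is the available proxy, and the fraction is exposed as a
parameter. Filters run in narrative order: (1) embedded-component triplets
are discarded; (2) calls left with exactly one surviving triplet whose two
components share a genome are removed; (3) calls whose every network
neighbor shares their genome are removed. With these definitions the
outcome is order-independent except that filter 2 counts triplets
surviving filter 1. The filters only remove, are idempotent, and safest
multicomposites are re-detected on the safest-composite subgraph.

## Network statistics

*Louvain first pass* is the local-moving phase only: from singleton
communities, nodes are swept in a seed-shuffled fixed order and greedily
moved to the neighboring community with the largest positive modularity
gain (ties to the smallest community id) until a sweep makes no move.
No aggregation or recursion follows — the communities reported are
level-one groups, which is what the supergraph then pools. Edges are
treated as unweighted. An edgeless graph yields the all-singleton
partition with modularity 0; an empty graph is an error.

*Cycle edges* of the community supergraph are the non-bridges — an edge
lies on some cycle iff its removal does not disconnect its component,
equivalently iff it belongs to the union of any cycle basis. Bridges are
found with networkx; the suite cross-checks against a remove-and-test
oracle.

*Assortativity* is Newman's categorical coefficient over the
edge-endpoint mixing matrix, each undirected edge counted in both
orientations. Edges touching unlabeled nodes are dropped by default
(exposed as a parameter — whether unknown-class nodes should enter is an
analysis choice). When every evaluated edge joins a single label the
denominator vanishes; this is reported as an error, explicitly distinct
from r = 1 measured over two or more labels. Per-class coefficients use
the binary indicator label (class vs rest), the standard construction for
obtaining one coefficient per class from a categorical labeling.

*Betweenness* is normalized shortest-path betweenness with endpoints
excluded (normalization 2/((n−1)(n−2)) for undirected graphs).
Approximate mode is the pivot estimator — single-source shortest paths
from k uniformly sampled pivots, dependencies rescaled by n/k — and
equals the exact computation when k = n. The pipeline uses exact mode up
to 2,000 nodes and k = 5,000 pivots beyond that. The estimator is
unbiased; the suite checks convergence of the seed-averaged estimate at
5% tolerance over 50 seeds.

## Enrichment

Functional categories are the 25 one-letter COG/KOG classes. Unannotated
sequences are excluded from all functional analyses. Composition uses
fractional weights (a sequence with m categories contributes 1/m to
each); count tables use full weights. Each category is tested against the
combination of all other categories with a two-sided Fisher exact test
(scipy's hypergeometric-sum definition, cross-checked in the suite
against exact rational enumeration for small margins). Because the
natural comparison (composites vs all sequences) nests one set inside the
other, the implementation tests subset vs complement so the 2×2 table is
well-defined. Bonferroni control is computed exactly as alpha/m
(0.05/25 = 0.002 per test by default), with alpha exposed.

## Synthetic data generator

The generator's defaults define the validation conditions: 30 unrelated
root families (uniform-random amino-acid strings, 300–600 aa), 10 members
per family derived by i.i.d. substitutions at d = 0.15 per site and rare
geometric indels (0.01/site, mean length 2 — rare so the member↔root
coordinate map stays piecewise-linear and exact), 20 planted composites,
5 planted multicomposites, segment fractions in (0.35, 0.65) so every
planted segment is ≥ ~100 aa, 50 genomes assigned round-robin, and a 1%
noise-hit rate. A composite is a prefix fraction of a fresh family member
concatenated with a suffix fraction of a fresh member of a second family,
with the junction recorded exactly; a multicomposite concatenates a
prefix of one planted composite (all of its first segment plus half its
second) with a suffix of another composite from a disjoint family pair,
so its parts trace to ≥ 3 families.

Two design rules keep the planted labels identical to the detectable
pattern. First, each family donates either prefixes or suffixes, never
both: two composites sharing a donor family therefore always share an
overlapping root segment (and hence an edge), whereas opposite-end
donation would make plain members of that family genuine fission-type
bridges — correctly detectable, but labeled "component" in truth. Second,
the families feeding multicomposites are used by exactly one composite
each, preventing partial segments of a multicomposite from forming
interior-interval bridges through ordinary members.

Instead of running an aligner, hits are derived from planted ancestry:
for each ordered pair sharing a family, the shared root interval of
length `Lseg` is mapped through the alignment blocks onto both sequences
and emitted with bitscore `S = λ·Lseg·(1 − 2·d_pair)` (λ = 2, clamped at
0; `d_pair` is the summed per-branch divergence, 2d for two independent
members) and E-value `min(1, m·n·2^(−S))`. This is a deliberately simple
Karlin–Altschul-shaped surrogate: it only needs to be monotone in segment
length and divergence, and it places default within-family and
composite–component hits far below 10⁻¹⁰ while 25-aa slivers at high
divergence clamp to unusable. Noise hits between unrelated pairs draw
E-values uniformly from [10⁻⁶, 10⁻⁵), deliberately hugging the build
threshold to exercise thresholding downstream.

What the generator does **not** emulate: realistic substitution matrices
or rate heterogeneity, domain architecture, genome structure and gene
order, overlapping genes, HSP fragmentation, and BLAST's hit-extension
artifacts (the 20-aa overlap tolerance is therefore never stressed by
construction — it is tested with hand-built networks instead). Passing
recovery tests shows the detection logic is correct on networks whose
edges faithfully reflect shared ancestry; it does not show robustness to
aligner noise on real data.

## Numerical choices and degenerate inputs

E-values of 0 are floored at 1e-180 before taking −log10 in diagnostics.
Percentages are rounded half-away-from-zero to one decimal, the rule that
reproduces published one-decimal tables from their printed counts.
Correlation diagnostics require ≥ 3 edges and non-zero variance per
group; the composite–component correlation is reported as absent when
fewer such edges exist. Zero-margin Fisher tables are degenerate with
p = 1 and never significant. Betweenness pivot counts above n clamp to n
with a logged notice. The pipeline runs detection before metrics so the
betweenness contrast can use the calls; the contrast is skipped (with a
notice) when either group is empty or the non-composite mean is zero.

## Problem sizes

The default validation run uses 325 sequences (~2,400 edges, ~38,000
centered triplets); oracle-equivalence tests use 200 random graphs of up
to 40 nodes for triplet calls, 30 supernodes for cycle edges, margins
≤ 30 for Fisher enumeration, and 200 nodes for pivot betweenness — sizes
at which the brute-force oracles are exact and fast while still
exercising every code path.

## Known limitations

Counts at the scale of real all-vs-all surveys (10⁵ sequences, 10⁸
triplets) are not reproduced here; the funnel enumeration is O(Σ deg²)
and would need the stringent-only mode plus out-of-core evidence handling
at that scale. The truth-derived E-value model is not calibrated to any
aligner's statistics. Multicomposite precision is not a meaningful target
under the default conditions because directly connected composites are a
legitimate multicomposite pattern, not an error mode.
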