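# Methods

## The network model

The regulatory network is a heterogeneous directed graph over four node
classes — transcription factors (TF), miRNAs, differentially expressed
target genes, and miRNA host genes — with typed, signed edges in four
layers:

| layer          | direction      | allowed endpoints            | default sign |
|----------------|----------------|------------------------------|--------------|
| `tf_mirna`     | TF → miRNA     | TF → miRNA                   | unknown      |
| `mirna_target` | miRNA → gene   | miRNA → TF or target gene    | repression   |
| `mirna_host`   | miRNA → host   | miRNA → host gene            | unknown      |
| `tf_gene`      | TF → gene      | TF → TF or target gene       | unknown      |

An unsigned miRNA→gene edge is treated as repressive during motif
classification because silencing is the canonical mode of miRNA action;
unsigned TF edges stay unknown and render any containing motif `unsigned`
rather than guessing. The `tf_gene` layer exists because feedforward-loop
closure needs direct TF→gene regulation alongside the miRNA route; it is a
distinct validated layer rather than an overload of the miRNA-targeting
layer so that the sign logic can tell the two T→G routes apart.

At most one edge exists per (source, target, layer); duplicate rows from
merged curation sources collapse to the first-seen sign with a logged
warning. `prune=True` removes degree-zero nodes, the convention for
discarding factors that lack any regulatory association. Node ids are
verbatim case-sensitive strings: symbol normalization (HGNC aliasing) is
out of scope, so `NFKB1` and `NF-kB1` would be distinct nodes if an input
mixed them.

## Hubs, bottlenecks, and the degree distribution

Degree and betweenness follow the usual definitions; betweenness is the
unnormalized pair-dependency sum Σ σ_st(v)/σ_st (ordered pairs on directed
networks, unordered on PPI graphs; disconnected pairs contribute zero).
Directedness defaults to the semantics of the graph: regulatory networks
are scanned directed, PPI graphs undirected.

Hub/bottleneck selection takes the upper `q` fraction (default q = 0.2,
config-overridable) of each statistic with an **inclusive** threshold: the
cut value is the ⌈qn⌉-th largest statistic and all ties at the cut are
kept. Ties therefore never split arbitrarily, the selected set can exceed
the nominal fraction, and the sets are monotone in `q`. No published
threshold exists for the hub-bottleneck intersection; 0.2 is the round
default nearest the observed ~17% intersection rate in comparable PPI
analyses.

Hub miRNAs are ranked by total degree, then by intramodular degree (number
of neighbors sharing the miRNA's module, modules being externally supplied
node sets such as MCODE clusters), then by id for determinism. "Module
membership" has no formal definition in this setting; intramodular degree
is this package's declared interpretation.

The power-law fit is an ordinary least-squares line on (log₁₀ degree,
log₁₀ frequency) over degrees ≥ 1 with nonzero frequency — the convention
behind the straight red line of scale-free-network figures — reporting
slope, intercept and r². Raw-histogram OLS is biased toward flat slopes
whenever high-degree bins hold single nodes, so a discrete MLE exponent
(Clauset-style, x_min = 1) is available via `method="mle"`; it reports only
the exponent. Neither variant is a statistical test of scale-freeness.

## MCODE

Stage 1 weights each vertex by the densest region around it: take the
subgraph induced by the vertex and its neighbors (closed neighborhood),
peel it to its highest non-empty k-core (iterative minimum-degree
removal), and set w(v) = k_max × density(core), density = 2E/(n(n−1)).
Vertices below the degree cutoff (default 2) get weight 0. Stage 2 grows a
complex from the highest-weight unvisited vertex, admitting unvisited
neighbors with weight ≥ w_seed·(1−vwp) breadth-first to `max_depth`; each
admitted vertex is visited once, so core memberships are disjoint. Stage 3
discards complexes lacking a 2-core, then optionally shaves degree-1
members iteratively (haircut, default on) and re-adds dense neighbors
(fluff, default off; fluff members may overlap between complexes).

The complex score is `density × n = 2E/(n−1)` on the final member set, and
complexes are reported in descending score order with ranks 1..K. This
loop-free density convention is the one that exactly reproduces reported
complex scores from their printed node/edge counts (27/308 → 23.692,
7/8 → 2.667, 3/3 → 3). Equal-weight seed ties break toward the
lexicographically smallest id, making the output deterministic. The
reported `seed_weight` is the seed's stage-1 weight.

## Motif census and null model

Feedback loops are unordered TF/miRNA pairs with a transcriptional edge
T→m and a targeting edge m→T. Both repressive → `double_negative` (the
bistable-switch configuration), both activating → `double_positive`,
otherwise `mixed` (oscillator-like). Feedforward loops are ordered triples
(T, m, G) with T→m, m→G and a direct T→G edge; with activation = +1 and
repression = −1 the loop is `coherent` iff sign(T→G) equals the sign
product of the indirect path. Any unknown sign (after the miRNA repression
default) yields `unsigned`. Co-regulation motifs are shared-neighbor
pairs: two TFs regulating the same miRNA, or two miRNAs targeting the same
gene; one instance per (pair, shared node).

Significance uses a degree-preserving rewiring null: within each edge
layer independently, double-edge swaps (a→b, c→d) ⇒ (a→d, c→b) are
attempted `n_rewires` times per sample, rejecting self-edges and
duplicates; signs travel with the source edge. Because a layer's sources
and targets share node classes, swaps preserve class validity and every
node's per-layer in/out degree exactly. Layers with fewer than two edges
are left intact with a warning. Counts over `n_samples` rewired networks
give the null mean/sd, and z = (observed − mean)/sd is reported where
sd > 0. Loop dynamics (bistability, oscillation) are annotated as labels
only; no kinetic simulation is attempted.

## Enrichment

`hypergeom_upper(k, K, n, N)` is the one-sided over-representation tail
P(X ≥ k) for X ~ Hypergeometric(N, K, n) (p = 1 at k = 0; depletion is out
of scope). BH adjustment is the step-up procedure (via statsmodels),
order-preserving and clipped at 1. Fisher's method combines m p-values as
X² = −2Σln p ~ χ²(2m); inputs are clamped below at 1e−300 with a warning.
Two properties worth noting: a single p-value passes through unchanged,
and combination only strengthens evidence for small p (two copies of
p = 0.3 combine to 0.307 — Fisher can weaken marginal evidence).

The multi-miRNA pathway analysis filters each miRNA's scored targets
(score ≥ 0.8, best 350 kept — the defaults of the web tool it mirrors),
tests each pathway per miRNA, and combines per-pathway evidence across
miRNAs by Fisher's method (default) or by a single test on the pooled
target union. The reported gene count is |pooled union ∩ pathway| (the
union-overlap interpretation; the alternative "annotated pathway size"
reading is not used), and `n_mirnas` counts miRNAs with ≥ 1 filtered
target in the pathway. BH runs across pathways.

GO annotation treats terms as flat gene sets — no DAG propagation of
annotations to ancestor terms (tools built on the GO graph do propagate;
this is a declared divergence that keeps the module database-free). The
default universe is all genes in the loaded collection, overridable, since
no background is otherwise specified.

## PWM scanning

A count matrix plus pseudocount (default 0.01/cell) normalizes to
per-position base frequencies f(i,b). Position information is
I(i) = Σ_b f(i,b)·ln(4·f(i,b)) (natural log; 0 at uniform positions, ln 4
at fixed ones — the normalizer only rescales I and cancels in the score).
The core is the 5 consecutive positions maximizing ΣI, leftmost on ties.
A window scores

    score = (Current − Min) / (Max − Min),  Current = Σ I(i)·f(i, b_i),

with Max/Min substituting each position's best/worst base; score = 1 when
Max = Min. Core similarity (css) applies this to the core positions as a
cheap pre-filter; matrix similarity (mss) uses the full length and is only
computed when css passes. Both strands are scanned (the window's reverse
complement is scored for the − strand) and − hits report the + strand
start; coordinates are 0-based half-open. Windows containing non-ACGT
symbols are skipped and counted; sequences shorter than the matrix are
skipped with a warning. Default cutoffs css = 0.75 / mss = 0.85 are fixed
conservative values: matrix-specific minFP/minFN profiles belong to the
reference tool's unpublished calibration and are deliberately not guessed
— cutoffs are explicit configuration. Note that the core of an even-length
palindromic matrix is off-center, so strand symmetry holds for mss but not
css.

## Synthetic data: what it emulates, what it does not

Every generator is a pure function of parameters + seed (bit-identical
reruns) and returns the planted ground truth so each stage's recovery can
be scored without re-derivation.

- `gen_regulatory_network` defaults to the curated study network's
  composition — 44 TFs, 37 miRNAs, 36 target genes, a small host layer —
  with layer edge probabilities (0.06 / 0.03 / 0.3-per-miRNA) chosen to
  land near its ~200-edge scale. Planted motifs are inserted with fixed
  signs (feedback: repression/repression; feedforward:
  activation/repression/activation) after background sampling, overwriting
  colliding background edges. Expression states are uniform up/down —
  realistic fold-change magnitudes and correlation structure are *not*
  simulated.
- `gen_ppi_planted` is an Erdős–Rényi background (default G(100, 0.05))
  with dense modules wired at a target internal density and attached by
  one bridge edge each. Real PPI degree distributions are heavy-tailed;
  the ER background is deliberately simple, so the power-law fit is only
  exercised for its numerics here, and a good fit on real data is not
  implied by these tests.
- `gen_annotations` draws random flat terms (default 50 terms of 50–300
  genes over a 2000-gene universe). The planted term is the designed
  treatment and is held at the top of the size range — a well-powered
  positive control; the query is composed so each slot is `planted_fold`
  times as likely to hold a planted member as a background gene
  (`planted_fold=1` reduces to a uniform draw). Real annotation overlap
  structure (nested GO terms, shared pathways) is not modeled.
- `gen_promoters` plants consensus (or frequency-sampled) sites at
  recorded non-overlapping offsets and strands in i.i.d. uniform 1000-nt
  windows. Real promoters have composition bias and repeats; background
  hit rates on real sequence will be higher.

Consequently, passing tests demonstrate algorithmic correctness and
calibration under clean conditions, not performance on real curated
networks.

### Packaged fixtures

The curated differentially-expressed miRNA table ships verbatim as printed
in its source: 35 records (21 up, 14 down), including a duplicated
hsa-miR-30d-5p row, RNA-alphabet sequences, `<0.001` p-values kept as
text, and negative log-scale fold values for four down-regulated miRNAs
(because of those negatives the values stay in the attribute table; the
network nodes carry expression state only). The duplicate collapses to a
single network node. The narrated loop network encodes exactly the
described regulatory relationships: six miRNAs targeting NFKB1, four
NFKB1→miRNA regulations (repression of miR-21-5p, activation otherwise),
the STAT3/STAT5/E2F1/REL/ESR1 regulations, the miR-21-5p and miR-17-5p
target sets, and the direct ESR1→NFKB1 activation that closes the
ESR1/miR-21-5p/NFKB1 incoherent feedforward loop. Its feedback census is
five loops — three centred on NFKB1, plus STAT3/miR-21-5p and
E2F1/miR-17-5p — with NFKB1/miR-21-5p the sole double-negative switch.

## Numerical and design notes

- p-values are floored at 1e−300 before logs; hypergeometric tails are
  clipped into (0, 1].
- Discrete-test calibration: exact p-values are uniform only at their
  attained values, so the null-calibration test evaluates the ECDF on the
  attained support per term; a naive KS distance against continuous U(0,1)
  is bounded below by the largest p-value atom and is not a meaningful
  criterion for discrete tests.
- All stochastic components (generators, rewiring null) take explicit
  seeds; MCODE and the motif census are deterministic with lexicographic
  tie-breaks.
- Problem sizes in the test suite and analysis scripts (e.g. 200 oracle
  graphs of ≤ 8 nodes, 100 brute-force motif networks of ≤ 30 nodes, 1000
  null queries, 100 enrichment replicates) are chosen so each check
  completes in seconds while keeping Monte-Carlo error well inside the
  asserted margins.
- Known limitations: no gene-symbol normalization; flat gene sets (no GO
  DAG); no statistical test of scale-freeness; no kinetic loop modeling;
  PWM cutoff profiles are user-supplied, not matrix-calibrated.
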