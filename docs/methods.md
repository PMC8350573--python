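# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of the `prionome` package. It states how results
are computed; all quantitative claims about behavior are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## Compositional PrLD scoring

Prion-like domains are detected with a sliding-window log-likelihood
model rather than a full HMM parse. Each canonical residue *a* scores
`llr(a) = log2(f(a)/b(a))` bits, with foreground *f* a packaged
composition modelled on canonical Q/N-rich yeast prion-forming domains
(N+Q ≈ 46%, S/G/Y enriched, hydrophobic and charged residues depleted)
and background *b* a blend of a species table and a default table:
`b = (α/100)·b_species + (1−α/100)·b_default`, α = 50 by default.
The species default is an *Arabidopsis thaliana* whole-proteome
composition; the default background is a broad cross-kingdom proteome
composition. All three tables are overridable (two-column TSV), and
both blend limits behave exactly (α = 100 → species only, α = 0 →
default only).

- **Core score**: maximum window sum over exactly L_core = 60 residues,
  leftmost window on ties. Proteins shorter than L_core are unscorable
  and skipped (not an error). The calling threshold is core score
  ≥ 25 bits, configurable.
- **Ambiguity codes** (B, Z, J, X, U, O, `*`) score 0 bits and are
  excluded from all frequency tables.
- **Domain boundaries**: the core window is extended independently left
  and right to the offset maximising the cumulative extension score,
  only when that maximum is strictly positive; ties resolve to the
  shorter extension. This equals exhaustive search over all segments
  containing the core, because the two sides are additive.

**Numerical determinism.** LLR values are quantised to multiples of
2⁻²⁰ bits (≈ 10⁻⁶, far below compositional signal). Quantised values
and their partial sums over realistic protein lengths are exactly
representable in double precision, so cumulative-sum window scoring,
brute-force per-window summation, and any other summation order give
bit-identical scores. Tests therefore assert exact equality against an
independent enumeration oracle.

Scoring windows of exactly L_core means appending zero-scoring residues
can only add candidate windows; the score is monotonically
non-decreasing under such padding and unchanged for proteins whose best
window dominates every partial suffix (the planted-domain case).

## Prionome summaries

Density is the exact quotient PrLP count / proteome size (reported to
4 decimals). Functional categories are assigned by an ordered,
case-insensitive keyword rule list (first match wins; no match →
"unclassified"); the packaged ten-category rule set (Ts/RTR first, then
RNA-binding, DNA-binding/TF, transport, flowering/development,
signaling, chromatin, stress, metabolism, protein homeostasis) is
illustrative and fully configurable, since no authoritative keyword
scheme exists for these categories. Summaries are produced at protein
or gene level; gene level collapses isoforms by gene id keeping the
highest-scoring one. Percentages are kept exact internally and rounded
to the nearest integer only for display.

## Expression preprocessing

- Ratio of expression potential:
  `(mean − background)/(potential − background + ε)` with ε = 1 guarding
  the degenerate potential ≈ background case.
- Min–max scaling per gene; a constant profile maps to all zeros (the
  quotient is undefined there and zero is the conservative choice).
  Pearson/Spearman statistics are invariant under this per-row affine
  map, so scaling never changes edge calls; it is applied for parity
  with the upstream protocol.
- log2 fold change uses pseudocount 1 in both numerator and
  denominator so zero counts are defined.
- Homolog filtering keeps alignment rows with e-value < 1e-5, query
  coverage > 50% and identity > 35% (all strict, per the "less
  than"/"more than" phrasing), with coverage defined as
  100·alignment_length/query_length (query-based; the alternative
  subject-based definition is not used). Per query the minimal-e-value
  row wins; ties fall back to bit score, then subject id.

## Co-expression network

Pearson r comes from the standard product-moment formula; Spearman r is
Pearson on average ranks. Both p-values use the two-sided
t-transformation `t = r·sqrt((n−2)/(1−r²))` with n−2 degrees of
freedom — appropriate at the 48-sample scale of diurnal series and
exactly what the tests' plain-sum oracle recomputes. |r| = 1 maps to
p = 0. Zero-variance genes have no defined correlation; their pairs are
excluded and logged.

The default edge call is conservative: both methods must pass |r| ≥ 0.8
and p < 0.01 with agreeing signs ("AND"); an "OR" mode accepts either
method alone and drops sign conflicts. Raw p-values are used (the
protocol's stated filter); a Benjamini–Hochberg option was considered
and left out of the default path to keep calls reproducible against the
stated thresholds. Correlogram ordering sorts genes by loading on the
first eigenvector of the Pearson correlation matrix, orientation fixed
so the first input gene has non-negative loading. Cluster detection
restricts to genes with at least one called edge, applies average
linkage on distance 1 − r, cuts at k = 2, and flags antagonism when
more than half of inter-cluster called edges are negative.

## Promoters and binding evidence

Promoters are strand-aware windows of upstream = 1,500 plus
downstream = 200 bases around the TSS; the TSS base itself is counted
in the downstream segment (the upstream/downstream wording is ambiguous
about that base; this convention is fixed here and configurable only
via the window sizes). The TSS is the 5′ end of the longest annotated
mRNA, falling back to the gene feature; internal coordinates are
0-based half-open, converted from 1-based GFF3 at the boundary.
Minus-strand sequences are reverse-complemented so all promoters read
5′→3′ relative to their gene; windows clipped at contig edges are
flagged truncated. PWMs are plain count matrices converted to log-odds
against a uniform background with pseudocount 0.25; scans check both
orientations and skip windows containing N. The binding filter keeps a
TF-source edge only when (tf, target) evidence exists, flags kept edges,
and passes non-TF edges untouched — only TF-binding claims are
filterable by promoter evidence.

## GRN assembly and MCODE

Edges are undirected (co-expression is symmetric); sign, layer and the
evidence flag are edge attributes, roles are node attributes exported
as a sidecar TSV since SIF carries none. Layers are prionome-anchored:
layer 1 = PrLP–PrLP, layer 2 = PrLP–TF, layer 3 = stress/memory genes
whose partner is a PrLP or a TF/Ts-RTR already connected through layers
1–2. Duplicate pairs collapse to the lowest layer; with no PrLPs the
network is empty by construction. Hubs are the top 5% of nodes by
degree (boundary ties included) — an explicit convention, configurable.

MCODE is implemented from scratch with the canonical defaults (degree
cutoff 2, vertex weight percentage 0.2, haircut on, fluff off).
Vertex weight is k · density of the highest k-core of the open
neighborhood. Growth from the highest-weight unvisited seed admits a
neighbor when its weight is ≥ seed_weight·(1 − vwp) **and** it is
adjacent to at least half of the current members. The second condition
is this package's design choice: weight thresholds alone cannot stop a
complex from leaking across a sparse bridge (in a barbell of two K5
cliques every vertex has identical weight, so pure threshold growth
would merge both cliques), and a proportional adjacency requirement
blocks such leakage at every cluster size, in the same spirit as the
2-core haircut applied afterwards. Haircut trims each cluster to its
2-core; clusters are ranked by density × size with lexicographic
tie-breaks throughout, so runs are fully deterministic. Signs are
ignored during clustering and retained on output. With the seed-relative
weight threshold, module members whose weight falls more than vwp below
the seed's cannot be included by any growth rule; on noisy dense
modules this bounds recovery slightly below perfect, which the
acceptance script reports as measured.

## Synthetic data

Generators are pure functions of (configuration, seed) via numpy's
`default_rng`; identical seeds give byte-identical files, and each
generator emits a ground-truth table validated for consistency.

- **Proteomes**: background residues drawn from the Arabidopsis table;
  planted proteins receive an 80-residue segment drawn from the
  prion-domain table at a random interior offset (80 > L_core = 60
  leaves margin for window placement). Default study conditions:
  10% planted, lengths 120–400 aa.
- **Diurnal matrices**: 48 samples at 0.5 h spacing over a 24 h period.
  Module genes are `baseline + A·sin(2πt/24 + φ) + N(0, σ)` with
  baseline 10 and amplitude 3; noise genes are independent
  N(baseline, 1). For sinusoids the expected intra-module correlation
  is `s/(s+σ²)` with signal variance `s = A²/2`, and the cross-module
  correlation scales by cos(Δφ), so target correlations (0.95 within,
  −0.9 across, matching the two ~15-gene antagonistic clusters the
  pipeline is meant to resolve) determine σ and Δφ in closed form;
  an unattainable combination (|cross| > intra) is rejected.
- **Genomes**: genes alternate strands at 4.2 kb spacing so neighboring
  1,700 bp promoter windows are genomically disjoint and a planted
  motif is attributable to exactly one promoter; the motif consensus
  (default a 10-mer, long enough that chance exact matches are rare)
  is inserted at a random offset of the promoter-oriented window,
  reverse-complemented on minus strands.
- **Role tables**: seeded draws of TF/Ts-RTR/stress/memory gene sets,
  by count or fraction, optionally disjoint.
- **Module graphs** (for clustering): 5 planted modules of 8 nodes with
  within-module edge probability 0.9, plus 40 noise nodes and 0.05
  background edge probability everywhere else.

What the generators do *not* emulate: count noise and
transcript-length effects of real TPM data, isoform structure, codon
usage, linkage between promoters and expression, or realistic motif
degeneracy. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not performance on real
proteomes or transcriptomes, whose annotation quality and correlation
structure are far less clean.

## Problem sizes

The default validation sizes — 500-protein proteomes over 10 seeds,
40-gene × 48-sample matrices over 50 seeds, 30-gene genomes, 80-node
module graphs over 50 seeds, a 120-gene end-to-end bundle — were chosen
as the smallest scales at which the planted effects are statistically
unambiguous, keeping the full suite and the acceptance script fast on a
single CPU.

## Known limitations

- The scanner is compositional only; it does not model the ordering of
  residues within a window, per-residue disorder, or PAPA/pWALTZ-style
  aggregation propensity, and an HMM parse of domain architecture is
  out of scope by design.
- Functional categories depend entirely on annotation text quality.
- The binding filter treats evidence as binary; affinity and site
  multiplicity are ignored.
- MCODE results on real networks can differ across published
  implementations because tie-breaking and post-processing details
  vary; this implementation is deterministic and documents its rules.
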