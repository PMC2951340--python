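# Methods

## The model

`neighborscan` detects *functional neighborhoods*: chromosomal regions in
which genes annotated with the same functional term (typically a Gene
Ontology biological-process term) are significantly over-represented. The
scan and the downstream characterizations are organized as independent
stages over shared data types.

### Sliding-window enrichment scan

Each chromosome is tiled with windows of fixed physical length `W`,
advancing in steps of `W/2`, so every interior gene lies in exactly two
windows. `W` is chosen per species so that a window holds on average
~50 genes: `W = round(total_extent / n_genes * 50)`, where the extent is
the per-chromosome maximum gene end, summed. Genes are assigned to windows
by midpoint, `start <= (gene_start + gene_end)/2 < end` — a single
unambiguous rule that never double-counts a gene within one window. A
trailing truncated window is kept only when it contains a gene midpoint,
so telomeric genes are never dropped silently. A rank-based alternative
(exactly *k* consecutive genes per window) is available for gene-density-
robust scans.

For every (window, term) pair a 2×2 contingency table is built over the
*annotated universe* — genes carrying at least one term; unannotated genes
are excluded by default, the standard enrichment convention (`universe="all"`
switches this). The table crosses window membership with term membership
and is tested with a one-sided Fisher exact test for over-representation
(`P(A >= a)` under the hypergeometric with fixed margins). Terms with fewer
than `min_term_genes = 5` genes genome-wide are untestable and skipped.
One-sidedness is a deliberate choice: under-representation cannot support a
neighborhood call; a two-sided flag exists.

All raw p-values in a run — across every window, term and species — enter
one Benjamini–Hochberg batch (`fdr_correct`), and tests with `q <= alpha`
(default `alpha = 0.05`, the conventional threshold) are significant.
Per-species correction is available behind the same function by batching
per species. Overlapping or abutting significant windows of the same term
on the same chromosome are merged into one neighborhood; `--merge-gap`
optionally bridges small gaps. A neighborhood records its *members* (genes
in the span annotated with the term) separately from *all genes in the
span*; gene density (genes/Mbp) and mean GC use all genes, while the
percentage of a species' genes living in neighborhoods uses the union of
members over the annotated universe.

### Coexpression

For each term with neighborhoods, pairwise Pearson correlations among
member genes are computed *within one neighborhood at a time* — pairs never
cross neighborhoods, since the hypothesis is local coexpression — and
compared against correlations among same-term genes lying in no
neighborhood of that term, with a two-sided two-sample Kolmogorov–Smirnov
test (asymptotic p; pair counts are large). Correlations use
pairwise-complete samples; genes with fewer than 3 complete values and
zero-variance pairs are dropped with a warning. The headline species-level
statistic pools pair correlations across terms into a single KS comparison
(`mode="pooled"`); per-term results are also emitted. How the original
species-level figure was aggregated is not specified anywhere we could
follow, so pooling — the simplest reading — is the default and both views
are always available.

### Duplication content

Three probes of the "neighborhoods are just duplications" hypothesis:

* **Segmental duplications.** SDs fully inside the (merged) neighborhood
  territory count as `k_in`, fully outside as `k_out`; boundary-straddling
  SDs are ambiguous and removed. One-sided binomial test of
  `k_in ~ Binomial(k_in + k_out, L_in / L_total)` with `L_total` the
  species' golden-path length.
* **Similarity-hit profiles.** For a window, each gene scores one self-hit
  plus the number of other window genes with pairwise protein identity at
  or above a threshold (95% and 98% are the conventional cutoffs); the
  window's profile is the mean hits per gene, so a single-copy region
  scores 1.0 and an N-fold amplified family scores N. "Normalization" of
  the raw hit count is taken as this per-gene mean — the one choice that
  reproduces both anchors. Neighborhood windows are compared with
  background windows by a two-sided Welch t-test. The pipeline consumes a
  precomputed similarity table; running the aligner is out of scope, which
  keeps the artifact self-contained and deterministic.
* **Paralog fraction.** Share of region genes with at least one paralog
  partner anywhere in the genome.

### Repeat enrichment

Repeat (e.g. SINE) enrichment in neighborhoods is tested by a seeded
permutation: the statistic is the number of repeat midpoints inside the
regions; the null re-places the regions uniformly on their own
chromosomes, preserving lengths and forbidding overlap (the spacings
construction: drop sorted uniform cut points into the collapsed free
space), with `p = (1 + #{perm >= obs}) / (1 + n_perm)`. This permutation
design is this package's own reconstruction — the original test was not
specified — and is labeled as such in the module docstring.

### Synteny breaks

Neighborhoods of two species share a function when the same term labels a
neighborhood in both; sharing is deliberately term-level, *not* defined
through orthologous genes, because the question under study is precisely
whether shared-function neighborhoods are built from orthologs.
Breakpoints are located by interval midpoint; a `min_break_bp` filter
(e.g. 25 kb) supports rearrangement sets with a size floor. Densities
(breaks/Mbp) are computed on merged region lengths, making them invariant
to region order and duplication. The shared-vs-rest contrast uses a
Pearson chi-square (df = 1, no continuity correction) on length-
proportional expected counts. Within the shared territory, neighborhoods
are split at the median orthology fraction (share of members with an
ortholog in the reference species); ties go to the LOW group, and an
all-tied split is reported as degenerate rather than silently emptied.
Expected counts can be used exactly (`rounding="none"`) or rounded to
whole events first (`rounding="integer"`); the genome-wide comparison
conventionally uses exact expecteds and the within-territory comparison
integer ones, and the CLI prints both.

### Phylogenetic placement

A term's presence pattern (presence = at least one called neighborhood in
that species) is placed on the species tree under Dollo parsimony: one
gain at the MRCA of the present leaves, losses on the maximal subtrees
below the gain containing no present leaf. Under the single-gain
constraint this is the unique minimum-event reconstruction; the test suite
proves it against exhaustive enumeration of every ancestral-state
assignment on all presence patterns of trees up to 8 leaves. Dollo was
chosen over free multi-gain parsimony because a function's origin on the
tree is the quantity of interest; unrestricted gains would admit cheaper
multi-origin solutions for some patterns and make "where did this
neighborhood function arise" ill-posed. Absence in poorly annotated
species may be coded `'?'`, removing those leaves from both the MRCA and
the loss count; the default treats absence as real.

## Synthetic data

`synthetic_data.simulate_genome` emits a complete input bundle plus a
truth table. Defaults are the benchmark conditions used throughout the
tests, chosen once:

| parameter | default | why |
|---|---|---|
| genome | 4 chromosomes × 25 Mb | large enough for ~200 windows at the 50-gene target |
| genes | 5000, fixed 1 kb, on a 1-kb grid | grid sampling gives uniform, non-overlapping placement |
| terms | 50 at background 0.02 | ~100 genes/term, comfortably testable |
| planted clusters | 3 × 50 genes, within-fraction 0.6 | a strong but not degenerate positional signal |
| expression | 30 samples, ρ_in = 0.8, ρ_out = 0 | one-factor model: `√ρ·F + √(1−ρ)·ε`, private factor per cluster |
| breakpoints | λ_out = 0.093/Mbp, rate ratio 1.68 | matches the density contrast scale of real shared neighborhoods |
| SDs / SINEs | 200 × 20 kb uniform; 5/Mbp Poisson | null placement, so enrichment tests calibrate |
| orthology | 0.8 in designated clusters vs 0.2 | produces a clean high/low split |

One master seed fans out to named substreams (CRC-keyed `SeedSequence`),
so adding a component never perturbs another's draws, and the same seed
reproduces a bundle byte-for-byte.

What the generator does *not* emulate: real GO term hierarchies and
annotation bias, gene length and density heterogeneity, chromosome-scale
GC gradients, clustered (rather than Poisson) repeat placement, and
tandem-duplicated gene families with positionally adjacent members.
Passing tests therefore validate the statistical machinery under its
stated assumptions, not the biological conclusions on real genomes.

## Numerical choices

* Fisher tails via the hypergeometric survival function, clipped into
  `(0, 1]`; the suite checks 500 random tables against an exact
  big-integer oracle at 1e-10 relative error.
* BH via the standard step-up; checked against the direct formula,
  order-invariance and monotonicity by property tests.
* KS uses the asymptotic two-sided p (pair counts are large); the D
  statistic is checked against an exhaustive ECDF sweep.
* Chi-square without continuity correction, as is standard for df = 1
  contrasts of this size; zero expected counts raise rather than return 0.
* Permutation p-values use the add-one estimator, bounded below by
  `1/(n_perm+1)`; all permutation and simulation code takes explicit
  seeds.
* Degenerate inputs fail loudly (empty universes, all-absent presence
  rows, regions longer than their chromosome) or produce flagged NA
  results where the comparison is undefined (term with no outside genes).

## Problem sizes in the validation suite

The stochastic suites run at: 20 null genomes (5000 genes, 50 terms,
background 0.02) for FDR calibration; 10 planted genomes for recall; 50
seeds for coexpression power and for breakpoint rate-ratio recovery.
These sizes keep the full suite under half a minute while leaving the
binomial slack on each stochastic assertion small.

## Known limitations

* The FatiGO-style scan tests windows against the genome-wide background;
  windows overlap, so neighboring tests are positively dependent. BH is
  robust to this in practice (and empirically conservative here because
  hypergeometric p-values are discrete), but FDR control is nominal, not
  exact.
* Orthology fractions treat any ortholog pair as evidence, with no
  one-to-one filtering.
* The coexpression stage takes the expression matrix as given (no log
  transform or normalization); feed it preprocessed values.
* Window spans, not gene extents, define neighborhood boundaries, so a
  neighborhood can begin upstream of its first member gene.
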