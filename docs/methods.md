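# Methods

`homoeoexpress` analyses homoeolog expression in allotetraploid
transcriptomes — genomes carrying two parental subgenomes (A and B) whose
corresponding gene copies (homoeologs) can be expressed asymmetrically.
The pipeline takes pairwise protein-alignment hit tables, a reference
A↔B anchor map and TPM expression matrices, and produces per-species
homoeolog pairs, subgenome-dominance classifications and tests,
trait-associated co-expression modules, and enrichment of the resulting
gene sets. A synthetic-data generator with planted truth backs every stage
with recoverable ground truth.

## Tiered ortholog assignment

Queries (species transcripts) are matched to reference genes through an
ordered list of (identity, coverage) thresholds, strictest first; the
default is (0.95, 0.80), (0.90, 0.75), (0.85, 0.70), (0.80, 0.65), applied
as strict inequalities. A query is assigned at the strictest tier that
leaves at least one hit, and the winning hit is the maximum under
(identity desc, coverage desc, bit score desc, subject id asc) — a total
order, so assignment is independent of input row order. Because the tiers
are nested, a strict-tier assignment can never be overwritten when the
relaxed tiers are merged in. Design choices the interface exposes rather
than hides:

- **Coverage** is alignment length over *query* length, capped at 1
  (gapped alignments can exceed the query span). The query side matches
  the direction of the search (species peptides against the reference
  panel).
- **E-value pre-filter** at 1e−3 during parsing, mirroring the alignment
  significance cutoff; configurable.
- **HSP handling**: one row per query–subject pair (best bit score); no
  HSP stitching.
- **Reference-side uniqueness**: when several queries claim one reference
  gene, the best claimant (same ordering, query id as final tie-break)
  keeps it and the others are demoted to 1:0. Demotion rather than
  reassignment keeps the procedure single-pass and deterministic.

## Homoeolog pairs

The Venn partition of assigned reference genes across species is computed
at the reference-gene level; the all-species region is the shared (1:1:1)
ortholog set. Per species, one homoeolog pair is emitted for each A↔B
anchor whose both members carry a 1:1 transcript; an optional restriction
limits pairing to anchors inside the shared set, since published pair
counts can be read either way.

## Dominance classification and the equal-split test

Replicate TPM values are aggregated by arithmetic mean per copy (the
aggregation method is otherwise unconstrained by the upstream protocol),
and a pair is dominant for the copy expressed at least `fold` times higher
(non-strict ≥, reading "at least"; default fold 2 with a 1.5 sensitivity
setting). A pair with one silent copy is dominant for the expressed copy
(the ratio is infinite); a pair with both copies silent is excluded from
counts and tests.

Subgenome bias is tested with a Pearson goodness-of-fit of the A- and
B-dominant counts against a 50:50 expectation: E = (O_A + O_B)/2,
χ² = Σ(O−E)²/E = (O_A − O_B)²/(O_A + O_B), df = 1, **no continuity
correction**, p = upper tail of χ²(1). The upper tail already captures
deviation in either direction of the two-category split, which is what
"two-sided" means for this statistic. The uncorrected form reproduces all
three published brain-tissue rows to four decimal places
((172, 255) → 16.1335, (155, 190) → 3.5507, (159, 165) → 0.1111); the
Yates-corrected form does not, which fixes the decision.

## Co-expression modules

Expression is filtered to genes with TPM > 0 in **all** retained samples
(the strict reading of a non-zero filter), log2(TPM + 1) transformed, and
correlated (Pearson). The unsigned adjacency is |cor|^β; β defaults to 6
or is chosen as the smallest candidate in 1..20 whose connectivity
distribution fits a scale-free law with R² ≥ 0.8 (log-binned frequency
regression; if none qualifies the best-fitting candidate is returned with
a warning). Topological overlap is

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,  k_i = Σ_{u≠i} a_iu,

computed vectorized and verified against the literal triple loop.

Modules come from average-linkage clustering on 1 − TOM with a **static
height cut**, a deliberate simplification of the dynamic tree cut used by
the reference R implementation (the dynamic algorithm's complexity is out
of proportion to what the downstream statistics need; the cut height is a
parameter). The default height is 0.90: on the planted regime
(within-module correlation 0.8, β = 6) module-internal merges complete
near 0.8 on the 1−TOM scale while module↔background merges occur above
0.93, so 0.90 separates them with margin on both sides. Note this height
lives on the 1−TOM dendrogram; it is unrelated to the 0.25 *eigengene
merge* height familiar from the R package. Clusters smaller than
`min_module_size` (default 20) are left unassigned (label 0).

Each module's eigengene is the first principal component of its
standardized expression, scaled to unit variance and sign-aligned with the
module's mean profile. Module–trait association is the Pearson r of the
eigengene against a per-sample trait (binary 0 = surface, 1 = cave for the
two-group design), with a two-sided t-based p-value; a module is selected
when |r| ≥ 0.70 and p < 0.05. Gene significance GS = |cor(gene, trait)|,
module membership MM = cor(gene, own eigengene); core genes of selected
modules satisfy GS > 0.40 and MM > 0.50 (strict), split into up/down by
the sign of the module's trait correlation.

## Divergence and enrichment

A homoeolog anchor is DE-up when either of its transcripts is in the
up-regulated core set (likewise down; membership in both sets is an
error) — the lifting rule from transcripts to anchors is a package
decision. DE direction crossed with dominance class gives the
{up, down} × {SubA, SubB} table; balanced/excluded DE anchors are counted
separately.

Enrichment is annotation-agnostic over-representation: for a term with K
of N universe genes and a query set of n genes overlapping k,
p = P[X ≥ k], X ~ Hypergeometric(N, K, n), with Benjamini–Hochberg
adjustment across terms with overlap ≥ 1 (zero-overlap terms report
p = q = 1 outside the BH family; a flag includes them). Results are sorted
by p with a configurable top-N slice (default 15).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the biology that produces it:

- **Reference panel**: `n_anchor_pairs` anchors, each one A and one B gene
  with amino-acid lengths uniform in 100–1000.
- **Hit tables**: one query per reference gene; the true hit draws
  identity and coverage uniformly inside its tier's half-open band (tier k
  band = [tier-k threshold, tier-(k−1) threshold), tier 1 capped at 1.0,
  with a 1e−4 margin so strict thresholds and 4-decimal percent formatting
  cannot flip tier membership). No-hit queries emit no rows. With
  probability `decoy_hit_prob` a query gains an extra hit with strictly
  lower identity (same subgenome as the true subject half the time), so
  best-hit resolution is exercised without corrupting the truth.
- **Expression**: each anchor pair shares a baseline log2 TPM drawn
  log-normal (log2 mean 4, sd 2, spanning a typical bulk TPM dynamic
  range). Pair classes follow `dominance_mix`; dominant pairs split a
  planted |log2 ratio| ~ Uniform(log2(fold) + 0.5, log2(fold) + 2.5)
  symmetrically between copies — unambiguous at the default threshold,
  degradable by noise — and balanced pairs draw Uniform(−0.5, 0.5).
  Replicates multiply by 2^N(0, `replicate_noise_sd`) (default sd 0.25).
- **Modules**: module genes share a per-sample latent factor; the driven
  module additionally shifts one group's log2 mean by
  `module_trait_effect`. The factor coefficient is chosen so the
  **marginal** within-module correlation (trait-shift variance plus factor
  variance over total variance) meets `module_cor` (default 0.8); when the
  trait shift alone exceeds the target the factor is floored at zero, so a
  strongly driven module is simply more coherent than requested. Defaults:
  three modules of 40/30/30 genes, effects (2.0, 0, 0) log2 units, two
  groups × three replicates.

What the generator does **not** emulate: sequence evolution (identities
are drawn, not aligned), read-level sampling noise and TPM
compositionality, library-size effects, correlated decoys, overlapping
modules, or any calibration to the real species' expression distributions
(the source study does not report them). Passing recovery tests therefore
demonstrates the pipeline's correctness under its own model assumptions,
not performance on real transcriptomes.

With `replicate_noise_sd = 0` the generator is exactly identifiable for
ortholog assignment and dominance (every class and direction recovered
verbatim); the co-expression stage is intentionally excluded from that
claim because the latent factor scales with the noise sd, so zero noise
makes module genes constant within groups and correlation degenerate.

## Numerical and testing notes

- All randomness flows through `numpy.random.default_rng` seeded from
  `(config.seed, CRC32(stage/species label))`; identical configs give
  byte-identical written outputs.
- TOM bounds, symmetry and the closed-form χ² identity are property-tested
  (the χ² sweep over 10⁴ random count pairs at 1e−9, TOM against the
  triple loop at 1e−10 on random matrices).
- Simulation-based tests run at deliberately modest sizes — 10,000 queries
  for tier recovery, 100 seeds × 400 pairs for dominance, 20 seeds × 200
  genes × 6 samples for module recovery — which keeps the whole suite
  under a minute while leaving the statistical margins (binomial coverage,
  recovery thresholds) intact.
- Degenerate inputs are errors, not silent fixes: constant genes in the
  network stage, constant traits, both-zero chi-squared counts, gene sets
  outside the universe, misordered tier thresholds.

## Known limitations

- The static dendrogram cut under-merges relative to dynamic tree cut on
  modules with very heterogeneous density; its height is exposed and the
  default is tuned to the generator's regime, so real data may need a
  different value (the reference implementation's static-cut default,
  0.99, is appropriate when background genes are absent).
- With six samples, Pearson correlations are heavy-tailed under the null;
  chance background correlations can attach stray genes to modules. The
  GS/MM core filter is what keeps downstream sets clean.
- The chi-squared test treats pairs as independent; linked homoeologs or
  shared regulatory programs violate that assumption in real data.
- The enrichment stage tests over-representation only; no ranked (GSEA)
  mode, no term hierarchy.
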