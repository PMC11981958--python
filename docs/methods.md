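# Methods

This note documents the models implemented in `ednariver`, the defaults and
their rationale, what the synthetic generator does and does not emulate, and
the numerical choices that affect results.

## Curation model

Reads arrive dereplicated per (site, replicate). Curation is a fixed cascade:

1. **d = 1 clustering.** Single-linkage agglomeration of sequences at edit
   distance ≤ 1 (Hamming for equal lengths, a single indel for lengths
   differing by one), seeded from the most abundant sequence. The cluster
   representative is the most abundant member (ties broken by lexicographic
   id) and counts are summed, so the grand total is conserved. This removes
   point-error daughters one substitution away from a genuine variant.
2. **Deletion filter**, applied once, in one pass: total reads ≥ `min_reads`
   (10), 160 ≤ length ≤ 200 bp, fish only, and relative abundance ≥ `min_freq`
   (0.001). The frequency denominator is the pre-filter grand total; a global
   (not per-sample) denominator was chosen because the cascade operates on the
   pooled table. The fish gate is an input list of orders, not a live
   registry lookup, so runs are hermetic.
3. **LULU-style post-clustering.** Candidate daughters are visited in
   increasing total abundance. A daughter merges into the most abundant
   qualifying parent satisfying all of: pairwise identity ≥ `lulu_min_match`
   (0.84), fraction of the daughter's occupied sites also occupied by the
   parent ≥ `lulu_cooccur` (0.95), and parent/daughter site-read ratio ≥
   `lulu_min_ratio` (1) in **every** shared site. These defaults are the
   published defaults of the algorithm this step reimplements. Merged reads
   are added to the parent; the procedure is deterministic under
   abundance-then-lexicographic tie-breaking.
4. **Replicate rule.** An ASV is present at a site iff detected in ≥ 2 of the
   site's replicates. A site with a single replicate is an error — the rule
   is undefined there.

**Identity.** Pairwise identity is matched columns / alignment columns of a
global alignment. Equal-length sequences are compared column-by-column: with
any positive gap penalty an optimal global alignment of equal-length
sequences never trades a substitution for two gaps, so the Hamming fraction
*is* the alignment identity, and it is orders of magnitude faster. Pairs of
different length go through an affine-gap global aligner (match +1, mismatch
−1, open −2.5, extend −0.5), with a unit-cost edit-distance short-circuit for
clearly distant pairs (< 50% identity), where band membership no longer
depends on alignment detail.

## Taxonomy

In-silico PCR scans both strands for a forward-primer site followed by a
reverse-complemented reverse-primer site, IUPAC-aware, with a shared mismatch
budget (default 3). The inter-primer segment is emitted when its length lies
in [150, 220] bp; per reference only the best (fewest mismatches, then
longest) amplicon is kept.

Assignment is two-pass: (1) exact (100%) matches to native-flagged species
win at species rank; (2) otherwise the best global hit is banded — species
≥ 0.98, genus [0.96, 0.98), family [0.90, 0.96), order < 0.90 — with closed
lower bounds (0.98 itself is a species-level hit; the underlying convention
is unstated upstream, so the finer band was chosen). Ties at the acting band
are resolved by the lowest common ancestor of the tied lineages at or above
the band's rank; if even the orders disagree, the ASV is unassigned.

## Biodiversity facets

- **TD** — row sums of the curated incidence table.
- **FD** — nine unitless ratios are formed from eleven raw morphological
  measurements (body length/depth, head depth, caudal peduncle/fin depth, eye
  diameter/height, oral gape position, jaw length, pectoral fin
  length/position). The default catalogue (Bl/Bd, CFd/CPd, Hd/Bd, Ed/Hd,
  Eh/Hd, Jl/Hd, Om/Bd, PFl/Bl, PFp/Bd) covers body elongation, caudal
  propulsion, head/eye/jaw geometry and fin placement; it is configuration,
  not hard-coded, because trait catalogues vary between studies. Ratios are
  unit-free (invariant to image rescaling). Missing ratios are imputed by the
  nearest non-empty taxonomic group mean (genus → family → order → global) —
  a deliberate, simpler replacement for phylogenetic imputation that needs no
  tree. Columns are then centred and scaled and embedded by PCoA on Euclidean
  distances (identical to PCA there); the retained dimensionality k is the
  smallest k reaching 95% cumulative variance, floored at 2 and capped at the
  matrix rank. FD(site) is the convex-hull volume of the site's ASVs in those
  k axes divided by the pool hull, so FD ∈ [0, 1] and the pool scores 1.
  Sites with < k+1 ASVs or a flat point set get FD = 0 with a warning.
- **GD** — nucleotide diversity π within each order having ≥ 2 ASVs present
  at the site (gap-vs-base counts as a difference; gap-vs-gap columns are
  excluded pairwise), averaged without weighting across eligible orders.
  Orders with one ASV carry no pairwise signal and are ignored; a site with
  no eligible order is missing.
- **Chao2** — from incidence over T sites with Q1 uniques and Q2 duplicates:
  S_obs + ((T−1)/T)·Q1²/(2Q2), or the bias-corrected Q1(Q1−1)/2 form when
  Q2 = 0. Coverage is S_obs/Ŝ. Note that coverage is *not* monotone under
  duplicating a sampling unit: extra occurrences can demote duplicates to
  triples, shrinking Q2 and raising the asymptote.

## Spatial structure and GLMs

The Moran correlogram bins pairwise great-circle distances into equal-count
classes (default 8) with binary weights; per class, significance is a
two-sided permutation test (default 999 permutations, add-one rule) of the
distance of Moran's I from its null mean −1/(n−1). Great-circle rather than
along-network distances are used because the autocovariate construction this
feeds is coordinate-based; network distances serve the upstream–downstream
trend analyses instead.

The autocovariate of a response is the inverse-distance-weighted mean of its
neighbours within a radius; the radius is coupled to the correlogram's first
significant class midpoint (falling back to the first class upper bound).
**AutoCor** is the residual of an intercept+slope regression of the response
on its autocovariate — the simplest residualisation consistent with using it
as an independent spatial covariate; isolated sites get autocovariate 0 with
a warning.

Per facet, two Gaussian GLMs are fitted on scaled responses and scaled
elevation: mod0 with elevation + footprint + AutoCor + Type, and mod1 adding
elevation × footprint. BIC is −2·logLik + k·ln(n) with k counting the
intercept and the Gaussian dispersion. The Bayes factor
bf01 = exp(0.5·(BIC₁ − BIC₀)) is > 1 when the BIC evidence favours mod0, so
the verdict is *no interaction* when bf01 ≥ 1 and *interaction supported*
when bf01 < 1; both BICs and bf01 are always reported so users can apply any
other convention. The Gaussian family (rather than Poisson for TD) matches
the scaling of responses before fitting.

The upstream–downstream trend is a penalized cubic B-spline (second-difference
penalty) with the penalty chosen by generalized cross-validation over a log
grid; pointwise 95% bands come from the smoother matrix
(var = σ̂²·diag(HHᵀ)). The Pearson correlation of (distance, facet) is
reported alongside, as the trend's scalar summary.

## PLS path model

Blocks: elevation and footprint are single-indicator composites; water
quality (TP, TN, BOD₅, TOC) and biodiversity (TD, FD, GD) are formative
(Mode B; Mode A selectable). Water quality is expressed as a pressure —
higher scores mean worse water. Indicators are standardized internally;
latent scores have unit variance throughout.

Estimation is Lohmöller's alternating algorithm: outer weights start at 1;
inner weights follow the centroid scheme by default (sign of adjacent score
correlations; factorial and path schemes are implemented); the outer update
is the indicator–proxy covariance (Mode A) or the multivariate regression of
the proxy on the block (Mode B). Iteration stops when the largest
outer-weight change is < 1e-6 (default) or after 300 iterations;
non-convergence flags the result rather than raising. Each composite's sign
is fixed by requiring a non-negative sum of correlations with its own
indicators, which removes the sign indeterminacy deterministically. Path
coefficients are per-equation OLS of each endogenous latent's scores on its
predecessors' scores, so single-indicator models collapse exactly to
standardized path analysis. Effects decompose as direct (edge coefficient)
plus indirect (sum over directed multi-step paths of coefficient products).
Permutation inference permutes the rows of the exogenous block(s) jointly
(default 100 permutations) and uses the add-one rule; row permutation was
chosen over indicator permutation because it preserves the within-block
correlation structure under the null.

## Synthetic generator

The generator reproduces the study conditions: 33 sites in 3 replicates on a
dendritic network (~2/3 mainstem), an elevation span of roughly 330–1400 m
rising upstream, a mid-basin footprint hump, per-site richness mapped into
13–79, FD into [0.049, 0.793], GD up to ~0.09 with the sign opposing the
richness gradient, a 232-variant pool over 11 orders with the two dominant
orders holding ≈ 78% of variants, and the six structural coefficients
(−0.5452 elevation→footprint; 0.4739 / 0.5485 elevation/footprint→water
quality; −0.7056 / −0.1779 / −0.0626 elevation/footprint/water
quality→biodiversity). Endogenous disturbances are scaled so every latent has
unit variance; an implied disturbance variance ≤ 0 raises an error. Facet
maps are affine (rank-preserving), so correlation-based estimands are
untouched; TD is additionally rounded to integers.

Because the covariate stage's humped footprint and the structural equation's
footprint cannot both hold, the bundle generator adopts the structural
footprint (and the structural water-quality latent) for the covariate table,
as an affine non-negative index, keeping every downstream stage coherent
with the facets; `footprint_mode="observed"` retains the hump for analyses
that only need the geographic gradient.

Sequences are evolved per order from a random ancestor with binomial
substitution counts targeting within-order π between 0.03 and 0.09. Two
guarantees make the ground truth recoverable by construction, mirroring
structure real communities have but random draws lack:

- true variants are kept ≥ 3 substitutions apart (so d = 1 clustering can
  never merge two genuine variants), every pool member occupies ≥ 1 site, and
  any variant whose total reads would fall below the global 0.001 frequency
  threshold is rescaled above it;
- a niche-separation pass gives every variant either a private site or a site
  of local dominance relative to any more abundant high-identity order-mate,
  evaluated on daughter-folded counts with conservative margins — otherwise
  a rare genuine variant would be *observationally indistinguishable* from a
  sequencing error and no curation method could keep it.

Planted errors are distance-1 mutants at 3–8% of the parent's reads in half
of the parent's sites and only in the parent's detected replicates. Replicate
noise is Bernoulli thinning with detection probability `p_detect` (default
0.9; recovery tests use 1.0 because the two-replicate rule deliberately
discards single-replicate detections).

**What the generator does not emulate:** chimeras, PCR/sequencing error
beyond single-substitution daughters, tag jumping, abundance-dependent
detection, hydrological transport of eDNA between sites, and spatially
structured order composition — so the *computed* genetic diversity has only a
weak emergent spatial gradient even though the latent GD facet opposes the
richness gradient. Passing tests therefore demonstrate the correctness of
the algorithms under controlled conditions, not field performance.

## Problem sizes and determinism

Default analysis sizes: 33 sites, 232-variant pool, 999 correlogram
permutations, 100 PLS permutations; parameter-recovery checks use 5000 sites,
where each path coefficient is recovered within ±0.05. All randomness flows
through one `numpy.random.Generator` seeded from the run seed; identical
seeds reproduce identical tables byte-for-byte.

## Known limitations

- LULU curation assumes parents strictly out-read daughters in shared sites;
  taxa with strong site-specific abundance reversals are protected, but a
  genuinely rare taxon perfectly nested within a high-identity dominant
  would be merged (by design — it is indistinguishable from an error).
- The AutoCor covariate uses the simplest residualisation (response on its
  own autocovariate); alternatives that residualise against the full
  covariate set would change the GLM estimates.
- FD depends on the retained PCoA dimensionality; sites below k+1 ASVs score
  0 rather than a lower-dimensional volume.
- Mixed (random-effect) models are out of scope; a pooled-vs-grouped residual
  variance likelihood ratio is provided as a lightweight check.
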