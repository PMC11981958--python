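# ednariver

Multi-facet fish biodiversity analysis for montane river networks from eDNA
metabarcoding data.

Environmental DNA surveys of mountain rivers yield amplicon sequence variant
(ASV) tables whose curation, conversion into biodiversity facets, and
regression against landscape gradients each involve method choices that are
rarely packaged together. `ednariver` implements the full chain as a tested
library plus a pipeline:

1. **Curation** — dereplicated per-replicate read counts are clustered by
   single-linkage at one edit (d = 1), passed through a single deletion filter
   (total reads ≥ 10, amplicon length 160–200 bp, fish only, global relative
   abundance ≥ 0.001), cleaned of erroneous "daughter" variants LULU-style
   (identity ≥ 0.84, co-occurrence ≥ 0.95, parent/daughter read ratio ≥ 1 in
   every shared site), and collapsed to presence/absence by a two-of-three
   replicate rule.
2. **Taxonomy** — in-silico PCR against a reference panel (amplicon 150–220 bp,
   ≤ 3 primer mismatches, IUPAC-aware) and identity-banded assignment: exact
   matches to native species first, then species (≥ 98%), genus ([96, 98)%),
   family ([90, 96)%) or order (< 90%), with lowest-common-ancestor resolution
   of ties.
3. **Facets** — per site: taxonomic diversity TD (ASV count); functional
   diversity FD (convex-hull volume of the site's ASVs in the ≥ 95%-variance
   PCoA space of nine unitless morphological ratios, normalised by the pool
   hull so FD ∈ [0, 1]); genetic diversity GD (unweighted mean across orders of
   nucleotide diversity π, the average pairwise proportion of differing
   positions).  Chao2 incidence extrapolation gives the richness asymptote
   S_obs + ((T−1)/T)·Q1²/(2Q2) and sampling coverage.
4. **Spatial models** — Moran correlogram over equal-count great-circle
   distance classes with permutation tests; a distance-weighted autocovariate
   aᵢ = Σ yⱼ/dᵢⱼ / Σ 1/dᵢⱼ within the first significant correlogram distance;
   its regression residuals (AutoCor) enter Gaussian GLMs comparing a direct
   model (facet ~ elevation + footprint + AutoCor + Type) against a synergy
   model adding elevation × footprint, judged by the BIC Bayes factor
   bf01 = exp(0.5·(BIC₁ − BIC₀)).
5. **PLS path model** — a from-scratch PLS-SEM engine (Lohmöller iteration,
   centroid/factorial/path schemes, Mode A/B blocks) for the structure
   elevation → footprint → water quality (TP, TN, BOD₅, TOC) → biodiversity
   (TD, FD, GD), with row-permutation inference and direct/indirect/total
   effect decomposition.
6. **Synthetic basin** — a generator producing a dendritic river network,
   covariate gradients, facets from known structural coefficients, and
   eDNA-style read tables with planted erroneous daughters, so every stage is
   testable against ground truth.

## Worked example

Run the numbered drivers from the repository root (later steps read the
outputs of earlier ones from `results/`):

```bash
python analysis/01_simulate.py    # synthetic 33-site basin → results/sim/
python analysis/02_curate.py     # curation cascade → results/incidence.tsv
python analysis/03_facets.py     # TD/FD/GD + Chao2 → results/facets.tsv
python analysis/04_spatial_glm.py
python analysis/05_plssem.py
```

Representative output (seed 42):

```
after d=1 clustering: 232 ASVs (reads conserved: True)
after filters + LULU: 232 ASVs
curated incidence identical to planted truth: True
richness: mean 45.9, min 15 at T06, max 80 at Y01
Chao2: observed 232 ASVs, asymptote 235.8, coverage 98.39%
facet  bic0  bic1   bf01  interaction_supported
   TD 43.64 46.37 3.9151                  False
   FD 32.66 35.46 4.0415                  False
   GD  1.72  3.59 2.5530                  False
recovery at n = 5000 (estimate vs generating value):
  elevation->biodiversity             -0.7030 vs -0.7056  [ok]
all six paths within ±0.05: True
```

Reading this: the curation cascade removed all 46 planted daughter variants
and reproduced the planted incidence exactly; bf01 > 1 for every facet, so the
BIC evidence favours the direct model (no elevation × footprint interaction,
as simulated); and the PLS engine recovers each generating structural
coefficient within ±0.05 at n = 5000.

The same stages are available as one command:

```bash
ednariver run --workdir out --seed 42       # simulate + all stages
ednariver sem --data indicators.tsv --out-prefix out/sem   # any single stage
```

## Layout

- `src/ednariver/` — the library (io_formats, curation, taxonomy, diversity,
  spatial, glm_models, plssem, synthetic, pipeline, cli)
- `analysis/` — numbered narrative drivers
- `tests/` — unit, property and criterion-level suites
- `docs/methods.md` — models, assumptions, parameter defaults, limitations
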