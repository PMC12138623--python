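# Methods

This note documents the models and procedures implemented in `gutmetab`,
the choices made where several reasonable designs exist, and what the
synthetic-data generator does and does not emulate.

## Multitaxonomy assignment

Each ASV is aligned to every reference 16S sequence with Needleman–Wunsch
scoring (match +1, mismatch −1, gap −2) and free terminal gaps — the
standard semi-global scheme for comparing a partial amplicon to a
full-length reference. Identity is matches / aligned columns, with
terminal-gap columns excluded and internal gap columns counted as
non-matches. With *M* the best identity, references with identity
≥ *M* − (1 − *M*)/4 are retained. The threshold is **inclusive**: a strict
"greater than" rule would retain nothing at *M* = 1, so the best hit is
always kept and ties at *M* across different lineages are all retained.
Retained lineages are merged per rank by deduplicating names, sorting
alphabetically (so labels are canonical and mergeable across samples) and
joining with "/".

Semi-global identity is only meaningful between homologous sequences: for
two unrelated random sequences the optimal free-end-gap alignment is a
short perfect overlap, which yields a high identity over very few columns.
16S references are homologs by construction, so this regime does not arise
in the intended use; the synthetic generator likewise produces reference
families descended from a common ancestor (see below).

Copy-number renormalization divides each taxon's abundance by its mean 16S
rRNA gene copy number at the analysis rank and re-closes columns to
relative abundance. A merged "/" label uses the mean copy number of its
member taxa. A label with no copy number at all falls back to the rank-wide
mean, then the database-wide mean, with a logged warning; renormalization is
applied after aggregation at the target rank.

## Diversity and group testing

Shannon entropy is reported in nats, Simpson as 1 − Σ p². Bray–Curtis
distances feed classical PCoA (double-centering + eigendecomposition);
negative eigenvalues are dropped, not corrected, and their total magnitude
is reported so strongly non-Euclidean inputs are visible.

"Wilcoxon test" between independent culture groups means the rank-sum test;
the signed-rank test is reserved for paired crude/inoculated metabolite
comparisons. Both tests compute exact two-sided p-values by full
enumeration for small samples (rank-sum up to n = 10 per group, signed-rank
up to 14 nonzero pairs), with midranks handling ties inside the
enumeration; larger samples use the tie-corrected normal approximation.
Two-sided p is defined symmetrically, P(|T − E[T]| ≥ |t − E[T]|). The
per-comparison significance threshold reported alongside raw p-values is
Bonferroni 0.05/n_pairs — 0.0083 for five groups, matching the common
"p < 0.008" starring convention in five-condition designs.

## Metabolomics features

The blank filter keeps features whose mean non-blank intensity is at least
3× the mean blank intensity (configurable); blank columns are retained so
the filter is idempotent. Zero intensities are offset by half the smallest
nonzero value in the table before fold changes, bounding log₂FC without
dropping features. Pairing for the signed-rank test follows the replicate
index within condition. PCA operates on log₁₀(area + 1), centered but not
scaled, because peak areas span decades and unit scaling would inflate
noise features.

## Molecular networking

Modified cosine: candidate fragment pairs match within 0.005 Da either
directly or shifted by the precursor mass difference; intensities are
square-root transformed (downweighting base peaks; configurable to none)
and unit-normalized; matching is greedy by descending intensity product
with each peak used at most once. Greedy matching is within 5% of the exact
Hungarian optimum on small spectra (enforced by test); the exact matcher
lives in the test suite only. Edges require cosine ≥ 0.7 and ≥ 4 matched
peaks. One spectrum per feature id is kept (highest total ion current).

Mass-shift annotation compares each networked pair's precursor delta to
moiety masses at Δ, Δ − 1.00783 and Δ + 1.00783 (hydrogen-count ambiguity
of conjugation chemistry), within a ppm tolerance of the moiety mass
(default 10 ppm). Candidates carry a direction-consistency flag (parent
log₂FC < 0 < product log₂FC) and are explicitly candidates, never
assignments — spectral similarity plus a mass delta is putative (MSI
level 2) evidence.

## Integration

Both blocks enter CLR-transformed (pseudocount, closure, log, subtract the
sample log-mean). CLR on peak areas is unusual but treats the two blocks
symmetrically; a log₁₀ alternative is available in the feature module.

The two-block sparse PLS keeps per component the top-k loading magnitudes
(soft-thresholded at the largest dropped magnitude, then renormalized),
alternating between blocks from a deterministic SVD initialization of XᵀY
until the loading change is < 1e-9 or 500 iterations (non-convergence warns
and returns the last iterate). Deflation is canonical — each block deflated
by its own variate — and loading signs are fixed so the largest-magnitude
entry is positive. With full keeps, component 1 coincides with classical
two-block PLS. Defaults keep 10 features per block per component with 2
components; a 5-fold cross-validated grid search over keep values
(maximizing held-out variate correlation) is provided for tuning, since no
universal keep value exists.

The association score between taxon *j* and metabolite *k* is
Σ_h corr(X_j, z_h) · corr(Y_k, z_h) with z_h the mean of the two block
variates of component h — the variate-projection similarity standard for
this model family, not raw pairwise Pearson (which is exposed separately if
wanted). Scores are clipped to [−1, 1] (the sum can exceed 1 by a rounding
margin when variates are not exactly orthogonal) and edges kept at
|score| ≥ 0.65. Group separation along component 1 is assessed by one-way
fixed-effects ANOVA; a zero within-group variance with distinct means is
reported as p = 0.

## Synthetic-data generator

The generator emulates the *structure* of a five-condition (control, three
herbs, one purified compound) x five-technical-replicate ex vivo study:

* **References**: 12 taxa descended from one random ancestral sequence
  (250–450 nt) at 12% per-taxon substitution — pairwise identities near
  0.78, like 16S variable regions — with nested 6-rank lineages and
  per-species copy numbers uniform on 1–15, averaged up the hierarchy.
* **ASVs**: 30 ASVs, each a reference copy with 0–10 point mutations.
  Counts follow a log-normal(μ=5, σ=1) baseline scaled to a 50,000-read
  library and closed by multinomial resampling. Four taxa carry a 5-fold
  condition effect (at least one enrichment is always planted); four others
  are coupled to a shared per-sample latent factor (effect 1.2 on the log
  scale).
* **Metabolome**: 120 features with paired crude/inoculated columns per
  culture plus three blanks at ~1% of sample means. A parent/product pair
  is planted whose precursor masses differ by the C3H6NO3S moiety mass; the
  parent falls 4.5–16-fold and the product rises correspondingly in every
  replicate. Four features track the same latent factor as the associated
  taxa, creating recoverable cross-block correlation; twenty background
  features shift 4-fold between crude and inoculated, giving the PCA its
  separation.
* **Spectra**: 10–30 fragment peaks per feature, intensities uniform on
  1e3–1e6, m/z jitter on shared peaks ≤ 0.002 Da (below the 0.005 Da match
  tolerance). The planted pair shares six dominant fragments, three direct
  and three shifted by the precursor delta.

Randomness is fanned out from one master seed into an independent stream
per artifact via stable string labels, so outputs are byte-identical across
reruns and adding a new output never perturbs existing ones.

What the generator does **not** emulate: read-level sequencing error and
denoising, chimeras, chromatographic peak shape and co-elution, adduct and
isotopologue redundancy, inter-donor variability (a single pooled inoculum
is assumed), and realistic phylogenetic sequence structure beyond a
star-shaped homolog family. Passing recovery tests therefore demonstrates
the pipeline's correctness on data with the planted statistical structure,
not field performance on real cultures.

## Problem sizes and determinism

Recovery checks run the default design over 10–20 seeds and the null
calibration over 20–50 seeds, sizes at which every statistic stabilizes
while the whole suite stays fast. The pipeline hashes every stage's inputs
and outputs into a manifest; a stage re-runs only when an output is missing
or an input's content changed, and identical config + seed reproduce
identical hashes end to end.

## Known limitations

* Alignment is exact Needleman–Wunsch (no k-mer prefilter), fine for
  hundreds of ASVs x hundreds of references, slow beyond that.
* The MTA identity depends on the stated scoring scheme; other schemes
  shift *M* slightly and hence the retention set near the threshold.
* The association score inherits sPLS's preference for dominant covariance
  directions: associations orthogonal to the retained components are
  invisible at any cutoff.
* Compositional closure induces negative correlations between unrelated
  taxa; CLR mitigates but does not remove this, and null calibration is
  therefore reported alongside sensitivity.
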