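# Methods

## Scope and model

`ippispace` implements a pipeline for comparing compound collections in a
descriptor-defined chemical space and for relating classes of
protein–protein-interaction (PPI) targets to classes of their binding
pockets. Its stages are: synthetic data generation, compound curation,
two-population statistics, the chemical-space overlap score Δ, sub-pocket
descriptor combination, and Ward hierarchical clustering.

## Synthetic descriptor generator

The generator emulates curated compound collections whose only published
statistics are a per-descriptor mean ± SD and a dataset size. Marginals are
therefore truncated Gaussians; nothing beyond the second moment (skewness,
multimodality, discreteness of count-like descriptors) is modelled, and
cross-descriptor correlation defaults to the identity matrix (the real
descriptors are certainly correlated — e.g. MW with aromatic ratio — but no
covariances are published). Consequences for interpretation: passing tests
demonstrate that the *metric machinery* behaves correctly on data with the
published first and second moments; they do not show how the metric behaves
under the real collections' higher-moment structure, and Δ values computed
on synthetic data can differ from those on real data by the contribution of
shape and correlation, not only noise.

Bounded descriptors (aromatic ratio and globularity in [0, 1], MW > 0)
are sampled by rejection. Because the published mean ± SD describe the
observed, in-bounds values, the parent Gaussian of a bounded descriptor is
moment-calibrated: the two parameters of the parent are solved numerically
so that the truncated distribution itself has the requested mean and SD
(material for globularity, where naive truncation at 0 would inflate the
mean by ≈ 0.008; negligible for MW, where the bound sits 3.7 SD away). If
no truncated Gaussian on the interval can reach the requested moments the
generator falls back to truncating the naive parent and logs a warning.

The built-in specs encode the two PPI-inhibitor collections at their
published sizes (1,650 and 1,598 compounds) over the seven discriminative
descriptors (MW, AlogP, aromatic ratio, CW2, IW4, glob, EDmin3). Reference
("non-iPPI") libraries' statistics are published only graphically, so the
shipped presets for them are labelled *illustrative* and are not estimates
of any real library. Every dataset owns an explicit integer seed; there is
no global random state, and identical spec + seed gives bit-identical
tables.

## Curation rules

A compound is kept iff its activity is a Kd/Ki/IC50/EC50 strictly below
30 µM, MW strictly below 1,200 g/mol, at least 10 heavy atoms, elements
within {C, N, O, S, P, halogens}, at most 3 contiguous peptide bonds, and
it is not a macrocycle, salt, metal complex or carbocation. Rule evaluation
is exhaustive (every violated rule is reported), a missing mandatory field
excludes with reason "incomplete", and duplicate ids collapse to the first
record. The peptide threshold is stated ambiguously in its source ("3
sequential" vs "more than 3 contiguous"); the Methods-style reading — keep
up to 3, exclude above — is implemented. Potency binning splits at
pXC50 = 7; the boundary itself is assigned to "high" (an arbitrary but
documented convention; the boundary is unpopulated in practice).
Drug-likeness flags use the original rules' thresholds: Lipinski RO5
(MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10, fail on > 1 violation), Veber
(rotatable ≤ 10, TPSA ≤ 140), Egan (logP ≤ 5.88, TPSA ≤ 131.6), GSK 4/400.

## Two-population statistics

Two samples are compared with Student's t test when both pass a Shapiro
normality test and a two-sided F ratio test accepts variance equality, and
with the Mann–Whitney–Wilcoxon test otherwise. All tests are two-tailed;
the pre-tests use the same α as the main test (the source procedure does
not state a separate level; 0.05 is the working default). Samples larger
than the classical Shapiro validity cap of 5,000 are tested on a fixed-seed
subsample of 5,000. MWW uses the exact distribution for tie-free samples of
≤ 50 and the tie-corrected normal approximation otherwise. Multi-group
comparisons use a Kruskal–Wallis omnibus followed by all pairwise MWW
tests; raw p-values are reported by default (matching the source
procedure), with Holm correction behind a flag. Groups need ≥ 5 members;
all-tied degenerate input yields omnibus p = 1 with a flag. Significance
stars: *** < 0.001 ≤ ** < 0.01 ≤ * < 0.05.

## Overlap score Δ

The PCA is fitted once on the union of all datasets being compared, after
per-descriptor standardization (mean 0, SD 1, ddof = 1), retaining **all**
components so the variance fractions sum to 100 %. A Δ value therefore
depends on the collection it was computed within, not only on the pair —
this is intrinsic to the definition, and the pairwise function takes the
whole collection for that reason.

Per-component densities use a Gaussian kernel with the rule-of-thumb
bandwidth 0.9·min(SD, IQR/1.34)·n^(−1/5), 512 grid points, and the grid
extended 3 bandwidths beyond the sample range — the classical defaults of
general-purpose density routines, since the source analysis specifies only
"default parameters". The Weitzman overlap δ = ∫ min(f₁, f₂) interpolates
both densities linearly onto a common 1,024-point grid spanning the union
of supports (density clamped to 0 outside each estimate's own grid) and
integrates trapezoidally; whether the original computation used a shared
grid is unstated, and this choice is documented rather than derived.
Components with zero variance fraction carry zero weight and are skipped.
Numerical error budget: the KDE + resampling pipeline returns
Δ(A, A) ≈ 0.998–1.000 at n = 2,000 (the self-overlap tolerance used
throughout is 0.02), and 1-D Gaussian pairs reproduce the closed form
2Φ(−d/2σ) within 0.03 at n = 10,000.

## Pocket descriptor combination

A sub-pocket record is a total cavity-point count, percentages over the
eight point features, and per-feature percentages over ten projection-
distance bins (canonical edges 0–100 in steps of 10; configurable, since
the full edge list is not published). Combination is count-weighted:
percentages are converted to (real-valued) counts, counts added, and
renormalised by the combined total, so point counts are conserved exactly
and combination is associative. The whole-pocket vector has 117 entries in
a fixed order: total count, 8 feature percentages, 80 binned percentages
(= 89 base descriptors; their exact identity is not enumerated in the
source and is reconstructed as this schema), 10 per-distance sums over the
features, and 18 externally computed shape descriptors. Pocket distances
are Euclidean; because the 117 descriptors mix counts, percentages and
shape measures, vectors are z-scored per descriptor by default (the source
does not state whether it standardized; a flag restores raw distances).
Cavity detection itself and the shape-descriptor computation are out of
scope — those values are inputs.

## Clustering

Dataset clustering uses d = 1 − Δ (the source does not state its exact
transform; the complement is the documented choice), pocket clustering the
Euclidean distances above. Agglomeration is Ward's method in the "D2"
convention — squared dissimilarities inside the Lance–Williams update,
heights reported on the original scale — because Δ-derived dissimilarities
need not be Euclidean; the plain "D" variant sits behind a flag. Ties in
the minimum search are broken by the lexicographically smallest pair of
node indices, making merges fully deterministic. The implementation is
validated against direct within-cluster-SSE minimization on Euclidean point
sets (n ≤ 8) and against scipy's Ward linkage heights. Trees export to
Newick with heights as cumulative branch lengths; cutting at k − 1 is a
strict coarsening of the cut at k. Cluster characterization runs the
Kruskal–Wallis + pairwise-MWW machinery per descriptor at α = 1e-4
(pocket space) and reports a descriptor for a cluster only when it is
significant against *every* other cluster, with the direction of the median
difference. Note the exact-MWW granularity: with fewer than ~10 members per
cluster the two-sided p cannot reach 1e-4, so characterization needs
cluster sizes in the tens — the bundled pocket analysis uses 15 pockets per
archetype for this reason.

## Problem sizes and runtime choices

The bundled analyses and tests run at the published ligand dataset sizes
(1,650 + 1,598; joined table 3,248 rows) — small enough that the full
pipeline completes in seconds. Closed-form KDE checks use n = 10,000;
the decision-tree type-I-error calibration uses 2,000 replicates at
n = 100 per side; the pocket study uses 60 pockets. The full ~569,000-
compound collection, the 17 real reference libraries, the 20-descriptor
PCA on real structures and the published pocket groupings (Brd+GP120,
MDM2+ITGAL, Xiap+IL-2, Bcl-2) require external databases and commercial
descriptor software and are not reproducible here; the property suites
above stand in for them.

## Known limitations

- Truncated-Gaussian marginals with identity correlation are a deliberately
  minimal model of the real collections (see above).
- Δ inherits KDE bias: heavy truncation or strong multimodality on a
  component can bias δ by a few hundredths; the self-overlap tolerance
  (0.02) quantifies the well-behaved case only.
- The 89-descriptor base schema is a reconstruction; real cavity software
  may order or name fields differently, so the readers accept any table
  matching the documented header.
- Structure-level curation (canonicalization, substructure filters such as
  PAINS) is out of scope; duplicate detection is by user-supplied id.
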