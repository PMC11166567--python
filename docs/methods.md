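# Methods

## Scope and data model

`morphmap` operates on well-level morphological profiles: one row per
well, `Metadata_`-prefixed metadata columns (plate, well, perturbation,
modality, control type, target genes, cell type, time point) followed
by numeric feature columns. Three perturbation modalities are
modelled — chemical compounds, CRISPR knockout guides, and ORF
overexpression constructs — each arrayed on its own 384-well plate
(16 rows × 24 columns). Target-gene sets are serialized as a
pipe-delimited string; negative controls carry none, genetic reagents
exactly one, compounds possibly several (polypharmacology).

## Plate design

The plate is split into an **outer zone** — the two rows (A, B, O, P)
and two columns (1, 2, 23, 24) nearest the edges, 4·24 + 12·4 = 144
wells — and an **inner zone** of 12·20 = 240 wells. Edge artifacts
concentrate in the outer zone, so the layout enforces: (a) sister
compounds sharing a target stay in one zone, (b) the target's CRISPR
guides and ORF occupy that same zone on their plates, (c) positive-
control compounds are inner-only. Genes coupled through dual-target
compounds move between zones as one unit (connected components of the
gene–compound graph); roughly the outer zone's share (144/384) of
treatments goes outer, growing if the inner zone would overflow, and
any remaining deficit raises a design error naming it.

Default cardinalities: 160 target genes; two compounds per target; two
guides per gene except the last 15 genes in sorted order (one guide,
305 guides total); 30 CRISPR negative controls (3 cutting + 27
non-cutting) in duplicate; 15 ORF negative controls in quadruplicate;
duplicated ORF treatments; 17 diverse positive-control compounds in
duplicate; 64 DMSO wells.

The 320 gene×compound target annotations cannot occupy 384 wells next
to 64 DMSO and 34 positive-control wells, so the generator merges
pairs of annotations (from different genes) into dual-target
compounds until the plate fits — with the defaults this yields exactly
303 distinct compounds on a full plate, matching the reference
design's compound count. DMSO wells are spread over rows and columns
by even striping of the remaining wells rather than placed randomly,
to avoid accidental clustering; all other placement within a zone is
uniform at random given the seed.

The schedule crosses each modality's replicate plates (4 compound, 4
CRISPR, 2 ORF) with two cell types (U2OS, A549) and two
modality-specific time points — 40 primary plates, one imaging each —
plus seven secondary conditions held as data rows (new plates for the
blasticidin/puromycin/seeding-density/Cas9-line variants; re-imaging
events for the photobleaching and sample-stability series). The
totals are pure functions of the specification: 51 physical plates,
107 plates of images, and 107·384·9·8 = 2,958,336 images at 9 sites
per well and 8 images per site.

Dataset splits are assigned at the entity level after grouping
perturbations that must travel together (both guides of a gene; the
identifier pairs of the three compounds known to exist under two
identifiers). Replicate wells, and cells within a well, inherit their
perturbation's split by construction.

## Preprocessing

Single-cell profiles are aggregated to the per-well **median**.
Normalization is per plate: subtract the median and divide by the raw
median absolute deviation (no 1.4826 consistency constant — the
cytominer convention) of a reference population, either the plate's
negative-control wells (default) or all wells. Features with zero
reference m.a.d. on any plate are dropped table-wide and logged.
Cross-plate pooling is deliberately not offered.

Feature selection removes near-zero-variance features (variance
< 1e−10 over all wells of all plates, or a modal value occupying >95%
of wells with <10 distinct values — caret-style, both thresholds
configurable), then iteratively prunes correlated pairs: while some
pair exceeds |r| = 0.9, the feature with the highest mean absolute
correlation among the retained set is dropped, ties breaking toward
the lexicographically later name. This makes the retained set
deterministic and independent of column order.

Optional well-position centering subtracts, per feature, the mean at
each well address across plates; it requires ≥2 plates and is off by
default (with few plates it removes biology along with the artifact).

## Retrieval statistics

Similarity is cosine, signed by default; absolute value where both
correlation directions count as a match (sister compounds, all
gene–compound cross-modality tasks). Rank lists are sorted by
descending similarity with a stable sort, so ties resolve by input
order.

Average precision uses the standard recall-weighted form
`AP = Σ_k (R_k − R_{k−1}) P_k`, equivalently the mean precision at
each positive's rank. Significance comes from the permutation null of
shuffled rank lists; since that null depends only on the number of
positives m and the list length n, one seeded sample (default 100,000
draws; tests use 9,999) is drawn per (m, n) and shared across queries —
identical in distribution to per-list shuffling and far cheaper. The
p-value uses the `(1 + #{null ≥ obs}) / (N + 1)` correction so it is
never zero and the test is valid. p-values are BH-adjusted *within a
task*; classes (perturbations for activity, genes for matching) are
summarized by mean AP and the geometric mean of member q-values, and a
task by its fraction of classes with combined q < 0.05 («fraction
retrieved»).

Task assemblies, each restricted to one cell type × time point ×
modality:

- **Replicate detection (activity):** each non-control well queries
  its replicate wells against all negative-control wells, signed
  cosine. A `position_match` switch restricts positives to the same
  or to different well addresses (exact-address interpretation) to
  expose layout artifacts. Perturbations with combined q > 0.05 are
  dropped by the activity filter before matching.
- **Sister matching:** consensus profiles (median over replicate
  wells; well-level mode available) of active treatments; positives
  share ≥1 annotated target gene, negatives share none — compounds
  sharing *any* target are excluded from the negatives to avoid
  mislabeling under polypharmacology. Rejected for ORF (one reagent
  per gene). Positive-control compounds are excluded by default.
- **Cross-modality matching:** each active compound queries all
  active genetic perturbations of one modality, absolute cosine;
  positives target one of the compound's genes. A query's score is
  credited to each of its target genes with a counterpart present, so
  both sister directions enter a class's mAP.

## Directionality

Same-gene cross-modality pairs (e.g. CRISPR vs ORF consensus
profiles) give the *true* signed cosines; all different-gene pairs
form the null (full pool, no subsampling). Thresholds are the null's
5th and 95th percentiles (linear interpolation). The contingency
table [[true above, true below], [null above, null below]] enters a
two-sided Fisher's exact test: the null is symmetric by construction
(~5% per tail), so an odds ratio above 1 means true pairs are
preferentially positively correlated, below 1 preferentially
negative. If no true pair lies beyond either threshold the result is
flagged `no_signal` with p = 1. At least 20 null pairs are required
for the percentiles to be meaningful.

## Synthetic generator

Each gene g gets a unit latent phenotype u_g (isotropic Gaussian,
normalized); features are exchangeable — real feature covariance is
out of scope. A well treated with an active perturbation measures

    x = s · effect_size · u + layout(well) + ε,  ε_j ~ N(0, noise_sd²)

where u is the perturbation's latent (multi-target compounds mix
their genes' latents 50/50, renormalized), and s ∈ {−1, 0, +1} comes
from the per-modality `sign_map` (with optional flip probabilities),
a sister-compound flip (`compound_sign_flip_prob`, default 0.3:
sister compounds can enhance or inhibit a target), and the activity
flag (inactive perturbations and negative controls have s = 0).
`polypharmacology_rate` (default 0.21, the annotated multi-family
fraction in the reference compound set) gives that share of
single-target compounds a second off-class target, recorded in the
ground-truth manifest.

The layout artifact is shared across all plates: a smooth radial edge
gradient (weight exp(−d/2) in the distance d from the plate edge)
plus an independent per-well-position offset, each a Gaussian vector
with norm ≈ `layout_effect_sd` so it competes with `effect_size` on
the same scale. Replicate plates reuse one plate map, so cross-plate
replicates share well positions (as in the real design); duplicated
ORF treatments additionally provide different-position replicates
within a plate.

Default conditions: 100 features; noise_sd = 0.1 (noise vector norm
≈ 1, so an effect_size-1 perturbation has replicate cosine ≈ 0.5 —
the mid-range of what active Cell Painting perturbations show);
layout_effect_sd = 0.05 (mild artifact); inactive_fraction = 0.2;
all-positive `sign_map`, mirroring the empirically observed tendency
of same-gene CRISPR/ORF/compound profiles to correlate positively;
replicate plates 4/4/2 as in the reference design. Everything is
determined by the single seed.

What passing tests on this generator do **not** show about real data:
real feature covariance, cell-count/viability effects, batch drift
between plates, annotation noise, and non-linear phenotype mixtures
are all absent; the generator validates the statistical machinery
(calibration, power, sign recovery, layout sensitivity), not
biological effect sizes.

## Numerical choices and limitations

- Problem sizes in the test suite (e.g. a 200-perturbation null
  calibration at 9,999 permutations; a five-rung effect-size ladder
  at 100 perturbations) were chosen to make calibration standard
  errors small while keeping the default run fast.
- Fraction-retrieved significance floors: with m positives in a list
  of n candidates the smallest attainable p is about
  C(n, m)⁻¹-bounded; tiny candidate sets can never reach q < 0.05,
  which is a property of the statistic, not a bug.
- Only 384-well geometry is supported; zone definitions and the
  outer/inner capacities are fixed by that geometry.
- BH is applied per task; combining across tasks or conditions is the
  caller's responsibility.
- The duplicate-structure compound names used for split grouping are
  matched by substring on the perturbation identifier; foreign naming
  schemes can supply explicit groups instead.
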