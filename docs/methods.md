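# Methods

## Quantification model

A sample's sequencing output is a vector of relative abundances over taxa,
including three spike-in organisms whose input DNA masses are known.  The
model has three steps, applied per sample:

1. **Calibration.** Ordinary least squares of spike input DNA mass *d*ᵢ (ng,
   response) on observed relative abundance *r*ᵢ (predictor).  The default
   constrains the line through the origin (a taxon observed at zero
   abundance carries zero DNA), for which a single spike point suffices;
   `through_origin=False` fits a free intercept and then needs at least two
   spike points at distinct abundances.  The fit direction is
   mass-on-abundance because prediction targets mass.  The goodness of fit
   *R*² is uncentred for the through-origin form (standard for no-intercept
   regression) and centred otherwise; a non-positive or non-finite slope is
   rejected as an invalid calibration.
2. **Mass estimation.** DNA mass of taxon *t* is the calibration line
   evaluated at *r*ₜ, floored at zero (a negative intercept could otherwise
   produce negative mass at low abundance).
3. **Cells from mass.** One genome weighs *L*ₜ × *m*_bp g/mol, with genome
   length *L*ₜ from the genome catalog and *m*_bp = 660 g/mol per
   double-stranded base pair by default (the standard average; configurable).
   CMU_t = mass × 10⁻⁹ / (L_t · m_bp) × N_A / k, with N_A Avogadro's number
   and *k* the assumed genome copies per cell (default 1; configurable for
   polyploid taxa).

Spike-in taxa are excluded from every CMU output.  Native relative
abundances are **not** renormalised after removing the spikes: the
calibration maps raw observed fractions to mass, and renormalising would
break that mapping.  Taxa without a genome record are skipped and reported,
rather than failing the sample.

Key invariants (all tested): quantification exactly inverts a noise-free
DNA-mass-proportional forward model; scaling all spike input masses by *c*
scales every CMU by *c*; a collinear calibration has *R*² = 1.

### Estimator shape

`CmuQuantifier` follows the scikit-learn transformer protocol, but the
fitted state is *per sample* (one calibration line per row), like other
per-sample normalisers: `transform` accepts only samples seen during `fit`,
and the intended call is `fit_transform` on the full table.

## Classification and pooling

Taxa map to a source (oral, extraoral contaminant, unknown/unclassified)
and, for oral taxa only, to overlapping clinical-relevance categories and
selective-media groups.  Source counts always partition the taxon universe;
universe taxa missing from the table count as unknown.  Category pooling
sums raw CMUs over the member species of **one** category and then takes
log₁₀ — summing before the log matches reporting of mean *total* category
loads, and confining the sum to a single category prevents species with
multiple memberships from inflating other categories' totals.
Selective-media-equivalent totals scale the sampled-site total to the whole
dentition by teeth_total / teeth_sampled (default 28/4 = 7, both
configurable); on the log scale this adds exactly log₁₀(7) ≈ 0.845.  Total
microbial load defaults to oral taxa only (contaminants excluded),
switchable to all taxa.

The bundled `classification_fixture.csv` is a **synthetic** stand-in for a
literature-curated classification: it reproduces the marginal counts of an
856-taxon plaque survey (213 oral / 257 contaminant / 386 unknown; category
counts 138 commensal, 32 gingivitis, 55 periodontitis, 29 malodor, 23
caries, 9 oral-health-associated, 85 opportunistic, 23 infectious; media
groups 153/3/22/2) with a small curated head of well-known oral taxa and
deterministic round-robin membership for the rest.  Individual memberships
beyond the curated head are not biologically meaningful;
`scripts/make_classification_fixture.py` regenerates the file.

## Diversity and ordination

- **Alpha.** Observed richness counts taxa above a detection threshold
  (default 0).  Shannon–Weaver *H* = −Σ *p*ᵢ ln *p*ᵢ in nats, with *p*ᵢ the
  taxon's share of the profile total; an all-zero profile is undefined and
  raises.
- **Weighted UniFrac.** Raw form: Σ_b ℓ_b · |p_A(b) − p_B(b)| over branches,
  where p_X(b) is the fraction of sample X's total abundance descending
  branch b; the normalized form (default) divides by Σ_b ℓ_b (p_A(b)+p_B(b)),
  the abundance-weighted depth sum, bounding distances by 1.  Branch
  fractions are per-sample, so absolute (CMU) and relative input give
  identical distances.  The implementation works directly on real-valued
  abundances via a branch × taxon descent-indicator matrix; scikit-bio's
  UniFrac (which casts counts to integers) serves as an independent
  cross-check on integer fixtures in the test suite.  The flag used is
  recorded in pipeline run metadata.
- **PCoA.** Classical metric scaling: double-centre −D²/2, eigendecompose,
  scale eigenvectors by √eigenvalue.  Axes from negative eigenvalues of
  non-Euclidean matrices are dropped from the coordinates but retained in
  the eigenvalue list; variance explained is computed over positive
  eigenvalues only (no Cailliez correction).  For Euclidean-embeddable input
  the embedding reproduces the pairwise distances to 1e−8 (tested, and
  cross-checked against scikit-bio's PCoA).
- **PERMANOVA.** One-way distance-based pseudo-F (among/within partition of
  squared distances); p = (1 + #{permuted F ≥ observed F}) / (1 + n_perm)
  with label permutations from `numpy.random.default_rng(seed)` — every
  stochastic operation in the package takes an explicit seed.  Requires ≥2
  groups of ≥2 samples and ≥99 permutations.  Factorial designs are out of
  scope; stratify and run one-way calls.  The pseudo-F is cross-checked
  against scikit-bio's PERMANOVA in the tests, and the permutation null is
  calibrated: type-I error at α = 0.05 stays within [0.03, 0.07] over 1000
  exchangeable-null replicates.

## Differential abundance

Per-species tests use log₁₀ CMUs with a positive floor for zeros: default
floor 1 cell (log₁₀ = 0); a sub-1 floor (e.g. 0.1) is selectable where
negative log abundances are wanted.  The two-sample Wilcoxon rank-sum test
reports W (sum of mid-ranks of the first sample) and a two-sided p: exact by
full enumeration of group assignments when `auto` and min(n₁, n₂) ≤ 10 with
no ties (enumeration handles ties naturally when forced), otherwise a normal
approximation with tie correction and continuity correction; the two agree
within 0.02 for tie-free samples of 8–10 (tested against an independent
enumeration oracle).  Group comparison tables report per-oral-species group
means, their difference (group2 − group1), and p — **unadjusted**, matching
per-species reporting at p < 0.05; a Benjamini–Hochberg `q` column is
available but off by default.  Paired analyses compute per-subject
Δ = log₁₀ CMU(visit) − log₁₀ CMU(baseline) and average over the subjects
observed at each visit, reporting the count; a post-baseline sample without
a same-subject baseline is an error.

## Clinical endpoint arithmetic

Percent difference versus control is 100 × (treatment − control) / control,
rounded to one decimal with ties going away from zero (the printed-table
convention); recomputing from already-rounded means can deviate ±0.1 from
values derived from unrounded means.  Dropout inflation returns the smallest
n with n × (1 − rate) ≥ required, in exact rational arithmetic so boundary
cases (e.g. rate 0.5, required 10 → 20) are not lost to float rounding.

## Synthetic data generator

The generator emulates a two-cohort (healthy vs. gingivitis) plaque survey:

- per-species baseline log₁₀ cell counts ~ Normal(mean 5.0, sd 1.0) —
  communities spanning several decades around 10⁵ cells;
- each species carries one clinical category; a group's per-category log₁₀
  effects shift its samples' counts (defaults: gingivitis +1.0,
  periodontitis +0.8, malodor +0.6, caries +0.3, commensal +0.2 in the
  disease group, matching the direction and magnitude of published
  baseline contrasts where disease-associated species exceed health by
  0.3–1.5 log₁₀ and absolute loads rise broadly);
- per-sample noise Normal(0, 0.3) on the log₁₀ scale;
- 32 samples per group (the per-arm recruitment size) and a sequencing
  depth of 3 × 10⁶ reads (shallow-shotgun scale) by default;
- spike-ins default to the three control organisms at 0.2 / 0.5 / 1.0 ng —
  the per-organism masses of the commercial spike mix are not published, so
  three distinct values spanning a decade were chosen once as a
  well-conditioned calibration range;
- genome lengths uniform on 2–6 Mbp for natives; approximate published
  sizes for the spike organisms;
- sequencing draws reads multinomially with probabilities proportional to
  **DNA mass** (cells × genome molecular weight), not cell count, because
  genome length biases shotgun read share — exactly the bias CMU
  quantification corrects, making this the right forward model to invert.
  `depth=None` returns exact mass fractions (the infinite-depth limit).
  A per-taxon extraction-efficiency knob exists for robustness studies
  (default 1.0, i.e. equal lysis across taxa — the method's implicit
  assumption).

Random trees for UniFrac are built by repeated random joins with
exponential branch lengths (scale 0.1); everything is deterministic per
seed.

**What passing tests do and do not show.**  The generator produces
log-normal abundances with clean multinomial sampling; it does not model
taxonomic misassignment, contaminant reads, PCR/GC bias, strain variation,
or unequal lysis (unless the efficiency knob is turned).  Recovery results
therefore demonstrate correctness of the *inversion*, not robustness to
every real-data artefact.

### Problem sizes in the tests and acceptance script

Sequencing-recovery checks run on a 30-species, 8-sample community with
baseline mean 10^4.2 cells and sd 0.5 log₁₀ (total community DNA ≈ 6 ng).
The size is chosen so the multinomial error bound is meaningful: at depth
10⁶ a species at the 10⁴-cell reporting threshold receives thousands of
reads, putting the sampling sd of its log₁₀ CMU (≈ 0.434/√reads) several
fold below the 0.05 tolerance.  With the default heavy-tailed community
(sd 1.0 log₁₀), occasional high-abundance species consume most reads and
threshold species can exceed that tolerance — a property of read allocation,
not of the estimator.  End-to-end effect recovery uses 40 species and 30
samples per group, recovering a configured +1.0 log₁₀ category effect within
±0.1.  PERMANOVA calibration uses 16-sample null datasets, 99 permutations,
1000 replicates.

## Known limitations

- Per-sample calibration cannot transform unseen samples; there is no
  pooled/global calibration mode.
- One genome copy per cell is assumed (configurable constant, not
  per-taxon).
- PERMANOVA is one-way only; no factorial or repeated-measures designs.
- The repeated-measures mixed models used for clinical endpoints and
  alpha-diversity significance in trial practice are standard off-the-shelf
  statistics and are not reimplemented here.
- Exact-match taxon identifiers: no fuzzy name resolution (use the
  `validate` subcommand to list mismatches).
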