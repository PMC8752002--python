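# Methods

## DNA shape representation

`shapesig` treats the local conformation of double-stranded B-DNA as a
function of the pentamer centered on a base pair, supplied as a lookup
table with one row per pentamer (4⁵ = 1024 rows) and 19 value columns:
minor groove width at the center (Å), six intra-base-pair parameters
(propeller, opening, buckle in degrees; stretch, stagger, shear in Å) and
six inter-base-pair step parameters (twist, roll, tilt in degrees; slide,
rise, shift in Å) for the step preceding and the step following the
central base. The published pentamer-resolved query tables produced by
DNAshape-style tools can be dropped in; the test fixtures use the
package's own synthetic table (below). Computing shape values from atomic
coordinates is out of scope.

A 5-mer therefore has 19 descriptors. A 7-mer is profiled by sliding the
pentamer window over its three central positions (45 descriptors =
3 mgw + 18 bp + 24 step). The two interior steps, (−1,0) and (0,+1), are
covered by two pentamer windows; we take the arithmetic mean of the two
window values. The exterior steps (−2,−1) and (+1,+2) come from their
single covering window. Descriptors are named by parameter and
position/step (`mgw0`, `prop-1`, `tw+1` = the step from the center to the
+1 base, `ro-2` = the step from −2 to −1).

All k-mers are oriented once to the pyrimidine strand before any lookup;
no reverse-complement shape algebra is applied, avoiding sign conventions
for the asymmetric step parameters.

### Binning

Each parameter *type* (mgw, prop, …, pooling the pre/post columns of step
parameters) is min–max normalized over all 1024 table values and cut into
three equal-width bins: L = [0, 1/3), M = [1/3, 2/3), H = [2/3, 1]. Edges
are half-open with a closed top bin, so binning is total and
deterministic; values outside the table range (possible only with a
foreign table) clamp to the nearest bin with a warning. An
equal-frequency (tertile) mode is available behind
`fit_binning(mode="tertile")` for users who prefer balanced bin
occupancy; the equal-width reading is the default because the bins are
meant to be *equally spaced* intervals of the normalized conformational
range, not population terciles. Normalization is over the table, not over
genome-weighted pentamer frequencies: the bins then describe the
conformational space itself and do not shift between genomes.

## Dual-block spectra

The sequence block is the standard 96-channel trinucleotide spectrum
(6 pyrimidine-centered mutation types × 4 × 4 flanks), ordered mutation
type first (C>A … T>G), then 5′ then 3′ flank. The structural block uses
the six focal descriptors with the clearest structural interpretation —
mgw0, prop0, ro−1, ro+1, tw−1, tw+1 — giving 6 × 3 bins × 6 mutation
types = 108 contexts, reduced to 96 by removing the 12 energetically
unsampled combinations: prop0(L) and ro−1(H) at C sites, prop0(H) and
tw+1(L) at T sites (each crossed with the three mutation types of that
central base).

Each mutation contributes one count to each of its six focal
(descriptor, bin, type) slots, so a sample's raw structural block sums to
six times its mutation count. Counts that land on a forbidden slot (only
possible with a shape table that does not honor the exclusions) are
dropped and tallied rather than forced to zero columns. The structural
block is then resampled from a multinomial with n equal to the
sequence-block sum and probabilities proportional to the raw structural
counts, so both blocks carry the same counting noise in joint analyses.
Only the structural block is resampled by default
(`match_block_totals(..., bootstrap_both=True)` also redraws the sequence
block); matching happens once per sample with a recorded seed, and the
same matched matrix feeds both PCA and NMF.

Contexts are extracted once at k = 5 and the trinucleotide taken as the
middle trimer, so a mutation enters both blocks or neither; mutations
whose 5-mer window leaves the contig or contains a non-ACGT base are
skipped and counted. The genome base must equal the recorded reference
allele; mismatches are a hard error by default (`skip_mismatch=True`
downgrades them to logged skips), because silent mismatches corrupt
spectra.

Genome-wide *nucleotides at risk* are tabulated with the same
stratification (`feature_opportunities`): trinucleotide occupancy expands
the k = 3 opportunity table over the three mutation types of each central
base, and structural occupancy bins every genome pentamer; forbidden
slots are reported as counted-but-flagged mass.

## Poisson mutability model

For one sample and one representation, every strand-collapsed k-mer
present in the genome is an observation (zero-count k-mers included —
they carry opportunity information), with pooled mutation count y over
all alternate alleles and genome occurrence D. The model is

    log E[y] = log D + β₀ + β₁x₁ + … + β_p x_p

with D as offset. Features are categorical: flanking base per position
(plus the central C/T) for "3nt-seq"/"5nt-seq", or the 19/45 binned
descriptors for "5nt-str"/"7nt-str". Mutation types are pooled per
central base (C>A/C>G/C>T jointly, T>A/T>C/T>G jointly) on the assumption
that a dominant process drives all of them; the central-base indicator
keeps the two pools distinguishable.

Coding is reference-level dummies — A for flanks, C for the center, M for
bins — with reference coefficients reported as 0; sum-to-zero contrasts
are available (`coding="sum"`). Fits use IRLS (statsmodels GLM, ≤ 100
iterations, tolerance 1e−10) and Wald 95% intervals. Dummy columns for
levels absent from the genome are removed (they are unidentifiable);
genuine rank deficiency raises an error naming the collinear columns.
Model fit is McFadden's pseudo-R² = 1 − ℓ/ℓ₀ against the
intercept-plus-offset null; since the null is nested, it lies in [0, 1].
The log-likelihoods are verified in the tests against direct summation of
the Poisson log-pmf.

## Block-attributed PCA

PCA of the samples × 192 matrix is computed by thin SVD after column
centering. Columns are not unit-scaled by default — block totals are
already matched and the channels share a counts scale — with
`scale=True` available. Component signs are fixed by making each loading
vector's largest-magnitude entry positive. Because loading columns are
orthonormal, variance explained splits exactly over any column partition
as ve_k · Σ_{j∈block} loading²_{jk}; the per-PC sequence/structure shares
sum to ve_k to machine precision. The broken-stick baseline is
g_k = (1/p) Σ_{i=k}^p 1/i (Σ g_k = 1); half of g_k is reported as the
customary retention guide for scree plots. A matrix whose centered form
is numerically zero reports zero variance on every component.

## Signature extraction

NMF uses Lee–Seung multiplicative updates minimizing the squared
Frobenius error, the canonical form of the cited update rule (a KL
objective was considered and not implemented; Frobenius is the variant
whose monotonicity we assert per iteration). W and H start uniform-random
in (0, 1] from the run's seed; iteration stops at `max_iter` (default
10000) or when the relative objective decrease over a 10-iteration check
window falls below `tol` (default 1e−9). W columns are L1-normalized on
output with the scale absorbed into H, so profiles are comparable across
runs and exposures keep the counts scale.

`hierarchical_extract` runs `n_boot` (default 300) per-sample multinomial
bootstraps × each rank k per round. After a round, a sample is removed
when *any* run of the round reconstructs its original (un-resampled)
spectrum above cosine 0.97; the aggregation across runs is not specified
by the procedure we follow, and the optimistic "any run" rule was chosen
because removal exists to let already-explained samples make room for
rarer signatures. At most 3 rounds are run; every run enters the pool
with (bootstrap, k, round) provenance.

Candidate matching uses cosine similarity on the 96 trinucleotide
channels only. For each catalog entry the best-matching pooled component
is kept if its cosine exceeds 0.85; the kept object is that single
component and its exposure row, not the whole factorization. Names encode
all matches at ≥ 0.85 in decreasing-cosine order (ties alphabetical),
the "SBS" prefix elided after the primary, with an "L" (like) suffix for
0.85 ≤ cosine < 0.95 — e.g. `SBS15/6L`. When two catalog entries pick the
same component it is reported once under its combined name.

Novel discovery clusters each k-batch of pooled candidates (standardized
profiles, Euclidean distance) with a CLARA-style k-medoids: PAM
(build + swap) on repeated 10% subsamples (at least 2k points, 5
subsamples), keeping the medoid set with the lowest full-data cost. Among
the cluster counts tried (default 2–40, bounded by batch size), the
clustering maximizing the number of medoids that resemble a catalog
entry (cosine > 0.85) is selected — ties prefer fewer clusters — and its
medoids with maximum catalog cosine < 0.8 are pooled across batches,
de-duplicated at cosine > 0.95 (keeping the larger total exposure), and
numbered SBS-SS1, SBS-SS2, … by decreasing total exposure. Exact CLARA
internals are not reproducible from its description; the subsample-PAM
approximation preserves its behavior at these batch sizes. Components of
under-ranked factorizations can appear "novel" while being mixtures of
known processes; SBS-SS output is a candidate list for inspection, not a
confirmed discovery.

## Synthetic data

The generators emulate the study inputs at desk scale:

* **Genomes** — i.i.d. bases at a target GC (default 0.41, the human
  genome-wide value), single contig. Real genomes' repeat structure,
  CpG depletion and chromatin context are *not* emulated, so passing
  tests demonstrate correctness of the machinery, not biological effect
  sizes.
* **Shape tables** — uniform values per parameter type within
  literature-plausible ranges (mgw 2.8–6.2 Å, propeller −25–5°, twist
  20–40°, roll −10–12°, the remaining parameters zero-centered spans);
  these are fixture magnitudes, not measured values. With
  `honor_forbidden=True` (default) the four excluded combinations are
  enforced by resampling offending cells into allowed bins, iterating
  against the refitted binning until clean.
* **Signatures** — sparse profiles (exponential weights on 6–12 random
  contexts), rejected until pairwise cosine < 0.25, so planted profiles
  are unambiguous.
* **Catalogs** — per mutation: signature by exposure (Dirichlet(1) per
  sample), context + alt by the profile, position uniform among genome
  sites carrying that strand-collapsed trimer (3 bp from contig ends, so
  7-mer windows always exist). The structural half of a simulated
  signature is *derived* by profiling the sampled contexts against the
  fixture table, keeping the two blocks internally consistent.
* **Poisson counts** — y ~ Poisson(D·exp(Xβ)) over a regression design,
  for parameter-recovery and CI-calibration studies.

## Study sizes and reference studies

`shapesig.evaluation` packages the recurring simulation studies; the
sizes below are the package's chosen desk-scale study conditions, used
identically by the test suite and `scripts/acceptance.py`:

* Wald coverage: 10⁵ bp genome, 512 pentamer rows, true β = (0.6, −0.4,
  0.3) at total rate 0.05 per opportunity, 200 replicates; coverage is
  averaged over the non-reference coefficients.
* PC1 attribution: 25 samples × 192 features of unit noise plus a
  rank-one structural-only signal (SD 3), 100 replicates.
* Planted recovery: 4 known + 1 novel ground-truth signatures (plus 2
  catalog decoys never simulated), 60 samples × 5000 mutations,
  Dirichlet(1) exposures, 30 bootstraps, k = 2…6, NMF `max_iter` 2000 /
  `tol` 1e−7 at this scale, clustering over 2–10 clusters. Success:
  every known profile selected at trinucleotide cosine ≥ 0.95 and a
  discovered SBS-SS at ≥ 0.95 to the held-out profile.

All internal seeds derive from a single master seed via
`numpy.random.SeedSequence`, so every study is exactly reproducible.

## Numerical choices and degenerate inputs

* Multiplicative updates guard denominators with ε = 1e−12; objective
  monotonicity is asserted in tests rather than assumed.
* Multinomial matching with a zero structural block and nonzero sequence
  counts is an error (there is no distribution to resample); zero-sum
  bootstrap rows pass through with a warning.
* Bin edges at exactly 1/3 fall into M (half-open intervals, closed top).
* A constant shape parameter cannot be binned and raises.
* Opportunity counting excludes windows containing non-ACGT characters;
  totals therefore equal the number of valid windows exactly.

## Known limitations

Shape descriptors model double-stranded DNA only; processes acting on
single-stranded or non-B DNA (e.g. hairpin-mediated deamination) are
outside the representation. The synthetic genomes carry no mutation-rate
covariates (replication timing, chromatin), so structural/sequence
pseudo-R² values on synthetic data are not comparable to values on real
tumors. Signature recovery statistics here are measured under the stated
desk-scale conditions; consortium-scale catalogs (hundreds of WGS
samples, 300 bootstraps, ranks to 40) are supported by the same code but
not exercised by the test suite.
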