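# Methods

This note documents the models, parameter choices and limitations of
`epibridge`, in the order data flows through the pipeline.

## Circular binary segmentation (shared core)

CBS segments a per-locus signal track (the methylation Δβ track, or a
CNV coverage log-ratio track) chromosome by chromosome. For a segment
of n loci, every contiguous arc (i, j] with arc and complement both at
least `min_seg` loci (default 3; a flank may also be empty, giving a
binary split) is scored with the standardized mean difference
T(i, j) = |mean_in − mean_out| / (s_p √(1/k + 1/(n−k))), s_p the pooled
SD. The maximizing arc is accepted when a within-segment permutation
test on max T yields p = (1 + #{T_perm ≥ T_obs}) / (1 + n_perm) < α
(defaults α = 0.01, n_perm = 1000); the recursion then continues in the
up to three sub-segments. Arcs never wrap around chromosome ends; the
"circular" aspect of the statistic is the arc-versus-complement
contrast itself.

Numerical and efficiency choices:

- The permutation loop stops early only on the *reject* side, once the
  p-value can no longer fall below α. Acceptance always consumes the
  full budget, so the test is an exact permutation test and the null
  split rate matches α (verified by Monte-Carlo in the test suite).
- For segments longer than 600 loci the arc search — for the observed
  track and for every permutation alike — runs on a regular grid of
  ≈400 candidate boundaries. The grid maximum is itself a valid test
  statistic, so calibration is unaffected; accepted boundaries are then
  refined by exhaustive local search within one grid step.
- Zero-variance segments: if the pooled SD vanishes but the means
  differ, T is +∞ (a noiseless step is always found exactly); if the
  means agree, T = 0.
- An arc and its contiguous complement produce the same statistic and
  the same changepoints; either parameterization may be reported.

## DMR calling

Five stages with defaults p < 0.01 (Welch, two-sided), |Δβ| > 0.1,
merge gap ≤ 100 bp (inclusive), seed test p < 0.01, CBS as above, 1-D
k-means with k = 3 on segment mean Δβ (hypo/null/hyper; deterministic
given the seed, labels ordered by ascending centroid).

Interpretation choices where the procedure leaves room:

- The Welch (unequal-variance) flavor of the t-test is used throughout;
  it is the robust default when group variances differ.
- The seed test pools per-sample mean betas over the candidate's loci
  and runs one two-sample test (it does not pair samples).
- The Δβ track given to CBS covers **all** tested loci, not only DML:
  segmentation describes the difference signal genome-wide, and seeds
  enter only at the final selection step.
- A k-means cluster is selected when **any** of its segments fully
  contains (half-open interval containment) **any** seed; the final DMR
  set is all segments of all selected clusters. A seed straddling a
  segment boundary selects nothing.
- Loci with fewer than two observations per group are skipped and
  counted; candidate and seed means use available samples.

## CNV masking

Per-tile coverage log-ratio: cells are normalized to mean 1 per tile
(depth removal), group means are compared to a reference group with a
pseudocount of 0.01 on that scale, and the track is median-centered.
Centering matters: in a genome with substantial gains or losses,
per-cell normalization shifts the baseline of all *other* tiles, and
without centering neutral tiles sit at a nonzero log-ratio (the
uncentered track remains available via `center=False`).

CBS segments the track; segments with |mean log2 ratio| > 0.3 are
gain/loss calls (the threshold sits between noise, ~0.1 at these cell
counts, and a single-copy change, ~0.58). A call is confirmed only by
reciprocal overlap ≥ 0.5 with a same-direction external (panel) CNV
segment. DMRs overlapping any confirmed region are **removed**, not
trimmed: a partially CNV-confounded feature is unsafe for epigenotype
clustering. Masking is idempotent and its output is a subset of its
input. Default tile width for external data is 500 kb; the synthetic
tiles are 5 kb so that a desk-scale simulation still has thousands of
features.

## Epigenotype clustering

Standard scATAC LSI: binarize counts (presence/absence; log1p-TF
optional), scale regions by idf = ln(1 + n_cells/(1 + df)), L2-normalize
cells, truncated SVD (ARPACK — exact partial SVD, so the embedding is
invariant to cell order up to fixed signs; default d = 30). Components
with |Pearson r| > 0.9 against ln(total counts) are flagged as depth
components and excluded from clustering distances. K-means (fixed seed,
10 restarts) assigns epigenotype labels; `k="auto"` scans 2–20 by mean
silhouette. Binarization makes the embedding invariant to per-cell
depth scaling by construction.

Diversity statistics are Shannon entropies in nats: per-cluster donor
diversity H = −Σ f_d ln f_d, and its transpose, per-donor cluster
heterogeneity. A normalized variant (H / ln K) is available since
figures often report bounded diversity.

## Transition graph

F is row-normalized per source cluster, so A = F·Fᵀ entries are
co-occupancy products (the probability two source clusters land in the
same joint cluster under independent draws from their occupancy
profiles). The denoising threshold is the (1−q) quantile of the
off-diagonal upper-triangle weights, zeros included, diagonal excluded;
ties at the threshold are kept; a weight of exactly 0 is never an edge
(the clusters share no joint cluster). The default q = 0.01 matches the
regime of dozens of source clusters and hundreds of joint clusters; for
small synthetic graphs q should be chosen so that the retained-edge
budget q·M (M = number of node pairs) is close to the number of
plausibly co-occupying pairs — the bundled scenarios with ~10 source
clusters use q = 0.15.

Cross-modality matching assigns each ATAC cell the cluster of its
nearest RNA cell (Euclidean, exact ties to the lowest cell ID); when
only a joint-cluster table is available, `matches_from_joint` uses the
majority RNA cluster of the cell's joint cluster. Plasticity entropy is
the Shannon entropy of an epigenotype's matched-cluster distribution;
epigenotypes without matched cells are reported as missing rather than
zero.

## TCR clonality

Multiplet removal (≥ 3 assembled chains per barcode) precedes clone
definition; chain identity is the exact (locus, V, J, C, uppercased
CDR3 nt) tuple and a clone is a donor-scoped identical chain multiset.
Expansion rules are applied literally: `global` (> 2 in ≥ 2 samples),
`local` (> 2 in exactly one sample, ≤ 1 in every other), `singlet`
(donor total ≤ 2). A clone with > 2 in one sample and exactly 2 in
another satisfies neither printed rule; rather than silently coercing
it, it gets the explicit label `diffuse`. Clonotype diversity is the
Shannon entropy of clone-size fractions within a donor or sample;
expansion prevalence is the per-stage fraction of donors with ≥ 1
local clone.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure each stage consumes;
they do not simulate reads, chemistry, or real genome annotation.

**Methylation** (`MethylSimConfig`): per-locus baseline beta ~
Beta(0.8, 0.8) (bimodal, methylome-like); per-sample observation =
baseline + N(0, σ) clipped to [0, 1]; planted windows shift the case
group by +Δβ, with in-window baselines rescaled into [0.05, 0.95−Δβ] so
the shift survives clipping. Default σ = 0.04 corresponds to
high-coverage targeted capture (binomial SD at ~150× for beta 0.5). At
that noise the fixed |Δβ| > 0.1 DML cutoff is a ≈5.6σ event per locus
under the null, so a 50k-locus genome yields ~10⁻³ expected false DML —
the regime in which the seed-gated pipeline is silent under the null.
Loci spacings are uniform 15–150 bp over 20 synthetic chromosomes.
Defaults (50k loci, 20 DMRs of 10–30 loci, Δβ = 0.3, 10 vs 10 samples)
are the stated study conditions for the recovery checks.

**Accessibility** (`AtacSimConfig`): counts are Poisson with rate =
cell depth × epigenotype region weight × donor CNV fold, renormalized
per cell; depth is lognormal around 1000. Each epigenotype elevates a
private scattered signature set (≈ n_regions/(k+1) regions) by
signal_fold = 3. Donor CNV is 6 contiguous segments of ~5% of the
tile space each (≈30% of the genome per donor) at fold 4 (gain) or 1/4
(loss); donor 0 carries no CNV and serves as the log-ratio reference.
These defaults deliberately put the simulation in the regime the
masking step exists for — CNV structure strong enough that unmasked
clustering segregates cells by donor, as tumor scATAC data do — while
leaving enough CNV-free signature regions (~half the genome after
masking the 4 donors' union) for clean epigenotype recovery.

**Joint clusters**: one joint cluster per mapped
(epigenotype, phenotype) pair; a bridging epigenotype's ATAC cells are
split uniformly over its phenotypes' clusters; 2% of cells are
reassigned uniformly at random as noise. This is a synthetic stand-in
for a trained co-embedding's cluster table; no embedding model is
trained or emulated beyond co-membership structure.

**TCR**: clone sizes are Zipf(2.5) truncated at 40 cells; each clone's
cells spread over the donor's samples by a Dirichlet(0.6)-multinomial,
which produces local, global and diffuse patterns at realistic rates;
2% of cells receive a third chain. Ground-truth labels are computed on
the multiplet-free counts.

Passing tests on these simulations demonstrates algorithmic
correctness and the intended qualitative phenomena (null calibration,
CNV-dependence of clustering, bridging connectivity), not performance
on real data, which adds batch structure, doublets, fragment-length
effects and annotation ambiguity that the generators deliberately omit.

## Problem sizes and determinism

Simulation sizes in the tests and the acceptance script (50k loci for
DMR checks; 1200 cells × 2500 regions for the CNV/epigenotype check;
100 repetitions for calibration and bridging rates) were chosen as the
smallest sizes at which the planted effects are comfortably in their
asymptotic regime. Every stochastic routine takes an explicit seed and
threads it through one `numpy.random.Generator`; there is no global
random state, and rerunning any stage with the same inputs and seed is
bit-identical.

## Known limitations

- CBS boundary refinement after a grid search is local; a boundary more
  than one grid step from the grid optimum would be missed (not
  observed at the bundled effect sizes).
- The seed-gated DMR selection inherits the false-DML rate: at much
  higher beta noise (σ ≳ 0.05 at n = 10 + 10) isolated false seeds can
  select a background k-means cluster and inflate the call set; the
  noise level, group sizes and thresholds should be considered jointly.
- `intersect_true_cnv` is O(n·m) over segments and assumes segment-level
  (not base-level) reciprocal overlap; profiles are expected to be
  modest in size.
- Clone identity requires exact chain-set equality; sequencing errors
  in CDR3s split clones rather than fuzzily merging them.
- The transition graph treats joint-cluster co-membership as the only
  evidence of adjacency; it does not use embedding distances.
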