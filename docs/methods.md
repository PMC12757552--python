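# Methods

## Data model

The quantified unit is the unique cysteine peptide: a protein accession plus
the sorted 1-based protein coordinates of its cysteines, rendered
`P04406:Cys152` (multi-Cys peptides list every position). PSM- or
export-level rows sharing a key are summed channel-wise, the usual
reporter-ion roll-up, which is monotone in evidence and order-independent.
Peptides mapping to several proteins keep the first listed accession as
primary; the full list is retained in a provenance column. A channel design
maps each reporter channel to (plex run, sample, condition, replicate, label
class), where the two label classes are SH (free thiols, labelled first) and
Sox (reversibly oxidized thiols, labelled after reduction); validation
enforces exactly one SH and one Sox channel per sample within its plex run.

Zeros in intensity tables encode "not observed" (reporter ions below
detection or not sampled), never a measured zero.

## Normalization and the oxidation statistic

Intensities are log2-transformed (zeros excluded, since log2(0) is
undefined and the zeros are censoring, not signal). Within each plex run and
label class, each channel's median is shifted additively to the mean of the
medians of that class, then values are back-transformed — an additive log2
shift equals a multiplicative linear correction. Normalization is restricted
to one plex run because channel medians are only comparable within one
multiplexed MS run, and to one label class because SH and Sox medians differ
for genuine biological reasons (most of the proteome is reduced): forcing
both classes to a common target would destroy the global oxidation scale.

Per sample, oxidation is `Sox/(SH+Sox)*100`, in [0, 100]. Two zero policies
are provided:

- **default**: a single zero in a pair yields the boundary value (0 % when
  Sox = 0, 100 % when SH = 0); only a zero sum is missing. This keeps true
  boundary states representable.
- **strict (`strict_pair_na`)**: a zero in either channel makes the pair
  missing. This is the behaviour implied by transforming to log2 before the
  ratio (a zero channel is undefined), and it is the right choice whenever
  zeros are censoring: imputing a boundary value from a censored channel
  biases the estimate by construction — one spurious 100 % among three
  replicates of a ~8 % site shifts its mean by ~30 points, an error no
  amount of averaging repairs. The recovery and CV analyses in the
  acceptance script therefore run with the strict policy; the default stays
  permissive so boundary states remain available when zeros are trusted.

A caveat of any data-dependent normalization: the class target is the mean
of the observed medians, so scaling a *single* channel by k moves its class
target by log2(k)/n and the whole class by that residual. Only zero-mean
(log2) per-channel perturbations within a class cancel exactly; this is the
invariance the tests assert, and the reason the simulator centres its
planted biases (below).

Replicate reproducibility is summarized as CV = 100·sd/mean over
non-missing replicate oxidation values per site and condition (sample
standard deviation, n−1), undefined below two values, with per-condition
medians over sites.

## Differential oxidation

Per site, a two-sided Student's t-test with pooled variance compares the
oxidation values of two conditions (an unequal-variance option exists but
the pooled test is the default, matching standard practice for small
balanced designs). Convention for zero variance in both groups: t = 0,
p = 1 when the means are equal — this avoids spurious infinities at
saturated 0 %/100 % sites — and |t| = ∞, p = 0 otherwise.

Multiple testing uses permutation-based FDR. Balanced label permutations
(group sizes preserved) are enumerated exhaustively when few enough,
otherwise uniformly sampled with a fixed seed; the observed assignment and
its label-swap complement are excluded from the null pool, since including
them puts a hard floor of 2/#permutations on every q-value (for a 3 vs 3
design the floor would be exactly 0.1, making the q < 0.1 criterion
unattainable regardless of effect size). For each site,
q = (mean permutation count of null |t| ≥ |t_site|) / (observed count of
|t| ≥ |t_site|), clipped to [0, 1] and made monotone non-increasing in |t|
by a suffix minimum, as in step-up corrections. Samples are put in a
canonical order before permuting so the sampled null depends only on the
sample set and seed — swapping the group labels then leaves q unchanged
exactly.

A site is called **oxidized** (or **reduced**) when its oxidation change
exceeds +5 (or −5) percentage points *and* q < 0.1. If no site in a
comparison meets the joint criterion, the comparison — not individual
sites — falls back to p < 0.05; the active criterion is recorded per record.
Default 1,000 permutations (3 vs 3 designs are exhaustive at 18).

Group-level comparisons of median oxidation use one-way ANOVA with Fisher's
(unprotected) LSD pairwise t-tests on the pooled within-group mean square
with N − k degrees of freedom. Cross-dataset agreement is the Pearson
correlation over sites non-missing in both profiles (≥ 3 shared sites
required).

## Annotation and the P-SSG index

Annotation joins are exact on (accession, 1-based position); a multi-Cys
peptide matches if any of its positions hits a record (peptides are
quantified, sites are annotated; this is the permissive reconciliation, and
the matched position is recorded). The global S-glutathionylation index is
the per-sample aggregate oxidation over sites annotated as
S-glutathionylated; both the median and the mean are reported because
neither aggregate is canonical, and the choice is surfaced rather than
hidden. Domain-level tagging (e.g. zinc fingers) reuses the same join with a
domain-type annotation table.

## Profile clustering

Site × condition mean-oxidation profiles (complete rows only; incomplete
rows are dropped and logged) are clustered by agglomerative hierarchical
clustering, average linkage on Euclidean distance, cut to exactly k clusters
(default k = 10). Rows are sorted by site key before linkage, making the
result invariant to input order. Optional per-row z-scoring clusters by
profile *shape* rather than level. Clusters whose centroid Pearson
correlation meets a threshold (default 0.8) are merged single-linkage into
groups labelled A, B, C, … by descending member count. Linkage, metric, k
and the merge threshold are parameters, not claims: the lettered grouping
automates what is usually a visual judgement on a clustered heatmap.

## Abundance track

Raw protein × channel intensities (zeros missing) are log2-transformed,
rows with fewer than 9 valid values across all channels are dropped (the
count is not per group, matching the unqualified valid-value rule), and each
channel is median-centred to the grand mean of the channel medians — the
standard isobaric normalization, which equalizes channel medians exactly and
leaves within-row channel contrasts untouched. An `already_log2` flag
accepts exports that are already on log scale. Differential abundance reuses
the same t-test and permutation FDR on log2 values; significance is
q < 0.1.

## Synthetic data generator

The generator emulates the structure of a paired SH/Sox experiment:
per peptide i, sample s in condition c,

    A_i  = 2^N(16, 1.5)                     base abundance (per peptide)
    Sox  = A_i · ox_ic · ε,   SH = A_i · (1 − ox_ic) · ε'
    ε, ε' independent mean-1 log-normal with CV = replicate_cv
    each channel scaled by 2^b_ch, each cell zeroed with prob. missing_rate

Defaults are the study conditions: 2,000 peptides, two conditions × three
biological replicates, replicate CV 0.10 (within the 7–12 % range typical of
replicate oxidation measurements), channel bias sd 0.3 log2, 5 % missing
cells, and a +15-point oxidation shift planted on 5 % of peptides in the
non-reference condition (clipped to keep fractions in (0, 1); a
configuration whose shifts are entirely clipped away is rejected). Resting
oxidation is drawn from a right-skewed mixture — Beta(1.2, 10) for the
mostly-reduced bulk plus a 3 % Beta(8, 2) high-oxidation tail — matching the
typical shape of proteome oxidation distributions; it can be overridden with
explicit per-condition values. The base-intensity scale (2^16) is arbitrary,
as no intensity-scale statistics are targeted; only ratios matter
downstream.

Two deliberate design choices, both load-bearing for exactness tests:

- **Per-peptide abundance.** A_i is drawn once per peptide, with all
  sample-to-sample variation carried by ε. Data-dependent median
  normalization is then an exact fixed point in the noise-free limit, so
  zero-noise recovery of planted truth is exact rather than merely close.
  (With per-sample abundance draws, channel medians differ by sampling noise
  and normalization would perturb every value slightly.) Noisy behaviour is
  unchanged in distribution — the oxidation CV is governed by ε either way.
- **Centred channel biases.** Planted biases are N(0, sd) mean-centred on
  the log2 scale within each (plex run, label class). Only relative channel
  offsets are identifiable — an overall class scale is indistinguishable
  from base abundance — and with this convention per-class median
  normalization removes the planted biases exactly, which is what the
  bias-invariance check asserts.

The exact-zero noise-free checks also plant no differential shifts: with
between-condition shifts the per-condition channel medians genuinely differ,
so data-dependent normalization is not a fixed point and the noise-free
error, while tiny, is not identically zero.

The abundance generator plants |log2FC| = 1 with random sign on 5 % of
3,000 proteins over a 16-plex (8 vs 8), normal log2 noise sd 0.25,
per-channel biases, 2 % missing.

What the generator does **not** emulate: co-isolation interference and
ratio compression, peptide identification error, intensity-dependent
missingness (missingness here is marginal/uniform), correlated noise across
peptides of one protein, and retention-time or acquisition effects. Passing
the recovery and calibration checks therefore demonstrates correctness of
the estimators under the stated noise model, not robustness to every
pathology of real reporter-ion data.

## Problem sizes and tolerances

The acceptance script and test suite use 2,000-peptide simulations (10,000
for null calibration over ten seeds), 3,000-protein abundance tables, and
200-site clustering problems — sizes at which the measured quantities are
stable to well within their acceptance bands while the whole suite runs in
seconds. Exactness claims (noise-free recovery, bias cancellation,
permutation-oracle agreement, channel-median equalization) are asserted at
float tolerance (≤ 1e−9 relative or absolute as appropriate); statistical
claims are asserted as bands (median CV in [7, 13] %, null p < 0.05 fraction
within 0.05 ± 0.01, false-discovery proportion ≤ 0.15 with recall ≥ 0.5,
precision > 0.8), averaged over ten seeds where the quantity is itself a
rate.

## Known limitations

- No isotopic-impurity correction or protein-level roll-up of oxidation.
- No imputation: missing oxidation values stay missing.
- The permutation FDR is unsmoothed (no variance-stabilization offset); with
  very few permutations q-values are granular.
- Cross-plex alignment relies on the experiment's bridging design (a shared
  condition across runs) and is reported, not re-corrected.
- The p < 0.05 fallback trades FDR control for sensitivity by design; the
  recorded `criterion_used` should accompany any downstream claim.
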