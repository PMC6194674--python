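# Methods

`fecalsource` implements a random-forest microbial source-tracking
workflow for 16S rRNA amplicon data, together with a synthetic-community
generator and an in-silico spike-in benchmark. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Read screening and ASV calling

Merged amplicon reads are screened before partitioning. A read is
discarded when it (i) contains any base outside {A,C,G,T}, (ii) carries
a single-nucleotide run longer than `max_homopolymer_run` (default 8),
or (iii) has a length outside `median * (1 ± tolerance)` with inclusive
bounds. The tolerance is a fraction of the median read length — 0.10
for the short V6 region (median ≈ 60 bp), 0.05 for V4V5 (median ≈ 372
bp) — and the median is computed from the data when not supplied.
Rejections are logged per read with a reason, and per-sample
conservation (kept + rejected = input) is a tested invariant.

ASVs are called by minimum entropy decomposition (MED). All reads in a
node are aligned positionally (unequal lengths are trimmed to the modal
length by default; an `error` policy is available); the Shannon entropy
(bits) of each position is computed, and while the maximum positional
entropy exceeds `entropy_threshold` the node is split by the nucleotide
at that position. Ties between equally entropic positions break to the
leftmost position, and child nodes are processed in nucleotide order,
which makes the partition invariant to input order. Final nodes with
fewer than `M = floor(N / divisor)` reads are discarded, where N is the
total read count and the divisor is 50,000 for V6 and 10,000 for V4V5;
discarded reads are dropped, not reassigned. The retained fraction of
reads is reported as a diagnostic. The representative sequence of an
ASV is its most frequent read (count ties break lexicographically).

The stopping entropy is the one genuinely open numerical choice — no
single value suits every region and depth. The default is 0.1 bits,
low enough that a 1%-frequency variant (entropy ≈ 0.08 bits) is
absorbed as sequencing noise while a 2% variant (≈ 0.14 bits) still
splits; it is an explicit, documented knob.

## Signature-ASV selection

For each source a one-vs-rest binary labelling is built (samples of the
source, or of a composite source's members, against all others).
Composite sources default to Pet = Cat ∪ Dog and Ruminant = Cow ∪ Deer,
which exist because those host pairs share ASVs heavily enough to
inflate out-of-bag error of the individual classifiers.

ASVs are ranked by mean decrease Gini (MDG): random forests are grown
on the relative-abundance table (classification defaults: sqrt(p)
features per split, n-of-n bootstrap, unlimited depth), the unnormalised
total impurity decrease attributed to each ASV is averaged over the
trees of each forest, and then over `n_rank_replicates` forests grown
with distinct sub-seeds (defaults: 100 replicates of 10,000 trees;
scaled profiles such as 10 x 1,000 are configuration, used by the
benchmarks here). The unnormalised per-tree average matches the
R randomForest MDG semantics; scikit-learn's `feature_importances_`
normalises importances to sum to one per forest, which changes the
scale but not the order — and selection consumes only the order.

The top 200 MDG values form a scree curve, which is segmented into
piecewise-constant plateaus by exact dynamic programming minimising the
within-segment sum of squared deviations. The number of breaks
(0..`max_breaks`, default 5) is chosen by BIC with 2m parameters for m
segments (m means, m−1 break positions, one variance); minimum segment
length is max(2, 5% of the series). The DP is pinned to an exhaustive
enumeration oracle in the tests. All ASVs ranked at or before the
*first* breakpoint are selected — the scree of a well-separated
classifier shows a single elbow, and the first plateau is the set the
elbow delimits. A perfectly flat scree has no breakpoint; the fallback
selects the top 10% of the cap. A constant series returns no
breakpoints by construction.

Degenerate-input conventions: ranking requires both classes with at
least two samples each; an all-zero sample row in the abundance table
is an error naming the sample; a sample whose selected-ASV counts are
all zero renormalises to the zero vector (a defined, not exceptional,
case).

## Training, voting and calls

The relative abundance of the selected ASVs is re-calculated — each
sample's selected-ASV counts renormalised to sum to one *within the
selected set* (the whole-sample denominator is a configuration switch).
`n_train_replicates` forests of `n_train_trees` (defaults 100 x 1,000)
are trained on these vectors with per-replicate sub-seeds and pooled
into a single voting ensemble; out-of-bag error is averaged over
replicates. All sub-seeds derive from one master seed through a
documented counter (`SeedSequence` spawn keys, one stream per use), so
a fixed master seed reproduces rankings, selections and votes bit for
bit.

An unknown sample is matched to a classifier by exact string identity
of representative sequences (a deliberate choice: the sequences are
same-region, same-length MED representatives; a near-match mode is not
enabled by default). Matched counts are renormalised over the
classifier's ASV order, unmatched positions are zero, and the vote
probability is the fraction of pooled trees voting "contaminated".
Calls band the probability: positive requires a strict majority
(> 0.50), 0.45–0.50 and 0.40–0.45 are high and low marginal bands, and
below 0.40 is a no-call. A tie at exactly 0.50 is not positive.

The proportion proxy ranks sources within a sample: a source's
numerator is the count of sample sequences matching that source's
classifier, and the default denominator is the multiset total — an ASV
shared by k classifiers contributes to k numerators and k times to the
denominator, so proxies always sum to 100%. The union denominator
(each read counted once) is a switch. The proxy is scale-invariant and
is a ranking, not a quantitative apportionment.

## Synthetic communities

The generator emulates the structure the method exploits. A pool of
`n_asvs_total` (default 500) fecal ASVs receives lognormal(0, 1) base
abundances. Each of the six sources (Cat, Cow, Deer, Dog, Pig, Sewage)
owns `n_signature_per_source` (default 40) signature ASVs: 30% are
exclusive (present only at home), the rest host-preferred — boosted
`effect_size`-fold (default 10x) at home and carried at base abundance
by each other source with probability 0.4 (at least one other host
always carries a preferred ASV, so "preferred" is never covertly
exclusive). The freshwater background is a separate pool (default 200
ASVs) disjoint from the fecal pool, emulating a background sample in
which fecal indicator bacteria are absent.

Sample-to-sample variability within a source is Dirichlet resampling of
the source profile with concentration c·p. The concentration is
calibrated by a grid search so that the median pairwise Bray–Curtis
dissimilarity among draws matches a target: 0.7 for animal sources and
0.3 for sewage, reproducing the well-documented contrast between
highly variable animal microbiota and consistent sewage communities
(BC ≈ 69 ± 19% vs 29 ± 7%). Reads are multinomial draws at `depth` (default 50,000) from
the resampled composition.

Artificial assemblages follow the in-silico spike-in protocol:
component communities are rarefied — sampled without replacement via
multivariate hypergeometric draws — to their shares of the total depth
and concatenated. Shares are integers by largest-remainder rounding,
so a 0.5% share of 100,000 reads is exactly 500 and the assemblage
depth is conserved exactly. The default number of rarefying repeats is
99. Expected proportions are stored with each mix as ground truth.

What the generator does *not* emulate: sequencing error within an ASV
(reads are exact ASV sequences), chimeras, taxonomic structure across
the two bacterial orders (a run of the pipeline corresponds to one
order's table), compositional correlations between ASVs beyond the
Dirichlet, and phylogenetic relatedness between hosts (Cat/Dog and
Cow/Deer are no more similar a priori than any other pair; composite
classifiers are still built and exercised). Passing benchmarks
therefore demonstrate the pipeline's mechanics and sensitivity under
controlled signal, not field performance on real communities.

## Benchmarks

*Robustness* repeats ensemble training and prediction with fresh
sub-seeds while reusing the selected ASVs — repetition covers the
training and the prediction, not the selection —
and reports mean and SD of vote percentages. SDs are computed after
centring on the first repeat so that identical seeds give exactly zero.

*Sensitivity* draws one held-out community per source plus one
background community, then for each spike fraction rebuilds the
assemblage by independently seeded rarefying repeats of those fixed
components — fixed test samples with repeated rarefying, not fresh
community redraws, whose community-level variance
would otherwise dominate the threshold. Detection is a positive band
(> 50% of votes); marginal bands are tabulated separately. The
detection threshold of a source is the smallest fraction at which at
least 95% of repeats are positive.

*Proxy accuracy* is the Spearman rank correlation (average-rank ties)
between expected mixture proportions and proxies across assemblages.
Under the default study conditions this statistic is design-sensitive:
assemblages spiking all six sources give rho ≈ 0.75–0.82, while sparse
two-to-three-source mixtures give rho ≈ 0.3–0.7, because a source's
proxy denominator is dominated by whichever other sources happen to be
present and by Cow/Deer cross-matching through the Ruminant classifier.
This mirrors the spread such correlations show between bacterial
orders on real data (roughly 0.55 to 0.79).

Problem sizes used by the packaged benchmarks: a 6-source panel of 10
samples per source at depth 50,000 over 500 fecal + 200 background
ASVs; ranking and training forests scaled to 10 replicates x 1,000
trees; spike assemblages of 100,000 reads with 20 rarefying repeats per
fraction; held-out accuracy over 5 independent panels with 5 held-out
samples per source. These sizes are the package's benchmark defaults;
the full-scale forest profile (100 x 10,000 ranking, 100 x 1,000
training) is one configuration object away.

## Known limitations

- The first-breakpoint selection rule typically selects compact
  signature sets (~10–20 ASVs on the synthetic panel, against ~40
  planted); this is the honest behaviour of the scree rule on steeply
  decaying importance curves, and matched prediction remains accurate.
- Composite classifiers (Pet, Ruminant) occasionally misclassify one
  training sample out-of-bag (error ~1/60) because their positive class
  is heterogeneous by construction.
- Detection at a 0.5% spike depends on the held-out community being
  typical of its source; under the calibrated animal-level dispersion
  roughly 1 community in 10–20 is atypical enough to be missed, which
  parallels the exceptions real benchmarks show at that spike level.
- MED here assumes positional comparability after trimming to the modal
  length; it does not build a multiple alignment.
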