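# Methods

## Scope and data model

The package operates on two modalities. *Beta matrices* hold per-sample,
per-CpG methylation fractions β ∈ [0, 1] with group labels (tumor and one or
more control groups) and, per CpG, a local sequence context with the CpG at
a known offset (0-based, half-open coordinates, '+'-strand representation).
*Count matrices* hold nonnegative integer smMIP read counts with probe
roles — `target`, two human-reference classes (`human_ref_nocpg`,
`human_ref_nomsre`; 300 each by default), and lambda spike-in classes
(`lambda_cut`, n = 12; `lambda_ref`, n = 10) — plus a sample sheet with
group, tissue type and a digested/undigested aliquot flag. The chemistry
being modeled: MSREs cut their recognition site only when its CpG is
unmethylated, so after digestion the read count of a target probe reflects
the methylated (uncut) template fraction.

## Candidate CpG selection

Per control group, each CpG is tested with Welch's unequal-variance t-test
on beta values, two-sided, with Benjamini–Hochberg adjustment across all
CpGs of that comparison; the intersection over comparisons is taken
afterwards. Welch was chosen deliberately over an empirical-Bayes
moderated test: at the cohort sizes this pipeline targets (tens of samples
per group) per-CpG variance is estimable, and the plain test keeps the
filter transparent. CpGs where both groups are exactly constant get p = 1
(equal constants) or p = 0 with a warning (unequal constants), so
degenerate synthetic inputs never crash the cascade.

A candidate must, for *every* control group, satisfy adjusted p ≤ 0.05 and
Δβ = mean(tumor) − mean(control) > 0, control mean ≤ 0.3 and control
SD ≤ 0.1 (applied per group, the stricter reading of "for the healthy
controls"), and an MSRE-site overlap. Survivors are ranked by
min over control groups of Δβ — the minimum, rather than mean or sum,
guarantees both differences are large — with ties broken by CpG id, and
truncated to the top k (default 1000).

MSRE-site scanning expands IUPAC codes positionally and scans both strands
of the context window; a hit counts when its span intersects the two bases
of the CpG dinucleotide. Window positions holding `N` never match. The
default enzyme set — AciI (CCGC), HinP1I (GCGC), Hpy99I (CGWCG), HpyCH4IV
(ACGT) — is a stand-in for a typical four-enzyme double-digest design and
is fully configurable; any analysis tied to a specific assay should supply
its own set.

## Count QC and normalization

Order is fixed: digestion QC → sample exclusion → probe-efficiency filter →
normalization. Percent undigested is 100 × mean(lambda cut-site counts) /
mean(lambda reference counts) within a sample — a ratio of within-sample
means rather than a mean of per-probe ratios, because the cut and reference
sets have different sizes (12 vs 10) and per-probe ratios would be
dominated by low-count probes. Samples strictly above 5% are excluded;
undigested aliquots are exempt, since they exist only to measure capture
efficiency. A target probe is retained when its raw counts summed over all
undigested aliquots reach 1000 (≥ rule; the boundary semantics are logged
and configurable). Normalization divides each target count of a digested
sample by that sample's pooled human-reference total (both reference
classes together), which cancels the library factor exactly — the
operation is invariant to scaling all of a sample's counts. Normalized
matrices contain non-integer values, which is also how re-submission of
normalized data as raw counts is detected and rejected.

## Classifier

Each probe gets a univariate two-class Gaussian LDA: class means μ₀, μ₁,
pooled within-class variance σ² (denominator n − 2), priors from class
proportions, posterior P(1|x) = σ(ax + b) with a = (μ₁−μ₀)/σ² and
b = (μ₀²−μ₁²)/(2σ²) + ln(π₁/π₀). Zero pooled variance is a degenerate-model
error. Decision cutoffs (posterior scale) are chosen by exhaustive scan
over the midpoints of adjacent sorted unique scores plus the sentinels 0
and 1 — a finite set complete with respect to achievable confusion
matrices — maximizing accuracy with ties resolved toward the smallest
threshold (favoring sensitivity).

Cross-validation uses k = 5 folds stratified by tissue type (per-stratum
fold counts differ by at most one; deterministic under the seed). Per
fold, the model is fit on the training folds and held-out samples are
scored by posterior; fold AUC is the rank statistic with ties counted 0.5,
and cvAUC is the unweighted mean over folds containing both classes.
Probes with cvAUC < 0.8 are dropped; among tiled probes of one CpG the
highest cvAUC wins (ties: higher cumulative undigested counts, then probe
id).

The ensemble counts votes: probe i votes for a sample when its posterior
reaches its cutoff, and the sample is called positive when votes ≥ C. The
evaluation protocol is strictly out-of-fold: within each fold all
single-probe models *and their cutoffs* are refit on the training folds and
votes recorded on held-out samples; C maximizes accuracy on the pooled
out-of-fold votes (ties: higher balanced accuracy, then smaller C), and the
reported confusion matrix pools out-of-fold predictions at that C. The
deployable model is then refit on all samples with cutoffs re-derived on
the full data; both cutoff sets are serialized. This choice resolves an
ambiguity inherent in combining k-fold evaluation with a single deployable
cutoff — resubstitution would be the optimistic alternative — and both
numbers are reported so the gap is visible. Per-fold ROC curves are traced
over all integer vote thresholds and averaged vertically on a fixed
false-positive-rate grid.

Two-step classification: Model A (positive = tumoral) gates Model B
(positive = PM); a sample below Model A's cutoff is `nontumoral` and Model
B is never consulted; above it, Model B decides `mesothelioma` vs
`metastasis`. Model B's positive class is PM, consistent with a
specificity-1.0 operating point where metastases are the negatives.

## Evaluation utilities

Confusion metrics keep full precision internally and round half-up to 3
decimals only at the reporting layer (29/31 → 0.935); ratios with zero
denominators are reported as NA, never 0. Welch's t-test returns the
statistic, Welch–Satterthwaite fractional df and two-sided p. Classical
(Torgerson) MDS double-centers −D²/2 on Euclidean distances over the
model's probe subset, takes the top eigenpairs and scales eigenvectors by
√eigenvalue; negative eigenvalues are truncated to zero with a warning and
missing positive dimensions are zero-padded.

## Synthetic data

The generator exists to give every stage inputs with the statistical
structure the analysis assumes, with known ground truth.

*Beta cohorts*: all CpGs sit at a control level (default mean 0.15,
SD 0.05) in every group; a chosen subset (default 50 of 5000) is shifted up
by `tumor_delta` (default 0.4) in the tumor group only. Noise is a Beta
distribution reparameterized by (mean, sd) — bounded and heteroskedastic
like array betas — with the SD shrunk where infeasible for the mean. Default
cohort sizes are 30 samples per group, the scale of a single-center tissue
collection.

*Count matrices*: expected target count in a digested sample is
`library factor × capture efficiency × [m + (1−m)(1−d)]` with m the
methylation fraction and d the digestion efficiency (default 0.99);
undigested aliquots and human reference probes carry the full
methylation-independent signal, and lambda cut sites survive at rate 1−d.
Counts are negative binomial with var = μ + φμ² (φ = 0.1 by default); the
φ → 0 limit returns rounded expectations deterministically, giving a
closed-form check. Library factors are lognormal (CV 0.3) and capture
efficiencies log-uniform on (0.5, 2) across human probes; lambda spike-in
probes use unit capture efficiency, mirroring a control set designed for
uniform capture — this is what makes the percent-undigested statistic an
unbiased estimate of 100(1−d). Undigested aliquots are generated as
separate pseudo-samples (default 3 per batch) flagged in the sample sheet.

*Target panels*: each context window (41 nt) receives a concrete expansion
of a random enzyme's recognition site aligned so its CpG coincides with the
scored CpG; deliberately non-assayable contexts are rebuilt from A/T until
no site overlaps. Tiling multiplicities follow a configurable
single:double:triple plan apportioned by largest remainder (the default
270:463:11 over 744 targets yields 1229 probes).

The four-group assay cohort (`generate_two_step_cohort`, 20 samples per
group) carries one probe block methylated in all tumoral samples and one
methylated only in PM, at 0.85 versus a 0.08 background — deliberately
strong effects. What passing tests on these cohorts demonstrate is that the
machinery is correct: filters select what they should, cross-validation and
cutoff selection behave, and the cascade recovers planted structure. They
do not demonstrate clinical performance: real cohorts have intermediate
effect sizes, tumor-fraction dilution, batch structure and correlated
probes, none of which the generator emulates.

## Determinism and numerics

Every stochastic step takes an explicit seed; fixed seed and configuration
give byte-identical outputs, including run manifests (which therefore
contain no timestamps). Tie-breaks are everywhere deterministic and
documented (smallest posterior cutoff, balanced accuracy then smallest C,
probe/CpG id lexicographic). Constancy checks use exact equality rather
than variance thresholds so float summation noise cannot flip the
degenerate-input rules. Posteriors use the numerically stable logistic;
values saturate to 0/1 in float arithmetic for extreme inputs, which the
rank-based AUC and threshold scans tolerate by construction.

## Known limitations

- The enzyme set, probe tiling and spike-in layout are configurable
  defaults, not a claim about any specific commercial assay.
- The efficiency filter requires undigested aliquots; the documented bypass
  flag skips it but leaves inefficient probes in the panel.
- Univariate LDA ignores correlation between probes; the vote ensemble
  inherits that independence assumption.
- MDS embeddings use Euclidean distance on normalized counts; heavy-tailed
  probe distributions may warrant a variance-stabilizing transform first,
  which is left to the caller.
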