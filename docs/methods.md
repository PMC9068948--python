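# Methods

## Problem and scope

The pipeline models a serum-miRNA screening test for early-stage ovarian
cancer. A fixed 14-member circulating miRNA signature is measured either by
a multiplexed particle-fluorescence assay (mouse xenograft studies, with 9
endogenous reference miRNAs and background/spike-in/blank control wells) or
by small-RNA sequencing (human case/benign/healthy cohort). A one-hidden-
layer perceptron converts the normalized signature into a cancer
probability; a global sensitivity analysis prunes the panel; confusion/ROC
metrics at a 50% cutoff and Bayes prevalence arithmetic translate the
classifier into screening terms. No real measurements ship with the
package: a synthetic-data module generates cohorts with the statistical
structure the analysis assumes, and every claim the tests make is about
recovery behaviour on those cohorts.

## Synthetic cohorts

**Fluorescence (mouse).** Designs are configurable; two constructors cover
the study layouts: a training design of 10 controls + 3 cell lines × 10
animals at 5×10⁵ cells, and a dose-range validation design of 15 controls +
5 animals each at 5×10⁴/5×10⁵/5×10⁶ cells, all bled at days 0/5/28 in
technical triplicates. Signal for probe *j* in animal *i* at day *t* is

    log2 level = baseline_j + s_j · f(t) · [tumor] + biological noise,

with `f(0)=0`, `f(5)=0.4` (configurable), `f(28)=1`: a saturating time
course whose day-28 value is independent of inoculum, so dose groups share
one steady-state effect. Biological noise is normal on the log2 scale
(SD 0.5 by default) drawn per animal×timepoint and shared by that well's
technical replicates, which add multiplicative log-normal noise (CV 8%).
Measured fluorescence is `2^level × tech-noise + background`, with
per-well background `N(50, 10)` AU; background-control probes and blank
wells measure background alone. Reference miRNAs are trend-free with
per-probe log2 dispersion; the defaults give miR-222 and miR-181a the two
smallest dispersions, encoding the assay-stability finding the
normalization step assumes. Effect sizes default to 0.8–2.0 log2 units
(all "up", matching the serial-increase behaviour of tumor markers); the
study never quantifies per-miRNA serum effects, so these are free
parameters and all performance claims are recovery claims, not predictions
of real-assay accuracy.

**Sequencing (human).** 75 cancer / 100 benign / 100 healthy subjects.
Each probe (14 signature members plus a 150-probe background
transcriptome) gets a deterministic baseline relative abundance; group
effects multiply signature abundances by `2^(±lfc)` (defaults: 14 members,
both directions, |lfc| 1.2–2.0, cancer-only; benign masses default to no
signature effect — their profiles are uncharacterized, and the config can
grant them partial effects). Counts are negative binomial (dispersion 0.2)
around the renormalized proportions of a log-normal library depth (mean
10⁶, CV 20%), then converted to TPM. Depth is a nuisance parameter —
TPM cancels it — so a desk-scale depth keeps simulation cheap without
changing the analysis.

**What the generators do not emulate:** plate/batch effects, probe
cross-hybridization, hemolysis and other pre-analytic artifacts,
correlated miRNA co-regulation, and any tumor-growth kinetics. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under idealized noise, not that the assay performs at any particular level
on real sera.

## Preprocessing

Order is fixed: background-correct, then normalize. Per sample, the mean
of the background-control probes is subtracted and values are floored at
ε = 1 AU (configurable) so logs stay defined; blank wells and control
columns are dropped. Reference stability is the coefficient of variation
of log2 signal across samples (smaller = more stable; ties break
lexicographically); references with sub-floor signal are excluded with a
warning. The two most stable references normalize the signature:
`log2(probe / geometric mean of the pair)` — the geometric-mean convention
matches multiplicative assay noise and makes the result exactly invariant
to per-sample intensity scaling. Sequencing data instead use
`log2(TPM + 1)` restricted to the signature; TPM is the standard per-sample
tags-per-million (rows sum to 10⁶ exactly). Technical replicates collapse
to per-(subject, timepoint) means (median or keep available).

## Classifier

Architecture: `h = g(W1ᵀx + b1)`, `p = logistic(w2·h + b2)`. The hidden
link `g` is linear, logistic, tanh or exponential; the output link is
fixed to logistic so the output is a probability compatible with the 50%
decision cutoff. The exponential link clamps its argument to ±30 to avoid
overflow (documented contract; its derivative is zero outside the clamp).
Inputs are standardized with training-split means/SDs stored in the model,
so saved models apply to raw data reproducibly.

Loss is mean binary cross-entropy computed through the logit (numerically
stable) plus an L2 penalty λ‖W‖² on weights (not biases), λ = 10⁻⁴ by
default — enough to tame the exponential link without materially biasing
the others. Gradients are exact analytic back-propagation; a property test
checks them against central finite differences on every run. Training is
full-batch quasi-Newton minimization: the default implementation is the
compiled limited-memory BFGS (`scipy`'s L-BFGS-B), with dense-Hessian BFGS
selectable; on these ~10²–10³-parameter networks the two find equivalent
minima, and the limited-memory path is an order of magnitude faster, which
is what makes the 500-candidate searches below practical. The best loss
seen along the optimization path is returned (iteration cap 80–100 by
default; the search uses 80).

Weight initialization is i.i.d. normal(0, 0.5²) from a per-candidate seed.
The loss surface is non-convex; the architecture search's many random
(width, link, seed) draws double as restarts.

## Splits and architecture search

Splitting is by subject, stratified by class, so replicates and timepoints
of one subject never straddle splits (leakage guard). Split sizes use
largest-remainder rounding with residuals carried across classes so the
totals equal the whole-cohort apportionment (275 at 3:1:1 → 165/55/55;
40 at 75/25 → 30/10).

The search samples candidates uniformly: hidden width from
`[⌈p/3⌉, ⌊1.5p⌋]` for `p` inputs, link from the admissible set, plus an
initialization seed — all from one seeded stream, so enlarging the search
extends it (a longer search can never select a worse test-split model).
Selection is by test-split balanced accuracy (robust to the cohorts'
moderate class imbalance); ties prefer fewer hidden neurons, then the
earlier candidate. The desk-scale default is 200–500 candidates; the
behaviour being tested (recovery, leakage) is insensitive to making this
larger.

## Sensitivity pruning

Usefulness of input *j* is the loss-inflation ratio after neutralizing its
column — mean substitution by default (permutation averaging over seeded
shuffles as an alternative), evaluated on the test split, consistent with
test-split model selection. Pruning repeatedly removes the lowest-ratio
variable and re-runs the search on the reduced panel (the width range
shrinks with `p`); a removal is accepted while the selected model's test
metric does not fall more than 0.01 (absolute) — an explicit stopping
tolerance standing in for "remove until removal hurts". With strongly
separable data the metric plateaus at 1.0 and pruning would run to the
floor, so workflows that mirror the 14→7 panel reduction set
`min_features = 7`; which seven survive is then decided entirely by the
sensitivity ranking, and the recovery tests check that planted-informative
members survive over pure-noise members.

## Evaluation and screening arithmetic

A score exactly at the cutoff is a positive call. AUC is the tie-aware
Mann-Whitney statistic (ties count ½), equal to the trapezoidal area under
the ROC curve; a brute-force pairwise oracle verifies exact agreement in
the tests. The default AUC interval is DeLong's (deterministic,
variance from midrank placements, normal interval truncated to [0, 1]);
a stratified bootstrap percentile interval is available.

PPV/NPV follow Bayes' rule from sensitivity, specificity and prevalence;
`fold_risk(π) = PPV/π → sens/(1−spec)` as π → 0. At the 73%/91% operating
point and 1% prevalence these give NPV 99.71% and fold-risk 7.57.
Confidence bands on prevalence curves come from binomial resampling of the
validation confusion table (tp* ~ Bin(tp+fn, sens), tn* ~ Bin(tn+fp,
spec)), with resampled rates clipped half a count away from 0/1 so the
Bayes formulas stay defined; bands are forced to contain the point curve.
The default grid is log-spaced from 0.0007 (general-population prevalence)
to 0.40 (BRCA1-carrier lifetime risk).

## Cohort statistics

Volcano tables use two-sided Mann-Whitney tests on log2 values with
Benjamini–Hochberg adjustment across probes (constant probes get p = 1,
flagged); the fold change is the difference of group means of log2 values.
Serial trends use the Jonckheere–Terpstra test for ordered alternatives
across timepoints within a group, tie-aware, with the exact permutation
null enumerated for total n ≤ 12 and the normal approximation otherwise
(the no-tie variance formula is used under ties — slightly conservative
for heavily tied data). Clustering z-scores each probe, then applies Ward
linkage on Euclidean distances; leaf order is deterministic (denser
subtree left, ties to the smaller sample index) and trees export to
Newick. Test choices (Mann-Whitney, BH, JT, Ward on z-scores) are
field-standard defaults; none is dictated by the underlying design.

## Mouse workflow unit of analysis

Classification uses day-28, replicate-collapsed (animal-level) samples:
tumor-inoculated animals at baseline are biologically identical to
controls, so earlier timepoints would carry wrong labels by construction,
and replicate wells share a biological draw, so well-level analysis would
pseudoreplicate. Well-level evaluation remains available via the
`replicate_policy="keep"` switch.

## Problem sizes used by the test suite and acceptance script

The suite's end-to-end checks run the full 275-subject cohort with
500-candidate searches and pruning over 10 seeds, and a 20-seed null
calibration (all effects zero) at 100 candidates; the acceptance script
runs one seed of each workflow (150–500 candidates). These sizes were
chosen so the whole battery runs on a single CPU in well under half an
hour while keeping the Monte-Carlo margins comfortable.

## Known limitations

* The synthetic effect sizes are free parameters; reported AUCs on
  synthetic cohorts characterize the pipeline, not the assay.
* The sensitivity-pruning stopping tolerance (0.01) and the
  `min_features = 7` mirror are policy choices; on weakly separable data
  the tolerance, not the floor, will govern where pruning stops.
* The NPV/PPV bands assume the validation confusion counts are binomial —
  no between-cohort heterogeneity.
* No batch correction, probe-level QC beyond background/blank handling, or
  read-level sequencing processing; inputs are matrices.
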