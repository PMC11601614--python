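# Methods

## Signal model and problem setting

A SNP array reports, for every probe, a Log R Ratio (LRR) and a B Allele
Frequency (BAF). At copy number 2 the LRR is centred at 0 and BAF clusters at
0, 0.5 and 1 (genotypes AA/AB/BB). A copy-number change shifts both: a
heterozygous deletion (one copy) removes the 0.5 cluster and depresses LRR; a
homozygous deletion leaves essentially no allele-specific signal and a
strongly negative LRR; a duplication (three copies) moves heterozygous BAF to
1/3 and 2/3 and raises LRR; a triplication (four copies) moves it to
1/4, 1/2, 3/4. The package classifies, per sample and per predefined region,
whether such an event is present — it does not segment the genome or call
breakpoints.

## Region geometry

A region is a gene (bundled hg38 table: PRKN, LINGO2, MAPT, SNCA;
user-extensible via a TSV with the same columns) or an explicit
chromosome/start/stop. A symmetric buffer (default 250,000 bp; clamped at
position 1) is added before window computation so signal flanking the gene is
visible to the model; for very large events a larger buffer (e.g. 10 Mb
around SNCA) is appropriate.

Region length is `L = stop − start` and all interval logic is half-open
`[start, end)`. Two integers control the layout:

* `split` — window length `W = floor(L / split)`;
* `total_windows` — `n` windows at stride `s = floor((L − W) / (n − 1))`
  (`s = 0` when `n = 1`).

The unbuffered PRKN interval pins the arithmetic: `L = 1,380,245`,
`W = 276,049` at split 5, `s = 22,534` at `n = 50`. MAPT under the same
formula gives `W = 26,790` and `s = 2,186`.

Numerical choices: the last window's end is raised to the interval stop so
flooring never truncates coverage; when `n = split` leaves a remainder the
floored stride can exceed `W` by up to `split − 1` bases, so the stride is
capped at `W`, keeping the tiling gapless in every accepted configuration;
configurations whose stride would floor to 0 with `n > 1` are rejected
rather than emitting duplicate windows.

## Candidate rules and features

Manufacturer-recommended ranges flag "CNV candidate" SNPs with strict
inequalities: LRR < −0.2 (deletion), LRR > 0.2 (duplication), and the open
insertion-pattern bands BAF ∈ (0.15, 0.35) ∪ (0.65, 0.85). A separate
inclusive band [0.15, 0.85] feeds mid-range BAF features. Missing LRR/BAF
never qualifies a SNP.

Per window, statistics are computed over four subsets — candidates,
insertion-band SNPs, mid-range SNPs, and all SNPs present. The deletion
catalog (13 features) uses candidate count / fraction / LRR mean, SD, IQR /
BAF mean, SD; mid-range count and BAF mean; and all-SNP count, LRR mean, LRR
SD, BAF mean. The duplication catalog (11 features) swaps the candidate BAF
moments for insertion-band count and fraction and drops the all-SNP LRR SD
and BAF mean. These exact lists are this package's own selection, constrained
to the candidate-dominated design and the 13/11 dimensionalities the printed
model-ready shapes require; most statistics deliberately derive from the
candidate subset.

Conventions pinned by tests: SD is the population (n-denominator) form; IQR
is Q3 − Q1 with linear interpolation; empty subsets impute 0 for every
statistic (a zero candidate count is itself signal, and the arrays stay
dense); a single-SNP subset has SD = IQR = 0. Features are z-scored per
feature across all samples and windows of the training array; the
center/scale vectors persist with the model, and inference-time arrays must
be built with those statistics — predicting from unscaled or differently
scaled arrays is an error, guarding against silent distribution shift. A
zero-variance feature gets scale 1 rather than dividing by zero.

## The scorer

Three LSTM layers (default 64/32/16 units) are stacked, each passing its full
hidden sequence to the next; the final hidden state feeds one dense unit with
a hard-sigmoid activation, `clamp(0.2x + 0.5, 0, 1)`, fixing slope 0.2 and
intercept 0.5 (definitions vary across frameworks, so one is pinned and
tested). Gates also use the hard sigmoid; the cell candidate and output
squash with tanh. The implementation is plain numpy — forward pass,
backpropagation through time, Adam at its usual defaults (lr 1e-3, β₁ 0.9,
β₂ 0.999) — verified against central-difference numerical gradients in the
test suite. Loss is binary cross-entropy with probabilities clipped to
[1e-7, 1 − 1e-7] since the hard sigmoid saturates exactly.

Training defaults: batch 32, at most 100 epochs, early stopping with
patience 10 and best-weight restore, monitoring a stratified validation
split when `validation_fraction > 0` and the training loss otherwise.
Initialisation is Glorot-uniform with forget-gate bias 1. Given a config
seed, initialisation and batch shuffling derive from one generator and
training is bitwise reproducible. Hidden sizes, batch and schedule are
declared defaults for training sets of a few hundred samples, not tuned
values.

Evaluation: AUC is computed by the Mann–Whitney rank formulation (ties count
1/2; cross-checked in tests against a brute-force pairwise oracle and
scikit-learn), the Brier score is the mean squared error of the
probabilities, and stratified k-fold (default 5) cross-validation reports
per-fold AUCs, their mean and the pooled out-of-fold Brier score. The 0.5 and
0.8 thresholds are reporting conventions (calling and review-flagging
respectively), not part of the model.

Model artifacts bundle architecture metadata, weights, scaling statistics
and training history in one versioned `.npz`; loading restores predictions
bit-for-bit and refuses artifacts of the wrong CNV type or version.

## Synthetic cohorts

The simulator emulates the input table: probe positions uniform over the
buffered region (default density 1 SNP/kb, roughly a dense array's coverage
of a well-tiled locus), per-SNP B-allele frequencies uniform on
[0.05, 0.95], genotypes Hardy–Weinberg given the state's copy number, BAF
normal around the genotype cluster mean (SD 0.03, truncated to [0, 1];
uniform noise at copy number 0) and LRR normal per state: diploid N(0, 0.15),
heterozygous deletion N(−0.45, 0.20), homozygous deletion N(−2.5, 0.5),
duplication N(+0.30, 0.18), triplication N(+0.55, 0.20). These parameters
are invented stand-ins — chosen once so that event SNPs cross the ±0.2
candidate thresholds often but not always (e.g. only ~71% of duplication
SNPs exceed +0.2) — because the arrays the pipeline targets do not come with
published noise figures. Carriers receive one event, sized uniformly on
53–455 kb (the span of validated deletions the method is expected to
resolve) and placed uniformly inside the unbuffered gene interval; GenTrain
scores are clipped normal (0.8, 0.1).

What passing on this generator shows: the windowing, aggregation, scaling and
sequence model recover localized dosage shifts of realistic size against
realistic cluster overlap, end to end, deterministically. What it does not
show: robustness to GC waves, batch effects, heteroskedastic probe noise,
mosaic events, multi-event samples or array-specific artifacts — none of
which are simulated. Performance numbers on synthetic cohorts are therefore
upper bounds, not estimates of accuracy on real cohort data.

## Reviewer feedback loop

Scored cohorts export a review table (sample, region, CNV type, prediction,
variant count, LRR min/max/mean, flagged at prediction ≥ 0.8, sorted by
descending prediction) and a per-SNP plot file for LRR/BAF-vs-position
rendering; any viewer that reads delimited text can display them. Reviewer
logs (Yes/Maybe/No with ISO-8601 timestamps) are ingested with latest-wins
resolution within a log; Yes → 1, No → 0, Maybe excluded so ambiguous
samples are never mislabeled negative. Training-set accretion is a union
with duplicate-key rejection: an existing label is never silently
overwritten, conflicts are returned for human attention, and each sample
records the accretion round it arrived in.

## Limitations

Binary, fixed-region output (no per-window localisation); one event per
simulated carrier; no genotype-cluster or probe-level QC beyond the GenTrain
cutoff; the feature catalogs, while dimensionally pinned, are one reasonable
selection among several; CPU-only training, practical to a few thousand
samples per region.
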