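# Methods

## Data model

An `ExpressionDataset` is a nonnegative gene × sample matrix with a layout
mapping each sample to a `(treatment, replicate)` pair. All statistics key on
the layout, never on column order. Missing cells (NaN) are never imputed: an
operation excludes any gene with a missing or nonpositive value in the
samples it uses and reports the exclusion count. Gene ids are opaque strings;
there are no coordinate or strand semantics anywhere. Delimiters of input
tables are auto-detected among tab/comma/semicolon and can be forced.

## Ratio-statistics reproducibility coefficients

For treatments a ≠ b with replicates r ∈ reps(a), s ∈ reps(b), the ratio
population P(a,r; b,s) holds the per-gene ratios x_{i,a,r}/x_{i,b,s} over all
genes with positive values in both samples (pairwise exclusion by default; a
listwise flag restricts every population to genes positive in all samples).
Both ordered directions (a,b) and (b,a) are built — keeping X/Y and Y/X as
separate measurements symmetrizes the skew of raw ratios around 1 without a
log transform, which would compress the very differences being measured.
With n treatments of r replicates each there are n(n−1)·r² populations
(48 for the 4×2 design).

Replicate substitution compares populations that share the same source
sample (a, r) and differ only in the target replicate: for each unordered
pair {s, s′} of b's replicates, the statistic ratios M(r,s)/M(r,s′) and
S(r,s)/S(r,s′) are formed (n(n−1)·r·C(r,2) comparisons per statistic; 24 + 24
for 4×2). Cross-source comparisons are deliberately not formed: substituting
the target replicate isolates the disagreement between two replicates of one
treatment while everything else is held fixed. Each ratio v > 0 is folded
into a deviation

    d(v) = v − 1      if v ≥ 1,
    d(v) = 1/v − 1    otherwise,

so d(v) = d(1/v) ≥ 0 and d = 0 iff v = 1. The **average of deviations** and
the **standard deviation of deviations** are the two reproducibility
coefficients. Mean- and SD-statistic deviations are pooled into one
coefficient by default; the per-statistic averages are always reported
alongside, and a `per-statistic` pooling flag makes the mean-statistic
average the headline number. The sample (n−1) SD convention is the default
everywhere, with a population-SD flag for parity with spreadsheet tools.

Degenerate SD comparisons (either S exactly 0, e.g. constant ratio
populations) are skipped and counted, never treated as 0 or infinite; a
warning is raised when exactly one of the two SDs is zero, since that is an
asymmetric degeneracy worth seeing.

Coefficients are descriptive, not inferential, and are data-dependent:
values should not be compared across unrelated experiments.

The between-replicates variant forms, within one treatment, the ratio
population between every ordered replicate pair (k, l); perfect
reproducibility makes its mean 1 and its SD 0, so the folded deviation of the
mean, averaged over pairs, is the coefficient, with the population SDs
reported alongside.

**Invariants** (tested): equality with a literal brute-force enumeration on
all small designs; invariance under a global rescaling of the matrix;
invariance under relabeling the replicates of any treatment; zero noise ⇒
exactly zero coefficients; monotone response to the replicate-noise level.

## Replicate QC

Per-gene variation is the fold ratio max(x,y)/min(x,y) − 1 — symmetric,
scale-invariant, and interpretable as "variation > 50% ⇔ the larger value
exceeds 1.5× the smaller". The exceedance fraction uses strict `>` by
default with an inclusive flag (both readings of a "50% or higher" cutoff
appear in practice). Regression is ordinary least squares of y on x *with*
intercept (the default of the plotting tools this diagnostic mirrors);
a through-origin slope is reported alongside since the convention is not
universal. Pearson r and its two-tailed p come from the same scale as the
regression (linear, log2 or log10); genes with a zero in either replicate are
excluded from log-scale fits and counted — no silent pseudocounts (an
explicit pseudocount argument exists). The log-distortion caveat is
mechanical: y = 2x has slope 2 linearly but slope 1 (intercept log 2) after
logging, so log-scale slopes near 1 must not be read as absence of bias.

Narrow-interval summaries restrict the scatter to genes whose replicate mean
falls in a window [low, high] and report the maximum and quantiles (default
0.5, 0.9, 0.95) of the fold deviation — small windows expose fold-level noise
the full dynamic range hides. An empty window is a valid result (n = 0), not
an error.

## Fold-change thresholds

The empirical null for technical noise is the pooled distribution of
within-treatment inter-replicate fold-changes FC = max/min ≥ 1 over the
requested replicate pairs (pooling across pairs is the default; per-pair
thresholds are also emitted by the CLI). The threshold at level α is the
smallest *observed* FC value t with #{FC ≥ t}/n < α: between observed values
the exceedance is flat, so observed values are the only meaningful
candidates. If even the maximum fails (ties at the maximum), the threshold is
placed just above it and flagged. The postcondition P(FC ≥ threshold) < α is
asserted on every constructed result. At application time, significant genes
(the significance flag is consumed from an external differential-expression
procedure, never produced here) pass only with FC strictly above the
threshold; "same or lower" is sub-threshold.

Grouped thresholds recompute the same rule within length or mean-abundance
bins (monotone edge list; last bin right-closed). Bins with fewer than 20
fold-changes are flagged as unstable; empty bins yield no threshold.

## Normalization

- **RPKM**: count × 10⁹ / (total mapped reads × length bp); totals default to
  column sums, overridable.
- **Total-count**: each column scaled to a common library size (mean library
  by default); factors recorded.
- **Reference-gene**: within each treatment the first replicate in sorted
  label order anchors; replicate k is multiplied by the mean over reference
  genes of (anchor value / replicate-k value). The anchor choice is
  arbitrary but declared and recorded in metadata; with a single reference
  gene the correction drives that gene's inter-replicate variation to zero
  exactly.
- **Quantile**: each column's values are replaced by the across-sample mean
  of order statistics at their rank, ties by rank-average (the RMA
  convention). Columns end up as identical multisets and the operation is
  idempotent; it requires a complete matrix.

Every corrected dataset carries a `NormalizationRecord` (method, parameters,
per-sample factors) in its metadata.

## ORF-length protein correction

CF_i = L_i / min_j L_j (so min CF = 1 exactly, CF is unit-free and invariant
to rescaling all lengths), CPF_i = PF_i × CF_i. The correction always
multiplies the protein side; an inverse flag is deliberately omitted to keep
the direction unambiguous. It applies identically to fold-changes and to raw
quantities. The correlation-shift report computes Pearson and Spearman on
(transcript, protein) and (transcript, CPF); constant vectors give NaN
("undefined"), never 0. The correction is deliberately minimal — a pure
translation-time argument. It does not model elongation-rate variation,
ramp effects near the start codon, ribosome occupancy/density, or
mRNA/protein half-lives; those are out of scope, not approximated.

## Synthetic data

The generator draws x_{i,t,k} = baseline_i × effect_{t,i} × exp(σ_rep z),
z ~ N(0,1) iid, with a log-normal baseline (default log-mean 5, log-sd 2,
giving the multi-decade dynamic range of real expression data) and a
rice-like default design of 4 treatments × 2 replicates and 10 000 genes.
Noise is multiplicative log-normal because the toolkit's statistics are
ratio-based; the closed form P(max/min ≥ f) = 2Φ(−ln f/(σ_rep√2)) then links
σ_rep directly to the "fraction of genes with >(f−1)·100% variation". The
default σ_rep ≈ 0.632 solves this for a 65% fraction at f = 1.5 — the level
seen in uncorrected bulk read counts — and is verified against a Monte-Carlo
oracle in the tests. All randomness flows through one seeded
`numpy.random.Generator`; identical configs are bit-identical.

The paired transcript/protein generator produces PF = (TF / CF) × noise by
default — the length mechanism the correction inverts, so at zero noise
correction restores PF·CF = TF and the corrected correlation is exactly 1.
An explicit per-gene protein response overrides the length-derived response
entirely (the caller supplies the observed fold, any length effect already
included), which is how regulated responses are injected.

What the generator does *not* emulate: count discreteness and negative
binomial overdispersion, gene-gene correlation, composition effects, batch
structure, or length-dependent noise. Passing tests therefore demonstrate
the correctness and calibration of the statistics under the multiplicative
model, not robustness to every artifact of real libraries.

## Numerical choices

- Sample SD (ddof = 1) by default; population SD behind a flag, applied
  consistently to population S and to the SD of deviations.
- Ratios are computed in double precision without logs; deviations are exact
  arithmetic on the ratio.
- Report serialization uses `repr`-shortest float formatting, which
  round-trips doubles exactly (read→write→read is bit-stable).
- Threshold candidates are scanned via a sorted/`searchsorted` pass that is
  equivalent to (and tested against) the brute-force candidate scan.
- Degenerate inputs: < 2 treatments, < 2 replicates, empty distributions,
  zero-variance regressors and zero column sums are hard errors; empty
  narrow intervals and empty bins are flagged results.

## Problem sizes

The test suite and the acceptance script use 2–5 genes for exact
hand-enumerable cases, a few hundred genes for monotonicity checks, and
10 000 genes (the generator default) for tail-calibration and threshold
quantities — enough for the binomial error on a 65% fraction to be ~0.5
percentage points. Everything runs in seconds on one core.
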