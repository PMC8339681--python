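# Methods

## Model overview and assumptions

`splicecall` treats each spliced alignment of a junctional read as a noisy
observation of a binary event: the read either arose from genuine splicing
at the aligned junction (y = 1) or from an artifact (y = 0). Three stages
turn read-level evidence into cohort-level calls.

**Stage 1 — read scoring.** A logistic regression with an L1 penalty is
fitted *per sample* (one 10x lane or one Smart-seq2 cell), which lets the
model absorb sample-specific batch effects. Training labels are proxy
labels: a junctional read that also has a contiguous (N-free) alignment
anywhere in the sample is treated as a negative, all others as positives.
The proxy rests on the assumption that a read genuinely spanning an intron
should not also fit the genome contiguously; repeats and stutter products
do. Genomic-alignment status is deliberately excluded from the predictors
so the labels do not privilege any feature. Each class is capped at 10,000
reads, sampled uniformly under the run seed. Classes are sampled per
spliced record, so a read spanning two introns can contribute two training
rows.

Predictors (single-end): `AS/read_length`, `NH`, `NM`, `overlap`,
`max_overlap`, `overlap*max_overlap`, soft-clip total, 5-mer entropy.
The interaction is read as main effects plus product, the standard model-
formula convention. Paired-end mode duplicates the seven per-read features
for the mate and adds `location_compatible` and `strand_compatible`
(strand-compatible iff R1 maps forward and R2 reverse on the same
reference; location additionally requires a leftmost-position gap ≤ 1 Mb,
a conventional mate-gap limit). A missing mate contributes zeros with both
flags 0; a contiguous mate contributes its alignment features with the
junction-overhang fields 0.

Features are standardized on the training set and the center/scale frozen
for scoring, preventing leakage from non-training reads. The penalty is a
pure lasso (elastic-net mixing 1) with strength chosen among 13
log-spaced values by 10-fold cross-validated deviance, folds seeded. The
fit is delegated to scikit-learn's `LogisticRegressionCV` (liblinear).
Fitted probabilities are clipped to [1e−6, 1 − 1e−6] because downstream
aggregation divides by p̂ and 1 − p̂.

**Stage 2 — junction scoring.** Records are collapsed by junction identity
(chromosome, first and last intronic base, 1-based; strand is annotation
only, from the XS tag when present). The aggregated score

    P = 1 / (1 + exp Σ_i ℓ_i),   ℓ_i = log((1 − p̂_i)/p̂_i)

is the posterior probability that *all* reads are true under a symmetric
two-hypothesis model with independent reads. Because P decays with N even
for confident reads, it is ranked against a null for the same N built from
the sample's full p̂ pool: for N ≤ 15, 10,000 resampled (with replacement)
aggregates, mid-rank tie handling; for N > 15, a Gaussian for Σℓ with the
pool's per-read log-odds mean and standard deviation (CLT). The boundary
case N = 15 uses the exact resampling branch. Nulls are cached per
distinct N within a sample.

The empirical p-value compares a junction's `P_cum` with the `P_cum`
distribution of *likely-artifact* junctions — those with ≥ 10% of reads
genomically co-aligned (a junction in that set is compared against a null
including itself; the effect vanishes for a large artifact set):

    emp_p = (#{artifact P_cum ≥ observed} + 1) / (M + 1).

The add-one smoothing keeps emp_p > 0 when the observation beats the whole
null, so a downstream median is never dominated by exact zeros. If fewer
than 50 artifact junctions exist (configurable), emp_p falls back to
1 − P_cum and the row is flagged.

**Stage 3 — cohort combination.** Per junction, the median of emp_p across
the samples of an individual is the cohort score; as the number of samples
grows the median converges to the expectation, giving a single consistent
decision per junction and robustness to one spuriously small emp_p among
many tests. Only samples where the junction passes all four filters enter
the median: genomic fraction < 0.1, ≥ 2 distinct alignment start offsets,
mean longest single-base run < 11, mean read entropy > 3. Each filter is
independent evidence of artifact origin. A junction of a single read
cannot show offset diversity and is therefore never median-eligible. A
junction with zero eligible samples receives score 1.0 and a reason flag.
An even count of eligible values takes the mean of the two central ones;
calling is strict (`score < threshold`, default 0.15). Samples where a
junction has no reads contribute nothing to its median.

## Read entropy

Entropy is computed over the overlapping 5-mers of the read sequence.
With N(k_i) the count of unique 5-mer k_i and T the total number of
overlapping positions (L − 4), frequencies f_i = N(k_i)/T sum to one and

    H = − Σ_i f_i ln f_i    (nats).

Normalizing by the total position count (rather than the number of unique
5-mers, which does not form a probability distribution) reproduces the
documented example values: 2.1 for the AC/TC-repeat 60-mer, 4.0 for the
high-complexity 60-mer, the latter equal to ln 56 since all its 5-mers are
distinct. Natural logarithm throughout; base 2 would give 5.8, not 4.0,
for the second example.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cap` | 10,000 | max training reads per class |
| `null_reps` | 10,000 | resampling-null draws |
| `null_boundary` | 15 | N ≤ boundary: resampling null; N > boundary: Gaussian |
| `artifact_frac_threshold` | 0.1 | genomic fraction defining likely-artifact junctions and the genomic-fraction filter |
| `min_artifact_null` | 50 | minimum artifact-set size before the 1 − P_cum fallback |
| `homopolymer_max` | 11 | filter: mean longest base run must be below |
| `entropy_min` | 3 | filter: mean read entropy must exceed (nats) |
| `call_threshold` | 0.15 | cohort-score calling cutoff |

All thresholds echo into the commented TSV headers together with the tool
version, a config hash and the seed. Every stochastic step (training
subsampling, CV folds, null resampling) derives from the run seed; reruns
are byte-identical, with rows sorted by junction key.

## Synthetic data generator

`splicecall.simulate` emits header-complete SAM with declared synthetic
references (no FASTA is materialized — the statistics consume only
alignment records). Defaults define the study conditions: 90 true and 60
artifact junctions, 12 reads each, read length 60, two samples sharing one
junction truth. True-class reads are drawn from high-complexity (iid
uniform) flank sequences, map uniquely (NH mostly 1), carry few mismatches
(Poisson mean 0.2) and receive a contiguous co-alignment with probability
0.02; artifact-class reads come from short tandem-repeat flanks (entropy
below 3), multimap (NH 2–10), carry more mismatches (mean 1.2) and are
co-aligned with probability 0.8. The true:artifact class ratio of 3:2
reflects that genuine junctions outnumber artifacts in real libraries and
makes the proxy-label/truth agreement ≈ 0.91 under the per-class
co-alignment rates above. Alignment scores follow a STAR-like linear
penalty `AS = L − 2·NM − softclip`, so ordering between classes is exact
by construction. Overhangs are uniform on [10, L − 10], which yields
offset diversity at every multi-read junction.

What the generator does **not** emulate: base-quality structure, UMI and
barcode errors (no deduplication is performed anywhere), splice-motif
sequence at junction boundaries, chimeric/supplementary alignments,
fragment-length distributions (the generator is single-end), and the
long-tailed read-depth and junction-frequency distributions of real
libraries. Passing end-to-end tests therefore demonstrates that the
statistics separate the encoded noise structure (low entropy, genomic
co-alignment, multimapping, mismatch load), not performance on any real
dataset.

## Numerical choices and degenerate inputs

- Aggregation uses the log-odds form with `logaddexp`; the ratio and
  log-odds forms agree to 1e−9 over random inputs (tested).
- Resampling-null ranks use the mid-rank (half-weight) tie rule, unbiased
  for degenerate score pools.
- Gaussian null with zero spread falls back to a sign rule (1 / 0.5 / 0
  as the observed log-odds sum is below / at / above the null center) and
  logs a warning.
- A sample whose training classes are not both non-empty aborts with an
  "untrainable sample" error naming the class sizes; a zero-variance
  design matrix is rejected.
- When a read has several spliced alignments only the lowest-HI one is
  kept; secondary spliced alignments beyond it are dropped entirely.
  Multi-intron CIGARs yield one record per N operator, with overhangs
  bounded by the read ends and adjacent N operators.
- Junction coordinate convention matches STAR `SJ.out.tab` (1-based
  first/last intronic base) for ecosystem interoperability.

## Problem sizes

The default synthetic cohort (2 samples × 150 junctions × 12 reads)
completes a full pipeline run in a few seconds; the discrimination test
repeats it over 20 seeds. These sizes were chosen as the smallest at which
all junction-level summaries (offset diversity, artifact-null size ≥ 50,
per-class entropy separation) are simultaneously in their intended
regimes.

## Known limitations

- The proxy training labels are imperfect by design (~9% of synthetic
  reads are mislabeled at the default co-alignment rates); the model
  tolerates this, but heavily repeat-rich samples could push the negative
  class toward genuine junctions.
- The artifact-null membership rule includes the junction under test when
  it qualifies; negligible for M ≥ 50 but conservative for tiny samples.
- Chimeric alignments, fusion and circular junctions are out of scope, as
  is UMI deduplication (delegated to external tools).
- Paired-end mode consumes one name-matched file containing both mates;
  mate resolution across two separate mate files is not implemented.
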