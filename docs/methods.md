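# Methods

This note documents the models, conventions and design choices behind
`scmirna`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. The problem

Small RNA sequencing from single-cell-level input is dominated by
artifacts of ligation-based library preparation: adapter dimers
(5′–3′ adapter ligation products with no insert), strong
sequence-dependent capture bias, and heavy PCR duplication. Comparing
protocol variants therefore needs (i) an accounting of dimer load,
(ii) an accuracy measure against a known equimolar spike-in pool,
(iii) molecule counting through unique molecular identifiers (UMIs),
and (iv) reproducibility and clustering statistics on the resulting
expression matrices. `scmirna` implements this evaluation pipeline and
a generative model of the libraries it is meant to analyse, so every
stage can be validated against ground truth.

## 2. Synthetic library model

A library of `n_reads` reads is a mixture of four read classes drawn
multinomially: miRNA-insert reads (the remainder), adapter dimers
(`frac_dimer`), fragments of a small annotated synthetic genome
(`frac_other_rna`, inserts of 30–70 nt overlapping non-miRNA features),
and junk (`frac_junk`; half N-riddled inserts that fail the ≤ 2 N rule,
half inserts of 4–17 nt that fail the length rule).

**Read layout (5′→3′).** `[UMI] + [4N flank] + insert + [4N flank] +
3′ adapter`, padded with G to the 75-nt read length (emulating the
dark-cycle polyG tail of two-channel sequencers) or truncated at 75 nt.
Dimer reads have an empty insert. The UMI occupies the first
`umi_len ∈ {0, 6, 8}` bases; 4N flanks (4 random nt at each ligation
site) are present only for 4N-family protocol architectures.

**Reference pool.** `generate_reference` draws `n_seqs` unique
sequences of 20–25 nt. Per-sequence G fraction comes from a
Beta(5.5, 16.5) distribution — mean 0.25, sd 0.09, matching the base
composition of real mature-miRNA pools; the remaining probability mass
is split evenly over A/C/T. An early wider profile (mean 0.25,
sd 0.17) was rejected as unphysical: its G-rich tail produces ≥ 9-nt
G runs that legitimate polyG-tail trimming consumes, turning whole
features into spurious adapter dimers.

**Capture bias.** Each feature's probability of contributing a molecule
is

    p_i ∝ exp(β_g · g_i + ε_i),   ε_i ~ Normal(0, σ²),

with `g_i` the feature's G fraction. `β_g = σ = 0` recovers the uniform
equimolar limit. Defaults `β_g = 1.5`, `σ = 0.5` give a mild positive
G-content detection bias plus per-feature noise. Note the σ that would
reproduce the accuracy of real best-case protocols (spike-in CV ≈ 1.5)
is ≈ 1; the default is deliberately milder so that individual effects
remain distinguishable in tests. `bias_seed` lets replicates of one
protocol share a bias profile while replicating independently.

**PCR duplication.** Reads per molecule are `1 + NegBin(r, p)` with
mean `pcr_mean_reads_per_molecule` (default 4.74, a realistic
single-cell duplication depth) and dispersion `r = pcr_dispersion`
(default 2). Molecules are drawn until the miRNA read budget is
covered; the last molecule is truncated to fit exactly.

**UMIs and errors.** UMIs are uniform random `umi_len`-mers per
molecule. With `unique_umis=True` they are rejection-sampled to
pairwise Hamming distance ≥ 2 within each feature — necessary for exact
molecule-recovery tests, because adjacency grouping merges
distance-1 UMI pairs by construction. Substitution errors hit every
base (UMI included) independently at `seq_error_rate` (default 0.002);
a `low_quality_tail_frac` of reads get a 5–25-nt 3′ tail of Phred < 12.
Indels, quality-score autocorrelation and instrument-specific error
profiles are *not* modeled.

One `numpy` generator seeded once per library drives all draws in a
fixed order (category counts → bias → molecules → duplication → UMIs →
assembly → errors → qualities), so identical configs give byte-identical
FASTQ and ground-truth output.

## 3. Preprocessing

Order: UMI extraction → one pass of 3′ quality trimming → ≤ 3 rounds of
adapter removal → classification.

- **Quality trimming** uses the running-partial-sum rule: walking from
  the 3′ end, accumulate `q_i − cutoff` (cutoff 20) and cut where the
  sum is most negative; ties keep the longest read.
- **Adapter search** (`find_adapter`) is a semi-global alignment:
  the full adapter may occur anywhere (everything from its start is
  removed), or a ≥ 3-nt adapter *prefix* may sit at the read's 3′ end.
  Substitutions and indels cost 1; a candidate is accepted iff
  `errors ≤ max_error_rate × matched_length` (default 10 %). Among
  acceptable candidates the fewest errors win, ties to the leftmost
  start. PolyA/polyG tails are 10-nt homopolymer adapters under the
  same error rule but must match at full length — a trailing `AAA` on
  an insert is signal, not a tail. Each round removes at most one
  artifact (earliest match across all adapters); rounds stop when
  nothing is found.
- **Classification** by post-trim length: < 4 nt → adapter dimer
  (precedence over everything else), < 18 nt → too short, > 2 N bases →
  quality fail, else kept. For 4N protocols the flanks are clipped from
  both insert ends before classification. The ≤ 2 N rule is evaluated
  after trimming.
- **Subsampling** is uniform without replacement, order-preserving,
  deterministic given its seed (default 300,000 reads, seed 42). It is
  *not* bit-compatible with external subsampling tools; determinism
  holds only within this package.

Implementation note: the adapter DP runs behind three provably lossless
fast paths (exact-substring search, a pigeonhole k-mer screen, and a
vectorised error-only DP); an exhaustive per-start DP oracle in the
test suite checks exact agreement on random reads.

### Known consequence: deterministic feature dropout

With multi-round trimming and ≥ 3-nt terminal prefix matching — the
standard trimmer semantics — any insert whose 3′ end equals the first
≥ 3 bases of the 3′ adapter loses those bases in the round after the
adapter itself is removed. Inserts of 20–21 nt then drop below the
18-nt minimum, and since this depends only on the sequence, *every*
read of such a feature is lost (~1.4 % of a 20–25-nt pool with the
default adapter). This is faithful to how the real pipeline behaves; it
matters for interpretation of the spike-in CV (§5) and for
molecule-recovery checks, which therefore compare against ground truth
restricted to QC-surviving reads.

## 4. Quantification and deduplication

- **Mapping** is a fitting alignment: the read aligns end-to-end inside
  the full-length reference, reference overhangs are free, unit costs.
  Identity is `1 − errors / read_length` (the spec of record for the
  denominator is the read, which for trimmed inserts equals the
  alignment span up to rare indels); hits require identity ≥ 0.80.
  Counting uses exactly one best hit per read, ties resolved to the
  lexicographically smallest feature id. Genome-scale spliced alignment
  is out of scope; class assignment consumes per-read alignment
  intervals from the simulator or an external TSV/BAM-derived table.
- **Class assignment** collects every annotation class covering ≥ 90 %
  of the read length over all its loci and assigns the highest-priority
  class of an 18-class hierarchy (miRNA, miRNA primary transcript,
  tRNA (GtRNAdb), Mt-tRNA, rRNA, Mt-rRNA, snoRNA, snRNA, sRNA, scaRNA,
  scRNA, piRNA, misc RNA, ribozyme, coding exon, lncRNA, ncRNA,
  protein-coding gene); no qualifying class → intergenic. Strand is
  ignored. Coordinates are 0-based half-open internally; GFF3 is
  converted on IO.
- **RPMM**: each sample column scaled to 10⁶ over mapped features.
- **Dedup** builds, per (sample, feature), the graph connecting UMIs at
  Hamming distance exactly 1 (no read-count ratio condition) and
  resolves it greedily: repeatedly take the unassigned UMI with the
  most reads (ties: lexicographically smallest — a determinism
  improvement over arbitrary tie-breaking) plus its unassigned
  neighbours as one molecule. UMIs containing N are dropped with a
  logged count. `group_by_length` (default on) deduplicates
  per trimmed read length within a feature, mirroring
  read-length-aware deduplication; per-feature molecule counts sum
  over lengths.

## 5. Metrics

- **CV** is the sample (n−1) standard deviation over the mean of one
  sample's spike-in expression (RPMM by default). Default mode includes
  *all* reference features, zeros included — the equimolar truth
  expects every feature present, so dropout is a real deviation.
  `detected_only=True` gives the alternative convention. The two can
  differ a lot: in an idealized (zero-bias, duplication-free,
  error-free) 500k-read simulation the detected-only CV sits at the
  multinomial floor (≈ 0.044 for ≈ 500 reads/feature) while the
  all-features CV is ≈ 0.13, entirely driven by the ~1.4 % deterministic
  trimming dropout of §3 (k features zeroed among F inflate CV² by
  ≈ k/F). The acceptance test for the idealized calibration asserts the
  all-features contract and is expected to fail; it documents this
  analysis rather than silently switching modes.
- **Reproducibility**: Euclidean distance on `log₂(x + 1)` between
  sample columns (RPMM by default; the layer is configurable), each
  unordered pair once, partitioned into within- and between-protocol
  sets.
- **G-content association**: Spearman rank correlation (average ranks
  on ties) between per-feature detection rate and G fraction, with the
  large-sample p-value. In the simulator's isolation design
  (β_g = 1.5, σ = 0, ~1.5 molecules/feature, 12 libraries) this lands
  at ρ ≈ 0.44; per-feature lognormal noise and shallow depth attenuate
  it (σ = 0.5 at 6 × 2.5k reads gives ρ ≈ 0.21).
- **Cell QC**: keep cells with ≥ 50 deduplicated miRNA molecules —
  the floor that separates real single cells from reagent-only negative
  controls (worked example: totals 7 and 14 are rejected, 60 passes).
- **Log-normalization**: natural log, `ln(1 + x·scale/library)`,
  scale 10,000.
- **Variable features** ("vst"): lowess fit (span 0.3, local linear) of
  log₁₀ variance on log₁₀ mean across features; raw counts are
  standardized by the predicted sd, clipped at ±√n_samples (the
  reference recipe clips only the upper tail; symmetric clipping is
  used here and documented because it can reorder borderline features);
  features are ranked by the variance of the standardized values.
- **Embedding/clustering**: PCA (full SVD, component signs anchored to
  the largest-magnitude loading so results are feature-order
  invariant) → kNN (self included) → shared-nearest-neighbor graph with
  Jaccard edge weights → Louvain at the configured resolution → UMAP on
  the same PCs with a fixed random state. Defaults: 15 PCs, k = 20
  (shrunk to n−1 for small n), resolution 1.4, 15 UMAP neighbours.
  Fewer than 3 samples is an error; requested PCs are shrunk to
  `min(features, samples) − 1`.
- **AMI** uses the arithmetic-mean normalization variant (variants
  differ in the second decimal); a direct hypergeometric expected-MI
  computation in the test suite pins the value.

## 6. What a green test does and does not establish

The generator reproduces the statistical structure the metrics respond
to — dimer load, G-content capture bias, per-feature lognormal noise,
PCR duplication depth, N/short-read junk, low-quality tails — with
known ground truth, so recovery tests are exact. It does not emulate:
ligation thermodynamics or secondary-structure effects (bias is a
one-parameter G-content model), indel sequencing errors, quality-score
correlation structure, carry-over between samples, genome-scale
multimapping, or isomiR heterogeneity. Green recovery tests therefore
validate the pipeline's logic, not the biological completeness of the
bias model.

## 7. Numerical conventions and edge cases

- Error-rate acceptance uses `errors ≤ rate·length + 1e−9` to keep
  float products (e.g. 0.1 × 20) from flipping the comparison.
- All-zero sample columns stay zero under RPMM and log-normalization,
  with a warning; a CV over a zero-mean sample is an error.
- Phred offset is 33 unless configured; N bases are forbidden in
  references, tolerated (≤ 2) in kept reads, and UMIs containing N are
  excluded from deduplication.
- Every stochastic step takes an explicit seed; the pipeline refuses a
  config without one, and derives per-sample seeds from the run seed
  via a seed sequence so sample order is immaterial to other samples'
  draws.

## 8. Known limitations

- The adapter-prefix dropout of §3 is inherent to the trimming rules;
  pools designed to avoid adapter-prefix 3′ ends would not show it.
- Hamming-1 UMI merging slightly undercounts molecules when true UMIs
  collide at distance 1 (expected for 8-nt UMIs at high molecule
  counts); `unique_umis` exists to remove this effect in tests, not to
  model reality.
- The subsampler, clusterer and UMAP are deterministic per seed but not
  guaranteed stable across library versions.
- `reads_per_umi` with `group_by_length` sums distinct UMIs over length
  strata; a UMI observed at two trimmed lengths counts twice (the
  strata are treated as separate molecules by construction).
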