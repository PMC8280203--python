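# scmirna

Evaluation toolkit for **single-cell small RNA sequencing**: a tested,
reusable implementation of the analysis pipeline used to benchmark
miRNA-seq library-preparation protocols down to single-cell input —
read preprocessing with adapter-dimer accounting, spike-in–based
quantification-accuracy and reproducibility metrics, UMI-based molecule
counting, and single-cell miRNA profiling QC/clustering — together with
a synthetic library generator that produces ground-truth-annotated
FASTQ libraries for end-to-end validation.

## Who this is for

Method developers and analysts comparing small RNA library-prep
protocols (ligation adapters, UMIs, randomized 4N ligation ends,
adapter-dimer suppression) on very low input — single cells, single-cell
equivalents, or equimolar spike-in pools — who need the downstream
statistics to be reproducible and testable against known ground truth.

## What it computes

- **Preprocessing** (`scmirna.preprocess`): UMI extraction into the read
  header, 3′ quality trimming at Q20 (BWA-style running partial sum), up
  to three rounds of 3′-artifact removal (3′ adapter, PCR primer, polyA
  and polyG tails) by semi-global alignment at a 10 % error rate, then
  read QC: reads with < 4 nt after trimming are **adapter dimers**,
  < 18 nt are too short, > 2 N bases fail quality. Deterministic
  subsampling (default 300,000 reads, seed 42).
- **Quantification** (`scmirna.quantify`): fitting alignment of each
  trimmed read inside every reference sequence (identity
  `1 − errors/read length`, threshold 0.80), best-hit counting,
  reads-per-million-mapped (RPMM) normalization, detection calls
  (count ≥ 1), and hierarchical RNA-class assignment over an 18-class
  priority list (miRNA first, protein-coding gene last; ≥ 90 % read
  overlap, multi-mapped loci pooled, otherwise *intergenic*).
- **Deduplication** (`scmirna.dedup`): UMI adjacency-network molecule
  counting per (sample, feature) — UMIs at Hamming distance 1 are
  connected; groups grow greedily from the highest-read UMI — plus
  reads-per-UMI duplication statistics and per-cell molecule totals.
- **Metrics** (`scmirna.metrics`): quantification accuracy as the
  coefficient of variation CV = σ/μ of spike-in expression per sample
  (an equimolar pool should be flat); reproducibility as Euclidean
  distances on log₂ expression split within/between protocols; Spearman
  association of detection rate with G-content; cell QC (≥ 50 miRNA
  molecules); log-normalization `ln(1 + x·10⁴/library)`;
  variance-stabilizing variable-feature ranking; PCA → shared-nearest-
  neighbor graph → Louvain clustering with a UMAP embedding; adjusted
  mutual information between labelings.
- **Simulation** (`scmirna.simulate`): libraries with configurable
  protocol architecture (adapters, 6/8-nt UMI, 4N flanks, 75-nt reads),
  adapter-dimer load, sequence-dependent capture bias
  `p_i ∝ exp(β_g·g_i + ε_i)` on G-content, shifted-negative-binomial PCR
  duplication (default mean 4.74 reads/molecule), substitution errors
  and low-quality tails — all with a per-read ground-truth table.

## Worked example

```python
from scmirna import simulate as sim, preprocess as pp, quantify as qt, \
    dedup as dd, metrics as mx

refs = sim.generate_reference(n_seqs=1006, seed=7)        # equimolar pool
arch = sim.ProtocolArchitecture(name="SBN", umi_len=8)
cfg  = sim.LibrarySimConfig(n_reads=50_000, frac_dimer=0.3, seed=1)
lib  = sim.simulate_library(refs, arch, cfg)

kept, qc = pp.preprocess_reads(lib.reads, pp.TrimConfig(), umi_len=8)
print(f"kept: {qc.counts[pp.TrimStatus.KEPT]}  "
      f"adapter_dimer: {qc.fraction(pp.TrimStatus.ADAPTER_DIMER):.3f}")

hits   = qt.map_to_reference(kept, refs)
matrix = qt.count_features({"SBN_r1": hits}, refs.feature_ids)
rpmm   = qt.rpmm_normalize(matrix.layer("raw"))
_, detected, _ = qt.detection_calls(matrix.layer("raw"))
cv = mx.coefficient_of_variation(rpmm["SBN_r1"], all_feature_ids=refs.feature_ids)

table = dd.UMITable.from_reads(kept, qt.best_hits(hits), "SBN_r1")
mols  = dd.molecules_per_cell(dd.dedup_table(table))
```

prints (and the later lines evaluate to):

```
kept: 33638  adapter_dimer: 0.299
mapped reads: 31208   detected spike-ins: 981 / 1006
spike-in CV: 0.741
miRNA molecules: 6623  mean reads/UMI: 4.43
```

Reading: the configured 30 % dimer load is recovered (0.299); nearly all
of the 1006 equimolar spike-ins are detected; the CV of 0.74 reflects
the simulated capture bias plus PCR duplication (a perfectly unbiased,
duplication-free library would sit near the multinomial sampling floor);
deduplication collapses ~31 k mapped reads to ~6.6 k molecules at
~4.4 reads per UMI, close to the configured duplication depth of 4.74.

The same flow is available as a CLI over a single YAML config:

```bash
scmirna validate --config run.yaml     # normalized config + provenance
scmirna run      --config run.yaml     # simulate → … → metrics + manifest
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — two
protocol architectures × three simulated 50,000-read replicates, seeded
entirely from `--seed` — and writes the JSON target report to `--out`
(intermediate matrices, QC tables and the run manifest land next to it):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the statistical model behind the simulator,
every tunable with its default and rationale, numerical conventions
(tie-breaks, log bases, CV variants), what the synthetic data does and
does not emulate, and known limitations — including a worked analysis of
why multi-round adapter trimming deterministically drops a small
fraction of reference features and how that propagates into the spike-in
CV.
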