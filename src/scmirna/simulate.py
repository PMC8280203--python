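"""Synthetic single-cell small RNA library generator with ground truth.

Emulates the statistical structure of ligation-based small-RNA libraries
built from an equimolar spike-in pool: sequence-dependent (G-content)
capture bias, protocol-specific UMI/adapter read architecture, adapter
dimers, PCR duplication per molecule, base-call errors and low-quality
3' tails. Every emitted read carries a ground-truth record (origin class,
origin feature, true UMI, molecule id) so downstream recovery can be
tested exactly.

Read layout (5'->3'): [UMI] + [5' 4N flank] + insert + [3' 4N flank] +
3' adapter, padded with G to the read length (emulating the dark-cycle
polyG tail of two-channel Illumina chemistry) or truncated at the read
length. Adapter dimers carry an empty insert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .refio import (
    AnnotationTrack,
    Interval,
    ReferenceSet,
    SmallRNARecord,
)

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: Standard Illumina small-RNA ligation adapters (stand-ins for real
#: protocol oligos, which are protocol-specific and configurable).
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclass
class ProtocolArchitecture:
    """Read architecture of one library-prep protocol variant.

    ``umi_len`` is 8 for the UMI-bearing ligation protocols, 6 for the
    shortened-UMI variants, 0 for UMI-free protocols; ``flank4n_len`` is 4
    for protocols with four random nucleotides at the ligation sites.
    """

    name: str = "SBN"
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    umi_len: int = 8
    flank4n_len: int = 0
    read_len: int = 75

    def __post_init__(self) -> None:
        if self.umi_len not in (0, 6, 8):
            raise ValueError("umi_len must be one of 0, 6, 8")
        if self.flank4n_len not in (0, 4):
            raise ValueError("flank4n_len must be 0 or 4")
        if not self.adapter3 or not self.adapter5:
            raise ValueError("adapters must be non-empty")


@dataclass
class LibrarySimConfig:
    """Mixture weights, bias, duplication and noise parameters of one
    simulated library.

    Defaults target the behaviour the metrics respond to on real
    single-cell libraries: a substantial dimer load, a PCR duplication
    depth of ~4.74 reads per molecule, and a mild positive G-content
    capture bias.
    """

    n_reads: int = 50_000
    frac_dimer: float = 0.3
    frac_other_rna: float = 0.05
    frac_junk: float = 0.02
    bias_beta_g: float = 1.5
    bias_sigma: float = 0.5
    pcr_mean_reads_per_molecule: float = 4.74
    pcr_dispersion: float = 2.0
    seq_error_rate: float = 0.002
    low_quality_tail_frac: float = 0.05
    unique_umis: bool = False
    seed: int = 0
    #: share one capture-bias profile across replicates of a protocol by
    #: fixing this; None derives it from ``seed`` (per-library profile)
    bias_seed: int | None = None

    def __post_init__(self) -> None:
        total = self.frac_dimer + self.frac_other_rna + self.frac_junk
        if total > 1 + 1e-12:
            raise ValueError("mixture fractions exceed 1")
        if self.pcr_mean_reads_per_molecule < 1:
            raise ValueError("pcr_mean_reads_per_molecule must be >= 1")
        if self.pcr_dispersion <= 0:
            raise ValueError("pcr_dispersion must be > 0")


GROUND_TRUTH_COLUMNS = [
    "read_id",
    "origin_class",
    "origin_feature",
    "true_umi",
    "molecule_id",
]


def generate_reference(
    n_seqs: int,
    len_range: tuple[int, int] = (20, 25),
    gc_profile: tuple[float, float] = (5.5, 16.5),
    seed: int = 0,
) -> ReferenceSet:
    """Generate a synthetic equimolar-pool reference of unique short RNAs.

    Per-sequence G fraction is drawn from a Beta distribution
    (``gc_profile`` = (alpha, beta)) so the pool spans a wide G-content
    range; remaining bases are A/C/T uniformly. Deterministic given
    ``seed``.
    """
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    lo, hi = len_range
    if not (15 <= lo <= hi <= 30):
        raise ValueError("reference lengths must lie in [15, 30]")
    rng = np.random.default_rng(seed)
    alpha, beta = gc_profile
    entries: dict[str, tuple[str, str]] = {}
    seen: set[str] = set()
    width = len(str(n_seqs))
    for i in range(n_seqs):
        for attempt in range(1000):
            length = int(rng.integers(lo, hi + 1))
            g_frac = float(rng.beta(alpha, beta))
            probs = [(1 - g_frac) / 3] * 4
            probs[2] = g_frac  # index of G in BASES
            seq = "".join(rng.choice(BASES, size=length, p=probs))
            if seq not in seen:
                break
        else:
            raise RuntimeError(
                f"could not draw a unique sequence after 1000 attempts (n={n_seqs})"
            )
        seen.add(seq)
        entries[f"syn-mir-{i + 1:0{width}d}"] = (seq, "miRNA")
    return ReferenceSet(entries)


def capture_probabilities(
    refs: ReferenceSet, beta_g: float, sigma: float, seed: int = 0
) -> pd.Series:
    """Per-feature capture probability under a log-linear G-content bias.

    ``p_i ∝ exp(beta_g * g_i + eps_i)`` with ``eps_i ~ Normal(0, sigma^2)``,
    normalised to sum to 1. ``beta_g = sigma = 0`` recovers the uniform
    (equimolar) limit.
    """
    if len(refs) == 0:
        raise ValueError("reference set is empty")
    rng = np.random.default_rng(seed)
    g = refs.g_content_series()
    eps = rng.normal(0.0, sigma, size=len(g)) if sigma > 0 else np.zeros(len(g))
    logit = beta_g * g.to_numpy() + eps
    w = np.exp(logit - logit.max())
    return pd.Series(w / w.sum(), index=g.index, name="capture_p")


def generate_genome(
    length: int = 10_000,
    n_features: int = 20,
    seed: int = 0,
    contig: str = "synchr1",
) -> tuple[str, AnnotationTrack]:
    """A small synthetic genome with annotated non-miRNA features, so class
    assignment has realistic competitors for reads that are not spike-ins."""
    rng = np.random.default_rng(seed)
    genome = "".join(rng.choice(BASES, size=length))
    classes = ["rRNA", "snoRNA", "GtRNAdb", "lncRNA", "protein_coding", "snRNA"]
    intervals = []
    # non-overlapping feature placement on a coarse grid
    slots = np.sort(rng.choice(length // 200 - 1, size=min(n_features, length // 200 - 1), replace=False))
    for i, slot in enumerate(slots):
        start = int(slot) * 200 + int(rng.integers(0, 50))
        span = int(rng.integers(80, 150))
        cls = classes[i % len(classes)]
        intervals.append(
            Interval(contig, start, min(start + span, length), "+", cls, f"{cls}-{i}")
        )
    return genome, AnnotationTrack(intervals)


@dataclass
class SimulatedLibrary:
    reads: list[SmallRNARecord]
    ground_truth: pd.DataFrame
    alignments: pd.DataFrame  # genome-true intervals for other_rna reads


def simulate_library(
    refs: ReferenceSet,
    arch: ProtocolArchitecture,
    cfg: LibrarySimConfig,
    genome: str | None = None,
    genome_track: AnnotationTrack | None = None,
    sample_id: str = "S1",
) -> SimulatedLibrary:
    """Simulate one library of exactly ``cfg.n_reads`` reads.

    Draw order is fixed (category counts -> capture bias -> molecules ->
    duplication -> UMIs -> per-read assembly -> errors -> qualities) so a
    given config reproduces byte-identical output.
    """
    if arch.read_len < arch.umi_len + 4:
        raise ValueError("read_len shorter than umi_len + 4")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    frac_mirna = 1.0 - cfg.frac_dimer - cfg.frac_other_rna - cfg.frac_junk
    counts = rng.multinomial(
        n, [cfg.frac_dimer, cfg.frac_other_rna, cfg.frac_junk, max(frac_mirna, 0.0)]
    )
    n_dimer, n_other, n_junk, n_mirna = (int(c) for c in counts)

    derived_bias_seed = int(rng.integers(2**31))
    probs = capture_probabilities(
        refs,
        cfg.bias_beta_g,
        cfg.bias_sigma,
        seed=cfg.bias_seed if cfg.bias_seed is not None else derived_bias_seed,
    )
    feature_ids = list(probs.index)

    # molecules + duplication: draw molecules until their reads cover the
    # miRNA read budget, truncating the last molecule's reads to fit
    mol_features: list[str] = []
    mol_reads: list[int] = []
    total = 0
    mu = cfg.pcr_mean_reads_per_molecule - 1.0
    r = cfg.pcr_dispersion
    batch = max(16, int(n_mirna / cfg.pcr_mean_reads_per_molecule * 1.2))
    while total < n_mirna:
        feats = rng.choice(feature_ids, size=batch, p=probs.to_numpy())
        if mu > 0:
            dups = 1 + rng.negative_binomial(r, r / (r + mu), size=batch)
        else:
            dups = np.ones(batch, dtype=np.int64)
        for f, d in zip(feats, dups):
            mol_features.append(str(f))
            take = int(min(d, n_mirna - total))
            mol_reads.append(take)
            total += take
            if total >= n_mirna:
                break
        batch = max(16, batch // 4)

    umis = _draw_umis(rng, len(mol_features), arch.umi_len, mol_features, cfg.unique_umis)

    reads: list[SmallRNARecord] = []
    gt_rows: list[tuple[str, str, str, str, str]] = []
    aln_rows: list[tuple[str, str, int, int]] = []
    read_no = 0

    def next_id() -> str:
        nonlocal read_no
        read_no += 1
        return f"{sample_id}:{read_no:07d}"

    def assemble(insert: str, umi: str) -> str:
        flank = arch.flank4n_len
        parts = [umi]
        if flank:
            parts.append("".join(rng.choice(BASES, size=flank)))
        parts.append(insert)
        if flank:
            parts.append("".join(rng.choice(BASES, size=flank)))
        parts.append(arch.adapter3)
        full = "".join(parts)
        if len(full) < arch.read_len:
            full += "G" * (arch.read_len - len(full))
        return full[: arch.read_len]

    def random_umi() -> str:
        if arch.umi_len == 0:
            return ""
        return "".join(rng.choice(BASES, size=arch.umi_len))

    # miRNA molecules
    for mol_idx, (feat, n_dup, umi) in enumerate(zip(mol_features, mol_reads, umis)):
        insert = refs.sequence(feat)
        mol_id = f"{sample_id}:mol{mol_idx + 1}"
        for _ in range(n_dup):
            rid = next_id()
            reads.append(_record(rid, assemble(insert, umi)))
            gt_rows.append((rid, "mirna", feat, umi, mol_id))

    # adapter dimers: empty insert
    for _ in range(n_dimer):
        rid = next_id()
        umi = random_umi()
        reads.append(_record(rid, assemble("", umi)))
        gt_rows.append((rid, "dimer", "", umi, f"{sample_id}:dimer:{rid}"))

    # other RNA: substrings of the synthetic genome overlapping annotation
    if n_other > 0 and genome is None:
        genome, genome_track = generate_genome(seed=int(rng.integers(2**31)))
    for _ in range(n_other):
        rid = next_id()
        umi = random_umi()
        span = int(rng.integers(30, 71))
        if genome_track is not None and genome_track.intervals and rng.random() < 0.8:
            iv = genome_track.intervals[int(rng.integers(len(genome_track.intervals)))]
            lo = max(0, iv.start - span // 4)
            hi = max(lo + 1, min(len(genome) - span, iv.end - span // 2))
            start = int(rng.integers(lo, hi))
            feat = iv.feature_id
        else:
            start = int(rng.integers(0, max(1, len(genome) - span)))
            feat = ""
        insert = genome[start : start + span]
        reads.append(_record(rid, assemble(insert, umi)))
        gt_rows.append((rid, "other_rna", feat, umi, f"{sample_id}:other:{rid}"))
        contig = genome_track.intervals[0].contig if genome_track and genome_track.intervals else "synchr1"
        aln_rows.append((rid, contig, start, start + span))

    # junk: N-riddled inserts or inserts too short to keep
    for j in range(n_junk):
        rid = next_id()
        umi = random_umi()
        if j % 2 == 0:
            length = int(rng.integers(18, 31))
            insert = list("".join(rng.choice(BASES, size=length)))
            n_ns = int(rng.integers(3, 7))
            for p in rng.choice(length, size=min(n_ns, length), replace=False):
                insert[p] = "N"
            insert = "".join(insert)
        else:
            insert = "".join(rng.choice(BASES, size=int(rng.integers(4, 18))))
        reads.append(_record(rid, assemble(insert, umi)))
        gt_rows.append((rid, "junk", "", umi, f"{sample_id}:junk:{rid}"))

    # shuffle read order so classes interleave as in a real run
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    gt = pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)
    gt = gt.set_index("read_id").loc[[r.read_id for r in reads]].reset_index()

    # base-call errors
    if cfg.seq_error_rate > 0:
        for rec in reads:
            seq = np.frombuffer(rec.sequence.encode(), dtype="S1")
            hits = np.nonzero(rng.random(len(seq)) < cfg.seq_error_rate)[0]
            if len(hits):
                seq = seq.copy()
                for p in hits:
                    current = seq[p].decode()
                    choices = [b for b in "ACGT" if b != current]
                    seq[p] = rng.choice(choices).encode()
                rec.sequence = seq.tobytes().decode()

    # qualities: high baseline, a fraction of reads get a low-quality 3' tail
    if cfg.low_quality_tail_frac > 0:
        for rec in reads:
            if rng.random() >= cfg.low_quality_tail_frac:
                continue
            L = len(rec.sequence)
            quals = np.full(L, 37, dtype=np.uint8)
            tail = min(int(rng.integers(5, 26)), L)
            quals[L - tail :] = rng.integers(2, 12, size=tail)
            rec.qualities = quals

    aln = pd.DataFrame(aln_rows, columns=["read_id", "contig", "start", "end"])
    return SimulatedLibrary(reads=reads, ground_truth=gt, alignments=aln)


def _record(read_id: str, sequence: str) -> SmallRNARecord:
    # uint8 keeps half-million-read libraries compact
    return SmallRNARecord(
        read_id=read_id,
        sequence=sequence,
        qualities=np.full(len(sequence), 37, dtype=np.uint8),
    )


def _draw_umis(
    rng: np.random.Generator,
    n: int,
    umi_len: int,
    features: Sequence[str],
    unique: bool,
) -> list[str]:
    """One UMI per molecule. With ``unique=True``, UMIs within a feature are
    rejected until pairwise Hamming distance >= 2, so adjacency grouping
    can recover molecules exactly."""
    if umi_len == 0:
        return [""] * n
    umis: list[str] = []
    per_feature: dict[str, list[str]] = {}
    for i in range(n):
        for _ in range(10_000):
            umi = "".join(rng.choice(BASES, size=umi_len))
            if not unique:
                break
            existing = per_feature.setdefault(features[i], [])
            if all(_hamming_ge2(umi, u) for u in existing):
                break
        else:
            raise RuntimeError("UMI space exhausted for unique draw")
        umis.append(umi)
        if unique:
            per_feature[features[i]].append(umi)
    return umis


def _hamming_ge2(a: str, b: str) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism >= 2:
                return True
    return False


def write_ground_truth(gt: pd.DataFrame, path: str | Path) -> None:
    gt.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
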