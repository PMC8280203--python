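"""Identity-thresholded mapping of trimmed reads against a short-RNA
reference, hierarchical RNA-class assignment, counting, RPMM
normalization and detection calls.

Mapping is a fitting (semi-global) alignment of the read inside each
full-length reference: the read must align end-to-end, reference
overhangs are free, substitutions and indels cost one error each.
Identity is ``1 - errors / read_length`` and a hit requires identity at
or above the threshold (default 0.80, the standard percent-identity
cutoff for spike-in read mapping). Genome-scale alignment is out of
scope; class assignment consumes externally produced (or simulated)
per-read alignment intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .refio import (
    CLASS_PRIORITY,
    INTERGENIC,
    AnnotationTrack,
    CountMatrix,
    ReferenceSet,
    SmallRNARecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    feature_id: str
    identity: float
    errors: int
    is_best: bool


class _ReferenceIndex:
    """Exact-substring index plus a padded integer matrix for the DP.

    Any zero-error occurrence of a read inside a reference is an exact
    substring match, so a dictionary over all reference substrings of at
    least ``min_sub_len`` bases resolves error-free reads in O(1).
    """

    QGRAM = 4

    def __init__(self, refs: ReferenceSet, min_sub_len: int = 15):
        self.refs = refs
        self.feature_ids = sorted(refs.entries)
        seqs = [refs.sequence(f) for f in self.feature_ids]
        self.max_len = max(len(s) for s in seqs)
        self.matrix = np.full((len(seqs), self.max_len), 255, dtype=np.uint8)
        self.lengths = np.array([len(s) for s in seqs])
        for i, s in enumerate(seqs):
            self.matrix[i, : len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
        self.substrings: dict[str, list[str]] = {}
        for fid, s in zip(self.feature_ids, seqs):
            for a in range(len(s)):
                for b in range(a + min_sub_len, len(s) + 1):
                    self.substrings.setdefault(s[a:b], []).append(fid)
        for fids in self.substrings.values():
            fids.sort()
        # q-gram presence mask per reference (last column: never-matching
        # sink for q-grams containing N)
        q = self.QGRAM
        self.qgram_mask = np.zeros((len(seqs), 4**q + 1), dtype=np.uint8)
        for i, s in enumerate(seqs):
            for code in _qgram_codes(s, q):
                if code < 4**q:
                    self.qgram_mask[i, code] = 1


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _qgram_codes(seq: str, q: int) -> np.ndarray:
    """Integer codes of all overlapping q-grams; q-grams containing a
    non-ACGT base map to the sink code 4**q."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(arr) < q:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, q)
    bad = (windows < 0).any(axis=1)
    codes = (windows * (4 ** np.arange(q - 1, -1, -1))).sum(axis=1)
    codes[bad] = 4**q
    return codes


def _fitting_errors(
    index: _ReferenceIndex, read: str, rows: np.ndarray | None = None
) -> np.ndarray:
    """Minimum fitting-alignment edit distance of ``read`` against every
    reference (or the subset ``rows``), vectorised across references
    (unit-cost substitutions and indels; reference overhangs free at both
    ends)."""
    q = np.frombuffer(read.encode(), dtype=np.uint8)
    L = len(q)
    matrix = index.matrix if rows is None else index.matrix[rows]
    lengths = index.lengths if rows is None else index.lengths[rows]
    R, W = matrix.shape
    # D[r, j]: distance of read prefix vs reference r ending at column j
    D = np.zeros((R, W + 1), dtype=np.int32)
    cols = np.arange(W + 1, dtype=np.int32)
    big = np.int32(10**6)
    pad_mask = np.concatenate(
        [np.zeros((R, 1), dtype=bool), cols[1:][None, :] > lengths[:, None]],
        axis=1,
    )
    for i in range(1, L + 1):
        mism = (matrix != q[i - 1]).astype(np.int32)
        cand = np.minimum(D[:, :-1] + mism, D[:, 1:] + 1)
        full = np.concatenate([np.full((R, 1), i, dtype=np.int32), cand], axis=1)
        # gap-in-reference (read-insertion) closure: running minimum of
        # full[k] + (j - k) over k <= j
        D = np.minimum.accumulate(full - cols, axis=1) + cols
    D = np.where(pad_mask, big, D)
    return D.min(axis=1)


def _candidate_rows(
    index: _ReferenceIndex, read: str, min_identity: float
) -> np.ndarray:
    """References that could reach the identity threshold.

    Two exact lower bounds on the fitting edit distance prune the rest:
    the length bound (a read longer than a reference needs at least the
    difference in insertions) and the q-gram bound (each error corrupts at
    most q of the read's overlapping q-grams; the survivors must occur in
    the reference).
    """
    L = len(read)
    e_max = int((1.0 - min_identity) * L + 1e-9)
    ok = (L - index.lengths) <= e_max
    q = index.QGRAM
    if L >= q:
        codes = _qgram_codes(read, q)
        need = (L - q + 1) - q * e_max
        if need > 0:
            counts = index.qgram_mask[:, codes].sum(axis=1)
            ok &= counts >= need
    return np.nonzero(ok)[0]


def map_to_reference(
    reads: Iterable[SmallRNARecord],
    refs: ReferenceSet,
    min_identity: float = 0.80,
    best_only: bool = True,
    index: _ReferenceIndex | None = None,
) -> list[AlignmentHit]:
    """Map trimmed reads against the reference set.

    Per read, every reference at identity >= ``min_identity`` is a hit and
    the best-identity hit(s) are flagged; counting later uses exactly one
    best hit per read (ties resolve to the lexicographically smallest
    feature id).

    With ``best_only`` (the default) reads that occur verbatim inside a
    reference report only their identity-1.0 hits, skipping the alignment
    of strictly worse references; ``best_only=False`` always aligns
    against every reference and returns the complete hit list.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if index is None:
        index = _ReferenceIndex(refs)
    hits: list[AlignmentHit] = []
    for read in reads:
        seq = read.sequence
        if not seq:
            continue
        if best_only:
            exact = index.substrings.get(seq)
            if exact is not None:
                for fid in exact:
                    hits.append(AlignmentHit(read.read_id, fid, 1.0, 0, True))
                continue
        rows = _candidate_rows(index, seq, min_identity)
        if len(rows) == 0:
            continue
        errors = _fitting_errors(index, seq, rows)
        identity = 1.0 - errors / len(seq)
        ok = np.nonzero(identity >= min_identity - 1e-12)[0]
        if len(ok) == 0:
            continue
        best = identity[ok].max()
        for j in ok:
            hits.append(
                AlignmentHit(
                    read.read_id,
                    index.feature_ids[rows[j]],
                    float(identity[j]),
                    int(errors[j]),
                    bool(abs(identity[j] - best) < 1e-12),
                )
            )
    return hits


def best_hits(hits: Sequence[AlignmentHit]) -> dict[str, str]:
    """Resolve each read to exactly one feature: its best-identity hit,
    ties broken by lexicographically smallest feature id."""
    resolved: dict[str, tuple[float, str]] = {}
    for h in hits:
        if not h.is_best:
            continue
        cur = resolved.get(h.read_id)
        if cur is None or h.identity > cur[0] or (
            h.identity == cur[0] and h.feature_id < cur[1]
        ):
            resolved[h.read_id] = (h.identity, h.feature_id)
    return {rid: fid for rid, (_ident, fid) in resolved.items()}


def assign_class(
    read_alignments: Mapping[str, Sequence[tuple[str, int, int]]],
    track: AnnotationTrack,
    min_overlap: float = 0.90,
) -> dict[str, str]:
    """Hierarchical class assignment.

    For each read, collect every annotation class whose interval covers at
    least ``min_overlap`` of the read length, over all the read's
    alignment loci (multi-mapped reads contribute all loci), and assign
    the highest-priority class present; reads with no qualifying class are
    intergenic. Strand is ignored.
    """
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    rank = {c: i for i, c in enumerate(CLASS_PRIORITY)}
    out: dict[str, str] = {}
    for rid, loci in read_alignments.items():
        best_rank = len(CLASS_PRIORITY)
        for contig, start, end in loci:
            read_len = end - start
            if read_len <= 0:
                continue
            for iv in track.overlapping(contig, start, end):
                if iv.overlap(start, end) >= min_overlap * read_len - 1e-9:
                    r = rank[iv.class_label]
                    if r < best_rank:
                        best_rank = r
        out[rid] = CLASS_PRIORITY[best_rank] if best_rank < len(CLASS_PRIORITY) else INTERGENIC
    return out


def class_distribution(assignments: Mapping[str, str]) -> pd.Series:
    """Per-class read fractions (the per-sample RNA-class profile)."""
    s = pd.Series(list(assignments.values()), dtype="object")
    frac = s.value_counts(normalize=True)
    return frac.reindex(list(CLASS_PRIORITY) + [INTERGENIC], fill_value=0.0)


def count_features(
    hits_per_sample: Mapping[str, Sequence[AlignmentHit]],
    feature_ids: Sequence[str],
) -> CountMatrix:
    """Raw read counts per feature and sample from best-hit-resolved reads;
    unmapped reads are excluded."""
    sample_ids = list(hits_per_sample)
    data = pd.DataFrame(
        0, index=list(feature_ids), columns=sample_ids, dtype=np.int64
    )
    for sample, hits in hits_per_sample.items():
        for rid, fid in best_hits(hits).items():
            data.loc[fid, sample] += 1
    return CountMatrix(
        feature_ids=list(feature_ids),
        sample_ids=sample_ids,
        layers={"raw": data},
    )


def rpmm_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Reads per million mapped: scale each sample column to a 10^6 total
    over mapped features. All-zero columns are left at zero with a warning."""
    sums = raw.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("all-zero columns left unnormalized: %s", list(sums.index[zero]))
    safe = sums.replace(0, np.nan)
    out = raw.astype(float) * 1e6 / safe
    return out.fillna(0.0)


def detection_calls(
    raw: pd.DataFrame, threshold: int = 1
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Detection at a minimum raw count (default: at least one read).

    Returns the boolean detection matrix, per-sample detected-feature
    counts and per-feature detection rates (fraction of samples detected).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    detected = raw >= threshold
    per_sample = detected.sum(axis=0)
    per_feature_rate = detected.mean(axis=1)
    return detected, per_sample, per_feature_rate


def load_alignment_tsv(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Import hook for externally produced per-read alignment intervals
    (columns: read_id, contig, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.read_id), []).append(
            (str(row.contig), int(row.start), int(row.end))
        )
    return out
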