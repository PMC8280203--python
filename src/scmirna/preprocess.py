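"""Read preprocessing: UMI extraction, 3' quality trimming, iterative
adapter removal, QC classification and deterministic subsampling.

The trimming rules mirror the standard small-RNA cleanup of ligation-based
libraries: a Phred-20 3'-quality cut, then up to three rounds of 3'-artifact
removal (3' adapter, PCR primer, polyA and polyG tails) at a 10% error
rate, followed by read QC (at most 2 N bases, minimum length 18 nt). Reads
with fewer than four bases left after trimming are counted as adapter
dimers — the ligation product of the two adapters with no insert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .refio import SmallRNARecord

logger = logging.getLogger(__name__)


class TrimStatus(str, Enum):
    KEPT = "kept"
    ADAPTER_DIMER = "adapter_dimer"
    TOO_SHORT = "too_short"
    QUALITY_FAIL = "quality_fail"


@dataclass
class TrimConfig:
    """Trimming parameters; the defaults are the small-RNA pipeline standard.

    ``adapters3`` lists explicit 3'-side artifact sequences (3' adapter, PCR
    primer). PolyA/polyG tails are modelled as homopolymer adapters of
    ``homopolymer_len`` bases subject to the same error rule.
    """

    adapters3: list[str] = field(
        default_factory=lambda: ["TGGAATTCTCGGGTGCCAAGG"]
    )
    homopolymer_len: int = 10
    homopolymers: tuple[str, ...] = ("A", "G")
    quality_cutoff: int = 20
    max_error_rate: float = 0.10
    max_rounds: int = 3
    max_n: int = 2
    min_len: int = 18
    dimer_max_len: int = 3
    min_adapter_prefix: int = 3
    flank4n_len: int = 0  # clip this many bases from each insert end (4N protocols)

    def __post_init__(self) -> None:
        if not self.dimer_max_len < self.min_len:
            raise ValueError("dimer_max_len must be smaller than min_len")
        if not 0 < self.max_error_rate < 1:
            raise ValueError("max_error_rate must be in (0,1)")

    def all_adapters(self) -> list[tuple[str, int]]:
        """(adapter sequence, minimum matched length) pairs.

        Explicit adapters may match down to ``min_adapter_prefix`` bases at
        the read's 3' end; homopolymer tails require the full run — a
        trailing AAA on an insert is signal, not a polyA tail.
        """
        pairs = [(a, self.min_adapter_prefix) for a in self.adapters3]
        pairs += [
            (base * self.homopolymer_len, self.homopolymer_len)
            for base in self.homopolymers
        ]
        return pairs


@dataclass
class TrimOutcome:
    status: TrimStatus
    trimmed: SmallRNARecord | None
    removed_segments: list[tuple[str, str]] = field(default_factory=list)


class AdapterMatch(NamedTuple):
    start: int  # read position where the adapter begins; bases from here on are removed
    errors: int
    matched_len: int  # adapter prefix length that matched


def extract_umi(read: SmallRNARecord, umi_len: int) -> SmallRNARecord:
    """Move the first ``umi_len`` bases of the read into its UMI slot.

    ``umi_len == 0`` is the identity. A UMI containing N is stored verbatim
    but flagged ``umi_has_n`` so deduplication can drop it; a read shorter
    than the UMI is flagged ``umi_truncated`` and left with an empty
    sequence (it fails length QC downstream).
    """
    if umi_len == 0:
        return read
    if len(read) <= umi_len:
        rec = replace(read, umi=read.sequence, sequence="", qualities=[])
        rec.flags = set(read.flags) | {"umi_truncated"}
        return rec
    umi = read.sequence[:umi_len]
    rec = SmallRNARecord(
        read_id=read.read_id,
        sequence=read.sequence[umi_len:],
        qualities=read.qualities[umi_len:],
        umi=umi,
        flags=set(read.flags),
    )
    if "N" in umi:
        rec.flags.add("umi_has_n")
    return rec


def quality_trim_3prime(read: SmallRNARecord, cutoff: int = 20) -> SmallRNARecord:
    """Trim low-quality 3' tails with the running-partial-sum rule.

    Walking from the 3' end, accumulate ``q_i - cutoff`` and cut at the
    position where the running sum is most negative (ties resolve to the
    longest kept read); reads whose qualities never dip below the cutoff
    are returned unchanged.
    """
    if len(read) == 0 or min(read.qualities) >= cutoff:
        return read
    # suffix sums of (q - cutoff), scanned from the 3' end; cumsum index k
    # corresponds to cut position i = n-1-k, so argmin's first-occurrence
    # rule picks the longest kept read on ties
    deltas = np.asarray(read.qualities, dtype=np.int64)[::-1] - cutoff
    sums = np.cumsum(deltas)
    k = int(np.argmin(sums))
    if sums[k] >= 0:
        return read
    best_cut = len(read) - 1 - k
    return replace(
        read,
        sequence=read.sequence[:best_cut],
        qualities=read.qualities[:best_cut],
    )


def find_adapter(
    sequence: str,
    adapter: str,
    max_error_rate: float = 0.10,
    min_prefix: int = 3,
) -> AdapterMatch | None:
    """Semi-global search for a 3'-side adapter in a read.

    The full adapter may occur anywhere in the read; alternatively a
    3'-terminal prefix of the adapter (length >= ``min_prefix``) may run off
    the read's 3' end. Substitutions and indels each cost 1; a candidate is
    accepted iff ``errors / matched_adapter_length <= max_error_rate``.
    Among acceptable candidates the smallest error count wins, ties by
    leftmost start. Returns ``None`` when no acceptable occurrence exists.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(sequence), len(adapter)
    if n == 0:
        return None
    exact = _find_adapter_exact(sequence, adapter, min_prefix)
    if exact is not None:
        return exact
    # only error-containing candidates remain; a cheap necessary-condition
    # screen and an error-only vectorised DP reject the common no-match
    # case before the full traceback DP runs
    if not _screen_kmers(sequence, adapter, max_error_rate):
        return None
    return _find_adapter_dp(sequence, adapter, max_error_rate, min_prefix)


def _screen_kmers(sequence: str, adapter: str, max_error_rate: float) -> bool:
    """Pigeonhole screen: any candidate with e >= 1 errors keeps at least
    one of these adapter chunks intact (hence exact in the read). Chunks
    cover every error budget the rate admits for prefix lengths whose
    budget is nonzero. Never returns False when a real candidate exists."""
    m = len(adapter)
    e_max = int(max_error_rate * m + 1e-9)
    if e_max <= 0:
        return False  # only 0-error candidates possible; exact path covered them
    k_min = int(np.ceil(1.0 / max_error_rate - 1e-9))  # shortest prefix allowing 1 error
    span = min(m, k_min)
    # 1-error candidates: adapter[:span] intact in one of two halves
    half = span // 2
    chunks = {adapter[:half], adapter[half:span]}
    if e_max >= 2:
        # e-error candidates include adapter[:k] for k >= ceil(e/rate);
        # split the shortest such prefix into e+1 pieces
        for e in range(2, e_max + 1):
            k = min(m, int(np.ceil(e / max_error_rate - 1e-9)))
            piece = k // (e + 1)
            chunks.update(
                adapter[p * piece : (p + 1) * piece] for p in range(e + 1)
            )
    return any(c and c in sequence for c in chunks)


def _find_adapter_dp(
    sequence: str, adapter: str, max_error_rate: float, min_prefix: int
) -> AdapterMatch | None:
    """Occurrence DP, vectorised over read positions.

    ``D[i][j]`` is the minimum edit distance aligning ``adapter[:i]``
    against a read substring ending at j, with free choice of start. The
    inner (read-insertion) recurrence ``D[i][j] = min(c[j], D[i][j-1]+1)``
    collapses to a running minimum of ``c[j] - j`` plus j. The leftmost
    start of the winning candidate is recovered by a traceback restricted
    to optimal cells.
    """
    q = np.frombuffer(sequence.encode(), dtype=np.uint8)
    a = np.frombuffer(adapter.encode(), dtype=np.uint8)
    n, m = len(q), len(a)
    cols = np.arange(n + 1, dtype=np.int32)
    D = np.empty((m + 1, n + 1), dtype=np.int32)
    D[0] = 0
    for i in range(1, m + 1):
        mism = (q != a[i - 1]).astype(np.int32)
        cand = np.minimum(D[i - 1, :-1] + mism, D[i - 1, 1:] + 1)
        full = np.concatenate([[np.int32(i)], cand])
        D[i] = np.minimum.accumulate(full - cols) + cols
    # candidate endpoints: full adapter ending anywhere; adapter prefix
    # (length >= min_prefix) at the read's 3' end
    endpoints: list[tuple[int, int, int]] = []  # (errors, i, j)
    e_star: int | None = None
    full_ok = np.nonzero(D[m, 1:] <= max_error_rate * m + 1e-9)[0] + 1
    for j in full_ok:
        endpoints.append((int(D[m, j]), m, int(j)))
    ks = np.arange(min_prefix, m + 1)
    pref_ok = ks[D[ks, n] <= max_error_rate * ks + 1e-9]
    for i in pref_ok:
        endpoints.append((int(D[i, n]), int(i), n))
    if not endpoints:
        return None
    e_star = min(e for e, _i, _j in endpoints)
    # winner: leftmost start among minimal-error candidates; on equal
    # start a full-adapter candidate outranks a prefix, and among prefixes
    # the shortest wins (stable against the enumeration order)
    scored = []
    for e, i, j in endpoints:
        if e == e_star:
            s = _traceback_min_start(D, q, a, i, j)
            scored.append((s, 0 if i == m else 1, i))
    s_min, _kind, i_win = min(scored)
    return AdapterMatch(start=s_min, errors=e_star, matched_len=i_win)


def _traceback_min_start(
    D: np.ndarray, q: np.ndarray, a: np.ndarray, i0: int, j0: int
) -> int:
    """Leftmost read position from which some optimal alignment to the
    endpoint (i0, j0) starts."""
    best = j0
    stack = [(i0, j0)]
    seen = {(i0, j0)}
    while stack:
        i, j = stack.pop()
        if i == 0:
            best = min(best, j)
            continue
        if j == 0:
            best = 0
            continue
        d = D[i, j]
        preds = (
            (i - 1, j - 1, d - (1 if q[j - 1] != a[i - 1] else 0)),
            (i - 1, j, d - 1),
            (i, j - 1, d - 1),
        )
        for pi, pj, need in preds:
            if D[pi, pj] == need and (pi, pj) not in seen:
                seen.add((pi, pj))
                stack.append((pi, pj))
    return best


def _find_adapter_exact(
    sequence: str, adapter: str, min_prefix: int
) -> AdapterMatch | None:
    """Fast path: a zero-error candidate, if one exists, is globally optimal
    (indels cost 1, so any 0-error occurrence is an exact string match);
    return the leftmost one. ``None`` means 'fall back to the DP', not
    'no match'."""
    n, m = len(sequence), len(adapter)
    candidates: list[int] = []
    pos = sequence.find(adapter)
    if pos != -1:
        candidates.append(pos)
    # terminal prefix: only positions where adapter[0] occurs in the tail
    # can start one; take the largest k (leftmost start)
    first = adapter[0]
    tail_from = max(0, n - m)
    p = sequence.find(first, tail_from)
    while p != -1:
        k = n - p
        if k >= min_prefix and sequence.endswith(adapter[:k]):
            candidates.append(p)
            break
        p = sequence.find(first, p + 1)
    if not candidates:
        return None
    start = min(candidates)
    matched = m if start + m <= n and sequence[start : start + m] == adapter else n - start
    return AdapterMatch(start=start, errors=0, matched_len=matched)


def trim_read(read: SmallRNARecord, cfg: TrimConfig) -> TrimOutcome:
    """Quality-trim once, then up to ``cfg.max_rounds`` rounds of adapter
    removal, then QC classification.

    Each round removes at most one artifact: every configured adapter is
    searched and the earliest (leftmost-start, then fewest-errors) match
    wins; everything from the match start to the 3' end is removed. Status
    precedence is dimer > too_short > quality_fail: a post-trim length
    below 4 is an adapter dimer regardless of N content.
    """
    removed: list[tuple[str, str]] = []
    rec = quality_trim_3prime(read, cfg.quality_cutoff)
    if len(rec) < len(read):
        removed.append(("quality", read.sequence[len(rec):]))
    adapters = cfg.all_adapters()
    for _round in range(cfg.max_rounds):
        hits: list[tuple[int, int, str]] = []
        for adapter, min_prefix in adapters:
            m = find_adapter(rec.sequence, adapter, cfg.max_error_rate, min_prefix)
            if m is not None:
                hits.append((m.start, m.errors, adapter))
        if not hits:
            break
        start, _errors, adapter = min(hits)
        removed.append(("adapter", rec.sequence[start:]))
        rec = replace(
            rec, sequence=rec.sequence[:start], qualities=rec.qualities[:start]
        )
        if len(rec) == 0:
            break
    if cfg.flank4n_len and len(rec) > cfg.dimer_max_len:
        k = cfg.flank4n_len
        if len(rec) > 2 * k:
            removed.append(("flank4n", rec.sequence[:k] + "/" + rec.sequence[-k:]))
            rec = replace(
                rec, sequence=rec.sequence[k:-k], qualities=rec.qualities[k:-k]
            )
        else:
            removed.append(("flank4n", rec.sequence))
            rec = replace(rec, sequence="", qualities=[])
    if len(rec) <= cfg.dimer_max_len:
        return TrimOutcome(TrimStatus.ADAPTER_DIMER, None, removed)
    if len(rec) < cfg.min_len or "umi_truncated" in rec.flags:
        return TrimOutcome(TrimStatus.TOO_SHORT, None, removed)
    if rec.sequence.count("N") > cfg.max_n:
        return TrimOutcome(TrimStatus.QUALITY_FAIL, None, removed)
    return TrimOutcome(TrimStatus.KEPT, rec, removed)


def preprocess_reads(
    reads: Iterable[SmallRNARecord],
    cfg: TrimConfig,
    umi_len: int = 0,
) -> tuple[list[SmallRNARecord], "QCSummary"]:
    """Run UMI extraction + trimming over a read stream.

    Returns the kept (trimmed) records, with UMIs attached, and a QC
    summary with per-status counts. Every input read receives exactly one
    status.
    """
    kept: list[SmallRNARecord] = []
    counts = {s: 0 for s in TrimStatus}
    statuses: list[tuple[str, str]] = []
    for read in reads:
        rec = extract_umi(read, umi_len)
        outcome = trim_read(rec, cfg)
        counts[outcome.status] += 1
        statuses.append((read.read_id, outcome.status.value))
        if outcome.status is TrimStatus.KEPT:
            kept.append(outcome.trimmed)
    return kept, QCSummary(counts=counts, statuses=statuses)


@dataclass
class QCSummary:
    counts: dict[TrimStatus, int]
    statuses: list[tuple[str, str]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, status: TrimStatus) -> float:
        return self.counts[status] / self.total if self.total else float("nan")

    def as_dict(self) -> dict[str, float | int]:
        out: dict[str, float | int] = {"total": self.total}
        for s in TrimStatus:
            out[s.value] = self.counts[s]
            out[f"frac_{s.value}"] = self.fraction(s)
        return out


def subsample_reads(
    records: Sequence[SmallRNARecord] | Iterable[SmallRNARecord],
    n: int,
    seed: int = 42,
) -> Iterator[SmallRNARecord]:
    """Downsample to exactly ``min(n, total)`` reads, uniformly without
    replacement, preserving input order; deterministic given ``seed``.

    Not bit-compatible with seqtk's RNG — determinism is guaranteed only
    within this package.
    """
    records = list(records)
    if n >= len(records):
        yield from records
        return
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    for i in np.sort(idx):
        yield records[i]
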