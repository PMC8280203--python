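"""UMI-based molecule counting via the adjacency network method.

Reads sharing a feature are grouped by their UMIs: UMIs at Hamming
distance exactly 1 are connected, and groups are resolved greedily from
the most-read-supported UMI outward (its unassigned direct neighbours
join its group). The number of groups is the molecule count. This is the
adjacency method of network-based UMI deduplication; unlike the
directional variant it applies no count-ratio condition on edges.

Deduplication is computed per (sample, feature); UMIs containing N are
dropped at table construction (Hamming distance is undefined for N) with
the dropped count logged. Ties on read count resolve to the
lexicographically smallest UMI — a determinism improvement over
arbitrary tie-breaking.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .refio import CountMatrix, SmallRNARecord

logger = logging.getLogger(__name__)


def hamming(u1: str, u2: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(u1) != len(u2):
        raise ValueError(f"unequal UMI lengths: {len(u1)} vs {len(u2)}")
    return sum(a != b for a, b in zip(u1, u2))


@dataclass
class UMIGroup:
    representative: str
    members: list[str]
    total_reads: int


@dataclass
class UMITable:
    """Per (sample, feature) UMI read counts."""

    counts: dict[tuple[str, str], Counter]  # (sample, feature) -> {umi: reads}
    dropped_n_umis: int = 0

    @classmethod
    def from_reads(
        cls,
        reads: Iterable[SmallRNARecord],
        read_to_feature: Mapping[str, str],
        sample_id: str,
        group_by_length: bool = True,
    ) -> "UMITable":
        """Build the table from mapped reads carrying UMIs.

        With ``group_by_length`` (default on, mirroring read-length-aware
        deduplication) reads of different trimmed lengths at the same
        feature are deduplicated separately; the per-feature molecule
        count is then summed over lengths.
        """
        counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
        dropped = 0
        umi_len: int | None = None
        for rec in reads:
            feat = read_to_feature.get(rec.read_id)
            if feat is None or not rec.umi:
                continue
            if "N" in rec.umi or "umi_has_n" in rec.flags:
                dropped += 1
                continue
            if umi_len is None:
                umi_len = len(rec.umi)
            elif len(rec.umi) != umi_len:
                raise ValueError("mixed UMI lengths within one table")
            key_feat = f"{feat}|len={len(rec.sequence)}" if group_by_length else feat
            counts[(sample_id, key_feat)][rec.umi] += 1
        if dropped:
            logger.info("dropped %d reads with N-containing UMIs", dropped)
        return cls(counts=dict(counts), dropped_n_umis=dropped)


def adjacency_dedup(umi_counts: Mapping[str, int]) -> list[UMIGroup]:
    """Resolve one UMI count table into molecule groups.

    Repeatedly select the unassigned UMI with the highest read count
    (ties: lexicographically smallest), form a group of it plus all its
    unassigned Hamming-distance-1 neighbours, until every UMI is assigned.
    """
    if not umi_counts:
        raise ValueError("empty UMI table entry")
    umis = sorted(umi_counts)
    neighbours: dict[str, list[str]] = {u: [] for u in umis}
    for i, a in enumerate(umis):
        for b in umis[i + 1 :]:
            if hamming(a, b) == 1:
                neighbours[a].append(b)
                neighbours[b].append(a)
    unassigned = set(umis)
    order = sorted(umis, key=lambda u: (-umi_counts[u], u))
    groups: list[UMIGroup] = []
    for u in order:
        if u not in unassigned:
            continue
        members = [u] + [v for v in neighbours[u] if v in unassigned]
        unassigned.difference_update(members)
        groups.append(
            UMIGroup(
                representative=u,
                members=sorted(members),
                total_reads=sum(umi_counts[m] for m in members),
            )
        )
    return groups


@dataclass
class DedupResult:
    """Molecule counts and UMI groups per (sample, feature)."""

    groups: dict[tuple[str, str], list[UMIGroup]]

    def molecule_counts(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(
            list(self.groups) or [("", "")], names=["sample", "feature"]
        )
        vals = [len(g) for g in self.groups.values()] or [0]
        return pd.Series(vals, index=idx, name="molecules")

    def per_feature(self, strip_length_key: bool = True) -> pd.Series:
        """Molecule counts aggregated to (sample, feature), summing over
        read-length strata when ``group_by_length`` was used."""
        rows: Counter = Counter()
        for (sample, feat), groups in self.groups.items():
            if strip_length_key and "|len=" in feat:
                feat = feat.split("|len=")[0]
            rows[(sample, feat)] += len(groups)
        idx = pd.MultiIndex.from_tuples(
            list(rows) or [("", "")], names=["sample", "feature"]
        )
        return pd.Series(list(rows.values()) or [0], index=idx, name="molecules")


def dedup_table(table: UMITable) -> DedupResult:
    return DedupResult(
        groups={key: adjacency_dedup(cnt) for key, cnt in table.counts.items()}
    )


def molecules_layer(
    result: DedupResult, feature_ids: Sequence[str], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Deduplicated molecule counts as a features x samples layer."""
    layer = pd.DataFrame(0, index=list(feature_ids), columns=list(sample_ids), dtype=np.int64)
    for (sample, feat), n in result.per_feature().items():
        if feat in layer.index and sample in layer.columns:
            layer.loc[feat, sample] += n
    return layer


def reads_per_umi(table: UMITable) -> pd.DataFrame:
    """Duplication depth: total reads / distinct UMIs per (sample, feature),
    plus per-sample means over features.

    Returns a tidy frame with columns sample, feature, reads, umis,
    reads_per_umi.
    """
    rows = []
    for (sample, feat), cnt in table.counts.items():
        feat_base = feat.split("|len=")[0]
        rows.append(
            {
                "sample": sample,
                "feature": feat_base,
                "reads": sum(cnt.values()),
                "umis": len(cnt),
            }
        )
    df = pd.DataFrame(rows, columns=["sample", "feature", "reads", "umis"])
    if len(df):
        df = df.groupby(["sample", "feature"], as_index=False).sum()
        df["reads_per_umi"] = df["reads"] / df["umis"]
    else:
        df["reads_per_umi"] = pd.Series(dtype=float)
    return df


def reads_per_umi_summary(per_feature: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean reads-per-UMI over features, with the cohort mean
    and standard deviation over samples."""
    if not len(per_feature):
        return pd.DataFrame(columns=["sample", "mean_reads_per_umi"])
    per_sample = (
        per_feature.groupby("sample")["reads_per_umi"].mean().rename("mean_reads_per_umi")
    ).reset_index()
    return per_sample


def molecules_per_cell(
    result: DedupResult, mirna_features: set[str] | None = None
) -> pd.Series:
    """Per-sample total molecule count over miRNA features (run dedup on
    miRNA-assigned reads, or pass the miRNA feature set to filter)."""
    per_feat = result.per_feature()
    totals: Counter = Counter()
    for (sample, feat), n in per_feat.items():
        if mirna_features is not None and feat not in mirna_features:
            continue
        totals[sample] += n
    return pd.Series(dict(totals), name="molecules", dtype=np.int64).sort_index()
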