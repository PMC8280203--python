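"""Readers/writers for the standard formats the pipeline touches.

Shared data model: sequencing reads (:class:`SmallRNARecord`), short-RNA
references with per-entry G-content (:class:`ReferenceSet`), genomic
annotation intervals (:class:`AnnotationTrack`) and layered count matrices
(:class:`CountMatrix`).

Coordinate convention is 0-based half-open everywhere in memory; GFF3
(1-based inclusive) is converted on read and write.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: RNA-class vocabulary, ordered by assignment priority (highest first).
CLASS_PRIORITY: tuple[str, ...] = (
    "miRNA",
    "miRNA_primary_transcript",
    "GtRNAdb",
    "Mt_tRNA",
    "rRNA",
    "Mt_rRNA",
    "snoRNA",
    "snRNA",
    "sRNA",
    "scaRNA",
    "scRNA",
    "piRBase",
    "misc_RNA",
    "ribozyme",
    "coding_exon",
    "lncRNA",
    "ncRNA",
    "protein_coding",
)

INTERGENIC = "intergenic"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SmallRNARecord:
    """A single sequencing read.

    ``umi`` is empty until extracted; once set it is never altered by
    downstream trimming.
    """

    read_id: str
    sequence: str
    qualities: "list[int] | np.ndarray"  # Phred scores, same length as sequence
    umi: str = ""
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"read {self.read_id!r}: non-IUPAC-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[SmallRNARecord]:
    """Stream reads from a (optionally gzipped) 4-line FASTQ file.

    Qualities are decoded with ``phred_offset`` (33 for modern Illumina).
    Malformed records raise :class:`FormatError` naming the record index.
    """
    with _open_text(path) as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(qual) != len(seq):
                    raise FormatError(
                        f"record {index}: quality string length {len(qual)} "
                        f"!= sequence length {len(seq)}"
                    )
                read_id, umi = parse_umi_header(title) if title else ("", "")
                yield SmallRNARecord(
                    read_id=read_id,
                    sequence=seq.upper(),
                    qualities=[ord(c) - phred_offset for c in qual],
                    umi=umi,
                )
                index += 1
        except ValueError as exc:  # biopython's malformed-FASTQ errors
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"record {index}: {exc}") from exc


def write_fastq(
    records: Iterable[SmallRNARecord], path: str | Path, phred_offset: int = 33
) -> int:
    """Write records as 4-line FASTQ; UMIs are carried in the header.

    The UMI of each read is appended to its header as ``UMI:<seq>`` so it
    survives a round-trip through FASTQ (mirrors copying the UMI into the
    read name before trimming). Returns the number of records written.
    """
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            name = rec.read_id
            if rec.umi:
                name = f"{name} UMI:{rec.umi}"
            qual = "".join(chr(q + phred_offset) for q in rec.qualities)
            handle.write(f"@{name}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def parse_umi_header(title: str) -> tuple[str, str]:
    """Split a FASTQ title into (read_id, umi); umi is '' when absent."""
    parts = title.split()
    umi = ""
    for token in parts[1:]:
        if token.startswith("UMI:"):
            umi = token[4:]
    return parts[0], umi


@dataclass
class ReferenceSet:
    """Named short-RNA sequences with class labels and G-content."""

    entries: dict[str, tuple[str, str]]  # feature_id -> (sequence, class_label)

    def __post_init__(self) -> None:
        for fid, (seq, _label) in self.entries.items():
            if not seq:
                raise FormatError(f"reference {fid!r}: empty sequence")
            if "N" in seq:
                raise FormatError(f"reference {fid!r}: N bases not permitted")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(f"reference {fid!r}: bad characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.entries)

    def sequence(self, feature_id: str) -> str:
        return self.entries[feature_id][0]

    def g_content(self, feature_id: str) -> float:
        seq = self.entries[feature_id][0]
        return seq.count("G") / len(seq)

    def g_content_series(self) -> pd.Series:
        return pd.Series(
            {fid: self.g_content(fid) for fid in self.entries}, name="g_content"
        )


def read_fasta_reference(path: str | Path, class_label: str = "miRNA") -> ReferenceSet:
    """Load a FASTA of short RNA references (e.g. an equimolar spike-in pool).

    Entries are keyed by the first whitespace-delimited header token;
    duplicate ids are an error.
    """
    entries: dict[str, tuple[str, str]] = {}
    with _open_text(path) as handle:
        fid: str | None = None
        chunks: list[str] = []
        for line in handle:
            line = line.rstrip()
            if line.startswith(">"):
                if fid is not None:
                    _add_ref_entry(entries, fid, "".join(chunks), class_label)
                fid = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
        if fid is not None:
            _add_ref_entry(entries, fid, "".join(chunks), class_label)
    return ReferenceSet(entries)


def _add_ref_entry(
    entries: dict[str, tuple[str, str]], fid: str, seq: str, label: str
) -> None:
    if fid in entries:
        raise FormatError(f"duplicate reference id {fid!r}")
    entries[fid] = (seq, label)


def write_fasta(refs: ReferenceSet, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for fid, (seq, _label) in refs.entries.items():
            handle.write(f">{fid}\n{seq}\n")


@dataclass(frozen=True)
class Interval:
    """One annotation interval, 0-based half-open: covers start..end-1."""

    contig: str
    start: int
    end: int
    strand: str
    class_label: str
    feature_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"interval {self.feature_id!r}: start {self.start} >= end {self.end}"
            )

    def overlap(self, start: int, end: int) -> int:
        """Overlap in bases with a 0-based half-open query interval."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class AnnotationTrack:
    """A list of class-labelled intervals over one or more contigs."""

    intervals: list[Interval]

    def __post_init__(self) -> None:
        allowed = set(CLASS_PRIORITY)
        for iv in self.intervals:
            if iv.class_label not in allowed:
                raise FormatError(
                    f"unknown class label {iv.class_label!r} for {iv.feature_id!r}"
                )
        self._by_contig: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            self._by_contig.setdefault(iv.contig, []).append(iv)

    def overlapping(self, contig: str, start: int, end: int) -> list[Interval]:
        return [
            iv for iv in self._by_contig.get(contig, ()) if iv.overlap(start, end) > 0
        ]


def read_gff3(path: str | Path) -> AnnotationTrack:
    """Read a GFF3 annotation track; 1-based inclusive coordinates are
    converted to the internal 0-based half-open convention.

    The feature ``type`` column carries the RNA class; the ``ID`` attribute
    the feature id.
    """
    intervals: list[Interval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 line {lineno}: expected 9 columns")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            fid = ""
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    fid = item[3:]
            intervals.append(
                Interval(contig, int(start) - 1, int(end), strand, ftype, fid)
            )
    return AnnotationTrack(intervals)


def write_gff3(track: AnnotationTrack, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for iv in track.intervals:
            handle.write(
                f"{iv.contig}\t.\t{iv.class_label}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={iv.feature_id}\n"
            )


@dataclass
class CountMatrix:
    """Features x samples table with named layers.

    ``layers`` maps a layer name (``raw``, ``molecules``, ``rpmm``,
    ``lognorm`` ...) to a dense features-x-samples :class:`pandas.DataFrame`;
    all layers share index and columns. ``metadata`` carries per-sample
    labels (protocol, patient, stage ...).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    layers: dict[str, pd.DataFrame]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, df in self.layers.items():
            if list(df.index) != self.feature_ids or list(df.columns) != self.sample_ids:
                raise ValueError(f"layer {name!r} does not share matrix dimensions")

    def layer(self, name: str) -> pd.DataFrame:
        if name not in self.layers:
            raise KeyError(
                f"unknown layer {name!r}; available: {sorted(self.layers)}"
            )
        return self.layers[name]

    def add_layer(self, name: str, values: pd.DataFrame) -> None:
        values = values.reindex(index=self.feature_ids, columns=self.sample_ids)
        self.layers[name] = values


def write_count_matrix(matrix: CountMatrix, prefix: str | Path) -> list[Path]:
    """Write one TSV per layer (``<prefix>.<layer>.tsv``) plus a metadata
    sidecar (``<prefix>.metadata.tsv``). Returns the written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in matrix.layers.items():
        p = prefix.parent / f"{prefix.name}.{name}.tsv"
        df.to_csv(p, sep="\t", index_label="feature_id")
        written.append(p)
    meta_path = prefix.parent / f"{prefix.name}.metadata.tsv"
    meta = (
        matrix.metadata
        if matrix.metadata is not None
        else pd.DataFrame(index=matrix.sample_ids)
    )
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")
    written.append(meta_path)
    return written


def read_count_matrix(prefix: str | Path) -> CountMatrix:
    """Inverse of :func:`write_count_matrix`; value round-trips are identical
    up to floating representation. A missing metadata sidecar yields empty
    metadata with a logged warning."""
    prefix = Path(prefix)
    layers: dict[str, pd.DataFrame] = {}
    for p in sorted(prefix.parent.glob(prefix.name + ".*.tsv")):
        layer_name = p.name[len(prefix.name) + 1 : -len(".tsv")]
        if layer_name == "metadata":
            continue
        layers[layer_name] = pd.read_csv(p, sep="\t", index_col="feature_id")
    if not layers:
        raise FileNotFoundError(f"no layer files found for prefix {prefix}")
    first = next(iter(layers.values()))
    meta_path = prefix.parent / f"{prefix.name}.metadata.tsv"
    metadata = None
    if meta_path.exists():
        metadata = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    else:
        warnings.warn(f"missing metadata sidecar {meta_path}; loading without")
        logger.warning("missing metadata sidecar %s", meta_path)
    return CountMatrix(
        feature_ids=[str(i) for i in first.index],
        sample_ids=[str(c) for c in first.columns],
        layers={k: v for k, v in layers.items()},
        metadata=metadata,
    )
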