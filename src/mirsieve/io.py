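"""Reading, trimming, filtering and collapsing of small-RNA reads.

A sequencing run yields millions of short reads; after 3' adapter removal,
identical inserts are collapsed into *unique tags* whose multiplicity is the
tag's read count.  The :class:`CountTable` (tag x sample count matrix, with
zero cells absent rather than stored) is the central container every later
stage consumes.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, ParseError

__all__ = [
    "ReadRecord",
    "LengthWindow",
    "CountTable",
    "read_reads",
    "trim_adapter",
    "filter_length",
    "collapse_reads",
    "merge_tables",
    "read_count_table",
    "write_count_table",
]

#: Default adapter overlap required before a 3' suffix is trimmed.
DEFAULT_MIN_OVERLAP = 6

#: Default insert-size window retained for intracellular libraries (nt).
DEFAULT_LENGTH_WINDOW = (18, 35)


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read: an id, an uppercase sequence, optional quality."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ParseError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LengthWindow:
    """Inclusive insert-length window, e.g. the 18-35 nt small-RNA gel cut."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ConfigurationError(
                f"invalid length window ({self.min_len}, {self.max_len})"
            )

    def __contains__(self, read: ReadRecord | str) -> bool:
        n = len(read)
        return self.min_len <= n <= self.max_len


@dataclass
class CountTable:
    """Unique tag sequences with per-sample read counts.

    ``counts`` maps tag -> {sample_id -> count}; a (tag, sample) pair with no
    reads is simply absent, never stored as zero.  ``annotations`` optionally
    maps a tag to its miRNA name (see :func:`mirsieve.mapping.annotate_table`).
    """

    samples: list[str] = field(default_factory=list)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def tags(self) -> list[str]:
        return list(self.counts)

    def get(self, tag: str, sample_id: str) -> int:
        return self.counts.get(tag, {}).get(sample_id, 0)

    def add(self, tag: str, sample_id: str, count: int) -> None:
        if count < 0:
            raise ValueError("counts must be non-negative")
        if count == 0:
            return
        if sample_id not in self.samples:
            self.samples.append(sample_id)
        row = self.counts.setdefault(tag, {})
        row[sample_id] = row.get(sample_id, 0) + count

    def sample_counts(self, sample_id: str) -> dict[str, int]:
        """Tag -> count for one sample (tags absent from the sample omitted)."""
        if sample_id not in self.samples:
            raise ConfigurationError(f"unknown sample {sample_id!r}")
        return {
            tag: row[sample_id] for tag, row in self.counts.items() if sample_id in row
        }

    def total(self, sample_id: str) -> int:
        return sum(self.sample_counts(sample_id).values())

    def name_of(self, tag: str) -> str:
        """Annotation if present, else the tag sequence itself."""
        return self.annotations.get(tag, tag)

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame (absent cells as 0) with an optional annotation column."""
        rows = []
        for tag, row in self.counts.items():
            rec: dict[str, object] = {"sequence": tag}
            for s in self.samples:
                rec[s] = row.get(s, 0)
            if self.annotations:
                rec["annotation"] = self.annotations.get(tag, "")
            rows.append(rec)
        cols = ["sequence", *self.samples] + (["annotation"] if self.annotations else [])
        frame = pd.DataFrame(rows, columns=cols)
        if len(frame) and self.samples:
            frame = frame.sort_values(
                [self.samples[0], "sequence"], ascending=[False, True]
            ).reset_index(drop=True)
        return frame


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_reads(path: str | Path, format: str | None = None) -> Iterator[ReadRecord]:
    """Stream reads from a FASTA or FASTQ file (gzip transparently handled).

    ``format`` is ``"fasta"`` or ``"fastq"``; when omitted it is inferred
    from the file extension.  Malformed records raise :class:`ParseError`
    naming the failing record.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        ext = stem.rsplit(".", 1)[-1].lower() if "." in stem else ""
        format = {"fa": "fasta", "fasta": "fasta", "fq": "fastq", "fastq": "fastq"}.get(ext)
    if format not in ("fasta", "fastq"):
        raise ConfigurationError(f"unknown read format {format!r} for {path}")

    n_seen = 0
    lines_per_record = 4 if format == "fastq" else 2
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, format):
                n_seen += 1
                quality = None
                if format == "fastq":
                    quality = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                yield ReadRecord(rec.id, str(rec.seq).upper(), quality)
        except ValueError as exc:  # Biopython's parse failure
            raise ParseError(
                f"{path}: malformed {format} record near line "
                f"{n_seen * lines_per_record + 1}: {exc}"
            ) from exc


def trim_adapter(
    reads: Iterable[ReadRecord],
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Iterator[ReadRecord]:
    """Remove the 3' adapter by longest exact suffix-prefix overlap.

    The longest read suffix (length >= ``min_overlap``) equal to a prefix of
    ``adapter`` is removed; reads without such an overlap pass unchanged and
    reads trimmed to nothing are dropped.
    """
    adapter = adapter.upper()
    if not adapter:
        raise ConfigurationError("adapter must be non-empty")
    if min_overlap < 1:
        raise ConfigurationError("min_overlap must be >= 1")
    for read in reads:
        seq = read.sequence
        longest = min(len(seq), len(adapter))
        cut = None
        for k in range(longest, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = k
                break
        if cut is None:
            yield read
            continue
        if cut == len(seq):
            continue  # pure adapter read: empty insert, dropped
        yield ReadRecord(
            read.read_id,
            seq[:-cut],
            read.quality[:-cut] if read.quality is not None else None,
        )


def filter_length(
    reads: Iterable[ReadRecord], window: LengthWindow
) -> Iterator[ReadRecord]:
    """Keep reads whose length lies within the inclusive window."""
    for read in reads:
        if read in window:
            yield read


def collapse_reads(reads: Iterable[ReadRecord], sample_id: str) -> CountTable:
    """Collapse identical sequences into unique tags with their multiplicity."""
    if not sample_id:
        raise ConfigurationError("sample_id must be non-empty")
    tally: Counter[str] = Counter(read.sequence for read in reads)
    table = CountTable(samples=[sample_id])
    for tag, count in tally.items():
        table.counts[tag] = {sample_id: count}
    return table


def merge_tables(tables: Sequence[CountTable]) -> CountTable:
    """Union per-sample tables into one multi-sample table."""
    merged = CountTable()
    for table in tables:
        for s in table.samples:
            if s in merged.samples:
                raise ConfigurationError(f"duplicate sample id {s!r} in merge")
            merged.samples.append(s)
        for tag, row in table.counts.items():
            dest = merged.counts.setdefault(tag, {})
            dest.update(row)
        merged.annotations.update(table.annotations)
    return merged


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a tag count table as TSV, sorted by the first sample's count."""
    frame = table.to_frame()
    frame.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (sequence column, one column per sample,
    optional trailing annotation column; '#' lines are comments)."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read TSV: {exc}") from exc
    if "sequence" not in frame.columns:
        raise ParseError(f"{path}: missing 'sequence' column")
    sample_cols = [c for c in frame.columns if c not in ("sequence", "annotation")]
    table = CountTable(samples=list(sample_cols))
    for i, rec in frame.iterrows():
        tag = rec["sequence"]
        for s in sample_cols:
            cell = rec[s]
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: row {i + 2}: non-integer count {cell!r} in column {s}"
                ) from None
            if value < 0:
                raise ParseError(f"{path}: row {i + 2}: negative count {value}")
            if value > 0:
                table.counts.setdefault(tag, {})[s] = value
        if "annotation" in frame.columns:
            note = rec["annotation"]
            if isinstance(note, str) and note:
                table.annotations[tag] = note
    return table
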