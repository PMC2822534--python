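"""Mismatch-tolerant mapping of unique tags onto mature miRNA sequences.

Tags are aligned ungapped against every mature reference sequence at every
offset; a tag's reported hits are all placements achieving its minimum
attainable Hamming distance, provided that distance does not exceed the
mismatch budget (default 3, the usual short-read bound).  Annotated counts
can then be projected onto genomic loci as a peak track whose interval
heights are summed read counts, written as BED5 or variableStep wiggle for
genome-browser display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConfigurationError, DataError, ParseError
from .io import CountTable

__all__ = [
    "MirnaReference",
    "MappingHit",
    "PeakTrack",
    "read_mirna_reference",
    "map_tags",
    "annotate_table",
    "build_peak_track",
    "peak_histogram",
    "write_bed",
    "read_bed",
    "write_wiggle",
]

logger = logging.getLogger(__name__)

#: Mismatch budget used throughout unless overridden.
DEFAULT_MAX_MISMATCHES = 3

#: Separator joining names of equal-best ambiguous annotations.
AMBIGUOUS_SEP = ";"

Locus = tuple[str, int, int, str]  # chrom, start (0-based), end (exclusive), strand


@dataclass
class MirnaReference:
    """Mature miRNA sequences, optionally with genomic loci (BED-style)."""

    entries: list[tuple[str, str]] = field(default_factory=list)
    loci: dict[str, Locus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate miRNA names in reference")
        for name, seq in self.entries:
            if len(seq) < 15:
                raise ConfigurationError(
                    f"reference {name!r}: mature sequence shorter than 15 nt"
                )
        for name, (chrom, start, end, strand) in self.loci.items():
            if end <= start:
                raise ConfigurationError(f"locus for {name!r}: end <= start")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]


@dataclass(frozen=True)
class MappingHit:
    """One ungapped placement of a tag within a mature sequence."""

    tag_sequence: str
    mirna_name: str
    mismatches: int
    offset: int


@dataclass
class PeakTrack:
    """Non-overlapping genomic intervals with summed read-count heights."""

    intervals: list[tuple[str, int, int, int]] = field(default_factory=list)

    def total_height(self) -> int:
        return sum(h for _, _, _, h in self.intervals)


def read_mirna_reference(
    fasta_path: str | Path, loci_bed: str | Path | None = None
) -> MirnaReference:
    """Load mature sequences from FASTA, and per-miRNA loci from BED6.

    FASTA headers are taken as miRNA names (first whitespace token); U is
    converted to T so RNA-alphabet references work directly.
    """
    entries = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        entries.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    loci: dict[str, Locus] = {}
    if loci_bed is not None:
        with open(loci_bed) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise ParseError(f"{loci_bed}: line {lineno}: expected BED6")
                chrom, start, end, name, _score, strand = fields[:6]
                try:
                    loci[name] = (chrom, int(start), int(end), strand)
                except ValueError:
                    raise ParseError(
                        f"{loci_bed}: line {lineno}: non-integer coordinates"
                    ) from None
    return MirnaReference(entries=entries, loci=loci)


def _hamming(tag: str, window: str) -> int:
    # N never matches anything, including another N
    return sum(1 for a, b in zip(tag, window) if a != b or a == "N")


def map_tags(
    table: CountTable,
    reference: MirnaReference,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[MappingHit]:
    """Align every tag against every mature sequence at every offset.

    For each tag the minimum attainable mismatch count m* over all
    (reference, offset) placements is found; all placements achieving m* are
    reported iff m* <= ``max_mismatches``.  References shorter than the tag
    contribute no placements.
    """
    if max_mismatches < 0:
        raise ConfigurationError("max_mismatches must be >= 0")
    if not reference.entries:
        raise ConfigurationError("empty miRNA reference")
    hits: list[MappingHit] = []
    for tag in table.tags:
        best = max_mismatches + 1
        placements: list[tuple[str, int, int]] = []
        for name, mature in reference.entries:
            span = len(mature) - len(tag)
            if span < 0:
                continue
            for offset in range(span + 1):
                d = _hamming(tag, mature[offset : offset + len(tag)])
                if d < best:
                    best = d
                    placements = [(name, d, offset)]
                elif d == best:
                    placements.append((name, d, offset))
        if best <= max_mismatches:
            hits.extend(
                MappingHit(tag, name, d, offset) for name, d, offset in placements
            )
    return hits


def best_annotations(hits: Iterable[MappingHit]) -> dict[str, list[str]]:
    """Tag -> sorted unique miRNA names among its equal-best hits."""
    by_tag: dict[str, list[MappingHit]] = {}
    for hit in hits:
        by_tag.setdefault(hit.tag_sequence, []).append(hit)
    out: dict[str, list[str]] = {}
    for tag, tag_hits in by_tag.items():
        best = min(h.mismatches for h in tag_hits)
        out[tag] = sorted({h.mirna_name for h in tag_hits if h.mismatches == best})
    return out


def annotate_table(table: CountTable, hits: Sequence[MappingHit]) -> CountTable:
    """Attach miRNA names to tags; drop tags without any reference hit.

    Tags whose best hit is unique get that miRNA's name; tags tied between
    several references get the names joined by ';' (and are treated as
    ambiguous downstream).
    """
    names = best_annotations(hits)
    out = CountTable(samples=list(table.samples))
    for tag, row in table.counts.items():
        if tag not in names:
            continue
        out.counts[tag] = dict(row)
        out.annotations[tag] = AMBIGUOUS_SEP.join(names[tag])
    return out


def build_peak_track(
    table: CountTable,
    hits: Sequence[MappingHit],
    reference: MirnaReference,
    sample_id: str,
) -> PeakTrack:
    """Project uniquely annotated tag counts onto genomic loci.

    Each unambiguous tag adds its count for ``sample_id`` to its miRNA's
    locus; overlapping loci are merged into one interval whose height is the
    sum.  Tags with ambiguous best hits, or whose miRNA lacks a locus, are
    skipped (the latter with a warning).
    """
    if sample_id not in table.samples:
        raise ConfigurationError(f"unknown sample {sample_id!r}")
    names = best_annotations(hits)
    weighted: dict[str, int] = {}
    for tag, count in table.sample_counts(sample_id).items():
        tag_names = names.get(tag)
        if not tag_names or len(tag_names) > 1:
            continue
        name = tag_names[0]
        if name not in reference.loci:
            logger.warning("miRNA %s has no locus; tag %s skipped", name, tag)
            continue
        weighted[name] = weighted.get(name, 0) + count

    raw = sorted(
        (reference.loci[name][0], reference.loci[name][1], reference.loci[name][2], h)
        for name, h in weighted.items()
    )
    merged: list[tuple[str, int, int, int]] = []
    for chrom, start, end, height in raw:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            pchrom, pstart, pend, pheight = merged[-1]
            merged[-1] = (pchrom, pstart, max(pend, end), pheight + height)
        else:
            merged.append((chrom, start, end, height))
    return PeakTrack(intervals=merged)


def peak_histogram(
    track: PeakTrack, log_base: float = 10.0, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of log-transformed peak heights.

    Returns (bin_edges, frequencies); edges partition [0, max(log height)]
    into ``bin_width``-wide bins in log space.  Frequencies sum to the
    number of intervals.
    """
    if log_base <= 1:
        raise ConfigurationError("log_base must be > 1")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be > 0")
    heights = np.array([h for _, _, _, h in track.intervals], dtype=float)
    if heights.size == 0:
        return np.array([0.0]), np.array([], dtype=int)
    if np.any(heights < 1):
        raise DataError("peak heights must be >= 1 to take logs")
    # round to stabilize exact powers of the base against log-ratio error
    logs = np.round(np.log(heights) / np.log(log_base), 12)
    n_bins = max(1, math.ceil(max(logs.max(), 0) / bin_width + 1e-12))
    edges = np.arange(n_bins + 1) * bin_width
    freqs, _ = np.histogram(logs, bins=edges)
    return edges, freqs


def write_bed(track: PeakTrack, path: str | Path, track_name: str = "peaks") -> None:
    """Write the track as BED5 (0-based half-open; height in column 5)."""
    with open(path, "w") as out:
        out.write(f'track name="{track_name}"\n')
        for i, (chrom, start, end, height) in enumerate(track.intervals, start=1):
            out.write(f"{chrom}\t{start}\t{end}\tpeak{i}\t{height}\n")


def read_bed(path: str | Path) -> PeakTrack:
    """Read a BED5 peak track written by :func:`write_bed`."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}: line {lineno}: expected BED5")
            chrom, start, end, _name, height = fields[:5]
            try:
                intervals.append((chrom, int(start), int(end), int(height)))
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer field") from None
    return PeakTrack(intervals=sorted(intervals))


def write_wiggle(track: PeakTrack, path: str | Path, track_name: str = "peaks") -> None:
    """Write the track as variableStep wiggle (1-based; height repeated per base)."""
    with open(path, "w") as out:
        out.write(f'track type=wiggle_0 name="{track_name}"\n')
        current_chrom = None
        for chrom, start, end, height in track.intervals:
            if chrom != current_chrom:
                out.write(f"variableStep chrom={chrom}\n")
                current_chrom = chrom
            for pos in range(start + 1, end + 1):
                out.write(f"{pos}\t{height}\n")
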