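"""Abundance ranking of miRNAs and comparison of top-N lists.

After thresholding, miRNAs are ranked by read count within each sample or
compartment; top-N lists from different platforms (sequencing vs array) or
compartments (intracellular vs secreted) are compared as sets, with Cohen's
kappa quantifying the chance-corrected overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .errors import ConfigurationError
from .io import CountTable
from .thresholds import AgreementResult, cohens_kappa

__all__ = ["RankedList", "rank_mirnas", "top_n_overlap", "family_summary"]

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """miRNA names with abundances, in non-increasing abundance order."""

    sample_or_group: str
    entries: list[tuple[str, int]]

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def top(self, n: int) -> set[str]:
        return set(self.names[:n])


def rank_mirnas(table: CountTable, sample_id: str, min_count: int = 1) -> RankedList:
    """Rank tags of one sample by descending count, keeping counts >= min_count.

    Annotated tables are ranked by miRNA name (annotation); bare tables by
    tag sequence.  Ties are broken lexicographically by name.
    """
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    entries = [
        (table.name_of(tag), count)
        for tag, count in table.sample_counts(sample_id).items()
        if count >= min_count
    ]
    entries.sort(key=lambda item: (-item[1], item[0]))
    return RankedList(sample_or_group=sample_id, entries=entries)


def top_n_overlap(
    list_a: RankedList, list_b: RankedList, n: int, universe: Iterable[str]
) -> AgreementResult:
    """Set overlap and kappa of the two top-n name sets over ``universe``.

    Lists shorter than n are truncated to their own length with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ConfigurationError("empty universe for top-N comparison")
    if n > list_a.n or n > list_b.n:
        logger.warning(
            "top-%d requested but lists have %d and %d entries; truncating",
            n, list_a.n, list_b.n,
        )
    top_a = list_a.top(n)
    top_b = list_b.top(n)
    return AgreementResult(
        set_a_size=len(top_a),
        set_b_size=len(top_b),
        intersection_size=len(top_a & top_b),
        universe_size=len(universe),
        kappa=cohens_kappa(top_a, top_b, universe | top_a | top_b),
    )


def family_summary(ranked: RankedList, family_prefix: str) -> tuple[int, int]:
    """(member count, summed abundance) of entries whose name starts with prefix."""
    members = [(name, c) for name, c in ranked.entries if name.startswith(family_prefix)]
    return len(members), sum(c for _, c in members)
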