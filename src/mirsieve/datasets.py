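"""Bundled example count tables.

Two small annotated tag-count tables ship with the package: the top-ranked
intracellular miRNAs of an hES-MSC deep-sequencing experiment (16 tags, two
replicates, all counts above 10,000) and the top-ranked extracellular
(secreted/exosomal) miRNAs of the same cells (20 tags, three replicates,
all counts in the mid-range band).  Both compartments are dominated by the
let-7 family.  They serve as worked-example inputs for ranking, tiering and
top-N comparison.
"""

from __future__ import annotations

from importlib import resources

from .io import CountTable, read_count_table
from .mapping import MirnaReference

__all__ = [
    "load_intracellular_top",
    "load_extracellular_top",
    "reference_from_table",
]


def _load(name: str) -> CountTable:
    with resources.as_file(resources.files("mirsieve") / "data" / name) as path:
        return read_count_table(path)


def load_intracellular_top() -> CountTable:
    """Top intracellular miRNA tag counts (samples IC1, IC2)."""
    return _load("intracellular_top.tsv")


def load_extracellular_top() -> CountTable:
    """Top extracellular miRNA tag counts (samples EC1, EC2, EC3)."""
    return _load("extracellular_top.tsv")


def reference_from_table(table: CountTable) -> MirnaReference:
    """Mature-miRNA reference built from an annotated table's (name, tag) pairs."""
    entries: dict[str, str] = {}
    for tag, name in table.annotations.items():
        entries.setdefault(name, tag)
    return MirnaReference(entries=sorted(entries.items()))
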