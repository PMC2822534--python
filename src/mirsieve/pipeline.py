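"""End-to-end orchestration: reads -> counts -> annotation -> threshold ->
tiers -> ranking -> (optional) network sieving and expression ratios.

A single declarative YAML config drives the run; every stage writes plain
TSV/BED/wiggle outputs into the output directory and a ``manifest.json``
records versions, parameters, seeds, completed stages and warning counts,
so that repeated runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .io import (
    CountTable,
    LengthWindow,
    collapse_reads,
    filter_length,
    merge_tables,
    read_count_table,
    read_reads,
    trim_adapter,
    write_count_table,
)
from .mapping import (
    annotate_table,
    build_peak_track,
    map_tags,
    read_mirna_reference,
    write_bed,
    write_wiggle,
)
from .networks import (
    ExpressionMatrix,
    common_nodes,
    direction_concordance,
    normalized_group_ratio,
    read_edge_list,
)
from .ranking import family_summary, rank_mirnas, top_n_overlap
from .thresholds import (
    adaptive_threshold,
    assign_tiers,
    cohens_kappa,
    count_distribution,
    cpm_scale,
    tier_venn,
    CountDistribution,
    TIERS,
)

__all__ = ["SampleSpec", "PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

COMPARTMENTS = ("intracellular", "extracellular")


@dataclass(frozen=True)
class SampleSpec:
    id: str
    path: str
    format: str = "fastq"  # fastq | fasta | counts
    compartment: str = "intracellular"

    def __post_init__(self) -> None:
        if self.format not in ("fastq", "fasta", "counts"):
            raise ConfigurationError(f"sample {self.id}: unknown format {self.format!r}")
        if self.compartment not in COMPARTMENTS:
            raise ConfigurationError(
                f"sample {self.id}: unknown compartment {self.compartment!r}"
            )


@dataclass
class PipelineConfig:
    """Validated run parameters; defaults are the workflow's standard values."""

    samples: list[SampleSpec]
    output_dir: str
    reference_fasta: str | None = None
    reference_loci: str | None = None
    adapter: str | None = None
    min_overlap: int = 6
    length_window: tuple[int, int] = (18, 35)
    length_filter_mode: str = "intracellular"  # intracellular | all | none
    max_mismatches: int = 3
    tier_boundaries: tuple[int, int] = (32, 10_000)
    sweep_t_min: int = 1
    sweep_t_max: int | None = None
    cpm_normalize: bool = False  # scale sweep inputs to counts per million
    top_n: dict[str, int] = field(
        default_factory=lambda: {"intracellular": 100, "extracellular": 50}
    )
    network_a: str | None = None
    network_b: str | None = None
    expression_matrix: str | None = None
    expression_groups: str | None = None
    housekeeping_gene: str = "GAPDH"
    ratio_numerator: str | None = None
    ratio_denominator: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.samples:
            raise ConfigurationError("at least one sample is required")
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate sample ids")
        if self.length_filter_mode not in ("intracellular", "all", "none"):
            raise ConfigurationError(
                f"unknown length_filter_mode {self.length_filter_mode!r}"
            )
        lo, hi = self.tier_boundaries
        if not lo < hi:
            raise ConfigurationError("tier boundaries must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw: dict[str, Any] = yaml.safe_load(handle) or {}
        try:
            samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
            reference = raw.pop("reference", {}) or {}
            sweep = raw.pop("sweep", {}) or {}
            networks = raw.pop("networks", {}) or {}
            expression = raw.pop("expression", {}) or {}
            cfg = cls(
                samples=samples,
                output_dir=raw.pop("output_dir", "mirsieve_out"),
                reference_fasta=reference.get("fasta"),
                reference_loci=reference.get("loci"),
                adapter=raw.pop("adapter", None),
                min_overlap=raw.pop("min_overlap", 6),
                length_window=tuple(raw.pop("length_window", (18, 35))),
                length_filter_mode=raw.pop("length_filter_mode", "intracellular"),
                max_mismatches=raw.pop("max_mismatches", 3),
                tier_boundaries=tuple(raw.pop("tier_boundaries", (32, 10_000))),
                sweep_t_min=sweep.get("t_min", 1),
                sweep_t_max=sweep.get("t_max"),
                cpm_normalize=sweep.get("cpm", False),
                top_n=raw.pop("top_n", {"intracellular": 100, "extracellular": 50}),
                network_a=networks.get("a"),
                network_b=networks.get("b"),
                expression_matrix=expression.get("matrix"),
                expression_groups=expression.get("groups"),
                housekeeping_gene=expression.get("housekeeping", "GAPDH"),
                ratio_numerator=expression.get("numerator"),
                ratio_denominator=expression.get("denominator"),
                seed=raw.pop("seed", 0),
            )
        except TypeError as exc:
            raise ConfigurationError(f"invalid config: {exc}") from exc
        unknown = set(raw)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cfg


def _load_sample(cfg: PipelineConfig, sample: SampleSpec) -> CountTable:
    if sample.format == "counts":
        table = read_count_table(sample.path)
        if sample.id not in table.samples:
            raise ConfigurationError(
                f"count table {sample.path} lacks a column {sample.id!r}"
            )
        sub = CountTable(samples=[sample.id])
        for tag, row in table.counts.items():
            if sample.id in row:
                sub.counts[tag] = {sample.id: row[sample.id]}
        sub.annotations = dict(table.annotations)
        return sub
    reads = read_reads(sample.path, sample.format)
    if cfg.adapter:
        reads = trim_adapter(reads, cfg.adapter, cfg.min_overlap)
    if cfg.length_filter_mode == "all" or (
        cfg.length_filter_mode == "intracellular"
        and sample.compartment == "intracellular"
    ):
        reads = filter_length(reads, LengthWindow(*cfg.length_window))
    return collapse_reads(reads, sample.id)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all configured stages; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "versions": {
            "mirsieve": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "parameters": {
            "adapter": config.adapter,
            "min_overlap": config.min_overlap,
            "length_window": list(config.length_window),
            "length_filter_mode": config.length_filter_mode,
            "max_mismatches": config.max_mismatches,
            "tier_boundaries": list(config.tier_boundaries),
            "sweep": {"t_min": config.sweep_t_min, "t_max": config.sweep_t_max},
            "top_n": config.top_n,
        },
        "stages": [],
        "notices": [],
        "selected_thresholds": {},
    }

    def done(stage: str) -> None:
        manifest["stages"].append(stage)

    def notice(msg: str) -> None:
        logger.info(msg)
        manifest["notices"].append(msg)

    # --- collapse ---------------------------------------------------------
    by_compartment: dict[str, list[str]] = {c: [] for c in COMPARTMENTS}
    tables = []
    for sample in config.samples:
        tables.append(_load_sample(config, sample))
        by_compartment[sample.compartment].append(sample.id)
    table = merge_tables(tables)
    write_count_table(table, out / "counts.tsv")
    done("collapse")

    # --- map & annotate ---------------------------------------------------
    reference = None
    hits = None
    if config.reference_fasta:
        reference = read_mirna_reference(config.reference_fasta, config.reference_loci)
        hits = map_tags(table, reference, config.max_mismatches)
        table = annotate_table(table, hits)
        write_count_table(table, out / "annotated_counts.tsv")
        done("map")
        if reference.loci:
            for sample in config.samples:
                track = build_peak_track(table, hits, reference, sample.id)
                write_bed(track, out / f"peaks_{sample.id}.bed", track_name=sample.id)
                write_wiggle(track, out / f"peaks_{sample.id}.wig", track_name=sample.id)
            done("peaks")
        else:
            notice("no loci supplied; peak-track stage skipped")
    else:
        notice("no reference supplied; mapping stage skipped")

    # --- count distributions ---------------------------------------------
    distributions = {}
    for sample in config.samples:
        dist = count_distribution(table, sample.id)
        distributions[sample.id] = dist
        values, freqs = np.unique(dist.counts, return_counts=True)
        pd.DataFrame({"count": values, "n_tags": freqs}).to_csv(
            out / f"distribution_{sample.id}.tsv", sep="\t", index=False
        )
    done("distributions")

    # --- KS sweep ---------------------------------------------------------
    sweepable = {c: ids for c, ids in by_compartment.items() if len(ids) >= 2}
    if not sweepable:
        raise DataError(
            "the KS threshold sweep requires at least two replicates in a "
            "compartment; provide a second sample or precomputed counts"
        )
    for compartment, ids in sweepable.items():
        pair = [distributions[ids[0]], distributions[ids[1]]]
        if config.cpm_normalize:
            pair = [
                CountDistribution(cpm_scale(d.counts), d.sample_id) for d in pair
            ]
        result = adaptive_threshold(
            pair[0],
            pair[1],
            t_min=config.sweep_t_min,
            t_max=config.sweep_t_max,
        )
        pd.DataFrame(
            {
                "threshold": result.thresholds,
                "D": result.D,
                "n_a": result.n_retained[:, 0],
                "n_b": result.n_retained[:, 1],
            }
        ).to_csv(out / f"sweep_{compartment}.tsv", sep="\t", index=False)
        manifest["selected_thresholds"][compartment] = result.selected_threshold
    done("sweep")

    # --- tiers, Venn, kappa ----------------------------------------------
    partition = assign_tiers(table, config.tier_boundaries)
    tier_rows = [
        {"tag": tag, "sample": s, "count": table.get(tag, s), "tier": tier}
        for s, tags in partition.tiers.items()
        for tag, tier in sorted(tags.items())
    ]
    pd.DataFrame(tier_rows, columns=["tag", "sample", "count", "tier"]).to_csv(
        out / "tiers.tsv", sep="\t", index=False
    )
    universe = set(table.tags)
    venn_rows = []
    for compartment, ids in by_compartment.items():
        for a, b in combinations(ids, 2):
            for tier in TIERS:
                agreement = tier_venn(partition, a, b, tier)
                kappa = cohens_kappa(
                    partition.tier_set(a, tier), partition.tier_set(b, tier), universe
                )
                venn_rows.append(
                    {
                        "compartment": compartment,
                        "sample_a": a,
                        "sample_b": b,
                        "tier": tier,
                        "n_a": agreement.set_a_size,
                        "n_b": agreement.set_b_size,
                        "overlap": agreement.intersection_size,
                        "kappa": round(kappa, 6),
                    }
                )
    pd.DataFrame(
        venn_rows,
        columns=[
            "compartment", "sample_a", "sample_b", "tier", "n_a", "n_b",
            "overlap", "kappa",
        ],
    ).to_csv(out / "venn_kappa.tsv", sep="\t", index=False)
    done("tiers")

    # --- ranking & top-N comparisons -------------------------------------
    ranked = {}
    # rank above the compartment's selected threshold; fall back to the
    # Low/Mid boundary when the compartment had no replicate pair to sweep
    min_counts = {
        c: manifest["selected_thresholds"].get(c, config.tier_boundaries[0])
        for c in COMPARTMENTS
    }
    for sample in config.samples:
        lst = rank_mirnas(table, sample.id, min_counts[sample.compartment])
        ranked[sample.id] = lst
        pd.DataFrame(
            [
                {"rank": i + 1, "name": name, "count": count}
                for i, (name, count) in enumerate(lst.entries)
            ],
            columns=["rank", "name", "count"],
        ).to_csv(out / f"ranked_{sample.id}.tsv", sep="\t", index=False)
    name_universe = {table.name_of(t) for t in table.tags}
    compare_rows = []
    pairs = [
        (a, b, config.top_n.get(c, 100), c)
        for c, ids in by_compartment.items()
        for a, b in combinations(ids, 2)
    ]
    if by_compartment["intracellular"] and by_compartment["extracellular"]:
        pairs.append(
            (
                by_compartment["intracellular"][0],
                by_compartment["extracellular"][0],
                config.top_n.get("extracellular", 50),
                "cross-compartment",
            )
        )
    for a, b, n, context in pairs:
        n_eff = min(n, ranked[a].n, ranked[b].n)
        if n_eff == 0:
            notice(f"top-N comparison {a} vs {b} skipped: empty ranked list")
            continue
        agreement = top_n_overlap(ranked[a], ranked[b], n_eff, name_universe)
        compare_rows.append(
            {
                "context": context,
                "sample_a": a,
                "sample_b": b,
                "n": n_eff,
                "overlap": agreement.intersection_size,
                "kappa": round(agreement.kappa, 6),
            }
        )
    pd.DataFrame(
        compare_rows,
        columns=["context", "sample_a", "sample_b", "n", "overlap", "kappa"],
    ).to_csv(out / "topn_comparisons.tsv", sep="\t", index=False)
    done("rank")

    # --- networks ---------------------------------------------------------
    if config.network_a and config.network_b:
        net_a = read_edge_list(config.network_a, label="alignment-derived")
        net_b = read_edge_list(config.network_b, label="prediction-derived")
        report = common_nodes(net_a, net_b)
        pd.DataFrame(
            [
                {
                    "gene": g,
                    "degree_a": report.degrees_a[g],
                    "degree_b": report.degrees_b[g],
                    "min_degree": min(report.degrees_a[g], report.degrees_b[g]),
                }
                for g in report.shared_hubs
            ],
            columns=["gene", "degree_a", "degree_b", "min_degree"],
        ).to_csv(out / "hubs.tsv", sep="\t", index=False)
        done("networks")
    else:
        notice("network inputs not supplied; network stage skipped")

    # --- expression ratios ------------------------------------------------
    if config.expression_matrix and config.expression_groups:
        if not (config.ratio_numerator and config.ratio_denominator):
            raise ConfigurationError(
                "expression stage needs numerator and denominator group labels"
            )
        values = pd.read_csv(config.expression_matrix, sep="\t", index_col=0)
        groups_frame = pd.read_csv(config.expression_groups, sep="\t")
        groups = dict(zip(groups_frame.iloc[:, 0], groups_frame.iloc[:, 1]))
        expr = ExpressionMatrix(
            values=values, groups=groups, housekeeping_gene=config.housekeeping_gene
        )
        genes = set(values.index) - {config.housekeeping_gene}
        ratios = normalized_group_ratio(
            expr, genes, config.ratio_numerator, config.ratio_denominator
        )
        pd.DataFrame(
            sorted(ratios.items()), columns=["gene", "ratio"]
        ).to_csv(out / "ratios.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["ratio_concordance_gt1"] = round(
            direction_concordance(ratios, ">1"), 6
        )
        done("expression")
    else:
        notice("expression inputs not supplied; expression stage skipped")

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return out
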