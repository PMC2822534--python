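"""Synthetic data generators mirroring the structure of real small-RNA runs.

The central generator, :func:`simulate_count_replicates`, emulates the
two-component count structure seen in deep-sequencing replicates: a large,
replicate-discordant noise component with exponentially declining counts
confined below an abundance boundary, and a smaller log-normal-like signal
component shared across replicates.  Because the components are separated at
a known boundary, the KS threshold sweep can be validated as a parameter-
recovery experiment: the sweep should select the generator's boundary.

Companion generators emit FASTQ reads (for end-to-end pipeline tests),
paired interaction networks with designated shared hubs, and expression
matrices with known fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, DataError
from .io import CountTable
from .mapping import MirnaReference
from .networks import ExpressionMatrix, InteractionNetwork

import pandas as pd

__all__ = [
    "MixtureSpec",
    "MixtureTruth",
    "simulate_count_replicates",
    "simulate_reads",
    "simulate_networks",
    "simulate_expression",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of the two-component replicate count mixture.

    Noise counts follow a geometric distribution (success probabilities per
    replicate) truncated to [1, boundary-1]; most noise tags are private to
    one replicate (co-occurrence probability ``noise_cooccurrence``).
    Signal tags are shared: each has a log-normal mean (location/scale on
    log2 counts), Poisson-resampled per replicate and floored at the
    boundary so that signal never leaks below it.

    The default noise success probabilities scale with the boundary —
    2/boundary and 4/boundary, i.e. untruncated mean counts of boundary/2
    and boundary/4 — so the exponential decline genuinely spans the whole
    sub-boundary range [1, boundary-1] (the truncation visibly shapes the
    tail) while the two replicates decay at clearly different rates.  A
    steeper choice would extinguish the noise far below the boundary,
    leaving the threshold-recovery experiment with nothing to detect at
    the boundary itself.
    """

    n_noise_tags: int = 5000
    n_signal_tags: int = 2000
    boundary: int = 32
    noise_p: tuple[float, float] | None = None
    noise_cooccurrence: float = 0.3
    signal_log2_location: float = math.log2(1000)
    signal_log2_scale: float = 1.5
    tag_length: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary < 2:
            raise ConfigurationError("boundary must be >= 2")
        if self.n_signal_tags < 2:
            raise ConfigurationError("need at least 2 signal tags")
        if not all(0 < p < 1 for p in self.noise_probs):
            raise ConfigurationError("noise probabilities must be in (0, 1)")
        if not 0 <= self.noise_cooccurrence <= 1:
            raise ConfigurationError("noise_cooccurrence must be in [0, 1]")

    @property
    def noise_probs(self) -> tuple[float, float]:
        """Per-replicate geometric success probabilities (resolved defaults)."""
        if self.noise_p is not None:
            return self.noise_p
        return (2.0 / self.boundary, 4.0 / self.boundary)


@dataclass
class MixtureTruth:
    """Ground truth of one simulated replicate pair."""

    signal_tags: list[str]
    signal_means: np.ndarray
    noise_tags: dict[str, set[str]] = field(default_factory=dict)  # sample -> tags


def _random_tags(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct random DNA sequences."""
    tags: set[str] = set()
    while len(tags) < n:
        block = _BASES[rng.integers(0, 4, size=(n - len(tags), length))]
        tags.update("".join(row) for row in block)
    return sorted(tags)


def _truncated_geometric(
    rng: np.random.Generator, p: float, upper: int, size: int
) -> np.ndarray:
    """Geometric(p) on {1, 2, ...} conditioned on values <= upper."""
    u = rng.random(size)
    cdf_upper = 1.0 - (1.0 - p) ** upper
    v = u * cdf_upper
    k = np.ceil(np.log1p(-v) / np.log1p(-p)).astype(np.int64)
    return np.clip(k, 1, upper)


def simulate_count_replicates(
    spec: MixtureSpec, return_truth: bool = False
) -> CountTable | tuple[CountTable, MixtureTruth]:
    """Draw a two-replicate count table from the noise + signal mixture.

    Samples are named ``rep1`` and ``rep2``.  All counts are >= 1; every
    signal-tag count is >= ``spec.boundary`` in both replicates.
    """
    rng = np.random.default_rng(spec.seed)
    samples = ["rep1", "rep2"]

    n_shared = int(round(spec.noise_cooccurrence * spec.n_noise_tags))
    n_private = spec.n_noise_tags - n_shared
    pool = _random_tags(
        rng, spec.n_signal_tags + n_shared + 2 * n_private, spec.tag_length
    )
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    signal_tags = pool[: spec.n_signal_tags]
    rest = pool[spec.n_signal_tags :]
    shared_noise = rest[:n_shared]
    private = {
        "rep1": rest[n_shared : n_shared + n_private],
        "rep2": rest[n_shared + n_private :],
    }

    table = CountTable(samples=list(samples))
    signal_means = np.exp2(
        rng.normal(spec.signal_log2_location, spec.signal_log2_scale, spec.n_signal_tags)
    )
    for sample, p in zip(samples, spec.noise_probs):
        noise_tags = shared_noise + private[sample]
        noise_counts = _truncated_geometric(
            rng, p, spec.boundary - 1, len(noise_tags)
        )
        for tag, count in zip(noise_tags, noise_counts):
            table.counts.setdefault(tag, {})[sample] = int(count)
        signal_counts = np.maximum(rng.poisson(signal_means), spec.boundary)
        for tag, count in zip(signal_tags, signal_counts):
            table.counts.setdefault(tag, {})[sample] = int(count)

    if not return_truth:
        return table
    truth = MixtureTruth(
        signal_tags=list(signal_tags),
        signal_means=signal_means,
        noise_tags={s: set(shared_noise) | set(private[s]) for s in samples},
    )
    return table, truth


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_reads(
    table: CountTable,
    reference: MirnaReference,
    adapter: str,
    error_rate: float,
    seed: int,
    out_dir: str | Path,
    strict: bool = True,
) -> dict[str, Path]:
    """Expand a count table back into per-sample FASTQ files.

    Each tag is emitted count-many times with the 3' adapter appended;
    substitution errors at ``error_rate`` are applied to the insert only
    (the adapter is left exact so trimming stays deterministic).  In strict
    mode every tag must equal a reference mature sequence.
    """
    if not 0 <= error_rate <= 0.05:
        raise ConfigurationError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mature = {seq for _, seq in reference.entries}
    if strict:
        missing = [t for t in table.tags if t not in mature]
        if missing:
            raise DataError(
                f"{len(missing)} tags absent from the reference (strict mode); "
                f"first: {missing[0]}"
            )
    paths: dict[str, Path] = {}
    for sample in table.samples:
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as out:
            i = 0
            for tag, count in table.sample_counts(sample).items():
                for _ in range(count):
                    i += 1
                    seq = _mutate(rng, tag, error_rate) + adapter
                    out.write(f"@{sample}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
    return paths


def simulate_networks(
    n_shared_hubs: int,
    n_private: int,
    degree: int,
    seed: int = 0,
    hub_names: list[str] | None = None,
) -> tuple[InteractionNetwork, InteractionNetwork]:
    """Build two networks sharing designated hub nodes of a given degree.

    Each hub appears in both networks connected to ``degree`` neighbors;
    neighbor and private-node name spaces are disjoint between the two
    networks, so the hubs are exactly the common nodes.
    """
    if min(n_shared_hubs, n_private, degree) < 0:
        raise ConfigurationError("parameters must be >= 0")
    if hub_names is None:
        hub_names = [f"HUB{i + 1}" for i in range(n_shared_hubs)]
    if len(hub_names) != n_shared_hubs:
        raise ConfigurationError("hub_names length must equal n_shared_hubs")
    rng = np.random.default_rng(seed)
    nets = []
    for side in ("A", "B"):
        edges: list[tuple[str, str]] = []
        for hub in hub_names:
            for j in range(degree):
                edges.append((hub, f"{side}_{hub}_N{j + 1}"))
        for j in range(n_private):
            edges.append((f"{side}_P{j + 1}", f"{side}_P{j + 1}C"))
        rng.shuffle(edges)
        nets.append(InteractionNetwork.from_edges(edges, label=f"net_{side}"))
    return nets[0], nets[1]


def simulate_expression(
    genes: Iterable[str],
    groups: Mapping[str, int],
    effect: Mapping[str, float] | float,
    noise_cv: float,
    seed: int = 0,
    housekeeping: str = "GAPDH",
    baseline: float = 100.0,
    housekeeping_value: float = 1000.0,
) -> ExpressionMatrix:
    """Expression matrix with known per-gene fold changes between two groups.

    ``groups`` maps exactly two group labels to sample counts; the first
    label is the fold-change (numerator) group, the second the baseline.
    Multiplicative mean-1 log-normal noise with coefficient of variation
    ``noise_cv`` is applied to every cell; at ``noise_cv`` 0 the recovered
    ratios are exact.
    """
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    labels = list(groups)
    if len(labels) != 2:
        raise ConfigurationError("exactly two groups are required")
    genes = sorted(set(genes) - {housekeeping})
    folds = (
        {g: float(effect) for g in genes}
        if isinstance(effect, (int, float))
        else {g: float(effect.get(g, 1.0)) for g in genes}
    )
    rng = np.random.default_rng(seed)
    samples: list[str] = []
    sample_groups: dict[str, str] = {}
    for label in labels:
        for i in range(groups[label]):
            name = f"{label}_{i + 1}"
            samples.append(name)
            sample_groups[name] = label

    def noisy(mean: float) -> float:
        if noise_cv == 0:
            return mean
        sigma = math.sqrt(math.log1p(noise_cv**2))
        return mean * float(rng.lognormal(-sigma**2 / 2, sigma))

    data = {}
    for sample in samples:
        is_num = sample_groups[sample] == labels[0]
        col = [
            noisy(baseline * (folds[g] if is_num else 1.0)) for g in genes
        ]
        col.append(noisy(housekeeping_value))
        data[sample] = col
    frame = pd.DataFrame(data, index=[*genes, housekeeping])
    return ExpressionMatrix(
        values=frame, groups=sample_groups, housekeeping_gene=housekeeping
    )
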