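"""Synthetic multi-round selection datasets with planted binder families.

Round 1 mixes a background of random NNK-encoded peptides with planted
families (a seed peptide plus independent per-position mutations).  Each
later round reweights unique-peptide frequencies by fitness
(p' ~ p * w) and redraws reads multinomially, emulating selection; reads
are reverse-translated to NNK-consistent DNA, wrapped in the library
architecture, and emitted as FASTQ with optional per-base substitution
error.  The ground truth (per-peptide family labels and multiplicities) is
retained so every downstream module can be checked exactly.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .libcode import (
    STOP,
    GeneticCode,
    LibraryArchitecture,
    nnk_codons,
    nnk_codons_for,
    translate_codon,
)

__all__ = [
    "FamilySpec",
    "SelectionSimConfig",
    "SimTruth",
    "SimResult",
    "BACKGROUND",
    "sample_library",
    "advance_round",
    "emit_fastq",
    "simulate_selection",
]

BACKGROUND = "background"

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NNK = nnk_codons()
_NNK_BY_AA = {aa: nnk_codons_for(aa) for aa in _AA20}


@dataclass(frozen=True)
class FamilySpec:
    """One planted binder family."""

    seed: str  # random-region peptide, length = random_codon_count
    mutation_rate: float  # independent per-position substitution probability
    fitness: float  # multiplicative selection weight, > 0
    initial_fraction: float  # share of round-1 reads

    def __post_init__(self) -> None:
        if not set(self.seed) <= set(_AA20):
            raise ValueError(f"seed must use the 20 residue letters: {self.seed!r}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.fitness <= 0:
            raise ValueError("fitness must be > 0")
        if not 0.0 <= self.initial_fraction <= 1.0:
            raise ValueError("initial_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SelectionSimConfig:
    seed: int
    families: tuple[FamilySpec, ...]
    rounds: int = 5
    reads_per_round: int = 10_000
    background_fitness: float = 1.0
    per_base_error: float = 0.0
    library_tag: str = "L"

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.reads_per_round < 1:
            raise ValueError("rounds and reads_per_round must be >= 1")
        if self.background_fitness <= 0:
            raise ValueError("background_fitness must be > 0")
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must be in [0, 1]")
        if self.library_tag not in ("L", "D"):
            raise ValueError("library_tag must be 'L' or 'D'")
        total = sum(f.initial_fraction for f in self.families)
        if total > 1.0 + 1e-9:
            raise ValueError("family initial fractions exceed 1")
        lengths = {len(f.seed) for f in self.families}
        if len(lengths) > 1:
            raise ValueError("all family seeds must share one length")

    @property
    def background_fraction_r1(self) -> float:
        return 1.0 - sum(f.initial_fraction for f in self.families)

    @classmethod
    def from_yaml(cls, path) -> "SelectionSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        families = tuple(FamilySpec(**f) for f in raw.pop("families", []))
        return cls(families=families, **raw)

    def to_yaml(self, path) -> None:
        raw = {
            "seed": self.seed,
            "rounds": self.rounds,
            "reads_per_round": self.reads_per_round,
            "background_fitness": self.background_fitness,
            "per_base_error": self.per_base_error,
            "library_tag": self.library_tag,
            "families": [
                {
                    "seed": f.seed,
                    "mutation_rate": f.mutation_rate,
                    "fitness": f.fitness,
                    "initial_fraction": f.initial_fraction,
                }
                for f in self.families
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth for one simulated round."""

    round_index: int
    labels: dict[str, str]  # random-region peptide -> family label
    multiplicities: Counter  # random-region peptide -> emitted read count
    expected_frequencies: dict[str, float]  # family label -> expected share

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("peptide\tfamily\tcount\n")
            for pep in sorted(self.multiplicities):
                fh.write(f"{pep}\t{self.labels[pep]}\t{self.multiplicities[pep]}\n")


@dataclass
class SimResult:
    config: SelectionSimConfig
    arch: LibraryArchitecture
    truths: list[SimTruth] = field(default_factory=list)
    fastq_paths: list[Path] = field(default_factory=list)

    def truth(self, round_index: int) -> SimTruth:
        return self.truths[round_index - 1]


_STD_CODE = GeneticCode()


def _random_nnk_peptide(length: int, rng: np.random.Generator) -> str:
    """Uniform NNK codon sampling with stop-codon rejection, translated."""
    residues = []
    while len(residues) < length:
        codon = _NNK[rng.integers(0, len(_NNK))]
        aa = translate_codon(codon, _STD_CODE)
        if aa == STOP:
            continue
        residues.append(aa)
    return "".join(residues)


def _mutate(seed: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seed
    out = list(seed)
    hits = rng.random(len(seed)) < rate
    for i in np.flatnonzero(hits):
        alternatives = _AA20.replace(seed[i], "")
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def sample_library(
    config: SelectionSimConfig,
    rng: np.random.Generator | None = None,
    *,
    length: int = 15,
) -> SimTruth:
    """Draw the round-1 pool: reads_per_round labelled random-region peptides."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.families:
        length = len(config.families[0].seed)
    probs = [f.initial_fraction for f in config.families] + [config.background_fraction_r1]
    labels_order = [f"family{i + 1}" for i in range(len(config.families))] + [BACKGROUND]
    draws = rng.multinomial(config.reads_per_round, probs)
    labels: dict[str, str] = {}
    multiplicities: Counter = Counter()
    for which, n in enumerate(draws):
        for _ in range(int(n)):
            if which < len(config.families):
                pep = _mutate(config.families[which].seed, config.families[which].mutation_rate, rng)
            else:
                pep = _random_nnk_peptide(length, rng)
            multiplicities[pep] += 1
            labels.setdefault(pep, labels_order[which])
    expected = dict(zip(labels_order, probs))
    return SimTruth(1, labels, multiplicities, expected)


def advance_round(
    frequencies: Mapping[str, float] | Sequence[float],
    fitness: Mapping[str, float] | Sequence[float],
) -> dict[str, float] | np.ndarray:
    """One deterministic selection update: p'_i = p_i w_i / sum_j p_j w_j."""
    if isinstance(frequencies, Mapping):
        keys = list(frequencies)
        p = np.asarray([frequencies[k] for k in keys], dtype=float)
        w = np.asarray([fitness[k] for k in keys], dtype=float)
    else:
        keys = None
        p = np.asarray(frequencies, dtype=float)
        w = np.asarray(fitness, dtype=float)
    z = float(np.sum(p * w))
    if z <= 0:
        raise ValueError("all-zero selection weights")
    out = p * w / z
    if keys is None:
        return out
    return dict(zip(keys, out))


def _reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in peptide:
        options = _NNK_BY_AA[aa.upper()]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def _apply_error(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = list(read)
    hits = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hits):
        alternatives = "ACGT".replace(arr[i], "")
        arr[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(arr)


def emit_fastq(
    pool: Counter,
    config: SelectionSimConfig,
    round_index: int,
    arch: LibraryArchitecture,
    path,
    rng: np.random.Generator | None = None,
) -> Path:
    """Write one round's reads as FASTQ (gzip if the path ends in .gz).

    Each pooled random-region peptide is reverse-translated to uniformly
    chosen NNK codons, wrapped in the architecture, and subjected to
    per-base substitution error; quality is a constant placeholder.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    i = 0
    with opener(path, "wt") as fh:
        for pep in sorted(pool):
            for _ in range(pool[pep]):
                i += 1
                dna = arch.coding_region(_reverse_translate(pep, rng))
                dna = _apply_error(dna, config.per_base_error, rng)
                fh.write(
                    f"@{config.library_tag}_r{round_index}_{i}\n{dna}\n+\n{'I' * len(dna)}\n"
                )
    return path


def _architecture_for(config: SelectionSimConfig) -> LibraryArchitecture:
    return LibraryArchitecture(
        upstream_anchor="GGATTAAGGAGGTGATATTT",
        initiator_symbol="Y" if config.library_tag == "L" else "y",
    )


def simulate_selection(
    config: SelectionSimConfig,
    arch: LibraryArchitecture | None = None,
    outdir=None,
    *,
    gzip_fastq: bool = False,
) -> SimResult:
    """Run the full multi-round simulation.

    Returns per-round ground truth; when ``outdir`` is given, also writes
    one FASTQ per round plus the truth TSVs and the config YAML.  Fully
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    arch = arch if arch is not None else _architecture_for(config)
    result = SimResult(config=config, arch=arch)

    truth = sample_library(config, rng, length=arch.random_codon_count)
    result.truths.append(truth)

    fams = {f"family{i + 1}": f for i, f in enumerate(config.families)}

    for round_index in range(2, config.rounds + 1):
        prev = result.truths[-1]
        total = sum(prev.multiplicities.values())
        peptides = sorted(prev.multiplicities)
        freqs = {p: prev.multiplicities[p] / total for p in peptides}
        fitness = {
            p: (
                fams[prev.labels[p]].fitness
                if prev.labels[p] in fams
                else config.background_fitness
            )
            for p in peptides
        }
        nxt = advance_round(freqs, fitness)
        draws = rng.multinomial(config.reads_per_round, [nxt[p] for p in peptides])
        multiplicities = Counter(
            {p: int(n) for p, n in zip(peptides, draws) if n > 0}
        )
        expected = _expected_family_frequencies(prev.expected_frequencies, fams, config)
        labels = {p: prev.labels[p] for p in multiplicities}
        result.truths.append(SimTruth(round_index, labels, multiplicities, expected))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if gzip_fastq else ".fastq"
        config.to_yaml(outdir / "sim_config.yaml")
        for truth in result.truths:
            fq = outdir / f"{config.library_tag}_round{truth.round_index}{ext}"
            emit_fastq(truth.multiplicities, config, truth.round_index, arch, fq, rng)
            truth.to_tsv(outdir / f"{config.library_tag}_round{truth.round_index}_truth.tsv")
            result.fastq_paths.append(fq)
    return result


def _expected_family_frequencies(
    prev: Mapping[str, float],
    fams: Mapping[str, FamilySpec],
    config: SelectionSimConfig,
) -> dict[str, float]:
    labels = list(prev)
    p = np.asarray([prev[label] for label in labels], dtype=float)
    w = np.asarray(
        [fams[label].fitness if label in fams else config.background_fitness for label in labels]
    )
    out = p * w / float(np.sum(p * w))
    return dict(zip(labels, out))
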