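"""Synthetic clades, genomes, and error-bearing read mixtures.

Gives every pipeline stage a self-contained test bed: a clade of closely
related target genomes, a set of more divergent non-target genomes, and
single-end reads drawn from a weighted genome mixture with substitution
errors — the in-silico analogue of sequencing a food sample containing a
small, known fraction of target DNA.

The error model is substitution-only (detection is exact k-mer matching,
so substitutions are the operative error mode) and read qualities are a
constant configurable score. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detector import ReadRecord
from .errors import ParameterError
from .kmer_core import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp_str(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale defaults: 20 kb genomes, 3 targets at 0.5% divergence,
    7 non-targets at 5% divergence, 85 bp reads."""

    genome_length: int = 20_000
    n_target_species: int = 3
    within_clade_divergence: float = 0.005
    n_nontarget_species: int = 7
    nontarget_divergence: float = 0.05
    read_length: int = 85
    error_rate: float = 0.002
    n_reads: int = 100_000
    target_fraction: float = 0.05
    quality_score: int = 38
    circular: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_clade_divergence", "nontarget_divergence",
                     "error_rate", "target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.read_length > self.genome_length:
            raise ParameterError(
                f"read_length {self.read_length} exceeds genome_length "
                f"{self.genome_length}"
            )
        if self.n_reads < 0:
            raise ParameterError(f"n_reads must be >= 0, got {self.n_reads}")
        if not 0 <= self.quality_score <= 93:
            raise ParameterError(f"quality_score must be in [0, 93]")


@dataclass
class MixtureTruth:
    """Per-read ground truth for a simulated mixture."""

    target_genome: str
    background_genome: str
    target_fraction: float
    n_target_reads: int = 0
    n_background_reads: int = 0
    #: (read_id, source_genome, strand, 1-based start, n_errors)
    rows: list[tuple[str, str, str, int, int]] = field(default_factory=list)


def random_genome(
    length: int, seed: int, inverted_repeat: int = 0, id: str = "genome"
) -> SequenceRecord:
    """I.i.d. uniform A/C/G/T sequence; deterministic per seed.

    ``inverted_repeat`` > 0 appends a reverse-complemented copy of the last
    that-many bases, mimicking a plastid inverted repeat.
    """
    if length < 1:
        raise ParameterError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    bases = _BASES[codes].tobytes().decode("ascii")
    if inverted_repeat > 0:
        if inverted_repeat > length:
            raise ParameterError(
                f"inverted_repeat {inverted_repeat} exceeds genome length {length}"
            )
        bases += revcomp_str(bases[-inverted_repeat:])
    return SequenceRecord(id=id, bases=bases)


def mutate(seq: SequenceRecord, rate: float, seed: int, id: "str | None" = None) -> SequenceRecord:
    """Independently substitute each site with probability ``rate``.

    A substituted site always changes to a uniformly chosen *different*
    base; length is preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise ParameterError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    raw = np.frombuffer(seq.bases.upper().encode("ascii"), dtype=np.uint8).copy()
    # map bytes -> 0..3; non-ACGT positions are never mutated
    codes = np.full(raw.size, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        codes[raw == b] = i
    hit = (rng.random(raw.size) < rate) & (codes >= 0)
    offsets = rng.integers(1, 4, size=raw.size)
    new_codes = (codes + offsets) % 4
    raw[hit] = _BASES[new_codes[hit]]
    return SequenceRecord(
        id=id if id is not None else f"{seq.id}_mut", bases=raw.tobytes().decode("ascii")
    )


def simulate_clade(
    config: SimConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Ancestor + mutated targets and (more divergent) non-targets.

    All genomes derive from one random ancestor; targets are independent
    mutations at ``within_clade_divergence``, non-targets at
    ``nontarget_divergence``. Deterministic per ``config.seed``.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(
        1 + config.n_target_species + config.n_nontarget_species
    )
    ancestor = random_genome(config.genome_length, int(seeds[0]), id="ancestor")
    targets = [
        mutate(ancestor, config.within_clade_divergence, int(seeds[1 + i]),
               id=f"target{i + 1}")
        for i in range(config.n_target_species)
    ]
    offset = 1 + config.n_target_species
    nontargets = [
        mutate(ancestor, config.nontarget_divergence, int(seeds[offset + i]),
               id=f"nontarget{i + 1}")
        for i in range(config.n_nontarget_species)
    ]
    return targets, nontargets


def simulate_reads(
    genomes: Sequence[SequenceRecord],
    n_reads: int,
    read_length: int,
    error_rate: float,
    seed: int,
    weights: "Sequence[float] | None" = None,
    quality_score: int = 38,
    truth: "MixtureTruth | None" = None,
    circular: bool = False,
) -> list[ReadRecord]:
    """Single-end reads from a weighted genome mixture.

    Each read: pick a genome by weight, a uniform start, a uniform strand
    (forward window or its reverse complement), then apply per-base
    substitution errors at ``error_rate``. Qualities are the constant
    ``quality_score``. When a ``truth`` record is given, one row per read
    is appended to it.

    ``circular`` treats each genome as a circle (reads may wrap around the
    origin), matching plastid topology and removing terminal-window
    coverage edge effects; with a linear genome the last k-mer windows are
    reachable from very few read starts.
    """
    if not genomes:
        raise ParameterError("at least one genome is required")
    for g in genomes:
        if read_length > len(g.bases):
            raise ParameterError(
                f"read_length {read_length} exceeds genome {g.id!r} "
                f"length {len(g.bases)}"
            )
    rng = np.random.default_rng(seed)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    picks = rng.choice(len(genomes), size=n_reads, p=weights)
    strands = rng.integers(0, 2, size=n_reads)
    u_start = rng.random(n_reads)
    n_errors = rng.binomial(read_length, error_rate, size=n_reads)

    qual_line = chr(33 + quality_score) * read_length
    doubled = {g.id: g.bases + g.bases[:read_length - 1] for g in genomes}
    reads: list[ReadRecord] = []
    for i in range(n_reads):
        g = genomes[picks[i]]
        span = len(g.bases) if circular else len(g.bases) - read_length + 1
        start = int(u_start[i] * span)
        source = doubled[g.id] if circular else g.bases
        window = source[start:start + read_length]
        if strands[i]:
            window = revcomp_str(window)
        ne = int(n_errors[i])
        if ne:
            pos = rng.choice(read_length, size=ne, replace=False)
            offs = rng.integers(1, 4, size=ne)
            chars = list(window)
            for p, o in zip(pos, offs):
                base = chars[p]
                chars[p] = "ACGT"[("ACGT".index(base) + o) % 4]
            window = "".join(chars)
        read_id = f"read{i + 1}"
        reads.append(ReadRecord(id=read_id, bases=window, quals=qual_line))
        if truth is not None:
            truth.rows.append(
                (read_id, g.id, "-" if strands[i] else "+", start + 1, ne)
            )
    return reads


def simulate_mixture(
    config: SimConfig,
    target_genome: "SequenceRecord | None" = None,
    background_genome: "SequenceRecord | None" = None,
) -> tuple[list[ReadRecord], MixtureTruth]:
    """Reads from a target/background mixture at ``config.target_fraction``.

    Defaults to the first target and first non-target genome of the clade
    simulated from the same config, so a panel built from that clade can be
    evaluated directly. Returns the reads and a per-read truth record.
    """
    if target_genome is None or background_genome is None:
        targets, nontargets = simulate_clade(config)
        if target_genome is None:
            target_genome = targets[0]
        if background_genome is None:
            if not nontargets:
                raise ParameterError("config has no non-target genomes for background")
            background_genome = nontargets[0]
    truth = MixtureTruth(
        target_genome=target_genome.id,
        background_genome=background_genome.id,
        target_fraction=config.target_fraction,
    )
    reads = simulate_reads(
        [target_genome, background_genome],
        n_reads=config.n_reads,
        read_length=config.read_length,
        error_rate=config.error_rate,
        seed=config.seed,
        weights=[config.target_fraction, 1.0 - config.target_fraction],
        quality_score=config.quality_score,
        truth=truth,
        circular=config.circular,
    )
    truth.n_target_reads = sum(1 for r in truth.rows if r[1] == target_genome.id)
    truth.n_background_reads = len(truth.rows) - truth.n_target_reads
    return reads, truth
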