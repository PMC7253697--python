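"""Taxon-specific k-mer panel construction by genome set algebra.

Genus panels are the intersection of per-target-genome k-mer sets minus the
union of all non-target sets; species panels subtract sibling species and
non-targets from a single genome's set. Panels can additionally be filtered
against confounder read sets: any panel k-mer observed at or above a
frequency cutoff within a single read set is dropped.

A "genome" argument anywhere below is one of: a path to a FASTA file
(plain or gzip), a :class:`~kmerpanel.kmer_core.SequenceRecord`, or an
iterable of records/strings. Each genome is one unit for intersection
purposes even when multi-record (records within a genome are unioned).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError, ParameterError
from .kmer_core import Kmer, SequenceRecord, canonical_window_codes, decode

GenomeLike = "str | os.PathLike | SequenceRecord | Iterable"


@dataclass(frozen=True)
class KmerSet:
    """Unordered set of canonical k-mers at a fixed k (encoded ints)."""

    k: int
    codes: frozenset[int]

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, item) -> bool:
        if isinstance(item, Kmer):
            return item.k == self.k and item.canonical().value in self.codes
        if isinstance(item, str):
            return Kmer.from_string(item).canonical().value in self.codes
        return int(item) in self.codes

    def _coerce(self, other: "KmerSet") -> None:
        if other.k != self.k:
            raise ParameterError(
                f"k mismatch: {self.k} vs {other.k} (k is a panel-level constant)"
            )

    def union(self, other: "KmerSet") -> "KmerSet":
        self._coerce(other)
        return KmerSet(self.k, self.codes | other.codes)

    def intersection(self, other: "KmerSet") -> "KmerSet":
        self._coerce(other)
        return KmerSet(self.k, self.codes & other.codes)

    def difference(self, other: "KmerSet") -> "KmerSet":
        self._coerce(other)
        return KmerSet(self.k, self.codes - other.codes)

    def to_strings(self) -> list[str]:
        """Members decoded and sorted lexicographically (== numerically)."""
        return [decode(c, self.k) for c in sorted(self.codes)]

    def sorted_array(self) -> np.ndarray:
        """Members as a sorted ``uint64`` array (for vectorized membership)."""
        return np.fromiter(sorted(self.codes), dtype=np.uint64, count=len(self.codes))


@dataclass
class KmerPanel:
    """A taxon-labelled k-mer set with provenance of how it was built."""

    taxon: str
    rank: str  # "genus" or "species"
    kmers: KmerSet
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rank not in ("genus", "species"):
            raise ParameterError(f"rank must be 'genus' or 'species', got {self.rank!r}")

    @property
    def k(self) -> int:
        return self.kmers.k

    @property
    def size(self) -> int:
        return len(self.kmers)

    @property
    def is_empty(self) -> bool:
        return self.size == 0


def _iter_bases(genome) -> Iterable[tuple[str, str]]:
    """Yield (label, bases) for each record of a genome-like input."""
    if isinstance(genome, (str, os.PathLike)):
        from .io import read_fasta

        for rec in read_fasta(genome):
            yield rec.id, rec.bases
    elif isinstance(genome, SequenceRecord):
        yield genome.id, genome.bases
    elif isinstance(genome, str):  # pragma: no cover - shadowed by PathLike
        yield "seq", genome
    else:
        for i, rec in enumerate(genome):
            if isinstance(rec, SequenceRecord):
                yield rec.id, rec.bases
            else:
                yield f"seq{i + 1}", str(rec)


def _genome_label(genome) -> str:
    if isinstance(genome, (str, os.PathLike)):
        return os.fspath(genome)
    if isinstance(genome, SequenceRecord):
        return genome.id
    return "<in-memory>"


def genome_kmer_set(genomes, k: int) -> KmerSet:
    """Union of unique canonical k-mers over all sequences of a collection.

    ``genomes`` may be a single genome-like object or a list of them; an
    empty collection (or a collection yielding no sequences at all) is an
    input error, but empty sequences are allowed and contribute nothing.
    """
    codes: set[int] = set()
    seen_any = False
    if isinstance(genomes, (str, os.PathLike, SequenceRecord)):
        genomes = [genomes]
    for genome in genomes:
        for _, bases in _iter_bases(genome):
            seen_any = True
            _, win = canonical_window_codes(bases, k)
            codes.update(win.tolist())
    if not seen_any:
        raise InputError("genome collection is empty")
    return KmerSet(k, frozenset(codes))


def build_genus_panel(
    target_genomes: Sequence,
    nontarget_genomes: Sequence = (),
    *,
    k: int = 32,
    taxon: str = "genus",
) -> KmerPanel:
    """Panel of k-mers present in every target genome and no non-target one.

    Each element of ``target_genomes`` is one genome (one FASTA file);
    records within it are unioned before the intersection is taken.
    """
    if not target_genomes:
        raise InputError("at least one target genome is required")
    panel_set: KmerSet | None = None
    provenance = []
    for genome in target_genomes:
        gset = genome_kmer_set(genome, k)
        provenance.append(f"target:{_genome_label(genome)}:{len(gset)} k-mers")
        panel_set = gset if panel_set is None else panel_set.intersection(gset)
    provenance.append(f"intersection:{len(panel_set)} k-mers")
    for genome in nontarget_genomes:
        nset = genome_kmer_set(genome, k)
        provenance.append(f"nontarget:{_genome_label(genome)}:{len(nset)} k-mers")
        panel_set = panel_set.difference(nset)
    provenance.append(f"after-subtraction:{len(panel_set)} k-mers")
    return KmerPanel(taxon=taxon, rank="genus", kmers=panel_set, provenance=provenance)


def build_species_panel(
    species_genome,
    sibling_genomes: Sequence = (),
    nontarget_genomes: Sequence = (),
    *,
    k: int = 32,
    taxon: str = "species",
) -> KmerPanel:
    """Panel of k-mers private to one species' genome.

    Result = set(species) − union(siblings) − union(non-targets).
    """
    panel_set = genome_kmer_set(species_genome, k)
    provenance = [f"species:{_genome_label(species_genome)}:{len(panel_set)} k-mers"]
    labelled = [("sibling", g) for g in sibling_genomes]
    labelled += [("nontarget", g) for g in nontarget_genomes]
    for kind, genome in labelled:
        nset = genome_kmer_set(genome, k)
        provenance.append(f"{kind}:{_genome_label(genome)}:{len(nset)} k-mers")
        panel_set = panel_set.difference(nset)
    provenance.append(f"after-subtraction:{len(panel_set)} k-mers")
    return KmerPanel(taxon=taxon, rank="species", kmers=panel_set, provenance=provenance)


def filter_panel_with_reads(
    panel: KmerPanel,
    read_sets: Sequence,
    removal_min_freq: int = 1,
) -> KmerPanel:
    """Drop panel k-mers observed in confounder reads.

    A k-mer is removed when its total occurrence count within any single
    read set reaches ``removal_min_freq`` (sets are thresholded separately,
    not pooled). Never adds k-mers; appends one provenance entry per set.
    """
    if removal_min_freq < 1:
        raise ParameterError(
            f"removal_min_freq must be >= 1, got {removal_min_freq}"
        )
    from .detector import count_panel  # local import avoids a cycle

    surviving = panel.kmers
    provenance = list(panel.provenance)
    for read_set in read_sets:
        label = _genome_label(read_set)
        table = count_panel(panel, _reads_of(read_set))
        removed = frozenset(
            code for code, n in table.counts.items() if n >= removal_min_freq
        )
        n_removed = len(surviving.codes & removed)
        surviving = KmerSet(surviving.k, surviving.codes - removed)
        provenance.append(
            f"read-filter:{label}:min_freq={removal_min_freq}:"
            f"removed={n_removed}:surviving={len(surviving)}"
        )
    return KmerPanel(
        taxon=panel.taxon, rank=panel.rank, kmers=surviving, provenance=provenance
    )


def _reads_of(read_set):
    if isinstance(read_set, (str, os.PathLike)):
        from .io import read_fastq

        return read_fastq(read_set)
    return read_set
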