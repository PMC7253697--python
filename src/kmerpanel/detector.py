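"""Read trimming, panel k-mer counting, subsampling curves, presence calls.

Counting is strand-agnostic: every window of every sequence is
canonicalized and looked up in the panel; overlapping occurrences all
count. Detection is the number of *distinct* panel k-mers seen at or above
a frequency cutoff. Sensitivity curves use nested subsamples (prefixes of
one seeded permutation) so they are deterministically monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, InputError, ParameterError
from .kmer_core import Kmer, SequenceRecord, canonical_window_codes
from .panel_builder import KmerPanel

#: Presence thresholds (minimum detected panel k-mers) by taxon label.
DEFAULT_THRESHOLDS: dict[str, int] = {
    "Lupinus": 1500,
    "Lupinus albus": 7500,
    "Lupinus luteus": 4000,
    "Lupinus westianus": 4300,
}

#: Per-taxon frequency-cutoff presets (distinct-k-mer detection cutoff).
TAXON_MIN_FREQ: dict[str, int] = {
    "Lupinus luteus": 2,
    "Lupinus westianus": 2,
}


@dataclass
class ReadRecord:
    """A sequencing read: id, bases, and Phred+33 quality string."""

    id: str
    bases: str
    quals: str

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise FormatError(
                f"quality length {len(self.quals)} != sequence length "
                f"{len(self.bases)} for read {self.id!r}"
            )
        try:
            qb = self.quals.encode("ascii")
        except UnicodeEncodeError:
            raise FormatError(
                f"non-ASCII quality characters in {self.id!r}"
            ) from None
        if qb and (min(qb) < 33 or max(qb) > 126):
            raise FormatError(f"quality characters out of Phred+33 range in {self.id!r}")

    @property
    def scores(self) -> list[int]:
        """Per-base Phred scores (0-93)."""
        return [ord(c) - 33 for c in self.quals]

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class CountTable:
    """Occurrence counts of panel k-mers over a scanned sequence stream."""

    taxon: str
    k: int
    panel_size: int
    counts: dict[int, int] = field(default_factory=dict)
    reads_scanned: int = 0
    bases_scanned: int = 0

    def count_of(self, kmer: "Kmer | str") -> int:
        if isinstance(kmer, str):
            kmer = Kmer.from_string(kmer)
        return self.counts.get(kmer.canonical().value, 0)

    def detected(self, min_freq: int = 1) -> int:
        return detected_count(self, min_freq)


@dataclass
class SensitivityCurve:
    """Detected panel k-mers as a function of subsampled read count."""

    points: list[tuple[int, int]]
    cutoff: int
    seed: int
    panel_size: int = 0


@dataclass
class PresenceCall:
    taxon: str
    detected: int
    panel_size: int
    threshold: int
    present: bool

    def __post_init__(self) -> None:
        if not 0 <= self.detected <= self.panel_size:
            raise ParameterError(
                f"detected={self.detected} outside [0, panel_size={self.panel_size}]"
            )
        if self.threshold < 1:
            raise ParameterError(f"threshold must be >= 1, got {self.threshold}")


def quality_trim(
    read: ReadRecord, quality_threshold: int = 35, min_length: int = 32
) -> "ReadRecord | None":
    """3'-trim low-quality bases; drop reads that end up too short.

    Bases are removed from the 3' end while their score is below
    ``quality_threshold``, stopping at the first base at or above it. The
    read is discarded (``None``) when the trimmed length is below
    ``min_length``.
    """
    cut = len(read.bases)
    floor = quality_threshold + 33
    q = read.quals
    while cut > 0 and ord(q[cut - 1]) < floor:
        cut -= 1
    if cut < min_length:
        return None
    if cut == len(read.bases):
        return read
    return ReadRecord(id=read.id, bases=read.bases[:cut], quals=read.quals[:cut])


def trim_reads(
    reads: Iterable[ReadRecord], quality_threshold: int = 35, min_length: int = 32
) -> Iterable[ReadRecord]:
    """Apply :func:`quality_trim` over a stream, dropping discarded reads."""
    for read in reads:
        trimmed = quality_trim(read, quality_threshold, min_length)
        if trimmed is not None:
            yield trimmed


def _bases_of(item) -> str:
    if isinstance(item, (ReadRecord, SequenceRecord)):
        return item.bases
    return str(item)


def _scan_into(
    counts: dict[int, int], panel_arr: np.ndarray, bases: str, k: int
) -> None:
    _, codes = canonical_window_codes(bases, k)
    if codes.size == 0:
        return
    idx = np.searchsorted(panel_arr, codes)
    idx[idx == panel_arr.size] = 0
    hits = codes[panel_arr[idx] == codes]
    if hits.size == 0:
        return
    uniq, n = np.unique(hits, return_counts=True)
    for code, c in zip(uniq.tolist(), n.tolist()):
        counts[code] = counts.get(code, 0) + c


_BATCH_BASES = 1 << 20


def count_panel(panel: KmerPanel, sequences: Iterable) -> CountTable:
    """Count occurrences of panel k-mers across a sequence/read stream.

    Reads are scanned in batches joined with 'N' separators (windows
    touching the separator are skipped), which amortizes the vectorized
    scan over many short reads.
    """
    if panel.is_empty:
        raise InputError(f"panel {panel.taxon!r} is empty")
    panel_arr = panel.kmers.sorted_array()
    table = CountTable(taxon=panel.taxon, k=panel.k, panel_size=panel.size)
    max_len = 0
    batch: list[str] = []
    batch_bases = 0
    for item in sequences:
        bases = _bases_of(item)
        table.reads_scanned += 1
        table.bases_scanned += len(bases)
        max_len = max(max_len, len(bases))
        batch.append(bases)
        batch_bases += len(bases)
        if batch_bases >= _BATCH_BASES:
            _scan_into(table.counts, panel_arr, "N".join(batch), panel.k)
            batch, batch_bases = [], 0
    if batch:
        _scan_into(table.counts, panel_arr, "N".join(batch), panel.k)
    if table.reads_scanned and max_len < panel.k:
        warnings.warn(
            f"k={panel.k} exceeds the longest scanned sequence ({max_len} bp); "
            "all counts are zero",
            stacklevel=2,
        )
    return table


def detected_count(table: CountTable, min_freq: int = 1) -> int:
    """Number of distinct panel k-mers with occurrence count >= ``min_freq``."""
    if min_freq < 1:
        raise ParameterError(f"min_freq must be >= 1, got {min_freq}")
    return sum(1 for c in table.counts.values() if c >= min_freq)


def subsample_reads(reads, n: int, seed: int) -> list:
    """Uniform random subset of ``n`` reads without replacement.

    Deterministic per (source, n, seed); nested: the size-n1 subset is
    contained in the size-n2 subset for n1 <= n2 under the same seed.
    """
    pool = list(reads)
    if n < 0 or n > len(pool):
        raise ParameterError(
            f"cannot subsample {n} reads from a source of {len(pool)} reads"
        )
    perm = np.random.default_rng(seed).permutation(len(pool))
    return [pool[i] for i in perm[:n]]


def sensitivity_curve(
    panel: KmerPanel,
    reads,
    sizes: Sequence[int],
    min_freq: int = 1,
    seed: int = 0,
) -> SensitivityCurve:
    """Detected panel k-mers at each nested subsample size.

    Single pass over one seeded permutation of the reads; the detected
    number at each size is exactly ``detected_count`` on that nested subset,
    and is non-decreasing across sizes by construction.
    """
    sizes = [int(s) for s in sizes]
    if sizes != sorted(sizes):
        raise ParameterError(f"sizes must be sorted ascending, got {sizes}")
    pool = list(reads)
    if sizes and sizes[-1] > len(pool):
        raise ParameterError(
            f"largest size {sizes[-1]} exceeds the {len(pool)} reads available"
        )
    panel_arr = panel.kmers.sorted_array()
    perm = np.random.default_rng(seed).permutation(len(pool))
    counts: dict[int, int] = {}
    detected = 0
    points: list[tuple[int, int]] = []
    boundaries = iter(sizes)
    next_boundary = next(boundaries, None)
    scanned = 0
    batch: list[str] = []
    batch_bases = 0

    def _flush() -> None:
        nonlocal detected, batch_bases
        if not batch:
            return
        _, codes = canonical_window_codes("N".join(batch), panel.k)
        if codes.size:
            idx = np.searchsorted(panel_arr, codes)
            idx[idx == panel_arr.size] = 0
            hits = codes[panel_arr[idx] == codes]
            if hits.size:
                uniq, n = np.unique(hits, return_counts=True)
                for code, c in zip(uniq.tolist(), n.tolist()):
                    old = counts.get(code, 0)
                    counts[code] = old + c
                    if old < min_freq <= old + c:
                        detected += 1
        batch.clear()
        batch_bases = 0

    while next_boundary == 0:
        points.append((0, 0))
        next_boundary = next(boundaries, None)
    for i in perm:
        if next_boundary is None:
            break
        bases = _bases_of(pool[i])
        batch.append(bases)
        batch_bases += len(bases)
        scanned += 1
        if batch_bases >= _BATCH_BASES and scanned != next_boundary:
            _flush()
        if scanned == next_boundary:
            _flush()
            while next_boundary is not None and scanned == next_boundary:
                points.append((scanned, detected))
                next_boundary = next(boundaries, None)
    return SensitivityCurve(
        points=points, cutoff=min_freq, seed=seed, panel_size=panel.size
    )


def call_presence(
    detected: int,
    panel_size: int,
    taxon: str,
    threshold: "int | None" = None,
) -> PresenceCall:
    """Presence verdict: present iff detected >= threshold (inclusive).

    Without an explicit threshold the built-in per-taxon table is consulted;
    an unknown taxon then raises a parameter error.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS.get(taxon)
        if threshold is None:
            raise ParameterError(
                f"no default presence threshold for taxon {taxon!r}; "
                "pass threshold explicitly"
            )
    return PresenceCall(
        taxon=taxon,
        detected=detected,
        panel_size=panel_size,
        threshold=threshold,
        present=detected >= threshold,
    )


def screen_fasta(panel: KmerPanel, assembly) -> tuple[int, float]:
    """Fraction of panel k-mers occurring at least once in an assembly."""
    import os

    if isinstance(assembly, (str, os.PathLike)):
        from .io import read_fasta

        assembly = read_fasta(assembly)
    records = list(assembly) if not isinstance(assembly, SequenceRecord) else [assembly]
    if not records:
        raise InputError("assembly is empty")
    table = count_panel(panel, records)
    detected = detected_count(table, min_freq=1)
    return detected, detected / panel.size
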