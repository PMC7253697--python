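"""Fixed-length k-mer encoding, reverse complement, canonicalization, extraction.

k-mers are packed 2 bits per base (A=0, C=1, G=2, T=3) into a Python int,
most-significant bits holding the 5' end, so integer order equals
lexicographic order over the decoded strings. k is capped at 32 so every
k-mer fits a 64-bit word and vectorized scans can use ``uint64`` arrays.

Windows containing any non-ACGT character are skipped entirely; input case
is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ParameterError

MAX_K = 32

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}

# byte -> 2-bit code, -1 for anything that is not ACGTacgt
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _CODE_TABLE[ord(_b)] = _c
    _CODE_TABLE[ord(_b.lower())] = _c

# chunk size (bases) for vectorized window scans; keeps peak memory bounded
# (a chunk expands to ~2 * CHUNK * k * 8 bytes of uint64 intermediates)
_CHUNK = 1 << 18


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise ParameterError(f"k must be an integer, got {k!r}")
    if not 1 <= k <= MAX_K:
        raise ParameterError(f"k must be in [1, {MAX_K}], got {k}")


def encode(seq: str) -> int:
    """Pack an ACGT string (case-insensitive) into its 2-bit integer code."""
    value = 0
    for ch in seq.upper():
        try:
            value = (value << 2) | _BASE_CODE[ch]
        except KeyError:
            raise ParameterError(f"cannot encode non-ACGT base {ch!r}") from None
    return value


def decode(value: int, k: int) -> str:
    """Inverse of :func:`encode` for a k-mer of length ``k``."""
    _check_k(k)
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(value >> shift) & 3])
    return "".join(out)


def revcomp_code(value: int, k: int) -> int:
    """Reverse complement of an encoded k-mer, staying in code space."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (value & 3))
        value >>= 2
    return out


def canonical_code(value: int, k: int) -> int:
    """Smaller of a code and its reverse-complement code."""
    rc = revcomp_code(value, k)
    return value if value <= rc else rc


@dataclass(frozen=True, order=True)
class Kmer:
    """An encoded k-mer: ``value`` packs the bases, ``k`` is the length."""

    k: int
    value: int

    def __post_init__(self) -> None:
        _check_k(self.k)
        if not 0 <= self.value < (1 << (2 * self.k)):
            raise ParameterError(
                f"k-mer value {self.value} out of range for k={self.k}"
            )

    @classmethod
    def from_string(cls, seq: str) -> "Kmer":
        _check_k(len(seq))
        return cls(k=len(seq), value=encode(seq))

    def __str__(self) -> str:
        return decode(self.value, self.k)

    def reverse_complement(self) -> "Kmer":
        return Kmer(k=self.k, value=revcomp_code(self.value, self.k))

    def canonical(self) -> "Kmer":
        return Kmer(k=self.k, value=canonical_code(self.value, self.k))


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (FASTA record)."""

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParameterError("sequence record id must be non-empty")


def reverse_complement(kmer: Kmer) -> Kmer:
    """Watson-Crick complement, reversed. Involution."""
    return kmer.reverse_complement()


def canonical(kmer: Kmer) -> Kmer:
    """Lexicographically smaller of ``kmer`` and its reverse complement."""
    return kmer.canonical()


def _codes_of(bases: str) -> np.ndarray:
    raw = np.frombuffer(bases.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def canonical_window_codes(bases: str, k: int):
    """Vectorized scan of every length-``k`` window of ``bases``.

    Returns ``(positions, codes)``: 1-based window starts (``int64``) and the
    canonical 2-bit codes (``uint64``) of the windows that contain only
    A/C/G/T. Both arrays are empty when the sequence is shorter than ``k``.
    """
    _check_k(k)
    n = len(bases)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)

    codes = _codes_of(bases)
    pow_fwd = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    pow_rc = (np.uint64(4) ** np.arange(k, dtype=np.uint64))

    pos_parts = []
    code_parts = []
    for start in range(0, n - k + 1, _CHUNK):
        stop = min(start + _CHUNK + k - 1, n)
        chunk = codes[start:stop]
        bad = (chunk < 0).astype(np.int64)
        cbad = np.concatenate(([0], np.cumsum(bad)))
        ok = (cbad[k:] - cbad[:-k]) == 0
        if not ok.any():
            continue
        win = np.lib.stride_tricks.sliding_window_view(
            chunk.astype(np.uint64), k
        )[ok]
        # codes may be 255 (uint64 view of -1) in masked windows only; the
        # `ok` filter above guarantees every retained window is pure ACGT
        fwd = (win * pow_fwd).sum(axis=1, dtype=np.uint64)
        rc = ((np.uint64(3) - win) * pow_rc).sum(axis=1, dtype=np.uint64)
        pos_parts.append(np.nonzero(ok)[0] + start + 1)
        code_parts.append(np.minimum(fwd, rc))

    if not pos_parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    return np.concatenate(pos_parts), np.concatenate(code_parts)


def extract_canonical_kmers(
    seq: "SequenceRecord | str", k: int
) -> list[tuple[int, Kmer]]:
    """All canonical k-mers of a sequence with their 1-based start positions.

    Windows touching a non-ACGT character are skipped; a sequence shorter
    than ``k`` yields an empty list.
    """
    bases = seq.bases if isinstance(seq, SequenceRecord) else seq
    positions, codes = canonical_window_codes(bases, k)
    return [(int(p), Kmer(k=k, value=int(c))) for p, c in zip(positions, codes)]


def iter_canonical_codes(bases: str, k: int) -> Iterator[int]:
    """Canonical codes of valid windows, in sequence order (ints)."""
    _, codes = canonical_window_codes(bases, k)
    return iter(int(c) for c in codes)
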