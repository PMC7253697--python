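"""File formats: FASTA/FASTQ streaming, panel serialization, report TSVs.

All readers accept plain or gzip-compressed files transparently. The panel
file is plain text for auditability: '#'-prefixed header lines carrying k,
taxon, rank and provenance, then one uppercase canonical k-mer per line,
lexicographically sorted.
"""

from __future__ import annotations

import gzip
import logging
import os
import warnings
from typing import IO, Iterable, Iterator

from .detector import CountTable, PresenceCall, ReadRecord, SensitivityCurve
from .errors import FormatError
from .kmer_core import MAX_K, SequenceRecord
from .panel_builder import KmerPanel, KmerSet

logger = logging.getLogger("kmerpanel")

REPORT_COLUMNS = [
    "taxon", "panel_size", "reads_scanned", "min_freq", "detected",
    "fraction_detected", "threshold", "present",
]
CURVE_COLUMNS = ["n_reads", "detected", "fraction_detected"]


def xopen(path, mode: str = "rt") -> IO:
    """Open a path, decompressing transparently when it ends in .gz."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _as_lines(source) -> tuple[Iterator[str], str]:
    if isinstance(source, (str, os.PathLike)):
        handle = xopen(source)
        return iter(handle), os.fspath(source)
    return iter(source), getattr(source, "name", "<stream>")


def read_fasta(source) -> Iterator[SequenceRecord]:
    """Stream FASTA records (wrapped lines allowed, gzip transparent).

    The description after the first whitespace is preserved separately from
    the id. Duplicate ids raise a warning; both records are kept. An empty
    file yields nothing (with a warning); a file whose first non-blank
    character is not '>' is a format error.
    """
    lines, name = _as_lines(source)
    header: "str | None" = None
    chunks: list[str] = []
    seen_ids: set[str] = set()
    n_lines = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        n_lines += 1
        if line.startswith(">"):
            if header is not None:
                yield _fasta_record(header, chunks, seen_ids, name)
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise FormatError(
                    "FASTA must start with a '>' header", source=name, line=lineno
                )
            chunks.append(line.strip())
    if header is not None:
        yield _fasta_record(header, chunks, seen_ids, name)
    elif n_lines == 0:
        warnings.warn(f"empty FASTA input: {name}", stacklevel=2)


def _fasta_record(header, chunks, seen_ids, name) -> SequenceRecord:
    parts = header.split(None, 1)
    rec_id = parts[0] if parts else ""
    if not rec_id:
        raise FormatError("FASTA record with empty id", source=name)
    if rec_id in seen_ids:
        warnings.warn(f"duplicate FASTA id {rec_id!r} in {name}", stacklevel=3)
    seen_ids.add(rec_id)
    return SequenceRecord(
        id=rec_id,
        bases="".join(chunks),
        description=parts[1] if len(parts) > 1 else "",
    )


def write_fasta(records: Iterable[SequenceRecord], sink, width: int = 70) -> None:
    close = False
    if isinstance(sink, (str, os.PathLike)):
        sink = xopen(sink, "wt")
        close = True
    try:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            sink.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.bases), width):
                sink.write(rec.bases[i:i + width] + "\n")
    finally:
        if close:
            sink.close()


def read_fastq(source) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records (Phred+33, gzip transparent).

    Truncated records, a missing '+' separator, or a sequence/quality
    length mismatch raise a format error carrying the record ordinal.
    """
    lines, name = _as_lines(source)
    record = 0
    while True:
        head = next(lines, None)
        if head is None:
            return
        head = head.rstrip("\n").rstrip("\r")
        if not head:
            continue
        record += 1
        if not head.startswith("@"):
            raise FormatError(
                "FASTQ header must start with '@'", source=name, record=record
            )
        seq = next(lines, None)
        plus = next(lines, None)
        qual = next(lines, None)
        if seq is None or plus is None or qual is None:
            raise FormatError("truncated FASTQ record", source=name, record=record)
        seq = seq.strip()
        qual = qual.rstrip("\n").rstrip("\r")
        if not plus.startswith("+"):
            raise FormatError(
                "FASTQ separator line must start with '+'", source=name, record=record
            )
        if len(qual) != len(seq):
            raise FormatError(
                f"quality length {len(qual)} != sequence length {len(seq)}",
                source=name, record=record,
            )
        yield ReadRecord(id=head[1:].split(None, 1)[0], bases=seq, quals=qual)


def write_fastq(reads: Iterable[ReadRecord], sink) -> None:
    close = False
    if isinstance(sink, (str, os.PathLike)):
        sink = xopen(sink, "wt")
        close = True
    try:
        for read in reads:
            sink.write(f"@{read.id}\n{read.bases}\n+\n{read.quals}\n")
    finally:
        if close:
            sink.close()


def write_panel(panel: KmerPanel, sink) -> None:
    """Serialize a panel: '#' headers, then sorted uppercase k-mer lines."""
    close = False
    if isinstance(sink, (str, os.PathLike)):
        sink = xopen(sink, "wt")
        close = True
    try:
        sink.write(f"#k={panel.k}\n")
        sink.write(f"#taxon={panel.taxon}\n")
        sink.write(f"#rank={panel.rank}\n")
        for entry in panel.provenance:
            sink.write(f"#provenance={entry}\n")
        for kmer in panel.kmers.to_strings():
            sink.write(kmer + "\n")
    finally:
        if close:
            sink.close()


def read_panel(source, strict_order: bool = True) -> KmerPanel:
    """Parse a panel file; lossless inverse of :func:`write_panel`.

    Body lines must have length k over {A,C,G,T} with no duplicates. An
    unsorted body is a format error under ``strict_order`` (default) and is
    silently re-sorted otherwise.
    """
    from .kmer_core import Kmer

    lines, name = _as_lines(source)
    k = None
    taxon = None
    rank = None
    provenance: list[str] = []
    codes: set[int] = set()
    previous = None
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            if key == "k":
                k = int(value)
                if not 1 <= k <= MAX_K:
                    raise FormatError(f"bad k={k}", source=name, line=lineno)
            elif key == "taxon":
                taxon = value
            elif key == "rank":
                rank = value
            elif key == "provenance":
                provenance.append(value)
            continue
        if k is None:
            raise FormatError("panel body before '#k=' header", source=name, line=lineno)
        if len(line) != k or any(c not in "ACGT" for c in line):
            raise FormatError(
                f"panel line {line!r} is not a length-{k} ACGT k-mer",
                source=name, line=lineno,
            )
        if strict_order and previous is not None and line <= previous:
            raise FormatError(
                "panel body not strictly sorted", source=name, line=lineno
            )
        previous = line
        code = Kmer.from_string(line).value
        if code in codes:
            raise FormatError(f"duplicate panel k-mer {line}", source=name, line=lineno)
        codes.add(code)
    if k is None or taxon is None or rank is None:
        raise FormatError("panel file missing #k/#taxon/#rank headers", source=name)
    return KmerPanel(
        taxon=taxon, rank=rank, kmers=KmerSet(k, frozenset(codes)),
        provenance=provenance,
    )


def _fmt_fraction(x: float) -> str:
    return f"{x:.6f}"


def write_report(
    table: CountTable, call: PresenceCall, min_freq: int, sink
) -> None:
    """Detection report TSV with the fixed column set."""
    close = False
    if isinstance(sink, (str, os.PathLike)):
        sink = open(sink, "w")
        close = True
    try:
        sink.write("\t".join(REPORT_COLUMNS) + "\n")
        fraction = call.detected / call.panel_size if call.panel_size else 0.0
        sink.write(
            "\t".join([
                call.taxon,
                str(call.panel_size),
                str(table.reads_scanned),
                str(min_freq),
                str(call.detected),
                _fmt_fraction(fraction),
                str(call.threshold),
                str(call.present),
            ]) + "\n"
        )
    finally:
        if close:
            sink.close()


def write_curve(curve: SensitivityCurve, sink) -> None:
    """Sensitivity-curve TSV: n_reads, detected, fraction_detected."""
    close = False
    if isinstance(sink, (str, os.PathLike)):
        sink = open(sink, "w")
        close = True
    try:
        sink.write("\t".join(CURVE_COLUMNS) + "\n")
        for n_reads, detected in curve.points:
            fraction = detected / curve.panel_size if curve.panel_size else 0.0
            sink.write(f"{n_reads}\t{detected}\t{_fmt_fraction(fraction)}\n")
    finally:
        if close:
            sink.close()


def write_truth(truth, sink) -> None:
    """Mixture truth TSV: read_id, source_genome, strand, start, n_errors."""
    close = False
    if isinstance(sink, (str, os.PathLike)):
        sink = open(sink, "w")
        close = True
    try:
        sink.write("read_id\tsource_genome\tstrand\tstart\tn_errors\n")
        for row in truth.rows:
            sink.write("\t".join(str(x) for x in row) + "\n")
    finally:
        if close:
            sink.close()
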