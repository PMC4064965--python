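"""Sequence primitives and FASTA/FASTQ I/O.

All coordinates in this package are 1-based and inclusive on mRNA
sequences, matching the convention of transcript annotations such as
"nt 4701-4720 of NM_015125.3". Sequences are canonicalized to uppercase
at ingest, so every downstream comparison is case-insensitive.

FASTQ quality strings are parsed and carried through the pipeline but
never used in matching: anchor scanning inspects sequence lines only.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import AlphabetError, CoordinateError, FormatError

DNA_ALPHABET = frozenset("ACGTN")

__all__ = [
    "DNA_ALPHABET",
    "TranscriptRecord",
    "SequenceRead",
    "Region1",
    "reverse_complement",
    "gc_percent",
    "subsequence",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
]


def _validate_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise AlphabetError(f"{what}: sequence is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{what}: characters {sorted(bad)} outside alphabet A,C,G,T,N"
        )
    return seq


@dataclass(frozen=True)
class TranscriptRecord:
    """A named reference mRNA sequence.

    `id` is the accession (e.g. an accession.version string), `symbol`
    an optional gene symbol. The sequence is stored uppercase over the
    alphabet {A,C,G,T,N}.
    """

    id: str
    sequence: str
    symbol: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("transcript record with empty id")
        object.__setattr__(
            self, "sequence", _validate_dna(self.sequence, f"transcript {self.id}")
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceRead:
    """One sequencing read; quality is optional and unused in matching."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_dna(self.sequence, f"read {self.id}")
        )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Region1:
    """A 1-based inclusive coordinate interval on a transcript."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"invalid region [{self.start},{self.end}]: need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = _validate_dna(seq, "reverse_complement input")
    # Seq handles this too; a translate table avoids object churn in the
    # inner scanning loops.
    return seq.translate(_RC)[::-1]


def gc_percent(seq: str) -> float:
    """Percent of G+C bases, 0-100. N counts in the denominator only.

    Returned unrounded; round only at report time.
    """
    seq = _validate_dna(seq, "gc_percent input")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def subsequence(t: TranscriptRecord, r: Region1) -> str:
    """Bases r.start..r.end of `t`, 1-based inclusive."""
    if r.end > len(t.sequence):
        raise CoordinateError(
            f"region [{r.start},{r.end}] outside transcript {t.id} "
            f"(length {len(t.sequence)})"
        )
    return t.sequence[r.start - 1 : r.end]


class _GzipTextWriter(io.TextIOWrapper):
    """Gzip text writer with a fixed header (mtime 0, no filename) so
    identical content compresses to identical bytes across runs."""

    def __init__(self, path: Path) -> None:
        self._raw = open(path, "wb")
        gz = gzip.GzipFile(fileobj=self._raw, mode="wb", mtime=0)
        super().__init__(gz, encoding="ascii")

    def close(self) -> None:
        try:
            super().close()
        finally:
            self._raw.close()


def _open_text(path: str | Path, mode: str, gzipped: bool | None = None) -> IO[str]:
    path = Path(path)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    if gzipped:
        if "r" in mode:
            return gzip.open(path, "rt")
        return _GzipTextWriter(path)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a (possibly multi-line, possibly gzipped) FASTA file.

    The first whitespace-delimited token of the header is the record id;
    the second, if present, the gene symbol.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with _open_text(path, "r") as fh:
        for i, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
            tokens = title.split()
            if not tokens:
                raise FormatError(f"{path}: record {i} has an empty header")
            if not seq:
                raise FormatError(
                    f"{path}: record {i} ({tokens[0]}) has an empty sequence"
                )
            if tokens[0] in seen:
                raise FormatError(f"{path}: duplicate record id {tokens[0]}")
            seen.add(tokens[0])
            symbol = tokens[1] if len(tokens) > 1 else ""
            records.append(TranscriptRecord(tokens[0], seq, symbol))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.symbol}" if rec.symbol else "")
            fh.write(f"{header}\n{rec.sequence}\n")


def read_fastq(
    path: str | Path, gzipped: bool | None = None
) -> Iterator[SequenceRead]:
    """Stream 4-line FASTQ records (gzip auto-detected by .gz extension).

    Constant memory in the number of reads; quality retained but unused
    downstream. Records with mismatched quality length raise FormatError
    naming the record.
    """
    with _open_text(path, "r", gzipped) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split()[0] if title.split() else title
                if len(qual) != len(seq):
                    raise FormatError(
                        f"{path}: read {rid}: quality length {len(qual)} != "
                        f"sequence length {len(seq)}"
                    )
                yield SequenceRead(rid, seq, qual)
        except ValueError as exc:  # biopython's format diagnostics
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(
    reads: Iterable[SequenceRead], path: str | Path, gzipped: bool | None = None
) -> None:
    with _open_text(path, "w", gzipped) as fh:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
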