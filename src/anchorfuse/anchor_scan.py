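"""Anchor-probe design and raw-read extraction.

An anchor probe is a short exact k-mer (20-mer by default in this
workflow) taken from the transcript region where fusion breakpoints
cluster — for CIC-DUX4 sarcoma, the coding part of CIC's last exon.
Scanning a read set for the anchor pulls out every read that carries the
5' side of a potential fusion, wild-type and chimeric alike, exactly as
a text `grep` over the FASTQ sequence lines would.

Two scan modes are provided:

* ``GREP_LITERAL`` — exact, forward-orientation, case-insensitive
  substring matching, faithful to a command-line grep of the file;
* ``FULL`` — adds reverse-complement search and a Hamming-distance
  mismatch tolerance.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParameterError, ProbeError
from .seqcore import Region1, SequenceRead, TranscriptRecord, reverse_complement, subsequence

__all__ = [
    "ScanMode",
    "Orientation",
    "AnchorProbe",
    "AnchorHit",
    "make_probe",
    "scan_reads",
    "write_hits",
    "read_hits",
]


class ScanMode(Enum):
    GREP_LITERAL = "grep_literal"
    FULL = "full"


class Orientation(Enum):
    FWD = "FWD"
    REVCOMP = "REVCOMP"


@dataclass(frozen=True)
class AnchorProbe:
    """A k-mer probe, optionally tied to transcript coordinates."""

    transcript_id: str
    sequence: str
    region: Region1 | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ProbeError("probe sequence is empty")
        if "N" in seq or set(seq) - set("ACGT"):
            raise ProbeError(f"probe {self.transcript_id}: only A,C,G,T allowed")
        if self.region is not None and len(self.region) != len(seq):
            raise ProbeError(
                f"probe {self.transcript_id}: region length {len(self.region)} "
                f"!= sequence length {len(seq)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def k(self) -> int:
        return len(self.sequence)

    @property
    def name(self) -> str:
        if self.region is None:
            return self.transcript_id
        return f"{self.transcript_id}:{self.region.start}-{self.region.end}"

    @classmethod
    def from_sequence(cls, sequence: str, probe_id: str = "probe") -> "AnchorProbe":
        return cls(probe_id, sequence)


@dataclass(frozen=True)
class AnchorHit:
    """One probe occurrence in one read; offset is 1-based on the read."""

    read_id: str
    offset: int
    orientation: Orientation
    mismatches: int
    probe_id: str


def make_probe(t: TranscriptRecord, r: Region1) -> AnchorProbe:
    """Extract an anchor probe from a reference transcript region.

    Warns if the k-mer occurs more than once in the source transcript
    (a non-unique anchor will also capture reads from elsewhere).
    """
    kmer = subsequence(t, r)
    if "N" in kmer:
        raise ProbeError(f"region [{r.start},{r.end}] of {t.id} contains N")
    if t.sequence.count(kmer) > 1:
        warnings.warn(
            f"anchor {kmer} occurs {t.sequence.count(kmer)} times in {t.id}; "
            "non-unique anchor",
            stacklevel=2,
        )
    return AnchorProbe(t.id, kmer, r)


def _find_exact(seq: str, pat: str) -> Iterator[int]:
    """0-based start positions of all (overlapping) exact occurrences."""
    i = seq.find(pat)
    while i != -1:
        yield i
        i = seq.find(pat, i + 1)


def _find_hamming(seq: str, pat: str, max_mm: int) -> Iterator[tuple[int, int]]:
    """(0-based start, mismatch count) for windows within max_mm."""
    k = len(pat)
    for i in range(len(seq) - k + 1):
        mm = 0
        for a, b in zip(seq[i : i + k], pat):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            yield i, mm


def scan_reads(
    reads: Iterable[SequenceRead],
    probe: AnchorProbe,
    max_mismatches: int = 0,
    orientations: Iterable[Orientation] = (Orientation.FWD,),
    mode: ScanMode = ScanMode.GREP_LITERAL,
) -> tuple[list[AnchorHit], int]:
    """Scan a read stream for an anchor probe.

    Returns (all hits, number of distinct matching reads). Every
    occurrence within a read is reported, including overlapping ones;
    a read with one or more hits counts once toward the distinct count.
    Duplicate read records are not collapsed.

    In ``GREP_LITERAL`` mode the orientation set and mismatch tolerance
    are ignored (exact forward match only). An N in a read never matches
    in exact mode and counts as a mismatch in tolerant mode.
    """
    if max_mismatches >= probe.k:
        raise ParameterError(
            f"max_mismatches {max_mismatches} must be < probe length {probe.k}"
        )
    if mode is ScanMode.GREP_LITERAL:
        patterns = [(probe.sequence, Orientation.FWD)]
        max_mismatches = 0
    else:
        orient = list(dict.fromkeys(orientations))
        patterns = []
        for o in orient:
            pat = probe.sequence if o is Orientation.FWD else reverse_complement(probe.sequence)
            patterns.append((pat, o))

    hits: list[AnchorHit] = []
    n_matched = 0
    for read in reads:
        read_hits: list[AnchorHit] = []
        for pat, orientation in patterns:
            if max_mismatches == 0:
                occs = ((i, 0) for i in _find_exact(read.sequence, pat))
            else:
                occs = _find_hamming(read.sequence, pat, max_mismatches)
            for i, mm in occs:
                read_hits.append(
                    AnchorHit(read.id, i + 1, orientation, mm, probe.name)
                )
        if read_hits:
            n_matched += 1
            read_hits.sort(key=lambda h: (h.offset, h.orientation.value))
            hits.extend(read_hits)
    return hits, n_matched


_HIT_COLUMNS = ["read_id", "offset", "orientation", "mismatches", "probe_id"]


def write_hits(hits: Iterable[AnchorHit], path: str | Path) -> None:
    """Write hits as TSV in read order, then offset."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_HIT_COLUMNS)
        for h in hits:
            w.writerow([h.read_id, h.offset, h.orientation.value, h.mismatches, h.probe_id])


def read_hits(path: str | Path) -> list[AnchorHit]:
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        return [
            AnchorHit(
                row["read_id"],
                int(row["offset"]),
                Orientation(row["orientation"]),
                int(row["mismatches"]),
                row["probe_id"],
            )
            for row in r
        ]
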