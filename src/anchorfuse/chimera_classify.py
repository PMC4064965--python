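"""Split-read classification of anchor-bearing reads.

Each read containing the anchor is split at the anchor's last base. The
downstream suffix is tested first against the native continuation (the
reference bases immediately 3' of the anchor): a read that simply
follows the reference is wild-type transcript. A read that diverges
early is tested against the expected first bases of the fusion partner
(the partner seed, 10 nt by default). Because the junction may carry
microhomology — bases identical in both partners — the seed window is
tried at every back-off over native-matched bases that also equal the
seed prefix, and the minimum mismatch count is reported.

This replaces a per-read BLAST against the full transcript database
with a deterministic test against explicit candidate partners, plus an
optional seed-and-extend local alignment to locate the partner segment
on a supplied partner reference.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from .anchor_scan import AnchorProbe
from .errors import FormatError, ParameterError
from .seqcore import SequenceRead, TranscriptRecord, reverse_complement

__all__ = [
    "Status",
    "ClassifyPolicy",
    "JunctionContext",
    "SplitReadCall",
    "PartnerAlignment",
    "classify_read",
    "classify_set",
    "align_partner_segment",
    "write_calls",
    "read_calls",
]


class Status(Enum):
    WILDTYPE = "WILDTYPE"
    CHIMERIC = "CHIMERIC"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ClassifyPolicy:
    """Thresholds for the split-read decision.

    wildtype_min: native-extension length above which a read is called
        wild-type continuation regardless of what follows.
    seed_mismatches: maximum mismatches allowed over the partner seed
        window for a chimeric call. The default 0 (exact seed) is what
        separates true fusion reads from paralog-variant reads such as
        D4Z4 copies differing within the first 10 partner bases.
    min_suffix: minimum bases required after the anchor to attempt any
        call.
    min_identity / min_aln: acceptance gates for the optional partner
        reference alignment.
    """

    wildtype_min: int = 10
    seed_mismatches: int = 0
    min_suffix: int = 10
    min_identity: float = 0.9
    min_aln: int = 15

    def __post_init__(self) -> None:
        if self.min_suffix < 1 or self.wildtype_min < 1:
            raise ParameterError("wildtype_min and min_suffix must be >= 1")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ParameterError("min_identity must be in [0,1]")


DEFAULT_POLICY = ClassifyPolicy()


@dataclass(frozen=True)
class JunctionContext:
    """Everything needed to split reads at one candidate junction."""

    native_probe: AnchorProbe
    native_continuation: str
    partner_seed: str
    partner_reference: TranscriptRecord | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "native_continuation", self.native_continuation.upper())
        object.__setattr__(self, "partner_seed", self.partner_seed.upper())
        if len(self.native_continuation) < self.seed_len:
            raise ParameterError(
                "native continuation shorter than the partner seed"
            )

    @property
    def seed_len(self) -> int:
        return len(self.partner_seed)


@dataclass(frozen=True)
class PartnerAlignment:
    """Best seed-and-extend locus of a partner segment."""

    offset: int  # 1-based start on the partner, forward coordinates
    strand: str  # "+" or "-"
    identity: float
    aligned_length: int
    accepted: bool


@dataclass(frozen=True)
class SplitReadCall:
    read_id: str
    status: Status
    native_extension: int
    partner_seed_mismatches: int | None = None
    partner_offset: int | None = None
    microhomology_used: int = 0
    reason: str = ""


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _seed_candidates(
    suffix: str, native_extension: int, seed: str
) -> list[tuple[int, int]]:
    """(back-off b, mismatches over the seed window) for each admissible b.

    A back-off of b is admissible when the last b native-matched bases
    equal the first b seed bases (junction microhomology) and the seed
    window fits within the suffix.
    """
    out: list[tuple[int, int]] = []
    s = len(seed)
    for b in range(0, min(native_extension, s) + 1):
        if suffix[native_extension - b : native_extension] != seed[:b]:
            continue
        window = suffix[native_extension - b : native_extension - b + s]
        if len(window) < s:
            continue
        out.append((b, sum(x != y for x, y in zip(window, seed))))
    return out


def classify_read(
    read: SequenceRead,
    ctx: JunctionContext,
    policy: ClassifyPolicy = DEFAULT_POLICY,
) -> SplitReadCall:
    """Classify one read as WILDTYPE, CHIMERIC or UNASSIGNED.

    Pure function of (read, ctx, policy). Reads without an exact anchor
    occurrence, or with fewer than policy.min_suffix bases after it, are
    UNASSIGNED with a reason rather than errors.
    """
    seq = read.sequence
    pos = seq.find(ctx.native_probe.sequence)
    if pos == -1:
        return SplitReadCall(read.id, Status.UNASSIGNED, 0, reason="no anchor")
    suffix = seq[pos + ctx.native_probe.k :]
    if len(suffix) < policy.min_suffix:
        return SplitReadCall(
            read.id, Status.UNASSIGNED, 0, reason="suffix too short"
        )

    ext = _lcp(suffix, ctx.native_continuation)
    if ext >= min(len(suffix), policy.wildtype_min):
        reason = ""
        if ext < len(suffix):
            # divergence after a convincing native run: possible
            # downstream event, still wild-type at this junction
            reason = "divergence after native extension"
        return SplitReadCall(read.id, Status.WILDTYPE, ext, reason=reason)

    candidates = _seed_candidates(suffix, ext, ctx.partner_seed)
    if not candidates:
        return SplitReadCall(
            read.id,
            Status.UNASSIGNED,
            ext,
            reason="suffix shorter than partner seed",
        )
    # minimum mismatches; tie broken toward the larger back-off, i.e.
    # toward explaining shared bases as microhomology
    mh, mm = min(candidates, key=lambda c: (c[1], -c[0]))
    if mm > policy.seed_mismatches:
        return SplitReadCall(
            read.id,
            Status.UNASSIGNED,
            ext,
            partner_seed_mismatches=mm,
            microhomology_used=mh,
            reason="partner seed mismatch",
        )

    partner_offset: int | None = None
    if ctx.partner_reference is not None:
        segment = suffix[ext - mh :]
        aln = align_partner_segment(
            segment, ctx.partner_reference, policy, seed_len=ctx.seed_len
        )
        if aln is None:
            return SplitReadCall(
                read.id,
                Status.UNASSIGNED,
                ext,
                partner_seed_mismatches=mm,
                microhomology_used=mh,
                reason="no partner locus",
            )
        if not aln.accepted:
            return SplitReadCall(
                read.id,
                Status.UNASSIGNED,
                ext,
                partner_seed_mismatches=mm,
                microhomology_used=mh,
                reason="partner identity below threshold",
            )
        partner_offset = aln.offset
    return SplitReadCall(
        read.id,
        Status.CHIMERIC,
        ext,
        partner_seed_mismatches=mm,
        partner_offset=partner_offset,
        microhomology_used=mh,
    )


def classify_set(
    reads: Iterable[SequenceRead],
    ctx: JunctionContext,
    policy: ClassifyPolicy = DEFAULT_POLICY,
) -> tuple[list[SplitReadCall], Counter]:
    """Classify every read; returns (calls in input order, status counts)."""
    calls = [classify_read(r, ctx, policy) for r in reads]
    counts = Counter(c.status for c in calls)
    for status in Status:
        counts.setdefault(status, 0)
    return calls, counts


def align_partner_segment(
    segment: str,
    partner: TranscriptRecord,
    policy: ClassifyPolicy = DEFAULT_POLICY,
    seed_len: int = 10,
) -> PartnerAlignment | None:
    """Locate a read segment on a partner reference by seed-and-extend.

    Exact seed_len-mer matches of the segment's prefix are sought on
    both strands; each candidate locus is scored by ungapped comparison
    (+1 match / -1 mismatch) over the overlap, and the best-scoring
    locus is returned with its identity. Returns None when no seed
    matches anywhere.

    The reported offset is always in forward partner coordinates of the
    locus where the (strand-adjusted) segment begins, so a segment that
    is the reverse complement of a partner slice reports the slice's own
    start with strand "-".
    """
    segment = segment.upper()
    if len(segment) < seed_len:
        return None
    ref = partner.sequence
    best: tuple[int, PartnerAlignment] | None = None

    def consider(start0: int, query: str, strand: str) -> None:
        nonlocal best
        aligned = min(len(query), len(ref) - start0)
        if aligned <= 0:
            return
        matches = sum(
            a == b for a, b in zip(query[:aligned], ref[start0 : start0 + aligned])
        )
        score = 2 * matches - aligned  # (+1 per match, -1 per mismatch)
        identity = matches / aligned
        aln = PartnerAlignment(
            offset=start0 + 1,
            strand=strand,
            identity=identity,
            aligned_length=aligned,
            accepted=identity >= policy.min_identity and aligned >= policy.min_aln,
        )
        if best is None or score > best[0]:
            best = (score, aln)

    seed = segment[:seed_len]
    i = ref.find(seed)
    while i != -1:
        consider(i, segment, "+")
        i = ref.find(seed, i + 1)

    rc = reverse_complement(segment)
    rc_seed = rc[-seed_len:]  # the segment prefix, on the forward strand
    j = ref.find(rc_seed)
    while j != -1:
        start0 = j + seed_len - len(rc)
        if start0 >= 0:
            consider(start0, rc, "-")
        j = ref.find(rc_seed, j + 1)

    return best[1] if best is not None else None


_CALL_COLUMNS = [
    "read_id",
    "status",
    "native_extension",
    "partner_seed_mismatches",
    "partner_offset",
    "microhomology_used",
    "reason",
]


def write_calls(calls: Iterable[SplitReadCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CALL_COLUMNS)
        for c in calls:
            w.writerow(
                [
                    c.read_id,
                    c.status.value,
                    c.native_extension,
                    "" if c.partner_seed_mismatches is None else c.partner_seed_mismatches,
                    "" if c.partner_offset is None else c.partner_offset,
                    c.microhomology_used,
                    c.reason,
                ]
            )


def read_calls(path: str | Path) -> list[SplitReadCall]:
    with open(path, newline="") as fh:
        r = csv.DictReader(fh, delimiter="\t")
        if r.fieldnames != _CALL_COLUMNS:
            raise FormatError(f"{path}: unexpected call-table columns {r.fieldnames}")
        return [
            SplitReadCall(
                row["read_id"],
                Status(row["status"]),
                int(row["native_extension"]),
                int(row["partner_seed_mismatches"]) if row["partner_seed_mismatches"] else None,
                int(row["partner_offset"]) if row["partner_offset"] else None,
                int(row["microhomology_used"]),
                row["reason"],
            )
            for row in r
        ]
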