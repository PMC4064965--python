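"""Consensus junction model, microhomology canonicalization, and the
junction-spanning probe.

Per-read breakpoints are aggregated by majority vote. When the bases at
the junction are identical in both partner references (microhomology),
the exact breakpoint is ambiguous by that many positions; the canonical
model assigns all shared bases to the partner (3') side — the
"native-minimal" convention — which reproduces coordinate styles such
as CIC nt 4724 | DUX4 nt 771 for the CIC-DUX4 junction, whose shared
post-anchor C could equally be counted as CIC nt 4725. Both conventions
are recoverable: native_end_maximal == native_end + microhomology_len.

The junction probe concatenates a per-side flank (default 10 nt) around
the canonical breakpoint; re-scanning the read set with it counts reads
that span the fusion point itself.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .anchor_scan import AnchorProbe, Orientation, ScanMode, scan_reads
from .chimera_classify import JunctionContext, SplitReadCall, Status
from .errors import CoordinateError, JunctionInferenceError, ParameterError
from .seqcore import Region1, SequenceRead, TranscriptRecord, subsequence

__all__ = [
    "JunctionModel",
    "JunctionProbe",
    "infer_junction",
    "make_junction_probe",
    "rescan_junction",
]


@dataclass(frozen=True)
class JunctionModel:
    """Consensus fusion breakpoint under the native-minimal convention."""

    native_id: str
    native_end: int  # 1-based last native base
    partner_id: str
    partner_start: int | None  # 1-based first partner base, if locatable
    microhomology_len: int
    supporting_reads: int
    junction_sequence: str  # flank*2 bases centred on the junction
    junction_flank: int = 10
    ambiguous: bool = False
    breakpoint_votes: tuple[tuple[int, int], ...] = ()  # (raw native end, count)

    @property
    def native_end_maximal(self) -> int:
        """Last native base when microhomology is assigned to the native side."""
        return self.native_end + self.microhomology_len

    @property
    def partner_start_maximal(self) -> int | None:
        if self.partner_start is None:
            return None
        return self.partner_start + self.microhomology_len

    def to_json(self) -> str:
        d = {
            "native_id": self.native_id,
            "native_end": self.native_end,
            "partner_id": self.partner_id,
            "partner_start": self.partner_start,
            "microhomology_len": self.microhomology_len,
            "native_end_maximal": self.native_end_maximal,
            "partner_start_maximal": self.partner_start_maximal,
            "supporting_reads": self.supporting_reads,
            "junction_sequence": self.junction_sequence,
            "junction_flank": self.junction_flank,
            "ambiguous": self.ambiguous,
            "breakpoint_votes": [list(v) for v in self.breakpoint_votes],
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "JunctionModel":
        d = json.loads(text)
        return cls(
            native_id=d["native_id"],
            native_end=d["native_end"],
            partner_id=d["partner_id"],
            partner_start=d["partner_start"],
            microhomology_len=d["microhomology_len"],
            supporting_reads=d["supporting_reads"],
            junction_sequence=d["junction_sequence"],
            junction_flank=d.get("junction_flank", 10),
            ambiguous=d.get("ambiguous", False),
            breakpoint_votes=tuple(tuple(v) for v in d.get("breakpoint_votes", [])),
        )


@dataclass(frozen=True)
class JunctionProbe:
    """A breakpoint-spanning k-mer: `flank` bases from each partner."""

    sequence: str
    flank: int

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ParameterError("flank must be >= 1")
        if len(self.sequence) != 2 * self.flank:
            raise ParameterError(
                f"junction probe length {len(self.sequence)} != 2*flank"
            )


def _microhomology(native_continuation: str, partner_seed: str, extension: int) -> int:
    """Longest b with the last b native-matched bases equal to the seed prefix."""
    b = 0
    for cand in range(1, min(extension, len(partner_seed)) + 1):
        if native_continuation[extension - cand : extension] == partner_seed[:cand]:
            b = cand
    return b


def infer_junction(
    calls: Iterable[SplitReadCall],
    ctx: JunctionContext,
    anchor_end_coord: int,
    flank: int = 10,
) -> JunctionModel:
    """Aggregate chimeric calls into a consensus junction model.

    Each chimeric read votes for a raw breakpoint
    ``anchor_end_coord + native_extension`` (its native-maximal reading:
    sequencing reads naturally extend through any shared bases). The
    majority raw breakpoint wins, ties broken toward the smaller native
    end; microhomology against the partner seed is then reassigned to
    the partner side to give the canonical native_end. supporting_reads
    counts concordant votes. If the top two raw breakpoints tie, the
    model is flagged ambiguous and the top votes are reported.

    partner_start is the majority partner_offset among concordant calls
    (available when classification aligned segments against a partner
    reference), else None.
    """
    chimeric = [c for c in calls if c.status is Status.CHIMERIC]
    if not chimeric:
        raise JunctionInferenceError("no chimeric calls to infer a junction from")

    votes = Counter(anchor_end_coord + c.native_extension for c in chimeric)
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    raw_end, support = ranked[0]
    ambiguous = len(ranked) > 1 and ranked[1][1] == ranked[0][1]

    extension = raw_end - anchor_end_coord
    if extension < 0 or extension > len(ctx.native_continuation):
        raise JunctionInferenceError(
            f"consensus extension {extension} outside the native continuation"
        )
    mh = _microhomology(ctx.native_continuation, ctx.partner_seed, extension)
    native_end = raw_end - mh

    concordant = [c for c in chimeric if anchor_end_coord + c.native_extension == raw_end]
    offsets = Counter(c.partner_offset for c in concordant if c.partner_offset is not None)
    partner_start = offsets.most_common(1)[0][0] if offsets else None

    # junction-adjacent context: anchor + native continuation on the
    # native side (anchor's last base sits at anchor_end_coord),
    # partner seed / reference on the partner side
    native_ctx = ctx.native_probe.sequence + ctx.native_continuation
    cut = ctx.native_probe.k + extension - mh  # index of the junction in native_ctx
    if cut < flank:
        raise CoordinateError("insufficient native context for the requested flank")
    native_flank = native_ctx[cut - flank : cut]
    if ctx.partner_reference is not None and partner_start is not None:
        partner_flank = subsequence(
            ctx.partner_reference, Region1(partner_start, partner_start + flank - 1)
        )
    elif flank <= ctx.seed_len:
        partner_flank = ctx.partner_seed[:flank]
    else:
        raise CoordinateError(
            "flank exceeds the partner seed and no partner reference is available"
        )

    return JunctionModel(
        native_id=ctx.native_probe.transcript_id,
        native_end=native_end,
        partner_id=(
            ctx.partner_reference.id if ctx.partner_reference is not None else "partner"
        ),
        partner_start=partner_start,
        microhomology_len=mh,
        supporting_reads=support,
        junction_sequence=native_flank + partner_flank,
        junction_flank=flank,
        ambiguous=ambiguous,
        breakpoint_votes=tuple((end, n) for end, n in ranked[:2]),
    )


def _native_flank(source: TranscriptRecord | str, j: JunctionModel, flank: int) -> str:
    if isinstance(source, TranscriptRecord):
        if j.native_end - flank + 1 < 1:
            raise CoordinateError("native flank extends before base 1")
        return subsequence(source, Region1(j.native_end - flank + 1, j.native_end))
    # a plain string is junction-adjacent context ending at native_end
    if len(source) < flank:
        raise CoordinateError("native context string shorter than flank")
    return source.upper()[-flank:]


def _partner_flank(source: TranscriptRecord | str, j: JunctionModel, flank: int) -> str:
    if isinstance(source, TranscriptRecord):
        if j.partner_start is None:
            raise CoordinateError("junction model has no partner_start coordinate")
        return subsequence(source, Region1(j.partner_start, j.partner_start + flank - 1))
    # a plain string is junction-adjacent context starting at partner_start
    if len(source) < flank:
        raise CoordinateError("partner context string shorter than flank")
    return source.upper()[:flank]


def make_junction_probe(
    j: JunctionModel,
    native: TranscriptRecord | str | None = None,
    partner: TranscriptRecord | str | None = None,
    flank: int = 10,
) -> JunctionProbe:
    """Build the breakpoint-spanning probe: `flank` native bases ending
    at native_end followed by `flank` partner bases from partner_start.

    `native`/`partner` may be full transcripts (sliced by coordinates)
    or plain junction-adjacent context strings (native ends at the
    junction, partner starts at it). With neither given, the probe is
    cut from the model's stored junction_sequence when its flank
    suffices.
    """
    if native is None and partner is None:
        if flank > j.junction_flank:
            raise CoordinateError(
                f"model stores flank {j.junction_flank}; cannot cut flank {flank}"
            )
        mid = len(j.junction_sequence) // 2
        return JunctionProbe(j.junction_sequence[mid - flank : mid + flank], flank)
    if native is None or partner is None:
        raise ParameterError("provide both native and partner contexts, or neither")
    return JunctionProbe(
        _native_flank(native, j, flank) + _partner_flank(partner, j, flank), flank
    )


def rescan_junction(
    reads: Iterable[SequenceRead],
    probe: JunctionProbe,
    max_mismatches: int = 0,
    orientations: Iterable[Orientation] = (Orientation.FWD,),
    mode: ScanMode = ScanMode.GREP_LITERAL,
) -> int:
    """Distinct reads containing the junction probe (junction support)."""
    anchor = AnchorProbe.from_sequence(probe.sequence, "junction")
    _, n = scan_reads(
        reads, anchor, max_mismatches=max_mismatches, orientations=orientations, mode=mode
    )
    return n
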