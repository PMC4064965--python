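"""In-silico PCR on a cDNA template, with GC-difficulty flagging.

Primers are matched exactly (the workflow's primers are exact template
slices; no melting-temperature model). The amplicon runs from the 5'
base of the forward primer to the 5' base of the reverse primer — the
standard PCR product, primers included. Products at or above the
GC-rich threshold (65% by default; empirically hard-to-amplify fusion
products run 69-70%) are flagged with a redesign recommendation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .errors import AlphabetError, CoordinateError, OrientationError, PrimerSiteError
from .junction import JunctionModel
from .seqcore import TranscriptRecord, gc_percent, reverse_complement

__all__ = [
    "PrimerDirection",
    "Primer",
    "AmpliconReport",
    "build_fusion_template",
    "find_amplicon",
    "gc_difficulty_report",
    "round_half_up",
]

GC_RICH_THRESHOLD = 65.0


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (report style)."""
    return int(math.floor(x + 0.5))


class PrimerDirection(Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3'."""

    name: str
    sequence: str
    direction: PrimerDirection

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or set(seq) - set("ACGT"):
            raise AlphabetError(f"primer {self.name}: only A,C,G,T allowed")
        object.__setattr__(self, "sequence", seq)

    @classmethod
    def from_spec(cls, spec: str, direction: PrimerDirection | None = None) -> "Primer":
        """Parse "NAME:SEQUENCE"; direction inferred from a trailing F/R
        in the name when not given explicitly."""
        name, _, seq = spec.partition(":")
        if not seq:
            raise PrimerSiteError(f"primer spec {spec!r}: expected NAME:SEQUENCE")
        if direction is None:
            if name.upper().endswith("F"):
                direction = PrimerDirection.FORWARD
            elif name.upper().endswith("R"):
                direction = PrimerDirection.REVERSE
            else:
                raise PrimerSiteError(
                    f"primer {name}: cannot infer direction from name"
                )
        return cls(name, seq, direction)


@dataclass(frozen=True)
class AmpliconReport:
    """Predicted PCR product; start/end are 1-based on the template."""

    template_id: str
    fwd_name: str
    rev_name: str
    start: int  # 5' base of the forward primer
    end: int  # 5' base of the reverse primer on the template
    length_bp: int
    gc_percent: float  # unrounded; round_half_up at report time
    gc_rich_flag: bool
    sequence: str

    @property
    def gc_percent_rounded(self) -> int:
        return round_half_up(self.gc_percent)


def build_fusion_template(
    native: TranscriptRecord, partner: TranscriptRecord, j: JunctionModel
) -> TranscriptRecord:
    """Reconstruct the fusion cDNA: native bases 1..native_end followed
    by partner bases partner_start..end."""
    if j.partner_start is None:
        raise CoordinateError("junction model has no partner_start coordinate")
    if not (1 <= j.native_end <= len(native)):
        raise CoordinateError(
            f"native_end {j.native_end} outside {native.id} (length {len(native)})"
        )
    if not (1 <= j.partner_start <= len(partner)):
        raise CoordinateError(
            f"partner_start {j.partner_start} outside {partner.id} "
            f"(length {len(partner)})"
        )
    seq = native.sequence[: j.native_end] + partner.sequence[j.partner_start - 1 :]
    fid = f"{native.id}:1-{j.native_end}|{partner.id}:{j.partner_start}-{len(partner)}"
    symbol = "-".join(s for s in (native.symbol, partner.symbol) if s)
    return TranscriptRecord(fid, seq, symbol)


def find_amplicon(
    template: TranscriptRecord,
    fwd: Primer,
    rev: Primer,
    gc_rich_threshold: float = GC_RICH_THRESHOLD,
) -> AmpliconReport:
    """Locate a primer pair on the template and report the product.

    The leftmost forward site and the rightmost compatible reverse site
    are used (the maximal product). Multiple forward sites trigger a
    warning. The product must begin with the forward primer and end
    with the reverse complement of the reverse primer.
    """
    seq = template.sequence
    fpat = fwd.sequence
    fpos = [i for i in _occurrences(seq, fpat)]
    if not fpos:
        raise PrimerSiteError(
            f"forward primer {fwd.name} not found on {template.id}"
        )
    if len(fpos) > 1:
        warnings.warn(
            f"forward primer {fwd.name}: {len(fpos)} sites on {template.id}; "
            "using leftmost",
            stacklevel=2,
        )
    f0 = fpos[0]

    rpat = reverse_complement(rev.sequence)
    rpos = [i for i in _occurrences(seq, rpat)]
    if not rpos:
        raise PrimerSiteError(
            f"reverse primer {rev.name} (as reverse complement) not found on "
            f"{template.id}"
        )
    compatible = [i for i in rpos if i >= f0]
    if not compatible:
        raise OrientationError(
            f"all {rev.name} sites lie upstream of {fwd.name} on {template.id}"
        )
    r0 = compatible[-1]

    start = f0 + 1
    end = r0 + len(rpat)  # 1-based last base == 5' base of the reverse primer
    product = seq[f0:end]
    gc = gc_percent(product)
    return AmpliconReport(
        template_id=template.id,
        fwd_name=fwd.name,
        rev_name=rev.name,
        start=start,
        end=end,
        length_bp=end - start + 1,
        gc_percent=gc,
        gc_rich_flag=gc >= gc_rich_threshold,
        sequence=product,
    )


def _occurrences(seq: str, pat: str) -> Iterable[int]:
    i = seq.find(pat)
    while i != -1:
        yield i
        i = seq.find(pat, i + 1)


_RECOMMENDATION = (
    "GC-rich product: use a high-fidelity polymerase suited to GC-rich "
    "templates and/or redesign a shorter or nested amplicon"
)


def gc_difficulty_report(reports: Iterable[AmpliconReport]) -> pd.DataFrame:
    """Tabulate amplicons with rounded GC, the GC-rich flag, and a
    redesign recommendation for flagged products."""
    rows = [
        {
            "template_id": r.template_id,
            "primer_pair": f"{r.fwd_name}/{r.rev_name}",
            "start": r.start,
            "end": r.end,
            "length_bp": r.length_bp,
            "gc_percent": r.gc_percent_rounded,
            "gc_rich": r.gc_rich_flag,
            "recommendation": _RECOMMENDATION if r.gc_rich_flag else "",
        }
        for r in reports
    ]
    columns = [
        "template_id",
        "primer_pair",
        "start",
        "end",
        "length_bp",
        "gc_percent",
        "gc_rich",
        "recommendation",
    ]
    return pd.DataFrame(rows, columns=columns)
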