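"""Reference constants for the CIC-DUX4 fusion workflow.

The anchor k-mers come from the coding part of CIC's last exon (exon
20, NM_015125.3), where all reported CIC breakpoints cluster. The
partner seed is the first 10 bases DUX4 (NM_033178.4) contributes after
the fusion point. Primer sequences are the published RT-PCR panel for
this fusion.
"""

from __future__ import annotations

from .anchor_scan import AnchorProbe
from .chimera_classify import JunctionContext
from .insilico_pcr import Primer, PrimerDirection
from .seqcore import Region1, TranscriptRecord

NATIVE_ACCESSION = "NM_015125.3"
NATIVE_SYMBOL = "CIC"
PARTNER_ACCESSION = "NM_033178.4"
PARTNER_SYMBOL = "DUX4"

#: CIC exon-20 anchor 20-mers with their NM_015125.3 coordinates
CIC_ANCHOR_A = AnchorProbe(NATIVE_ACCESSION, "GCCGCCTTCCAGGCCCGCTA", Region1(4511, 4530))
CIC_ANCHOR_B = AnchorProbe(NATIVE_ACCESSION, "CAGGGGGCCCTGACCCCACC", Region1(4701, 4720))

#: NM_015125.3 bases from nt 4721 onward (wild-type continuation after
#: anchor B), as carried by wild-type exon-20 reads
CIC_CONTINUATION_AFTER_4720 = (
    "TCACCCAGCTCGGACTCTGGCACGGCCCAGGCTGCCCCGCCACTGCCTCCACCCCCCGAGTCGGGGCCTGG"
)

#: NM_033178.4 nt 771-780: the first 10 DUX4 bases after the fusion point
DUX4_SEED_FROM_771 = "CGGCAGAGGG"
DUX4_SEED_COORD = 771


def cic_dux4_context(
    partner_reference: TranscriptRecord | None = None,
) -> tuple[JunctionContext, int]:
    """Junction context for the CIC-DUX4 exon-20 breakpoint cluster.

    Returns (context, anchor end coordinate on NM_015125.3).
    """
    ctx = JunctionContext(
        native_probe=CIC_ANCHOR_B,
        native_continuation=CIC_CONTINUATION_AFTER_4720,
        partner_seed=DUX4_SEED_FROM_771,
        partner_reference=partner_reference,
    )
    return ctx, CIC_ANCHOR_B.region.end


_F = PrimerDirection.FORWARD
_R = PrimerDirection.REVERSE

#: published RT-PCR primer panel for the CIC-DUX4 fusion (5'->3')
TABLE1_PRIMERS: dict[str, Primer] = {
    p.name: p
    for p in [
        Primer("CIC-4105F", "CGAAGAGCGCTTTGCTGAGTTGCC", _F),
        Primer("CIC-4283F", "AGAAGACGCTCCAGCTGCAGCTCG", _F),
        Primer("CIC-4377F", "CCGAGGACGTGCTTGGGGAGCTA", _F),
        Primer("CIC-4453F", "GGCCCTGGTCATGCAGCTCTTTCA", _F),
        Primer("CIC-4856R", "CTCAGGGGTCCCTCACCTGCCTGT", _R),
        Primer("CIC-4958R", "CCCAAACTGGAGAGGACGAAATGGC", _R),
        Primer("DUX4-1053R", "ACCGAGGAGCCTGAGGGTGGGAG", _R),
        Primer("DUX4-1151R", "CTTGAGCGGGCCCAGGCTGTG", _R),
        Primer("DUX4-1507R", "CTTCCAGCGAGGCGGCCTCTTC", _R),
        Primer("DUX4-1538R", "GCAGAGCCCGGTATTCTTCCTCGC", _R),
    ]
}
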