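"""Synthetic references, fusion transcripts and read sets with known truth.

The generator emulates the read structures seen around a fusion
breakpoint in ~100-nt single-end RNA-seq data: wild-type reads that
follow the native reference through the anchor region, fusion reads
that switch to the partner at a configurable breakpoint (with
engineered microhomology), and "variant" fusion reads drawn from a
diverged paralog copy of the partner — the failure mode by which
near-identical D4Z4 repeat copies produce partner-seed mismatches.
Substitution errors are i.i.d. per base; indels are not modelled.

Everything is deterministic given the config seed: one NumPy generator
drives the whole run, drawing in a fixed order (native reference,
partner reference, variant mutations, then per-source read counts,
start positions and errors in source order WILDTYPE, CHIMERIC,
VARIANT).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .junction import JunctionModel
from .insilico_pcr import build_fusion_template
from .seqcore import SequenceRead, TranscriptRecord, write_fasta, write_fastq

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "write_simulation",
    "table2_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the CIC-DUX4 worked example: a ~5.5-kb native
    transcript broken at nt 4724 joined to a ~1.6-kb partner from nt
    771 with 1 base of junction microhomology; 100-nt single-end reads;
    roughly a quarter of anchor-region reads wild-type and ~12% of
    fusion-derived reads from a diverged partner copy.
    """

    native_len: int = 5500
    partner_len: int = 1600
    native_end: int = 4724
    partner_start: int = 771
    microhomology_len: int = 1
    read_len: int = 100
    coverage: float = 30.0
    wildtype_fraction: float = 0.23
    variant_partner_rate: float = 0.12
    variant_divergence: float = 0.02
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.native_len, self.partner_len, self.read_len) < 1:
            raise ConfigError("lengths must be positive")
        for name in ("wildtype_fraction", "variant_partner_rate", "error_rate",
                     "variant_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.coverage < 0:
            raise ConfigError("coverage must be >= 0")
        if not (1 <= self.native_end <= self.native_len):
            raise ConfigError("native_end outside the native transcript")
        if not (1 <= self.partner_start <= self.partner_len):
            raise ConfigError("partner_start outside the partner transcript")
        if self.native_end + self.microhomology_len > self.native_len:
            raise ConfigError("microhomology extends past the native transcript")
        fusion_len = self.native_end + (self.partner_len - self.partner_start + 1)
        if self.read_len > min(self.native_len, fusion_len):
            raise ConfigError(
                f"read_len {self.read_len} exceeds a source transcript length"
            )


@dataclass(frozen=True)
class SimulationResult:
    config: SimulationConfig
    references: list[TranscriptRecord]  # native, partner, fusion, variant fusion
    reads: list[SequenceRead]
    truth: pd.DataFrame  # read_id, origin, source_id, start, junction_overlap

    @property
    def native(self) -> TranscriptRecord:
        return self.references[0]

    @property
    def partner(self) -> TranscriptRecord:
        return self.references[1]

    @property
    def fusion(self) -> TranscriptRecord:
        return self.references[2]


_TRUTH_COLUMNS = ["read_id", "origin", "source_id", "start", "junction_overlap"]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            force_window: tuple[int, int] | None = None) -> str:
    """Substitute bases i.i.d. at `rate`; optionally force >=1 change in
    a 0-based half-open window."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    if force_window is not None:
        lo, hi = force_window
        if not mask[lo:hi].any():
            mask[int(rng.integers(lo, hi))] = True
    idx = np.nonzero(mask)[0]
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Generate references, reads and a truth table for one run.

    The fusion transcript is native[1..native_end] + partner
    [partner_start..]; the partner is engineered so that exactly
    cfg.microhomology_len bases after the junction are shared with the
    native continuation (and the next base is forced to differ). Read
    counts per source are Poisson with mean coverage * weight * L /
    read_len; starts are uniform; substitution errors i.i.d. at
    error_rate. Fully deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)

    native_arr = list(_random_dna(rng, cfg.native_len))
    partner_arr = list(_random_dna(rng, cfg.partner_len))
    # engineer microhomology: partner bases at the junction copy the
    # native continuation, and the following base is forced to differ
    mh = cfg.microhomology_len
    for i in range(mh):
        partner_arr[cfg.partner_start - 1 + i] = native_arr[cfg.native_end + i]
    brk = cfg.partner_start - 1 + mh
    if brk < cfg.partner_len and cfg.native_end + mh < cfg.native_len:
        nat_next = native_arr[cfg.native_end + mh]
        if partner_arr[brk] == nat_next:
            alt = [b for b in "ACGT" if b != nat_next]
            partner_arr[brk] = alt[int(rng.integers(0, 3))]
    # repair any accidental microhomology beyond the engineered length:
    # if the canonical (partner-side) back-off over the last native
    # bases would exceed mh, perturb the native base where the spurious
    # shared window begins, so the planted breakpoint is canonical
    seed_cap = min(10, cfg.partner_len - cfg.partner_start + 1)
    while True:
        seed = "".join(partner_arr[cfg.partner_start - 1 : cfg.partner_start - 1 + seed_cap])
        detected = 0
        limit = min(cfg.native_end + mh, seed_cap)
        for b in range(1, limit + 1):
            if "".join(native_arr[cfg.native_end + mh - b : cfg.native_end + mh]) == seed[:b]:
                detected = b
        if detected <= mh:
            break
        i = cfg.native_end + mh - detected
        alt = [b for b in "ACGT" if b != native_arr[i] and b != seed[0]]
        native_arr[i] = alt[int(rng.integers(0, len(alt)))]
    native_seq = "".join(native_arr)
    partner_seq = "".join(partner_arr)

    native = TranscriptRecord("SYN_NATIVE", native_seq, "NATIVE")
    partner = TranscriptRecord("SYN_PARTNER", partner_seq, "PARTNER")
    j = JunctionModel(
        native_id=native.id,
        native_end=cfg.native_end,
        partner_id=partner.id,
        partner_start=cfg.partner_start,
        microhomology_len=mh,
        supporting_reads=1,
        junction_sequence=(
            native_seq[cfg.native_end - 10 : cfg.native_end]
            + partner_seq[cfg.partner_start - 1 : cfg.partner_start + 9]
        ),
    )
    fusion = build_fusion_template(native, partner, j)
    fusion = TranscriptRecord("SYN_FUSION", fusion.sequence, "NATIVE-PARTNER")

    variant_partner = _mutate(
        rng,
        partner_seq,
        cfg.variant_divergence,
        force_window=(cfg.partner_start - 1, cfg.partner_start - 1 + 10),
    )
    variant_fusion = TranscriptRecord(
        "SYN_FUSION_VARIANT",
        native_seq[: cfg.native_end] + variant_partner[cfg.partner_start - 1 :],
        "NATIVE-PARTNERVAR",
    )

    wf, vr = cfg.wildtype_fraction, cfg.variant_partner_rate
    sources = [
        ("WILDTYPE", native, wf),
        ("CHIMERIC", fusion, (1 - wf) * (1 - vr)),
        ("VARIANT", variant_fusion, (1 - wf) * vr),
    ]

    reads: list[SequenceRead] = []
    rows: list[dict] = []
    counter = 0
    for origin, src, weight in sources:
        mean = cfg.coverage * weight * len(src) / cfg.read_len
        n = int(rng.poisson(mean)) if mean > 0 else 0
        if n == 0:
            continue
        starts = rng.integers(0, len(src) - cfg.read_len + 1, size=n)
        for s0 in starts:
            counter += 1
            rid = f"R{counter:06d}"
            raw = src.sequence[s0 : s0 + cfg.read_len]
            seq = _mutate(rng, raw, cfg.error_rate) if cfg.error_rate > 0 else raw
            reads.append(SequenceRead(rid, seq, "I" * cfg.read_len))
            overlap = (
                origin != "WILDTYPE"
                and s0 + 1 <= cfg.native_end
                and s0 + cfg.read_len >= cfg.native_end + 1
            )
            rows.append(
                {
                    "read_id": rid,
                    "origin": origin,
                    "source_id": src.id,
                    "start": int(s0) + 1,
                    "junction_overlap": overlap,
                }
            )

    truth = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    return SimulationResult(
        config=cfg,
        references=[native, partner, fusion, variant_fusion],
        reads=reads,
        truth=truth,
    )


def write_simulation(
    result: SimulationResult, outdir: str | Path, gzip_reads: bool = True
) -> dict[str, Path]:
    """Write refs.fa, reads.fastq[.gz] and truth.tsv under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = outdir / "refs.fa"
    reads = outdir / ("reads.fastq.gz" if gzip_reads else "reads.fastq")
    truth = outdir / "truth.tsv"
    write_fasta(result.references, refs)
    write_fastq(result.reads, reads, gzipped=gzip_reads)
    result.truth.to_csv(truth, sep="\t", index=False)
    return {"refs": refs, "reads": reads, "truth": truth}


def junction_context(
    result: SimulationResult,
    anchor_gap: int = 4,
    k: int = 20,
    seed_len: int = 10,
    with_partner: bool = False,
):
    """Build the classification context matching a simulation's truth.

    The anchor is the k-mer ending `anchor_gap` bases before the planted
    native_end (mirroring the published design, where the anchor ends 4
    nt upstream of the breakpoint); the partner seed is the first
    seed_len partner bases from partner_start. Returns (JunctionContext,
    anchor end coordinate).
    """
    from .anchor_scan import make_probe
    from .chimera_classify import JunctionContext
    from .seqcore import Region1

    cfg = result.config
    anchor_end = cfg.native_end - anchor_gap
    if anchor_end < k:
        raise ConfigError("anchor region extends before base 1")
    probe = make_probe(result.native, Region1(anchor_end - k + 1, anchor_end))
    continuation = result.native.sequence[anchor_end : anchor_end + 200]
    seed = result.partner.sequence[cfg.partner_start - 1 : cfg.partner_start - 1 + seed_len]
    ctx = JunctionContext(
        native_probe=probe,
        native_continuation=continuation,
        partner_seed=seed,
        partner_reference=result.partner if with_partner else None,
    )
    return ctx, anchor_end


def table2_fixture() -> list[SequenceRead]:
    """The 22 published anchor-positive read sequences, uppercased, ids
    T2L01..T2L22 in printed order."""
    from .seqcore import read_fasta

    with resources.as_file(
        resources.files("anchorfuse.data") / "table2_reads.fasta"
    ) as path:
        return [SequenceRead(t.id, t.sequence) for t in read_fasta(path)]
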