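# Methods

## Model and procedure

anchorfuse detects a *specific*, hypothesized fusion transcript in raw
RNA-seq reads. It assumes: (i) the 5′ partner ("native" gene) has a known
breakpoint-hotspot region on its mRNA, so a short anchor k-mer upstream of
every plausible breakpoint tags all relevant reads; (ii) fusion-spanning
reads are split reads — a prefix following the native reference and a
suffix following the 3′ partner; and (iii) single-end, substitution-noise
sequencing at read lengths (~100 nt) comfortably longer than
anchor + junction evidence.

### Anchor scan

The default scan is exact, forward-orientation, case-insensitive substring
matching over read sequence lines — deliberately faithful to a command-line
text search of a FASTQ file, so counts are directly comparable with that
practice. Quality lines are parsed but never searched, which removes the
(rare) possibility of a text search hitting a quality string. The tolerant
mode (`FULL`) adds reverse-complement search and a Hamming mismatch budget;
an `N` in a read never matches exactly and counts as one mismatch in
tolerant mode. Every occurrence in a read is reported, but the headline
statistic is the number of distinct matching reads; duplicate reads are not
collapsed. The scanner is a naive sliding window: at desk scale (one probe,
up to a few million reads) nothing faster is warranted, and exactness
against a brute-force oracle is trivially testable.

### Split-read classification

For each anchor-bearing read, let S be the suffix after the anchor's last
base and `native_extension` e the longest common prefix of S with the
native continuation (the reference bases immediately 3′ of the anchor).

* e ≥ min(|S|, 10) → **WILDTYPE** (with a warning reason if the read later
  diverges — a possible downstream event; none occur in the worked example).
* Otherwise the 10-nt partner seed is tested. Because junction bases may be
  shared between the partners, the seed window is tried at every back-off
  b where the last b native-matched bases equal the first b seed bases
  (b = 0 … microhomology); the reported `partner_seed_mismatches` is the
  minimum over admissible windows, ties broken toward larger b. 0
  mismatches (default policy) → **CHIMERIC**; else **UNASSIGNED** with the
  count. This minimum-over-back-offs rule is what cleanly separates true
  junction reads (0 mismatches at b=1 in the worked example) from
  D4Z4-paralog variants (1–2 mismatches at their best window).
* Reads without an anchor, or with fewer than 10 bases after it, are
  UNASSIGNED with an explicit reason, never dropped silently.

When a partner reference is supplied, the partner segment is located by
seed-and-extend: exact 10-mer matches of the segment prefix on both
strands, ungapped ±1 scoring over the overlap, best locus kept, accepted at
identity ≥ 0.9 over ≥ 15 aligned bases. This replaces a per-read BLAST
against a remote database with a deterministic, offline test against
explicit candidates; the identity threshold (not the seed) absorbs deeper
paralog variation in the extension. A segment that aligns nowhere, or below
threshold, demotes the call to UNASSIGNED.

### Junction consensus and microhomology

Each chimeric read votes for a raw breakpoint `anchor_end + e`. Reads
naturally extend through any bases shared by both partners, so the raw vote
is the native-maximal reading. The majority wins (ties flagged ambiguous
and broken toward the smaller coordinate; sequencing-error outliers lose
the vote rather than being pre-filtered). The microhomology length is the
longest suffix of the native-matched bases equal to a prefix of the partner
seed; the canonical model subtracts it from the native side — the
**native-minimal convention**, shared junction bases belong to the 3′
partner. Both conventions are always recoverable
(`native_end_maximal = native_end + microhomology_len`, partner start
shifting oppositely), since the data cannot distinguish them. The junction
probe concatenates `flank` bases ending at the canonical native end with
`flank` bases from the canonical partner start (default flank 10, probe
length 20).

### In-silico PCR

Primers are matched exactly: the use case is verifying primer panels
against a reconstructed fusion cDNA whose primers are exact template
slices, so no melting-temperature or 3′-mismatch model is included (a
deliberate non-goal, as is thermodynamic primer design). The product runs
from the forward primer's 5′ base to the reverse primer's 5′ base,
primers included; leftmost forward and rightmost compatible reverse sites
give the maximal product, with a warning on multiple forward sites. GC% is
computed unrounded over the full product (N counts in the denominator
only) and rounded half-up to integer percent only at report time. Products
at ≥ 65% GC are flagged GC-rich with a redesign recommendation; the
threshold sits just below the 69–70% range where standard polymerases
empirically fail, and is configurable.

## Synthetic data generator

`synth.simulate` emulates the read structures this workflow confronts:
random native and partner mRNAs; a fusion transcript joined at a planted
breakpoint; an engineered microhomology (partner bases at the junction
copied from the native continuation, with the following base forced to
differ, and any *accidental* longer shared run repaired so the planted
breakpoint is the canonical one); a diverged paralog copy of the partner
(2% substitutions, at least one forced into the 10-nt seed window)
providing "variant" fusion reads; uniform single-end read sampling with
Poisson counts per source at mean `coverage × weight × length / read_len`;
and i.i.d. substitution errors. One seeded NumPy generator drives the run
in a documented draw order, so outputs are fully deterministic — including
byte-identical gzip (fixed header, no mtime).

Defaults mirror the worked example's conditions: native 5.5 kb broken at
nt 4724, partner 1.6 kb entered at nt 771, microhomology 1, read length
100 nt (the published captured reads are 101 nt), wild-type fraction 0.23
(5 of 22 anchor reads), variant rate 0.12 (2 of 17 fusion-derived anchor
reads), error rate 0.001 (typical HiSeq substitution scale). What the
generator does **not** model: indels, paired ends, quality-score structure,
expression-level and fragment-size realism, intron-aware genomic
coordinates. Passing tests on simulated data therefore demonstrate
correctness of the split-read logic and consensus arithmetic under
substitution noise — not robustness to indels near the junction or to
mapping artefacts in real libraries.

## Numerical and design choices

* **Coordinates** are 1-based inclusive on mRNA sequences throughout
  ("nt 4701–4720" style), eliminating off-by-one drift against published
  breakpoint coordinates; read offsets in reports are also 1-based.
* **Case** is canonicalized to uppercase at ingest; published read tables
  use case to mark gene of origin, and matching must ignore it.
* **Wild-type precedence**: a read following the native reference for ≥ 10
  bases is wild-type even if it diverges later — divergence after a
  convincing native run is more likely error or a different event than the
  junction under study.
* **Exact partner seed by default** (0 mismatches): tolerating even one
  mismatch would recruit paralog reads (the worked example's two variant
  reads) into the chimeric set; sensitivity studies can relax
  `ClassifyPolicy.seed_mismatches`.
* **Tie-breaks**: consensus ties go to the smaller native end (conservative
  toward the anchor); seed-window mismatch ties go to the larger back-off
  (explaining shared bases as microhomology).
* **Anchor placement in simulations** defaults to ending 4 nt before the
  planted breakpoint, mirroring the worked example's geometry
  (anchor end 4720, breakpoint 4724).
* Problem sizes in the test suite (references of 0.6–2 kb, coverages
  8–60×, 20 seeds for the noisy-consensus check) are chosen so each
  property has comfortable statistical margin (3σ bounds on Poisson/error
  calibration; ≥ 15 junction-spanning reads per noisy consensus) while the
  whole suite stays a desk-scale computation.

## Known limitations

* Partner discovery requires explicit candidate references or a seed
  string; there is no genome-wide search (by design — no network, no
  database dependency).
* Genome-scale claims (read counts out of ~10⁸-read libraries) are not
  reproducible here; the toolkit's accuracy surface is the packaged
  worked example plus simulation truth.
* Microhomology canonicalization is a convention, not an inference: the
  reads genuinely cannot resolve which side shared bases belong to, which
  is why both conventions are emitted.
* The in-silico PCR engine validates printed amplicon arithmetic only
  against templates the user supplies; fetching deposited GenBank records
  is out of scope.
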