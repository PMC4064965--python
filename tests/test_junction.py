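"""Consensus junction inference, microhomology canonicalization, the
junction probe, and junction-support rescan."""

import pytest

from anchorfuse.chimera_classify import SplitReadCall, Status, classify_set
from anchorfuse.errors import CoordinateError, JunctionInferenceError
from anchorfuse.junction import (
    JunctionModel,
    JunctionProbe,
    infer_junction,
    make_junction_probe,
    rescan_junction,
)
from anchorfuse.seqcore import SequenceRead, TranscriptRecord, subsequence, Region1
from anchorfuse.synth import SimulationConfig, junction_context, simulate


@pytest.fixture(scope="module")
def fixture_junction(t2_reads, cic_ctx):
    ctx, anchor_end = cic_ctx
    calls, _ = classify_set(t2_reads, ctx)
    return infer_junction(calls, ctx, anchor_end)


class TestWorkedExample:
    def test_consensus_breakpoint(self, fixture_junction):
        j = fixture_junction
        assert j.native_end == 4724
        assert j.microhomology_len == 1
        assert j.supporting_reads == 15
        assert not j.ambiguous

    def test_junction_probe_sequence(self, fixture_junction):
        probe = make_junction_probe(fixture_junction, flank=10)
        assert probe.sequence == "CCCACCTCACCGGCAGAGGG"

    def test_rescan_support_equals_chimeric_count(self, t2_reads, fixture_junction):
        probe = make_junction_probe(fixture_junction, flank=10)
        assert rescan_junction(t2_reads, probe) == 15

    def test_convention_identity(self, fixture_junction):
        j = fixture_junction
        assert j.native_end + j.microhomology_len == j.native_end_maximal == 4725


class TestInference:
    def test_empty_calls_is_error(self, cic_ctx):
        ctx, anchor_end = cic_ctx
        with pytest.raises(JunctionInferenceError):
            infer_junction([], ctx, anchor_end)

    def test_tied_votes_flag_ambiguous_toward_smaller_end(self, cic_ctx):
        ctx, anchor_end = cic_ctx
        calls = [
            SplitReadCall("a", Status.CHIMERIC, 5, 0),
            SplitReadCall("b", Status.CHIMERIC, 7, 0),
        ]
        j = infer_junction(calls, ctx, anchor_end)
        assert j.ambiguous
        assert j.breakpoint_votes == ((anchor_end + 5, 1), (anchor_end + 7, 1))
        assert j.native_end_maximal == anchor_end + 5

    def test_majority_wins_over_outlier(self, cic_ctx):
        ctx, anchor_end = cic_ctx
        calls = [SplitReadCall(f"r{i}", Status.CHIMERIC, 5, 0) for i in range(4)]
        calls.append(SplitReadCall("odd", Status.CHIMERIC, 3, 0))
        j = infer_junction(calls, ctx, anchor_end)
        assert j.native_end == 4724
        assert j.supporting_reads == 4
        assert not j.ambiguous

    def test_single_error_free_read_recovers_planted_breakpoint(self):
        cfg = SimulationConfig(
            native_len=600,
            partner_len=400,
            native_end=300,
            partner_start=100,
            microhomology_len=0,
            coverage=0.0,
            error_rate=0.0,
            seed=5,
        )
        sim = simulate(cfg)
        ctx, anchor_end = junction_context(sim)
        start0 = cfg.native_end - 60  # spans anchor and junction
        read = SequenceRead("one", sim.fusion.sequence[start0 : start0 + 100])
        calls, _ = classify_set([read], ctx)
        j = infer_junction(calls, ctx, anchor_end)
        assert j.native_end == cfg.native_end
        assert j.microhomology_len == 0
        assert j.supporting_reads == 1

    @pytest.mark.parametrize("mh", [0, 1, 3])
    def test_engineered_microhomology_canonicalized_to_partner_side(self, mh):
        cfg = SimulationConfig(
            native_len=1200,
            partner_len=800,
            native_end=700,
            partner_start=250,
            microhomology_len=mh,
            coverage=8.0,
            error_rate=0.0,
            variant_partner_rate=0.0,
            seed=40 + mh,
        )
        sim = simulate(cfg)
        ctx, anchor_end = junction_context(sim, with_partner=True)
        calls, counts = classify_set(sim.reads, ctx)
        assert counts[Status.CHIMERIC] >= 3
        j = infer_junction(calls, ctx, anchor_end)
        assert j.microhomology_len == mh
        assert j.native_end == cfg.native_end  # native-minimal convention
        assert j.native_end_maximal == cfg.native_end + mh
        assert j.partner_start == cfg.partner_start
        assert j.partner_start_maximal == cfg.partner_start + mh


class TestJunctionProbe:
    def test_flank_one_toy_junction(self):
        native = TranscriptRecord("N", "TTA")
        partner = TranscriptRecord("P", "GCC")
        j = JunctionModel("N", 3, "P", 1, 0, 1, "AG", junction_flank=1)
        assert make_junction_probe(j, native, partner, flank=1).sequence == "AG"

    def test_probe_equals_brute_force_slices(self, small_sim):
        cfg = small_sim.config
        j = JunctionModel(
            "SYN_NATIVE", cfg.native_end, "SYN_PARTNER", cfg.partner_start,
            1, 1, "N" * 30, junction_flank=15,
        )
        probe = make_junction_probe(j, small_sim.native, small_sim.partner, flank=15)
        expected = (
            subsequence(small_sim.native, Region1(cfg.native_end - 14, cfg.native_end))
            + subsequence(
                small_sim.partner, Region1(cfg.partner_start, cfg.partner_start + 14)
            )
        )
        assert probe.sequence == expected
        assert len(probe.sequence) == 30

    def test_string_contexts_slice_at_the_junction(self):
        j = JunctionModel("N", 50, "P", 9, 0, 1, "ACGTTGCA", junction_flank=4)
        probe = make_junction_probe(j, "AAACGT", "TGCAAA", flank=4)
        assert probe.sequence == "ACGTTGCA"

    def test_insufficient_context_is_coordinate_error(self):
        j = JunctionModel("N", 2, "P", 1, 0, 1, "AG", junction_flank=1)
        native = TranscriptRecord("N", "TTA")
        partner = TranscriptRecord("P", "GCC")
        with pytest.raises(CoordinateError):
            make_junction_probe(j, native, partner, flank=5)

    def test_probe_found_in_fusion_transcript(self, small_sim):
        ctx, anchor_end = junction_context(small_sim, with_partner=True)
        calls, _ = classify_set(small_sim.reads, ctx)
        j = infer_junction(calls, ctx, anchor_end)
        probe = make_junction_probe(j, small_sim.native, small_sim.partner, flank=10)
        assert probe.sequence in small_sim.fusion.sequence
        assert rescan_junction([SequenceRead("f", small_sim.fusion.sequence)], probe) == 1

    def test_json_round_trip(self, fixture_junction):
        j2 = JunctionModel.from_json(fixture_junction.to_json())
        assert j2 == fixture_junction


class TestRescan:
    def test_empty_stream(self):
        probe = JunctionProbe("ACGTACGTTT", 5)
        assert rescan_junction([], probe) == 0

    def test_simulated_planted_support(self, small_sim):
        """Literal rescan finds exactly the reads whose overlap covers
        the full junction probe, on error-free data."""
        cfg = small_sim.config
        ctx, anchor_end = junction_context(small_sim, with_partner=True)
        calls, _ = classify_set(small_sim.reads, ctx)
        j = infer_junction(calls, ctx, anchor_end)
        probe = make_junction_probe(j, small_sim.native, small_sim.partner, flank=10)
        truth = small_sim.truth
        spans = truth[
            (truth.origin == "CHIMERIC")
            & (truth.start <= cfg.native_end - 9)
            & (truth.start + cfg.read_len - 1 >= cfg.native_end + 10)
        ]
        assert rescan_junction(small_sim.reads, probe) == len(spans) > 0
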