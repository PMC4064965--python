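"""The synthetic-data generator: determinism, planted truth, error
model calibration, and the exact-match fragility property."""

import numpy as np
import pytest

from anchorfuse.anchor_scan import AnchorProbe, Orientation, ScanMode, scan_reads
from anchorfuse.chimera_classify import Status, classify_set
from anchorfuse.errors import ConfigError
from anchorfuse.junction import infer_junction, make_junction_probe, rescan_junction
from anchorfuse.synth import (
    SimulationConfig,
    junction_context,
    simulate,
    table2_fixture,
    write_simulation,
)

SMALL = dict(
    native_len=1500, partner_len=900, native_end=800, partner_start=300, coverage=10.0
)


class TestTable2Fixture:
    def test_twenty_two_reads_in_printed_order(self):
        reads = table2_fixture()
        assert [r.id for r in reads] == [f"T2L{i:02d}" for i in range(1, 23)]

    def test_every_read_contains_the_anchor(self):
        assert all("CAGGGGGCCCTGACCCCACC" in r.sequence for r in table2_fixture())

    def test_first_line_prefix(self):
        assert table2_fixture()[0].sequence.startswith("CCCACTCCCAGCCCCG")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(read_len=2000),
            dict(native_end=5000, native_len=1500),
            dict(error_rate=1.5),
            dict(wildtype_fraction=-0.1),
            dict(coverage=-1),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**{**SMALL, **kwargs})


class TestDeterminism:
    def test_same_seed_same_objects(self):
        cfg = SimulationConfig(**SMALL, error_rate=0.01, seed=99)
        a, b = simulate(cfg), simulate(cfg)
        assert a.references == b.references
        assert a.reads == b.reads
        assert a.truth.equals(b.truth)

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(**SMALL, error_rate=0.01, seed=99)
        pa = write_simulation(simulate(cfg), tmp_path / "a")
        pb = write_simulation(simulate(cfg), tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_different_seeds_differ(self):
        a = simulate(SimulationConfig(**SMALL, seed=1))
        b = simulate(SimulationConfig(**SMALL, seed=2))
        assert a.native.sequence != b.native.sequence

    def test_coverage_zero_empty_outputs(self):
        res = simulate(SimulationConfig(**{**SMALL, "coverage": 0.0}))
        assert res.reads == [] and len(res.truth) == 0


class TestCalibration:
    def test_read_count_within_poisson_bounds(self):
        cfg = SimulationConfig(**{**SMALL, "coverage": 25.0}, seed=3)
        res = simulate(cfg)
        wf, vr = cfg.wildtype_fraction, cfg.variant_partner_rate
        lengths = {r.id: len(r) for r in res.references}
        expected = (
            cfg.coverage
            / cfg.read_len
            * (
                wf * lengths["SYN_NATIVE"]
                + (1 - wf) * (1 - vr) * lengths["SYN_FUSION"]
                + (1 - wf) * vr * lengths["SYN_FUSION_VARIANT"]
            )
        )
        assert abs(len(res.reads) - expected) <= 3 * np.sqrt(expected)

    def test_empirical_substitution_rate(self):
        cfg = SimulationConfig(
            native_len=2000, partner_len=1000, native_end=1000, partner_start=200,
            coverage=60.0, error_rate=0.01, seed=8,
        )
        res = simulate(cfg)
        sources = {r.id: r.sequence for r in res.references}
        truth = res.truth.set_index("read_id")
        total = mism = 0
        for read in res.reads:
            row = truth.loc[read.id]
            original = sources[row["source_id"]][row["start"] - 1 : row["start"] - 1 + len(read)]
            mism += sum(a != b for a, b in zip(read.sequence, original))
            total += len(read)
        assert total >= 100_000
        expected = total * cfg.error_rate
        assert abs(mism - expected) <= 3 * np.sqrt(expected)


class TestEndToEndTruth:
    def test_error_free_recovery_of_planted_junction(self, small_sim):
        cfg = small_sim.config
        ctx, anchor_end = junction_context(small_sim, with_partner=True)
        calls, counts = classify_set(small_sim.reads, ctx)
        # no false chimeric calls: every CHIMERIC call is a fusion read
        origins = small_sim.truth.set_index("read_id")["origin"]
        assert all(
            origins[c.read_id] == "CHIMERIC"
            for c in calls
            if c.status is Status.CHIMERIC
        )
        assert counts[Status.CHIMERIC] > 0
        j = infer_junction(calls, ctx, anchor_end)
        assert (j.native_end, j.partner_start) == (cfg.native_end, cfg.partner_start)
        assert j.microhomology_len == cfg.microhomology_len

    def test_variant_reads_fail_the_exact_seed(self):
        cfg = SimulationConfig(
            **{**SMALL, "coverage": 15.0},
            variant_partner_rate=0.5,
            error_rate=0.0,
            seed=21,
        )
        res = simulate(cfg)
        ctx, _ = junction_context(res)
        calls, _ = classify_set(res.reads, ctx)
        origins = res.truth.set_index("read_id")["origin"]
        chimeric_ids = {c.read_id for c in calls if c.status is Status.CHIMERIC}
        # variant-origin junction reads carry >=1 forced seed mismatch
        assert all(origins[rid] == "CHIMERIC" for rid in chimeric_ids)
        variant_mm = [
            c.partner_seed_mismatches
            for c in calls
            if origins[c.read_id] == "VARIANT" and c.partner_seed_mismatches is not None
        ]
        assert variant_mm and all(mm >= 1 for mm in variant_mm)


class TestSensitivityProperty:
    def test_literal_rescan_finds_all_probe_covering_reads_error_free(self, small_sim):
        cfg = small_sim.config
        ctx, anchor_end = junction_context(small_sim, with_partner=True)
        calls, _ = classify_set(small_sim.reads, ctx)
        j = infer_junction(calls, ctx, anchor_end)
        probe = make_junction_probe(j, small_sim.native, small_sim.partner, flank=10)
        truth = small_sim.truth
        covering = truth[
            (truth.origin != "WILDTYPE")
            & (truth.start <= cfg.native_end - 9)
            & (truth.start + cfg.read_len - 1 >= cfg.native_end + 10)
        ]
        assert rescan_junction(small_sim.reads, probe) == len(covering)

    def test_tolerant_mode_recovers_reads_lost_to_errors(self):
        """With sequencing errors, exact matching loses junction reads
        that one-mismatch search recovers — the fragility that makes
        literal search miss real support."""
        cfg = SimulationConfig(**SMALL, error_rate=0.02, seed=31)
        res = simulate(cfg)
        ctx, anchor_end = junction_context(res)
        probe_seq = (
            res.native.sequence[cfg.native_end - 10 : cfg.native_end]
            + res.partner.sequence[cfg.partner_start - 1 : cfg.partner_start + 9]
        )
        probe = AnchorProbe.from_sequence(probe_seq)
        _, literal = scan_reads(res.reads, probe, mode=ScanMode.GREP_LITERAL)
        _, tolerant = scan_reads(
            res.reads, probe, 1, (Orientation.FWD,), ScanMode.FULL
        )
        assert tolerant >= literal
        assert tolerant > 0
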