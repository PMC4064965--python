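import numpy as np
import pytest

from anchorfuse import refdata
from anchorfuse.seqcore import TranscriptRecord
from anchorfuse.synth import SimulationConfig, simulate, table2_fixture

#: partner segment observed in the longest published chimeric read;
#: embedded in a synthetic backbone to emulate a partner reference
PARTNER_SEGMENT = (
    "CGGCAGAGGGGGTCTCCCAACCTGCCCCGGCGCGCGGGGATTTCGCCTACGCCGCCCCGGCTCCTCCC"
)


@pytest.fixture(scope="session")
def t2_reads():
    return table2_fixture()


@pytest.fixture(scope="session")
def cic_ctx():
    """(JunctionContext, anchor end coordinate) for the CIC-DUX4 junction."""
    return refdata.cic_dux4_context()


@pytest.fixture(scope="session")
def synthetic_partner():
    """Synthetic stand-in for a partner mRNA: random backbone with the
    observed partner segment planted so its seed starts at nt 771."""
    rng = np.random.default_rng(20140620)
    seq = "".join(rng.choice(list("ACGT"), size=1200))
    seq = seq[:770] + PARTNER_SEGMENT + seq[770 + len(PARTNER_SEGMENT) :]
    return TranscriptRecord("SYN_PARTNER_771", seq, "PARTNERSYN")


@pytest.fixture(scope="session")
def small_sim():
    """Error-free simulation with a planted 800|300 junction, mh 1."""
    cfg = SimulationConfig(
        native_len=1500,
        partner_len=900,
        native_end=800,
        partner_start=300,
        coverage=10.0,
        error_rate=0.0,
        variant_partner_rate=0.0,
        seed=7,
    )
    return simulate(cfg)
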