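import pytest

from tcwch2 import TCWCH2_CONSENSUS, ProteinRecord, SpacingConfig


@pytest.fixture
def consensus_record() -> ProteinRecord:
    """The 64-aa tandem-motif consensus used as the worked example."""
    return ProteinRecord(id="consensus", sequence=TCWCH2_CONSENSUS)


@pytest.fixture
def strict_cfg() -> SpacingConfig:
    return SpacingConfig.strict()


@pytest.fixture
def loose_cfg() -> SpacingConfig:
    return SpacingConfig.loose()
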