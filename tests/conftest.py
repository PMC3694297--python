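import pytest

from barrierkit import InsertGeometry, TransferSchedule


@pytest.fixture
def geom() -> InsertGeometry:
    return InsertGeometry()  # 1.13 cm², 0.5 ml donor, 1.5 ml receiver


@pytest.fixture
def schedule() -> TransferSchedule:
    return TransferSchedule()  # 5 / 15 / 30 min
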