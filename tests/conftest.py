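import pytest

from latticebind import LatticeModel, MassContext


@pytest.fixture
def model_20bp() -> LatticeModel:
    """Fitted model for the 20-bp duplex: Kd = 0.92 mM, site size 3 bp."""
    return LatticeModel(Ka=1.0 / 0.92e-3, n=3, N=20)


@pytest.fixture
def ctx_20bp() -> MassContext:
    """Mass context for a 20-bp duplex immobilized at 450 RU."""
    return MassContext(M_protein=7900.0, M_DNA=13400.0, N=20, R_L=450.0)


@pytest.fixture
def ctx_30bp() -> MassContext:
    """Mass context for the 30-bp screening duplexes."""
    return MassContext(M_protein=7900.0, M_DNA=19500.0, N=30, R_L=450.0)
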