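import numpy as np
import pytest
from hypothesis import settings

from sfekin import BedSpec, EquilibriumParams, ModelParams, flow_derived

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def nanno_eq() -> EquilibriumParams:
    """Equilibrium parameters of the ground Nannochloropsis oil at 30 MPa, 40 C."""
    return EquilibriumParams(ys=0.0093, xt=0.11, K=0.049)


@pytest.fixture
def nanno_bed() -> BedSpec:
    """1.25 g of alga mixed with glass beads in a 5 cm3 extractor, 0.35 g/min CO2."""
    return BedSpec(
        N=1.25e-3, Qp=0.35e-3, rho_f=910.0, eps=0.40, V=5e-6, with_beads=True
    )


@pytest.fixture
def nanno_params(nanno_eq, nanno_bed) -> ModelParams:
    fd = flow_derived(nanno_bed)
    return ModelParams(eq=nanno_eq, xu=0.345, tc=0.45, tr=fd.tr, gamma=fd.gamma)


@pytest.fixture
def worked_params(nanno_eq) -> ModelParams:
    """The hand-checkable parameter set used in worked derivations
    (gamma = 1.456, tr = 2.35 min, tc = 0.30 min)."""
    return ModelParams(eq=nanno_eq, xu=0.345, tc=0.30, tr=2.35, gamma=1.456)
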