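import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from adhesim import _kernel as K  # noqa: E402
from adhesim.lattice import MembraneState  # noqa: E402
from adhesim.params import ModelParameters  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """8x8 lattice with a handful of every species."""
    return ModelParameters(
        lattice_nx=8,
        lattice_ny=8,
        u_self=5.9,
        u_foreign=12.0,
        n_tcr=4,
        n_lfa=4,
        n_self_pmhc=3,
        n_foreign_pmhc=1,
        n_icam=4,
        n_steps=1000,
        equilibration_steps=0,
        sampling_interval=10,
        dwell_start_step=0,
        rng_seed=7,
    )


def random_state(params: ModelParameters, rng, l_range=(10.0, 45.0)) -> MembraneState:
    """Random occupancies matching ``params`` counts, rough separation field."""
    nx, ny = params.lattice_nx, params.lattice_ny
    l = rng.uniform(*l_range, size=(nx, ny))
    occ1 = np.zeros((nx, ny), dtype=np.int8)
    occ2 = np.zeros((nx, ny), dtype=np.int8)
    sites1 = rng.permutation(nx * ny)[: params.n_proteins_membrane1]
    sites2 = rng.permutation(nx * ny)[: params.n_proteins_membrane2]
    codes1 = [K.M1_TCR] * params.n_tcr + [K.M1_LFA] * params.n_lfa
    codes2 = (
        [K.M2_SMHC] * params.n_self_pmhc
        + [K.M2_FMHC] * params.n_foreign_pmhc
        + [K.M2_ICAM] * params.n_icam
    )
    for flat, code in zip(sites1, codes1):
        occ1.flat[flat] = code
    for flat, code in zip(sites2, codes2):
        occ2.flat[flat] = code
    return MembraneState(l, occ1, occ2)
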