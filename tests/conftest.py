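import numpy as np
import pytest

from synctoj import design as dsn


@pytest.fixture(scope="session")
def small_session():
    """One full run sequence + design matrix, shared across tests."""
    rng = np.random.default_rng(1234)
    comps = {t: dsn.assign_block_composition(rng) for t in dsn.TASKS}
    seq = dsn.build_run_sequence(comps, rng)
    X = dsn.build_design_matrix(seq, tr_s=2.0)
    return seq, X


@pytest.fixture(scope="session")
def optimized_1000():
    """The full 1000-candidate design optimization (shared: it is the
    expensive object both the selection checks and the trade-off property
    need)."""
    return dsn.optimize_design(n_candidates=1000, master_seed=20260922, tr_s=2.0)
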