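import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture
def toy_panel(rng):
    """Small analyte panel with a planted consistent and an inconsistent
    candidate under a negative prespecified direction.

    The exposure lowers both analytes; A_cons's decrease tracks the outcome's
    decrease (consistent with direction -1), A_incons's decrease tracks an
    outcome *increase* (inconsistent).  Remaining analytes are noise.
    """
    n = 30
    e = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    noise = rng.standard_normal((6, n)) * 0.4
    a_cons = -1.5 * e + noise[0]
    a_incons = -1.5 * e + noise[1]
    y = -2.0 * e + 1.2 * a_cons - 1.2 * a_incons + 0.3 * rng.standard_normal(n)
    M = pd.DataFrame(
        np.vstack([a_cons, a_incons, noise[2:]]),
        index=["A_cons", "A_incons", "N1", "N2", "N3", "N4"],
        columns=[f"S{i}" for i in range(n)],
    )
    pheno = pd.DataFrame({"exposure": e, "outcome": y},
                         index=M.columns)
    return M, pheno
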