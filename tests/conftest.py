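import numpy as np
import pytest

import clusterdisp as cd


@pytest.fixture(scope="session")
def low_dispersal_n1_ensemble():
    """Neutral two-species ensemble deep in the low-dispersal regime with
    single-individual clusters: every community fixes the first arrival."""
    params = cd.two_species(0.5, c=1e-4, n=1, K=300)
    return cd.assemble_ensemble(params, 400, root_seed=7)


@pytest.fixture(scope="session")
def multispecies_low_dispersal_ensemble():
    """Seven neutral species, single-individual clusters, low dispersal."""
    params = cd.validate(
        cd.ModelParams(S=7, p=(1 / 7,) * 7, r=(1.0,) * 7, c=1e-4, n=1, K=300)
    )
    return cd.assemble_ensemble(params, 300, root_seed=11)


def exact_mean_dispersal_events(c: float, r: float, K: int, n: int) -> tuple[float, float]:
    """Independent oracle: exact mean and variance of the number of
    dispersal events before N reaches K, by backward recursion over the
    embedded jump chain of the neutral model (composition is irrelevant to
    the total-size dynamics when all replication rates are equal)."""
    f = [0.0] * (K + 1)
    g = [0.0] * (K + 1)  # second moment
    for N in range(K - 1, -1, -1):
        q = c / (r * N + c)
        Nd = min(N + n, K)
        f[N] = q * (1 + f[Nd]) + (1 - q) * f[N + 1]
        g[N] = q * (1 + 2 * f[Nd] + g[Nd]) + (1 - q) * g[N + 1]
    return f[0], g[0] - f[0] ** 2
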