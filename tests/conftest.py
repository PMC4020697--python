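import numpy as np
import pytest

from smoltherit import SimulationConfig, apply_marker_qc, build_grms, simulate_cohort
from smoltherit.greml import MixedModelSpec


@pytest.fixture(scope="session")
def small_sim():
    """A small two-population cohort under the default additive architecture."""
    cfg = SimulationConfig(n1=80, n2=40, m=400, h2_a_target=0.6, h2_d_target=0.2,
                           seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit_inputs(small_sim):
    """QC'd genotypes, aligned cohort, GRM pair and a liability-scale model spec."""
    g, cohort, truth = small_sim
    g_qc, _ = apply_marker_qc(g)
    cohort = cohort.aligned_to(g_qc)
    pair = build_grms(g_qc)
    spec = MixedModelSpec.from_cohort(pair, cohort, y=truth.liability)
    return g_qc, cohort, pair, spec, truth


def random_toy_spec(rng, n=None, include_dominance=True):
    """A dense random mixed-model instance with PSD relationship matrices."""
    if n is None:
        n = int(rng.integers(6, 11))
    W = rng.standard_normal((n, 15))
    A = W @ W.T / 15
    W2 = rng.standard_normal((n, 15))
    D = W2 @ W2.T / 15
    group = rng.permutation(np.arange(n) % 2).astype(float)  # both levels present
    X = np.column_stack([np.ones(n), group])
    theta = rng.uniform(0.1, 1.0, 3)
    V = theta[0] * A + theta[1] * D + theta[2] * np.eye(n)
    y = X @ rng.standard_normal(2) + np.linalg.cholesky(V + 1e-9 * np.eye(n)) @ rng.standard_normal(n)
    return MixedModelSpec(y=y, X=X, A=A, D=D, include_dominance=include_dominance)
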