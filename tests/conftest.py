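import numpy as np
import pytest

from hdscan.synthetic_data import (
    MethModel,
    RohPlanEntry,
    SimulationConfig,
    simulate_genotypes,
    simulate_methylation,
    simulate_phenotypes,
)


def small_config(seed: int = 7, **kw) -> SimulationConfig:
    defaults = dict(
        n_families=20,
        snps_per_chromosome=300,
        n_chromosomes=2,
        chromosome_length_bp=60_000_000,
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic cohort shared across read-only tests."""
    cfg = small_config()
    gm, truth = simulate_genotypes(cfg)
    pt = simulate_phenotypes(gm, truth, cfg)
    ms = simulate_methylation(gm, truth, cfg)
    return cfg, gm, truth, pt, ms


@pytest.fixture(scope="session")
def default_scale_dataset():
    """Default-scale cohort (60 families, 2 x 2000 SNPs) for recovery tests."""
    cfg = SimulationConfig(seed=11)
    gm, truth = simulate_genotypes(cfg)
    pt = simulate_phenotypes(gm, truth, cfg)
    return cfg, gm, truth, pt


def wls_oracle(u: np.ndarray, x: np.ndarray, w: np.ndarray, degree: int) -> float:
    """Independent weighted least squares fit evaluated at u = 0.

    Brute force via lstsq on the sqrt(weight)-scaled design, no shared code
    with the estimator under test.
    """
    keep = (w > 0) & np.isfinite(x)
    u, x, w = u[keep], x[keep], w[keep]
    X = np.column_stack([u ** d for d in range(degree + 1)])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], x * sw, rcond=None)
    return float(beta[0])
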