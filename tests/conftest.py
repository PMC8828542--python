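import numpy as np
import pandas as pd
import pytest

from rootpheno.sim import (
    RootParams,
    VarianceComponents,
    generate_design,
    simulate_phenotypes,
    simulate_root_system,
)


def recovery_params(seed: int) -> RootParams:
    """Root-growth configuration with cleanly separable laterals.

    A straight-ish primary and moderately steep laterals that neither hug
    nor re-cross the primary axis — the regime in which pixel-level branch
    counting is well posed.
    """
    return RootParams(
        primary_rate=2.8,
        lateral_rate_per_cm=0.12,
        lateral_angle_mean_deg=50.0,
        lateral_angle_sd_deg=8.0,
        lateral_rate=0.6,
        tortuosity_sd_deg=1.0,
        gravitropism=0.02,
        diameter_base_cm=0.12,
        diameter_tip_cm=0.06,
        seed=seed,
    )


def straight_params(seed: int = 0, **overrides) -> RootParams:
    """Noise-free vertical primary with no laterals unless overridden."""
    base = dict(
        primary_rate=2.0,
        lateral_rate_per_cm=0.0,
        lateral_angle_mean_deg=45.0,
        lateral_angle_sd_deg=0.0,
        lateral_rate=0.5,
        tortuosity_sd_deg=0.0,
        gravitropism=0.0,
        diameter_base_cm=0.08,
        diameter_tip_cm=0.08,
        seed=seed,
    )
    base.update(overrides)
    return RootParams(**base)


@pytest.fixture
def recovery_system():
    """One well-separated simulated system with its day-15 snapshot."""
    truth = simulate_root_system(
        recovery_params(3), days=(12, 15), min_lateral_spacing_cm=0.5
    )
    return truth


@pytest.fixture
def small_design():
    """96 genotypes x 8 chamber replicates (1 block of 8 complete sub-blocks)."""
    spec = (tuple([12] * 8),)
    return generate_design(96, n_chambers=8, seed=0, block_spec=spec)


@pytest.fixture
def balanced_table(small_design):
    vc = VarianceComponents(sigma2_g=1.0, sigma2_block=0.0, sigma2_subblock=0.0, sigma2_e=1.0)
    table, truth = simulate_phenotypes(small_design, vc, traits=("TRL",), mu=10.0, seed=1)
    return table, truth


@pytest.fixture
def tiny_mixed_table():
    """Printed 3-genotype x 2-chamber fixture for likelihood oracles."""
    return pd.DataFrame(
        {
            "genotype": ["A", "A", "B", "B", "C", "C"],
            "chamber": [1, 2, 1, 2, 1, 2],
            "y": [5.1, 4.7, 6.2, 6.8, 3.9, 4.1],
        }
    )


def reml_grid_oracle(y, X, Z_blocks, gammas_grid):
    """Brute-force profiled REML criterion on a dense variance-ratio grid.

    Evaluates -2 l_R by direct construction of H = I + sum(gamma Z Z') —
    an independent path from the fitter's Woodbury/Cholesky algebra.
    Returns (best_criterion, best_gammas).
    """
    import itertools
    import math

    n, p = X.shape
    best = (np.inf, None)
    for gams in itertools.product(*gammas_grid):
        H = np.eye(n)
        for gam, Z in zip(gams, Z_blocks):
            H += gam * Z @ Z.T
        Hi = np.linalg.inv(H)
        XHiX = X.T @ Hi @ X
        P = Hi - Hi @ X @ np.linalg.inv(XHiX) @ X.T @ Hi
        qy = float(y @ P @ y)
        if qy <= 0:
            continue
        s2 = qy / (n - p)
        crit = (
            (n - p) * (math.log(s2) + 1.0 + math.log(2.0 * math.pi))
            + np.linalg.slogdet(H)[1]
            + np.linalg.slogdet(XHiX)[1]
        )
        if crit < best[0]:
            best = (crit, gams)
    return best
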