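"""Shared fixtures: correctly specified simulations of the smoothing model."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import solve_triangular

from hrbayes import (
    ARNoiseModel,
    build_ar_whitening_matrix,
    build_second_difference_matrix,
)

# AR(2) with complex roots of modulus sqrt(0.3) ~ 0.55 (clearly stationary)
AR2_COEFFS = np.array([-1.0, 0.3])


def simulate_irw_plus_ar(
    seed: int,
    n: int = 200,
    lambda2: float = 0.01,
    sigma2: float = 1.0,
    coefficients=(-0.5,),
):
    """Exact draw from the smoother's generative model.

    u = F^{-1} v with v ~ N(0, lambda2 I) (an integrated random walk) and
    w = A^{-1} eps with eps ~ N(0, sigma2 I); returns (u, y=u+w, model).
    The triangular solves are the literal definition of the priors, kept
    independent of the estimator code path.
    """
    rng = np.random.default_rng(seed)
    model = ARNoiseModel(coefficients=np.asarray(coefficients, dtype=float))
    F = build_second_difference_matrix(n)
    A = build_ar_whitening_matrix(model, n)
    u = solve_triangular(F, np.sqrt(lambda2) * rng.standard_normal(n), lower=True)
    w = solve_triangular(A, np.sqrt(sigma2) * rng.standard_normal(n), lower=True)
    return u, u + w, model


def simulate_ar(seed: int, n: int, coefficients, sigma: float = 1.0) -> np.ndarray:
    """Monic AR recursion w(k) = -sum a_i w(k-i) + sigma z(k), from rest,
    with a 500-sample burn-in."""
    rng = np.random.default_rng(seed)
    a = np.asarray(coefficients, dtype=float)
    p = a.size
    total = n + 500
    w = np.zeros(total)
    z = sigma * rng.standard_normal(total)
    for k in range(total):
        acc = z[k]
        for i in range(1, min(p, k) + 1):
            acc -= a[i - 1] * w[k - i]
        w[k] = acc
    return w[500:]


@pytest.fixture(scope="session")
def ar2_model() -> ARNoiseModel:
    return ARNoiseModel(coefficients=AR2_COEFFS.copy())


@pytest.fixture(scope="session")
def recovery_fits():
    """50 seeded fits of the correctly specified model (n=200), shared by
    the parameter-recovery and CI-coverage checks."""
    from hrbayes import estimate_gamma

    lambda2, sigma2 = 0.01, 1.0
    out = []
    for seed in range(50):
        u, y, model = simulate_irw_plus_ar(seed, 200, lambda2, sigma2)
        fit = estimate_gamma(y, model)
        out.append((u, fit))
    return {"fits": out, "lambda2": lambda2, "sigma2": sigma2}
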