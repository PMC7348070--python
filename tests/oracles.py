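"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's log-space code paths: densities are
multiplied term by term with an explicitly computed lattice normalization
constant N, so cancellation of N in posterior ratios is demonstrated rather
than assumed.
"""

import math

import numpy as np

from hypothegon import STRATEGIES, generate_lattice


def lattice_kernel_normalization(d: float, resolution: int = 48) -> float:
    """Kernel mass on a triangular lattice (one constant for every strategy).

    The classifier's model treats N as a property of the kernel shape alone,
    shared across strategies; this evaluates it at the simplex centroid.
    """
    lattice = generate_lattice(resolution)
    center = np.full(3, 1.0 / 3.0)
    sq = np.sum((lattice.points - center) ** 2, axis=1)
    return float(np.sum(np.exp(-sq / d)))


def brute_force_posterior(subject, predictions, d: float, resolution: int = 48):
    """Posterior over strategies by direct six-term density products.

    Returns (posterior dict, product dict).  Equal strategy priors.
    """
    N = lattice_kernel_normalization(d, resolution)
    products = {}
    for strategy in STRATEGIES:
        prod = 1.0
        for case_id, judgment in subject.judgments:
            diff = np.asarray(judgment) - predictions[case_id][strategy]
            prod *= math.exp(-float(diff @ diff) / d) / N
        products[strategy] = prod * (1.0 / 3.0)
    total = sum(products.values())
    return {s: products[s] / total for s in STRATEGIES}, products


def dirichlet_mc_log_bf10(counts, a: float, n_draws: int, seed: int):
    """Monte-Carlo marginal-likelihood estimate of the contingency log-BF10.

    Importance-samples both models' marginals with Dirichlet prior draws.
    Returns (log_bf10, standard_error).
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(counts, dtype=float)
    r, c = y.shape

    def log_mean_exp(ll):
        m = ll.max()
        w = np.exp(ll - m)
        mean = w.mean()
        se_log = w.std(ddof=1) / (math.sqrt(len(w)) * mean)
        return m + math.log(mean), se_log

    theta = rng.dirichlet(np.full(r * c, a), size=n_draws)
    ll1 = (np.log(theta) * y.ravel()).sum(axis=1)
    log_m1, se1 = log_mean_exp(ll1)

    phi = rng.dirichlet(np.full(r, a), size=n_draws)
    psi = rng.dirichlet(np.full(c, a), size=n_draws)
    ll0 = (np.log(phi) * y.sum(axis=1)).sum(axis=1) + (
        np.log(psi) * y.sum(axis=0)
    ).sum(axis=1)
    log_m0, se0 = log_mean_exp(ll0)

    return log_m1 - log_m0, math.sqrt(se1**2 + se0**2)
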