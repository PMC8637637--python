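"""Independent oracles used by the tests.

These deliberately avoid the package's own bivariate-normal and optimizer
code paths: rectangle probabilities come from scipy's Genz multivariate
normal CDF and the polychoric maximizer is found by grid search.
"""

import numpy as np
from scipy import stats


def mvn_rectangle_probs(tau_x, tau_y, rho):
    """Cell probabilities via scipy.stats.multivariate_normal.cdf."""
    mvn = stats.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]])

    def cdf(h, k):
        if h == -np.inf or k == -np.inf:
            return 0.0
        if h == np.inf and k == np.inf:
            return 1.0
        if h == np.inf:
            return stats.norm.cdf(k)
        if k == np.inf:
            return stats.norm.cdf(h)
        return float(mvn.cdf([h, k]))

    bx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    by = np.concatenate(([-np.inf], tau_y, [np.inf]))
    grid = np.array([[cdf(h, k) for k in by] for h in bx])
    probs = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    return np.clip(probs, 0.0, 1.0)


def _table_loglik(table, tau_x, tau_y, rho):
    probs = mvn_rectangle_probs(tau_x, tau_y, rho)
    return float(np.sum(table * np.log(np.maximum(probs, 1e-12))))


def grid_polychoric(table):
    """Grid-search polychoric MLE with margin-fixed thresholds.

    Two-stage grid (step 0.01 over [-0.99, 0.99], then step 0.001 around the
    coarse maximizer); the profile likelihood in rho is unimodal so the
    refinement reaches the global 0.001-grid maximizer.  Applies the same
    0.5 zero-cell correction as the estimator under test.
    """
    table = np.asarray(table, dtype=float)
    if (table == 0).any():
        table = table + 0.5
    tau_x = stats.norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / table.sum())
    tau_y = stats.norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / table.sum())
    coarse = np.arange(-0.99, 0.991, 0.01)
    ll = [_table_loglik(table, tau_x, tau_y, r) for r in coarse]
    best = coarse[int(np.argmax(ll))]
    fine = np.arange(best - 0.01, best + 0.0101, 0.001)
    fine = fine[(fine >= -0.999) & (fine <= 0.999)]
    ll = [_table_loglik(table, tau_x, tau_y, r) for r in fine]
    return float(fine[int(np.argmax(ll))])


def sample_table(rho, thresholds_x, thresholds_y, n, rng):
    """Draw an ordinal contingency table from a discretized bivariate normal."""
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.searchsorted(np.asarray(thresholds_x), z[:, 0])
    y = np.searchsorted(np.asarray(thresholds_y), z[:, 1])
    kx, ky = len(thresholds_x) + 1, len(thresholds_y) + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (x, y), 1.0)
    return table
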