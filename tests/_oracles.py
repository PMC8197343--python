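"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the probit oracle is a
brute-force grid refinement of the binomial log-likelihood, the additivity
oracle is plain Monte-Carlo propagation, and the rank-test oracle builds the
two-sample normal-approximation statistic from raw ranks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def grid_ml_oracle(dataset, n_rounds: int = 10, grid: int = 41):
    """Maximise the binomial probit log-likelihood over (log10 ED50, slope)
    by iterative dense-grid refinement.

    Returns (max_loglik, log10_ed50, slope); final grid spacing is below
    1e-7 on both axes, so the returned optimum is accurate to well under
    1e-6 in log-likelihood.
    """
    x = np.log10(np.asarray(dataset.doses, dtype=float))
    n = np.array([g.n_subjects for g in dataset.groups], dtype=float)
    k = np.array([g.n_responders for g in dataset.groups], dtype=float)

    def loglik(m, s):
        # m, s broadcastable grids; z shape (..., n_doses)
        z = s[..., None] * (x - m[..., None])
        return (k * stats.norm.logcdf(z)
                + (n - k) * stats.norm.logcdf(-z)).sum(axis=-1)

    m_lo, m_hi = x.min() - 1.0, x.max() + 1.0
    s_lo, s_hi = 0.05, 60.0
    best = (-np.inf, np.nan, np.nan)
    for _ in range(n_rounds):
        ms = np.linspace(m_lo, m_hi, grid)
        ss = np.linspace(s_lo, s_hi, grid)
        M, S = np.meshgrid(ms, ss, indexing="ij")
        ll = loglik(M, S)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(ll[i, j]), float(ms[i]), float(ss[j]))
        dm, ds = (m_hi - m_lo) / (grid - 1), (s_hi - s_lo) / (grid - 1)
        m_lo, m_hi = ms[i] - 2 * dm, ms[i] + 2 * dm
        s_lo, s_hi = max(ss[j] - 2 * ds, 1e-6), ss[j] + 2 * ds
    return best


def mc_additive_oracle(ed50s, sems, fractions, n_draws: int = 10**6,
                       seed: int = 0):
    """Monte-Carlo propagation of a fixed-ratio additive ED50.

    Draws independent normal component ED50s and returns (mean, sd,
    se_mean, se_sd) of the weighted sum sum_i f_i X_i.
    """
    rng = np.random.default_rng(seed)
    draws = sum(f * rng.normal(e, s, n_draws)
                for f, e, s in zip(fractions, ed50s, sems))
    sd = draws.std(ddof=1)
    return (draws.mean(), sd, sd / np.sqrt(n_draws),
            sd / np.sqrt(2 * (n_draws - 1)))


def ranksum_h_oracle(a, b):
    """Squared two-sample rank-sum normal-approximation statistic.

    For two tie-free groups this equals the Kruskal-Wallis H.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    N = n1 + n2
    W = ranks[:n1].sum()
    z = (W - n1 * (N + 1) / 2) / np.sqrt(n1 * n2 * (N + 1) / 12.0)
    return float(z**2)
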