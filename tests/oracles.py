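"""Independent brute-force oracles shared across the test suite.

These re-derive expected values by exhaustive enumeration or plain-loop
evaluation and are kept deliberately separate from the implementations they
check.
"""

import itertools

import numpy as np
from scipy import stats as sps


def huang_cost_reference(hist, levels):
    """Plain-loop Huang-Wang fuzziness over every candidate split level."""
    C = levels[-1] - levels[0]
    costs = np.full(len(levels), np.inf)
    for t in range(len(levels)):
        w0, w1 = hist[:t + 1].sum(), hist[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t + 1] * levels[:t + 1]).sum() / w0
        mu1 = (hist[t + 1:] * levels[t + 1:]).sum() / w1
        total = 0.0
        for g, h in zip(levels, hist):
            if h == 0:
                continue
            mu = mu0 if g <= levels[t] else mu1
            u = min(max(1.0 / (1.0 + abs(g - mu) / C), 1e-12), 1 - 1e-12)
            total += h * (-u * np.log(u) - (1 - u) * np.log(1 - u))
        costs[t] = total
    return costs


def mann_whitney_exact_p(x, y):
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)

    def u_stat(ix):
        return ranks[list(ix)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_stat(range(n1))
    mean_u = n1 * len(y) / 2
    count = total = 0
    for ix in itertools.combinations(range(len(pooled)), n1):
        if abs(u_stat(ix) - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
        total += 1
    return count / total


def wilcoxon_exact_p(d):
    """Two-sided signed-rank p by enumerating every sign flip."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean_w = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / 2**n
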