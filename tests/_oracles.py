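"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's scipy-vectorized code path: the
conditional split distribution is rebuilt in plain Python from lgamma, so an
agreement check between `nb_exact_test` and `exact_test_oracle` exercises
two separate derivations of the same law.
"""

import math


def nb_log_pmf(x: int, mean: float, dispersion: float) -> float:
    if dispersion == 0:
        return x * math.log(mean) - mean - math.lgamma(x + 1)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return math.lgamma(x + r) - math.lgamma(r) - math.lgamma(x + 1) + r * math.log(p) + x * math.log1p(-p)


def exact_test_oracle(group_a, group_b, dispersion: float) -> float:
    """Minimum-likelihood two-sided conditional p by direct enumeration."""
    n_a, n_b = len(group_a), len(group_b)
    s_a = int(sum(group_a))
    total = s_a + int(sum(group_b))
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    log_probs = []
    for x in range(total + 1):
        la = nb_log_pmf(x, n_a * mu, dispersion / n_a if dispersion else 0.0)
        lb = nb_log_pmf(total - x, n_b * mu, dispersion / n_b if dispersion else 0.0)
        log_probs.append(la + lb)
    top = max(log_probs)
    probs = [math.exp(v - top) for v in log_probs]
    norm = sum(probs)
    probs = [v / norm for v in probs]
    p_obs = probs[s_a]
    return min(1.0, sum(v for v in probs if v <= p_obs * (1 + 1e-12)))
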