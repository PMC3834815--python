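"""Independent brute-force oracles used across the test suite."""

import numpy as np


def direct_convolution(irf: np.ndarray, decay: np.ndarray) -> np.ndarray:
    """O(N^2) causal discrete convolution, truncated to the input length."""
    n = len(decay)
    out = np.zeros(n)
    for k in range(n):
        out[k] = np.dot(irf[: k + 1], decay[k::-1])
    return out


def multiexp(times: np.ndarray, lifetimes, amplitudes) -> np.ndarray:
    t = times - times[0]
    out = np.zeros_like(t)
    for tau, a in zip(lifetimes, amplitudes):
        out += a * np.exp(-t / tau)
    return out


def runs_test_pvalue(signs: np.ndarray) -> float:
    """Closed-form normal-approximation runs test, written independently."""
    from scipy.stats import norm

    n1 = int(np.sum(signs))
    n2 = len(signs) - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2 * n1 * n2 / n + 1
    var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1))
    z = (runs - mu) / np.sqrt(var)
    return float(2 * norm.sf(abs(z)))
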