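"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def brute_force_tau_b(x, y):
    """Tie-adjusted Kendall correlation by explicit pair enumeration."""
    n = len(x)
    concordant = discordant = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx * dy > 0:
            concordant += 1
        elif dx * dy < 0:
            discordant += 1
    n0 = n * (n - 1) / 2
    tx = sum(1 for i, j in itertools.combinations(range(n), 2) if x[i] == x[j])
    ty = sum(1 for i, j in itertools.combinations(range(n), 2) if y[i] == y[j])
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom
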