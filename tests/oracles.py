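"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the statistics by direct enumeration /
textbook formulas, sharing no code with the package implementation.
"""

from __future__ import annotations

import math

from scipy import stats


def welch_oracle(x, y):
    """Textbook Welch t: statistic, Welch-Satterthwaite dof, two-sided p."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    s = (mx - my) / math.sqrt(se2)
    dof = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(s), dof)
    return s, dof, p


def es_oracle(genes, metrics, member_genes, weight_exponent):
    """Enumerate every running-sum value and return (es, runs).

    Hits add |metric|^w / NR, misses subtract 1/(N-k); ES is the value of
    maximal absolute deviation from zero, positive winning exact ties.
    """
    members = set(member_genes)
    n = len(genes)
    k = sum(1 for g in genes if g in members)
    assert 0 < k < n
    nr = sum(abs(m) ** weight_exponent for g, m in zip(genes, metrics) if g in members)
    runs = []
    total = 0.0
    for g, m in zip(genes, metrics):
        if g in members:
            total += (abs(m) ** weight_exponent) / nr if nr > 0 else 1.0 / k
        else:
            total -= 1.0 / (n - k)
        runs.append(total)
    vmax = max(max(runs), 0.0)
    vmin = min(min(runs), 0.0)
    es = vmax if vmax >= -vmin else vmin
    return es, runs
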