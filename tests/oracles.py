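"""Independent brute-force oracles used by the test suite.

Deliberately naive (explicit Python loops, no shared code with the package)
so they can arbitrate the vectorized implementations.
"""

from __future__ import annotations

import math


def anova_mean_squares_loops(data) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares by explicit double loops."""
    n = len(data)
    k = len(data[0])
    total = 0.0
    for i in range(n):
        for j in range(k):
            total += data[i][j]
    gm = total / (n * k)
    row_means = [sum(data[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ssr = sum((rm - gm) ** 2 for rm in row_means) * k
    ssc = sum((cm - gm) ** 2 for cm in col_means) * n
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (data[i][j] - row_means[i] - col_means[j] + gm) ** 2
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def icc_a1_loops(a, b) -> float:
    """ICC(A,1) from the loop-based mean squares."""
    data = [[x, y] for x, y in zip(a, b)]
    n, k = len(data), 2
    msr, msc, mse = anova_mean_squares_loops(data)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def paired_t_loops(a, b) -> tuple[float, float, float]:
    """(mean difference, standard error, t statistic) by hand."""
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    se = math.sqrt(var / n)
    return mean, se, mean / se if se > 0 else float("inf")
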