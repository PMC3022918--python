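"""Independent brute-force oracles used to check the package implementations.

These deliberately avoid the package's code paths: plain-Python loops and
``statistics.median`` for median polish, exhaustive pair enumeration for
the concordance index.
"""

from __future__ import annotations

import math
from statistics import median


def median_polish_oracle(matrix, tol=1e-9, max_iter=1000):
    """Row-first median polish by explicit loops; returns the residual matrix.

    ``matrix`` is a list of lists with ``None``/NaN for missing cells.
    """
    nr = len(matrix)
    nc = len(matrix[0])

    def is_obs(v):
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    z = [[float(v) if is_obs(v) else None for v in row] for row in matrix]

    def sar():
        return sum(abs(v) for row in z for v in row if v is not None)

    prev = sar()
    for _ in range(max_iter):
        for i in range(nr):
            obs = [v for v in z[i] if v is not None]
            m = median(obs)
            for j in range(nc):
                if z[i][j] is not None:
                    z[i][j] -= m
        for j in range(nc):
            obs = [z[i][j] for i in range(nr) if z[i][j] is not None]
            m = median(obs)
            for i in range(nr):
                if z[i][j] is not None:
                    z[i][j] -= m
        cur = sar()
        if cur == 0.0 or prev == 0.0 or (prev - cur) / prev < tol:
            break
        prev = cur
    return z


def auc_oracle(scores, labels):
    """Concordance index by exhaustive pair enumeration, ties credited 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
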