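"""Brute-force Krippendorff's alpha by direct pair enumeration.

Deliberately independent of anatoscore.agreement: no coincidence matrix
is formed. Observed disagreement averages the pairwise differences
within each unit (each pair weighted by 1/(m_u - 1)); expected
disagreement enumerates every ordered pair of pooled pairable values.
Used as the oracle the fast implementation must match exactly.
"""

from __future__ import annotations


def _ordinal_delta(pooled: list) -> dict[tuple, float]:
    """delta^2 for each value pair from cumulative pooled frequencies."""
    order = sorted(set(pooled))
    freq = {v: pooled.count(v) for v in order}
    table: dict[tuple, float] = {}
    for i, v in enumerate(order):
        for j, w in enumerate(order):
            if i == j:
                table[(v, w)] = 0.0
                continue
            lo, hi = min(i, j), max(i, j)
            between = sum(freq[order[g]] for g in range(lo, hi + 1))
            table[(v, w)] = (between - (freq[v] + freq[w]) / 2.0) ** 2
    return table


def alpha_bruteforce(units: list[list], level: str = "nominal") -> float:
    """Alpha over units (lists of observed values; singletons dropped).

    Raises ZeroDivisionError when expected disagreement is zero (alpha
    undefined), mirroring the degenerate case of the real implementation.
    """
    pairable = [vs for vs in units if len(vs) >= 2]
    if not pairable:
        raise ValueError("no pairable unit")
    pooled = [v for vs in pairable for v in vs]

    if level == "nominal":
        delta = lambda x, y: 0.0 if x == y else 1.0  # noqa: E731
    elif level == "interval":
        delta = lambda x, y: float(x - y) ** 2  # noqa: E731
    elif level == "ordinal":
        table = _ordinal_delta(pooled)
        delta = lambda x, y: table[(x, y)]  # noqa: E731
    else:
        raise ValueError(level)

    n = len(pooled)
    d_obs = 0.0
    for vs in pairable:
        m = len(vs)
        for a in range(m):
            for b in range(m):
                if a != b:
                    d_obs += delta(vs[a], vs[b]) / (m - 1)
    d_obs /= n

    d_exp = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_exp += delta(pooled[i], pooled[j])
    d_exp /= n * (n - 1)
    return 1.0 - d_obs / d_exp
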