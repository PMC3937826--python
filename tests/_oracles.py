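"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid scipy's rank-test machinery: the null distribution
of the rank-sum statistic is enumerated over all assignments of pooled
values to the two groups.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence


def enumerate_wmw(oxic: Sequence[float], anoxic: Sequence[float]) -> tuple[float, float]:
    """Exact one- and two-tailed WMW p by enumeration of all assignments.

    The statistic is U = #{(x, y) : x > y} for x in the first group; the
    one-tailed p (alternative: first group stochastically greater) is
    P(U >= u_obs) over all C(n, n1) equally likely assignments of the pooled
    values; the two-tailed p is min(1, 2 * min(P(U >= u), P(U <= u))).
    Assumes distinct pooled values.
    """
    n1 = len(oxic)
    pooled = list(oxic) + list(anoxic)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"

    def u_stat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y)

    u_obs = u_stat(oxic, anoxic)
    total = 0
    ge = 0
    le = 0
    indices = range(len(pooled))
    for combo in itertools.combinations(indices, n1):
        chosen = set(combo)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in indices if i not in chosen]
        u = u_stat(xs, ys)
        total += 1
        if u >= u_obs:
            ge += 1
        if u <= u_obs:
            le += 1
    p_one = ge / total
    p_two = min(1.0, 2.0 * min(ge, le) / total)
    return p_one, p_two


def ols_two_group(a: Sequence[float], b: Sequence[float]) -> dict:
    """Closed-form two-group OLS on an indicator regressor.

    slope = mean(a) - mean(b); se from the pooled residual variance with
    n_a + n_b - 2 degrees of freedom.
    """
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    sse = sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    s2 = sse / df
    se = math.sqrt(s2 * (1.0 / na + 1.0 / nb))
    est = ma - mb
    return {"estimate": est, "se": se, "t": est / se if se else math.nan, "df": df}
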