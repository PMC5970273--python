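"""Independent brute-force oracles used to verify the optimized implementations.

Everything here is written from the definitions alone (naive enumeration,
no shared code with the package) so that agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric support.

    Sums P(X = k) over all tables with the observed margins whose point
    probability is <= that of the observed table (relative tolerance 1e-7).
    Zero margin -> 1.0.
    """
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 == 0 or c + d == 0 or col1 == 0 or b + d == 0:
        return 1.0
    kmin = max(0, col1 - (n - row1))
    kmax = min(row1, col1)
    pmf = hypergeom.pmf(np.arange(kmin, kmax + 1), n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def ranksum_two_sided_enumeration(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    The pooled values are partitioned into every possible split of sizes
    (|x|, |y|); p = 2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1, where
    U is the Mann-Whitney statistic of the first group. Assumes no ties.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    u_obs = u_stat(x, y)
    idx = range(n + m)
    total = 0
    n_le = 0
    n_ge = 0
    for comb in itertools.combinations(idx, n):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        u = u_stat(xs, ys)
        total += 1
        n_le += u <= u_obs
        n_ge += u >= u_obs
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def reference_caller_enumeration(pos, beta, stats, params):
    """Naive window-enumeration DMR caller on one chromosome.

    ``pos``: sorted positions; ``beta``: sample values; ``stats``: dict of
    arrays mean/sd/q_upper/q_lower/max/min aligned to pos; ``params``: has
    window_bp, min_outlier_probes, mean_delta, extreme_delta. Returns a list
    of events, each a dict with direction, crit1 (frozenset of indices),
    crit2 (frozenset). Windows are anchored at every probe; qualifying
    windows of one direction merge (transitive closure) when sharing
    criterion-(i) probes.
    """
    pos = np.asarray(pos)
    beta = np.asarray(beta, float)
    n = pos.size
    events = []
    for direction in ("hyper", "hypo"):
        qualifying = []
        for anchor in range(n):
            inside = [
                i for i in range(n)
                if pos[anchor] <= pos[i] < pos[anchor] + params.window_bp
            ]
            crit1, crit2 = set(), set()
            for i in inside:
                b = beta[i]
                if np.isnan(b):
                    continue
                if direction == "hyper":
                    if b > stats["q_upper"][i] and b >= stats["mean"][i] + params.mean_delta:
                        crit1.add(i)
                    if b >= stats["max"][i] + params.extreme_delta:
                        crit2.add(i)
                else:
                    if b < stats["q_lower"][i] and b <= stats["mean"][i] - params.mean_delta:
                        crit1.add(i)
                    if b <= stats["min"][i] - params.extreme_delta:
                        crit2.add(i)
            if len(crit1) >= params.min_outlier_probes and crit2:
                qualifying.append((crit1, crit2))
        # merge windows sharing crit1 probes (transitive closure)
        merged: list[tuple[set, set]] = []
        for crit1, crit2 in qualifying:
            hit = [g for g in merged if g[0] & crit1]
            for g in hit:
                merged.remove(g)
                crit1 |= g[0]
                crit2 |= g[1]
            merged.append((crit1, crit2))
        for crit1, crit2 in merged:
            events.append(
                {
                    "direction": direction,
                    "crit1": frozenset(crit1),
                    "crit2": frozenset(crit2),
                }
            )
    return events


def failed_cluster_enumeration(pos, failing_mask, window_bp=3000, min_probes=3):
    """Naive deletion-cluster finder for one sample and chromosome.

    Tests every window anchored at every failing probe; windows holding
    >= min_probes failing probes merge when sharing failing probes. Returns
    a list of frozensets of failing-probe indices.
    """
    pos = np.asarray(pos)
    fail = [i for i in range(pos.size) if failing_mask[i]]
    qualifying = []
    for a in fail:
        inside = {i for i in fail if pos[a] <= pos[i] < pos[a] + window_bp}
        if len(inside) >= min_probes:
            qualifying.append(inside)
    merged: list[set] = []
    for q in qualifying:
        hit = [g for g in merged if g & q]
        for g in hit:
            merged.remove(g)
            q |= g
        merged.append(q)
    return [frozenset(g) for g in merged]
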