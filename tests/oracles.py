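"""Independent, deliberately naive reference implementations used as test
oracles.  Pure-Python dict/loop arithmetic, no shared code with the package
internals beyond the public data containers."""

import math


def greedy_expansion_trace(edge, net, lam=1.0, t=1.0):
    """Step-by-step greedy expansion from a seed edge.

    Re-derives the loop directly: keep a member list, recompute density by a
    double loop, recompute every candidate's mean weight into the current
    set, and add the best candidate (lowest vertex order on ties) while its
    score is at least (1 - 1/(2*lam*(|C|+t))) * density.
    """
    verts = list(net.vertices)
    w = {(a, b): net.weight(a, b) for a in verts for b in verts if a != b}
    members = [edge[0], edge[1]]
    outside = [v for v in verts if v not in members]
    while outside:
        dens_num = 0.0
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                dens_num += w[(members[i], members[j])]
        dens = dens_num / (len(members) * (len(members) - 1) / 2.0)
        threshold = (1.0 - 1.0 / (2.0 * lam * (len(members) + t))) * dens
        best_v, best_score = None, -1.0
        for v in outside:  # outside keeps the network's vertex order
            score = sum(w[(v, u)] for u in members) / len(members)
            if score > best_score:
                best_v, best_score = v, score
        if best_score < threshold:
            break
        members.append(best_v)
        outside.remove(best_v)
    return members


def logrank_oe_v(time1, event1, time2, event2):
    """Observed-minus-expected log-rank statistic from first principles.

    Walks the pooled distinct event times; at each, tallies deaths and
    at-risk counts per group, accumulates group-1 observed, expected
    (hypergeometric mean) and variance, and returns the chi-square.
    """
    data = [(t, e, 0) for t, e in zip(time1, event1)] + [
        (t, e, 1) for t, e in zip(time2, event2)
    ]
    event_times = sorted({t for t, e, _ in data if e})
    O = E = V = 0.0
    for et in event_times:
        n1 = sum(1 for t, _, g in data if t >= et and g == 0)
        n2 = sum(1 for t, _, g in data if t >= et and g == 1)
        d1 = sum(1 for t, e, g in data if t == et and e and g == 0)
        d2 = sum(1 for t, e, g in data if t == et and e and g == 1)
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V == 0.0:
        return 0.0
    return (O - E) ** 2 / V


def kaplan_meier_at(time, event, query_t):
    """Product-limit survival at ``query_t`` by explicit risk-set products."""
    event_times = sorted({t for t, e in zip(time, event) if e and t <= query_t})
    s = 1.0
    for et in event_times:
        n_risk = sum(1 for t in time if t >= et)
        d = sum(1 for t, e in zip(time, event) if t == et and e)
        s *= 1.0 - d / n_risk
    return s
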