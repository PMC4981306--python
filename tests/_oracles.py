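"""Independent brute-force oracles shared across test modules."""

from oabtree.econ import DOMINATED, EXTENDED_DOMINATED, ON_FRONTIER


def brute_force_frontier(outcomes):
    """Pairwise strict dominance plus gift-wrapping of the upper-left hull
    (repeatedly take the lowest-ICER improvement from the current point).
    An algorithm independent of the sort-and-prune implementation."""
    items = list(outcomes.items())
    status = {}
    for sid, (c, e) in items:
        if any(
            c2 <= c and e2 >= e and (c2 < c or e2 > e) for s2, (c2, e2) in items if s2 != sid
        ):
            status[sid] = DOMINATED
    nd = sorted((x for x in items if x[0] not in status), key=lambda kv: (kv[1][0], -kv[1][1]))
    cur = nd[0]
    hull = {cur[0]}
    while True:
        cands = [x for x in nd if x[1][1] > cur[1][1]]
        if not cands:
            break
        cur = min(cands, key=lambda kv: (kv[1][0] - cur[1][0]) / (kv[1][1] - cur[1][1]))
        hull.add(cur[0])
    for sid, _ in nd:
        status[sid] = ON_FRONTIER if sid in hull else EXTENDED_DOMINATED
    return status
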