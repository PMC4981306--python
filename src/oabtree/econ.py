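"""Discounting, net monetary benefit and the cost-effectiveness frontier.

Discounting follows the convention that costs and outcomes accruing in
the first 12 months are not discounted, with annual compounding at the
given rate thereafter. The frontier removes strictly dominated
strategies (at least as costly and no more effective than another, one
comparison strict) and extended-dominated strategies (a non-increasing
ICER sequence along the cost-sorted frontier), then reports ICERs
between adjacent frontier members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


def discount_factor(year, rate: float):
    """Discount weight for an event in model year ``year``.

    Years 0 and 1 (anything within the first 12 months) are undiscounted;
    year t >= 2 is weighted (1 + rate)^-(t - 1). Accepts arrays.
    """
    y = np.asarray(year)
    if np.any(y < 0):
        raise ValueError("year must be non-negative")
    out = np.where(y <= 1, 1.0, (1.0 + rate) ** -(np.maximum(y, 1) - 1))
    return float(out) if np.isscalar(year) else out


def annuity_factor(years: int, rate: float) -> float:
    """Sum of discount factors over ``years`` consecutive years, the first
    undiscounted: sum_{t=1..years} (1 + rate)^-(t-1)."""
    return float(sum((1.0 + rate) ** -(t - 1) for t in range(1, years + 1)))


def nmb(cost, effect, wtp):
    """Net monetary benefit: wtp x effect - cost."""
    return wtp * np.asarray(effect) - np.asarray(cost)


def icer(delta_cost: float, delta_effect: float) -> float:
    if delta_effect == 0:
        return float("inf") if delta_cost > 0 else float("-inf")
    return delta_cost / delta_effect


@dataclass(frozen=True)
class FrontierRow:
    strategy: str
    cost: float
    effect: float
    status: str
    icer_vs_previous: float | None = None


def frontier(outcomes: dict[str, tuple[float, float]], effect_kind: str = "effect") -> pd.DataFrame:
    """Dominance-pruned incremental cost-effectiveness table.

    ``outcomes`` maps strategy id to (expected cost, expected effect).
    Returns a data frame sorted by cost with columns ``strategy``,
    ``cost``, ``effect``, ``status`` and ``icer_vs_previous`` (NaN for
    everything but frontier members beyond the cheapest). Exact
    cost-and-effect ties are kept, with all but the first (by strategy
    id) flagged dominated so reports are reproducible.
    """
    if len(outcomes) < 2:
        raise ValueError("frontier needs at least two strategies")
    ids = list(outcomes)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strategy ids")

    rows = sorted(outcomes.items(), key=lambda kv: (kv[1][0], -kv[1][1], kv[0]))
    status = {}
    for sid, (c, e) in rows:
        dominated = any(
            (c2 <= c and e2 >= e and (c2 < c or e2 > e))
            or (c2 == c and e2 == e and s2 < sid and s2 not in status)
            for s2, (c2, e2) in rows
            if s2 != sid and status.get(s2) != DOMINATED
        )
        if dominated:
            status[sid] = DOMINATED

    survivors = [(sid, ce) for sid, ce in rows if sid not in status]
    # extended dominance: drop members until ICERs strictly increase
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            c0, e0 = survivors[i - 1][1]
            c1, e1 = survivors[i][1]
            c2, e2 = survivors[i + 1][1]
            if icer(c1 - c0, e1 - e0) >= icer(c2 - c1, e2 - e1):
                status[survivors[i][0]] = EXTENDED_DOMINATED
                del survivors[i]
                changed = True
                break

    icers: dict[str, float] = {}
    for i, (sid, (c, e)) in enumerate(survivors):
        status.setdefault(sid, ON_FRONTIER)
        if i > 0:
            c0, e0 = survivors[i - 1][1]
            icers[sid] = icer(c - c0, e - e0)

    return pd.DataFrame(
        {
            "strategy": [sid for sid, _ in rows],
            "cost": [c for _, (c, _) in rows],
            effect_kind: [e for _, (_, e) in rows],
            "status": [status[sid] for sid, _ in rows],
            "icer_vs_previous": [icers.get(sid, np.nan) for sid, _ in rows],
        }
    )


def round_icer(value: float, nearest: int = 100) -> float:
    """Presentation rounding of an ICER to the nearest 100 GBP."""
    if not np.isfinite(value):
        return value
    return round(value / nearest) * nearest
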