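"""Deterministic sensitivity scenarios.

Re-runs the base case under each univariate/multivariate scenario
(cheaper urodynamics, doubled sling cost, lower cured utility, lower
urodynamic accuracy with diary-assisted history, expert-elicited cure
rates at their lowest/highest bounds, and a single diagnostic test) and
reports how each shifts strategy outcomes and which strategy leads the
frontier.

Run from the repository root:  python analysis/03_scenarios.py
"""

from pathlib import Path

from oabtree.cli import frontier_tables, outcome_table, scenario_deltas
from oabtree.econ import ON_FRONTIER
from oabtree.parameters import SCENARIOS, apply_scenario, load_parameters

OUT = Path("results/scenarios")
OUT.mkdir(parents=True, exist_ok=True)

ps = load_parameters()
table = scenario_deltas(ps)
table.to_csv(OUT / "scenario_outcomes.csv", index=False)


def cheapest_frontier_winner(params, effect):
    ftab = frontier_tables(params)[effect]
    on = ftab[ftab.status == ON_FRONTIER]
    return on.sort_values("cost")["strategy"].iloc[0]


base = outcome_table(ps).set_index("strategy")
print("Base case: cheapest frontier strategy per QALY:",
      cheapest_frontier_winner(ps, "qalys"))
for sid in SCENARIOS:
    modified = apply_scenario(ps, sid)
    winner = cheapest_frontier_winner(modified, "qalys")
    uds = outcome_table(modified).set_index("strategy").loc["uds_all"]
    print(
        f"  {sid:<28} cheapest frontier strategy: {winner:<22} "
        f"(uds_all cost {uds.cost:7.0f}, qalys {uds.qalys:.3f})"
    )
print(f"\nFull per-strategy deltas written to {OUT / 'scenario_outcomes.csv'}")
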