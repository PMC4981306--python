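"""Base-case evaluation of the seven test-treat strategies.

Evaluates every strategy tree at the analytic parameter means and
reports both economic analyses: (1) the three unconditional strategies
(urodynamics, clinical history, ultrasonography for all women) and
(2) all seven ways of combining a test with clinical history, each with
dominance-pruned ICERs per woman successfully treated and per QALY.

Run from the repository root:  python analysis/02_base_case.py
"""

from pathlib import Path

from oabtree.cli import ANALYSIS1, ANALYSIS2, frontier_tables, outcome_table
from oabtree.econ import ON_FRONTIER, round_icer
from oabtree.parameters import load_parameters

OUT = Path("results/base_case")
OUT.mkdir(parents=True, exist_ok=True)

ps = load_parameters()

for label, strategies in (("analysis1", ANALYSIS1), ("analysis2", ANALYSIS2)):
    table = outcome_table(ps, strategies)
    table.to_csv(OUT / f"{label}_outcomes.csv", index=False)
    print(f"\n=== {label}: expected outcomes per woman (5-year horizon, 3.5% discount) ===")
    print(table.round({"cost": 0, "success": 3, "qalys": 3}).to_string(index=False))
    for effect, ftab in frontier_tables(ps, strategies).items():
        ftab.to_csv(OUT / f"{label}_frontier_{effect}.csv", index=False)
        print(f"\n--- frontier on {effect} ---")
        for row in ftab.itertuples():
            note = row.status
            if row.status == ON_FRONTIER and row.icer_vs_previous == row.icer_vs_previous:
                note += f", ICER ~GBP {round_icer(row.icer_vs_previous):,.0f} per {effect}"
            print(f"  {row.strategy:<30} cost {row.cost:7.0f}  {effect} {getattr(row, effect):.3f}  {note}")

print(
    "\nAccuracy and prevalence inputs are synthetic stand-ins (see analysis/01),"
    "\nso these absolute values characterise the model under the packaged fixture,"
    "\nnot the primary study's cohort."
)
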