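"""Probabilistic sensitivity analysis and value of information.

Runs the 10,000-iteration Monte Carlo analysis over all seven
strategies, writes cost-effectiveness acceptability frontiers for both
outcomes (successful treatment, QALYs) and the per-person / population
expected value of perfect information over the willingness-to-pay grids,
and prints the headline decision-uncertainty summaries.

Run from the repository root:  python analysis/04_psa_voi.py [seed]
"""

import sys
from pathlib import Path

from oabtree.parameters import load_parameters
from oabtree.psa import ceaf, evpi_curve, evpi_per_person, population_evpi, run_psa

OUT = Path("results/psa")
OUT.mkdir(parents=True, exist_ok=True)

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ps = load_parameters()
econ = ps.econ
samples = run_psa(ps, seed=seed)
print(f"PSA: {samples.n_iterations:,} iterations x {len(samples.strategies)} strategies (seed {seed})")
samples.mean_outcomes().rename_axis("strategy").reset_index().to_csv(OUT / "psa_mean_outcomes.csv", index=False)

for effect, grid in (("success", econ.wtp_grid_success), ("qaly", econ.wtp_grid_qaly)):
    curve = ceaf(samples, grid, effect_kind=effect)
    curve.to_csv(OUT / f"ceaf_{effect}.csv", index=False)
    voi = evpi_curve(samples, grid, effect, econ.incidence_per_year,
                     econ.research_horizon_years, econ.discount_rate)
    voi.to_csv(OUT / f"evpi_{effect}.csv", index=False)

for effect, wtp in (("qaly", 20_000.0), ("success", 28_000.0)):
    row = ceaf(samples, [wtp], effect_kind=effect).iloc[0]
    per = evpi_per_person(samples, wtp, effect)
    pop = population_evpi(per, econ.incidence_per_year, econ.research_horizon_years, econ.discount_rate)
    print(
        f"  at GBP {wtp:,.0f} per {effect}: optimal {row.optimal_strategy} "
        f"(P(cost-effective) = {row.probability_optimal_cost_effective:.2f}); "
        f"EVPI GBP {per:,.0f}/woman, population GBP {pop / 1e6:,.1f} million"
    )
print(f"Curves written to {OUT}/")
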