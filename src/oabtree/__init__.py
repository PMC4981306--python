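"""Decision-analytic cost-effectiveness model of test-treat strategies for
women with refractory overactive bladder or urgency-predominant mixed
urinary incontinence: urodynamics, bladder-wall-thickness ultrasound and
clinical history, alone or conditioned on history, compared over a
five-year horizon on cost per woman successfully treated and cost per
QALY, with deterministic scenarios, probabilistic sensitivity analysis,
acceptability frontiers and expected value of perfect information."""

from .cohort import (
    CONDITIONS,
    AccuracyEstimate,
    GeneratorConfig,
    estimate_accuracy,
    estimate_prevalence,
    generate_cohort,
)
from .distributions import (
    FittedDistribution,
    dist_mean,
    fit_beta_from_counts,
    fit_beta_from_mean_ci,
    fit_gamma_dispersed,
    fit_gamma_from_mean_ci,
    sample,
)
from .econ import discount_factor, frontier, icer, nmb
from .parameters import (
    ParameterSet,
    SCENARIOS,
    apply_scenario,
    expected_botulinum_course_cost,
    load_parameters,
    point_estimates,
)
from .psa import ceaf, evpi_curve, evpi_per_person, population_evpi, run_psa
from .tree import (
    STRATEGIES,
    StrategyOutcome,
    accrue_qalys,
    build_strategy_tree,
    enumerate_paths,
    evaluate,
    export_outline,
)

__version__ = "0.1.0"


def evaluate_strategies(ps: ParameterSet, strategies=STRATEGIES) -> "pd.DataFrame":
    """Base-case expected cost, QALYs and success probability per strategy."""
    import pandas as pd

    env = point_estimates(ps)
    rows = {}
    for strat in strategies:
        out = evaluate(build_strategy_tree(strat, ps), env, ps.econ)
        rows[strat] = {
            "cost": out.expected_cost,
            "success": out.p_success,
            "qalys": out.expected_qalys,
        }
    return pd.DataFrame(rows).T
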