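"""Strategy-tree construction, evaluation and the path-enumeration oracle."""

import numpy as np
import pytest

from oabtree.econ import discount_factor
from oabtree.parameters import apply_scenario
from oabtree.tree import (
    STRATEGIES,
    Const,
    CostEvent,
    Node,
    Outcome,
    accrue_qalys,
    build_strategy_tree,
    enumerate_paths,
    evaluate,
    export_outline,
    to_dot,
)


def _disc_years(rate, horizon=5):
    return sum(discount_factor(k + 1, rate) for k in range(horizon))


# ---------------------------------------------------------------------------
# QALY accrual


def test_accrue_qalys_undiscounted_and_discounted(ps):
    assert accrue_qalys([(1.0, 0, 5)], {}, ps.econ.__class__(discount_rate=0.0)) == pytest.approx(5.0)
    econ = ps.econ
    expected = 1 + sum(1.035 ** -(t - 1) for t in range(2, 6))
    assert accrue_qalys([(1.0, 0, 5)], {}, econ) == pytest.approx(expected)
    assert expected == pytest.approx(4.673, abs=5e-4)


def test_accrue_qalys_cure_with_side_effects(ps):
    econ = ps.econ.__class__(discount_rate=0.0)
    assert accrue_qalys([("cured_se", 0, 5)], {"cured_se": 0.87}, econ) == pytest.approx(4.35)
    mixed_then_cured = accrue_qalys([(0.6, 0, 2), (0.92, 2, 5)], {}, econ)
    assert mixed_then_cured == pytest.approx(0.6 * 2 + 0.92 * 3)


def test_accrue_qalys_rejects_bad_timelines(ps):
    with pytest.raises(ValueError):
        accrue_qalys([(1.0, 0, 3), (1.0, 4, 5)], {}, ps.econ)  # gap
    with pytest.raises(ValueError):
        accrue_qalys([(1.0, 0, 3), (1.0, 2, 5)], {}, ps.econ)  # overlap
    with pytest.raises(ValueError):
        accrue_qalys([(1.0, 0, 4)], {}, ps.econ)  # stops short of horizon


# ---------------------------------------------------------------------------
# hand-built tree oracle


def test_three_leaf_tree_matches_hand_computation(ps):
    econ = ps.econ
    rate = econ.discount_rate
    leaf1 = Node(1, "a", costs=(CostEvent(Const(100.0), 0),),
                 outcome=Outcome("detrusor_overactivity", cured=True, cure_year=0))
    leaf2 = Node(2, "b", costs=(CostEvent(Const(200.0), 2),),
                 outcome=Outcome("detrusor_overactivity", cured=False))
    leaf3 = Node(3, "c", outcome=Outcome("detrusor_overactivity", cured=True, cure_year=2,
                                         side_effects=True))
    root = Node(0, "root", branches=((Const(0.5), leaf1), (Const(0.3), leaf2), (Const(0.2), leaf3)))
    env = {
        "util.detrusor_overactivity": 0.6,
        "util.cured_no_side_effects": 0.92,
        "util.cured_with_side_effects": 0.87,
    }
    out = evaluate(root, env, econ)
    d5 = _disc_years(rate)
    d2 = 1 + 1 / 1.035
    assert out.expected_cost == pytest.approx(0.5 * 100 + 0.3 * 200 / 1.035)
    expected_q = 0.5 * (0.92 * d5) + 0.3 * (0.6 * d5) + 0.2 * (0.6 * d2 + 0.87 * (d5 - d2))
    assert out.expected_qalys == pytest.approx(expected_q)
    assert out.p_success == pytest.approx(0.7)
    paths = enumerate_paths(root, env, econ)
    assert len(paths) == 3
    assert sum(p.probability for p in paths) == pytest.approx(1.0)


def test_cycle_detection(ps):
    leaf = Node(1, "leaf", outcome=Outcome("detrusor_overactivity", cured=False))
    a = Node(0, "a", branches=((Const(1.0), leaf),))
    object.__setattr__(leaf, "outcome", None)
    object.__setattr__(leaf, "branches", ((Const(1.0), a),))
    with pytest.raises(ValueError, match="cycle"):
        enumerate_paths(a, {"util.detrusor_overactivity": 0.6}, ps.econ)


# ---------------------------------------------------------------------------
# full strategy trees


@pytest.mark.parametrize("strategy", STRATEGIES)
def test_path_probabilities_conserve_and_rollback_equals_enumeration(ps, env, strategy):
    tree = build_strategy_tree(strategy, ps)
    paths = enumerate_paths(tree, env, ps.econ)
    assert sum(p.probability for p in paths) == pytest.approx(1.0, abs=1e-9)
    out = evaluate(tree, env, ps.econ)
    assert sum(p.probability * p.discounted_cost for p in paths) == pytest.approx(
        out.expected_cost, rel=1e-9
    )
    assert sum(p.probability * p.discounted_qalys for p in paths) == pytest.approx(
        out.expected_qalys, rel=1e-9
    )
    assert sum(p.probability for p in paths if p.cured) == pytest.approx(out.p_success, rel=1e-9)
    # QALYs bounded by horizon x best utility; cures are absorbing (terminal)
    max_q = max(v for k, v in env.items() if k.startswith("util.")) * _disc_years(ps.econ.discount_rate)
    for p in paths:
        assert 0 <= p.discounted_qalys <= max_q + 1e-12
        assert p.probability >= 0


def test_do_diagnosis_offers_exactly_two_first_line_treatments(ps, env):
    tree = build_strategy_tree("uds_all", ps)
    first = set()
    for p in enumerate_paths(tree, env, ps.econ):
        if p.probability == 0 or "uds[do]" not in p.trace:
            continue
        i = p.trace.index("uds[do]")
        if p.trace[i + 1].startswith("oab_choice"):
            first.add(p.trace[i + 2].split("@")[0])
    assert first == {"botox_course", "neurostim"}


def test_all_cure_forced_cost(ps, env):
    """With certain cure, forced botulinum choice and no voiding
    difficulty, the urodynamics strategy costs exactly the test plus the
    first-line treatment of each diagnosis."""
    e = dict(env)
    for k in e:
        if k.startswith("cure."):
            e[k] = 1.0
    e["path.choose_botox_over_neurostim"] = 1.0
    e["path.choose_botox_prior_to_sling"] = 0.0
    e["path.voiding_difficulty_after_botox"] = 0.0
    out = evaluate(build_strategy_tree("uds_all", ps), e, ps.econ)
    course = e["cost.botulinum_injection"] * (1 + 0.8 + 0.736 / 1.035)
    expected = (
        e["cost.urodynamics"]
        + e["prev.detrusor_overactivity"] * course
        + (e["prev.stress_incontinence"] + e["prev.mixed_incontinence"]) * e["cost.sling"]
    )
    assert out.expected_cost == pytest.approx(expected, rel=1e-12)
    treatable = (
        e["prev.detrusor_overactivity"] + e["prev.stress_incontinence"] + e["prev.mixed_incontinence"]
    )
    assert out.p_success == pytest.approx(treatable, rel=1e-12)


@pytest.mark.parametrize("strategy", ["uds_all", "history_all", "ultrasound_if_mixed_history"])
def test_monotonicity_in_cures_and_costs(ps, env, strategy):
    tree = build_strategy_tree(strategy, ps)
    base = evaluate(tree, env, ps.econ)
    for key in ("cure.botulinum.detrusor_overactivity", "cure.sling.mixed_incontinence",
                "cure.implanted_neurostimulator.detrusor_overactivity"):
        bumped = dict(env)
        bumped[key] = min(1.0, env[key] + 0.1)
        out = evaluate(tree, bumped, ps.econ)
        assert out.p_success >= base.p_success - 1e-12
        assert out.expected_qalys >= base.expected_qalys - 1e-12
    for key in ("cost.sling", "cost.urodynamics", "cost.implant", "cost.neurostimulation_course"):
        bumped = dict(env)
        bumped[key] = env[key] * 2
        out = evaluate(tree, bumped, ps.econ)
        assert out.expected_cost >= base.expected_cost - 1e-9


def test_side_effect_utility_only_matters_with_voiding_difficulty(ps, env):
    tree = build_strategy_tree("uds_all", ps)
    lower = dict(env)
    lower["util.cured_with_side_effects"] = 0.5
    assert evaluate(tree, lower, ps.econ).expected_qalys < evaluate(tree, env, ps.econ).expected_qalys
    no_vd = dict(lower)
    no_vd["path.voiding_difficulty_after_botox"] = 0.0
    ref = dict(env)
    ref["path.voiding_difficulty_after_botox"] = 0.0
    assert evaluate(tree, no_vd, ps.econ).expected_qalys == pytest.approx(
        evaluate(tree, ref, ps.econ).expected_qalys
    )


def test_second_test_appears_only_in_conditional_strategies(ps):
    for strategy in STRATEGIES:
        outline = export_outline(build_strategy_tree(strategy, ps))
        if strategy in ("uds_all", "history_all", "ultrasound_all"):
            assert "second_" not in outline
        else:
            assert "second_" in outline
    single = apply_scenario(ps, "single_test_only")
    for strategy in STRATEGIES:
        assert "second_" not in export_outline(build_strategy_tree(strategy, single))


def test_evaluation_accepts_array_environments(ps, env):
    tree = build_strategy_tree("uds_all", ps)
    arr_env = {k: np.full(4, v) for k, v in env.items()}
    uds = env["cost.urodynamics"]
    arr_env["cost.urodynamics"] = np.array([uds, uds, uds - 228.0, 0.0])
    out = evaluate(tree, arr_env, ps.econ)
    scalar = evaluate(tree, env, ps.econ)
    assert out.expected_cost.shape == (4,)
    assert out.expected_cost[0] == pytest.approx(scalar.expected_cost)
    assert out.expected_cost[0] - out.expected_cost[2] == pytest.approx(228.0)


def test_exports_smoke(ps):
    tree = build_strategy_tree("uds_if_mixed_history", ps)
    outline = export_outline(tree)
    assert "urodynamics" in outline and "cured" in outline
    dot = to_dot(tree)
    assert dot.startswith("digraph") and "->" in dot


def test_unknown_strategy_rejected(ps):
    with pytest.raises(ValueError, match="uds_all"):
        build_strategy_tree("nope", ps)
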