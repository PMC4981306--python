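"""Decision trees for the seven test-treat strategies.

Each strategy is a rooted tree over a cohort of women with refractory
urgency symptoms. The root splits over the true urodynamic condition;
test results and clinical history then determine which condition the
woman is *managed as*, and the treatment pathway unfolds on a yearly
event grid over a five-year horizon:

* managed as overactive bladder: botulinum toxin (chosen with
  probability ``path.choose_botox_over_neurostim``) or percutaneous
  neurostimulation; on failure a peripheral nerve evaluation leads to a
  permanent implant (``path.require_implant_after_pne``) or to whichever
  first-line modality was not yet tried;
* managed as stress incontinence: sling surgery, then Burch
  colposuspension unless overactive-bladder treatment was given before;
* managed as mixed incontinence: optional botulinum toxin first
  (``path.choose_botox_prior_to_sling``), then sling, then
  colposuspension under the same restriction;
* normal bladder / low compliance only / voiding dysfunction only:
  no further invasive treatment.

Branch probabilities, costs and utilities are symbolic references into
the flat parameter name space, resolved only at evaluation time, so one
tree structure serves the base case, every deterministic scenario and
every probabilistic draw. Evaluation accepts scalar or array-valued
environments; arrays propagate elementwise, which is how the
probabilistic sensitivity analysis evaluates all iterations in one pass.

Cure probabilities always condition on the woman's *true* condition, so
mistreatment after misdiagnosis is penalised through the effectiveness
table, with the most conservative elicited estimate as proxy for women
whose condition has no invasive treatment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .cohort import CONDITIONS
from .econ import discount_factor
from .parameters import EconSettings, ParameterSet, cure_param, utility_param

STRATEGIES = (
    "uds_all",
    "history_all",
    "ultrasound_all",
    "uds_if_mixed_history",
    "uds_if_oab_history",
    "ultrasound_if_mixed_history",
    "ultrasound_if_oab_history",
)

STRATEGY_LABELS = {
    "uds_all": "Urodynamics - all women",
    "history_all": "Clinical history - all women",
    "ultrasound_all": "Bladder ultrasonography - all women",
    "uds_if_mixed_history": "Urodynamics - conditional on history of mixed incontinence",
    "uds_if_oab_history": "Urodynamics - conditional on history of overactive bladder",
    "ultrasound_if_mixed_history": "Bladder ultrasonography - conditional on history of mixed incontinence",
    "ultrasound_if_oab_history": "Bladder ultrasonography - conditional on history of overactive bladder",
}

_DO = "detrusor_overactivity"
_STRESS = "stress_incontinence"
_MIXED = "mixed_incontinence"


# ---------------------------------------------------------------------------
# symbolic expressions over the parameter environment


class Expr:
    def value(self, env):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    v: float

    def value(self, env):
        return self.v

    def __repr__(self):
        return f"{self.v:g}"


@dataclass(frozen=True)
class Param(Expr):
    name: str

    def value(self, env):
        try:
            return env[self.name]
        except KeyError as exc:
            raise KeyError(f"parameter {self.name!r} missing from environment") from exc

    def __repr__(self):
        return self.name


@dataclass(frozen=True)
class Comp(Expr):
    """1 - x."""

    child: Expr

    def value(self, env):
        return 1.0 - self.child.value(env)

    def __repr__(self):
        return f"1-{self.child!r}"


@dataclass(frozen=True)
class Scale(Expr):
    """k * x."""

    child: Expr
    k: float

    def value(self, env):
        return self.k * self.child.value(env)

    def __repr__(self):
        return f"{self.k:g}*{self.child!r}"


ONE = Const(1.0)


# ---------------------------------------------------------------------------
# tree nodes


@dataclass(frozen=True)
class CostEvent:
    """A cost item incurred on reaching a node.

    ``year`` is the model year used for discounting; ``weight`` scales
    the amount (fixed uptake fractions, or the marginal probability of a
    contingent item such as device follow-up, costed in expectation).
    """

    amount: Expr
    year: int
    weight: Expr = ONE
    label: str = ""


@dataclass(frozen=True)
class Outcome:
    """Terminal health outcome of one root-to-leaf pathway."""

    condition: str
    cured: bool
    cure_year: int | None = None
    side_effects: bool = False


@dataclass(frozen=True)
class Node:
    id: int
    label: str
    costs: tuple[CostEvent, ...] = ()
    branches: tuple[tuple[Expr, "Node"], ...] = ()
    outcome: Outcome | None = None

    @property
    def is_terminal(self) -> bool:
        return self.outcome is not None


@dataclass(frozen=True)
class PathRecord:
    probability: float
    discounted_cost: float
    discounted_qalys: float
    cured: bool
    trace: tuple[str, ...]


@dataclass(frozen=True)
class StrategyOutcome:
    expected_cost: float
    expected_qalys: float
    p_success: float


@dataclass(frozen=True)
class _State:
    cond: str
    t: int
    side: bool = False
    botox: bool = False
    neuro: bool = False
    sling: bool = False
    hook: bool = False  # untested woman still owed the strategy's second test

    @property
    def prior_oab(self) -> bool:
        return self.botox or self.neuro


class _TreeBuilder:
    """Builds one strategy tree; identical sub-states share one node."""

    def __init__(self, strategy: str, ps: ParameterSet):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; valid: {', '.join(STRATEGIES)}")
        self.strategy = strategy
        self.ps = ps
        self.horizon = ps.econ.horizon_years
        self.refpos = {_DO} | ({_MIXED} if ps.reference_positive_includes_mixed else set())
        self.test = (
            "uds" if strategy.startswith("uds") else "ultrasound" if strategy.startswith("ultrasound") else None
        )
        self._ids = itertools.count()
        self._memo: dict = {}

    # -- node construction helpers

    def node(self, label, costs=(), branches=(), outcome=None) -> Node:
        return Node(next(self._ids), label, tuple(costs), tuple(branches), outcome)

    def wrap_cost(self, label: str, events, child: Node) -> Node:
        return self.node(label, costs=events, branches=[(ONE, child)])

    def symptomatic(self, s: _State) -> Node:
        key = ("sympt", s.cond, s.side)
        if key not in self._memo:
            self._memo[key] = self.node(
                "remains_symptomatic", outcome=Outcome(s.cond, cured=False, side_effects=s.side)
            )
        return self._memo[key]

    def cured(self, s: _State, year: int, costs=()) -> Node:
        year = min(year, self.horizon)
        return self.node(
            f"cured_y{year}",
            costs=costs,
            outcome=Outcome(s.cond, cured=True, cure_year=year, side_effects=s.side),
        )

    def _memoised(self, key, fn):
        if key not in self._memo:
            self._memo[key] = fn()
        return self._memo[key]

    # -- entry layer

    def build(self) -> Node:
        branches = []
        for cond in CONDITIONS:
            branches.append((Param(f"prev.{cond}"), self.entry(cond)))
        return self.node(f"strategy:{self.strategy}", branches=branches)

    def entry(self, cond: str) -> Node:
        s = _State(cond=cond, t=0)
        strat = self.strategy
        if strat == "uds_all":
            return self.wrap_cost("urodynamics", [CostEvent(Param("cost.urodynamics"), 0, label="urodynamics")], self.uds_dx(s))
        if strat == "ultrasound_all":
            return self.wrap_cost(
                "ultrasound", [CostEvent(Param("cost.ultrasonography"), 0, label="ultrasound")], self.us_dx(s)
            )
        if strat == "history_all":
            # no diagnostic test exists in this strategy, so no second test
            return self.history_split(s, tested_arm=None)
        if strat == "uds_if_mixed_history":
            return self.history_split(s, tested_arm="mixed")
        if strat == "uds_if_oab_history":
            return self.history_split(s, tested_arm="urgency_only")
        if strat == "ultrasound_if_mixed_history":
            return self.history_split(s, tested_arm="mixed")
        if strat == "ultrasound_if_oab_history":
            return self.history_split(s, tested_arm="urgency_only")
        raise AssertionError(strat)

    def history_split(self, s: _State, tested_arm) -> Node:
        """Split on clinical history; ``tested_arm`` names the label that
        receives the strategy's test at entry (None: nobody tested)."""
        p_mixed = Param(f"hist.mixed_given.{s.cond}")

        def arm(label: str) -> Node:
            tested = tested_arm == label
            if tested:
                if self.test == "uds":
                    return self.wrap_cost(
                        "urodynamics", [CostEvent(Param("cost.urodynamics"), s.t, label="urodynamics")], self.uds_dx(s)
                    )
                return self.wrap_cost(
                    "ultrasound", [CostEvent(Param("cost.ultrasonography"), s.t, label="ultrasound")], self.us_dx(s)
                )
            hooked = replace(s, hook=self.test is not None and self.ps.second_test_enabled)
            if label == "mixed":
                return self.manage_mixed(hooked)
            return self.manage_oab(hooked)

        return self.node(
            f"history[{s.cond}]",
            branches=[(p_mixed, arm("mixed")), (Comp(p_mixed), arm("urgency_only"))],
        )

    def uds_dx(self, s: _State) -> Node:
        """Urodynamic diagnosis: the reference standard, exact except for
        the (scenario-only) chance of missing detrusor overactivity, in
        which case the woman is managed as mixed incontinence."""
        if s.cond == _DO:
            sens = Param("acc.uds_sensitivity")
            return self.node(
                "uds[do]",
                branches=[(sens, self.dispatch(_DO, s)), (Comp(sens), self.dispatch(_MIXED, s))],
            )
        return self.dispatch(s.cond, s)

    def us_dx(self, s: _State) -> Node:
        """Ultrasound: wall thickness at or above the threshold indicates
        overactive bladder; below it the scan cannot separate the
        syndromes and mixed-incontinence treatment starts."""
        pos = (
            Param("acc.bwt_sensitivity")
            if s.cond in self.refpos
            else Comp(Param("acc.bwt_specificity"))
        )
        return self.node(
            f"ultrasound[{s.cond}]",
            branches=[(pos, self.manage_oab(s)), (Comp(pos), self.manage_mixed(s))],
        )

    def dispatch(self, dx: str, s: _State) -> Node:
        if dx == _DO:
            return self.manage_oab(s)
        if dx == _STRESS:
            return self.manage_stress(s)
        if dx == _MIXED:
            return self.manage_mixed(s)
        return self.symptomatic(s)

    # -- overactive-bladder management

    def manage_oab(self, s: _State) -> Node:
        return self._memoised(("oab", s), lambda: self._manage_oab(s))

    def _manage_oab(self, s: _State) -> Node:
        if s.t > self.horizon - 1:
            return self.symptomatic(s)
        if s.botox and s.neuro:
            return self.stage2(replace(s, hook=False))
        if s.botox:
            return self.neuro_cycle(s, self.after_first_oab_cycle)
        if s.neuro:
            return self.botox_cycle(s, self.after_first_oab_cycle)
        p_botox = Param("path.choose_botox_over_neurostim")
        return self.node(
            f"oab_choice@{s.t}",
            branches=[
                (p_botox, self.botox_cycle(s, self.after_first_oab_cycle)),
                (Comp(p_botox), self.neuro_cycle(s, self.after_first_oab_cycle)),
            ],
        )

    def after_first_oab_cycle(self, s: _State) -> Node:
        if s.t > self.horizon - 1:
            return self.symptomatic(s)
        if s.hook:
            return self.second_test(s)
        return self.stage2(s)

    def stage2(self, s: _State) -> Node:
        """Peripheral nerve evaluation, then implantation or the
        first-line modality not yet tried; failures beyond this point
        remain symptomatic."""
        return self._memoised(("stage2", s), lambda: self._stage2(s))

    def _stage2(self, s: _State) -> Node:
        if s.t > self.horizon - 1:
            return self.symptomatic(s)
        p_impl = Param("path.require_implant_after_pne")
        followup = [
            CostEvent(Param("cost.implant_followup"), self.horizon, Param(f"path.{name}"), label=name)
            for name in (
                "implant_revision_lt2y",
                "implant_revision_ge2y",
                "implant_maintenance_ge2y",
                "implant_removal",
            )
        ]
        p_cure = Param(cure_param("implanted_neurostimulator", s.cond))
        implant = self.node(
            f"implant@{s.t}",
            costs=[CostEvent(Param("cost.implant"), s.t, label="implant"), *followup],
            branches=[
                (p_cure, self.cured(s, s.t)),
                (Comp(p_cure), self.symptomatic(s)),
            ],
        )
        if not s.botox:
            alt = self.botox_cycle(s, lambda ns: self.symptomatic(ns))
        elif not s.neuro:
            alt = self.neuro_cycle(s, lambda ns: self.symptomatic(ns))
        else:
            alt = self.symptomatic(s)
        return self.node(
            f"pne@{s.t}",
            costs=[CostEvent(Param("cost.pne"), s.t, label="pne")],
            branches=[(p_impl, implant), (Comp(p_impl), alt)],
        )

    # -- treatment cycles

    def botox_cycle(self, s: _State, on_fail) -> Node:
        """Up to three injections at yearly intervals from ``s.t``.

        Injection uptake follows the drop-out schedule; the overall cure
        probability is split across injections by their contributions,
        truncated to injections that fall within the horizon. Voiding
        difficulty triggers self-catheterisation training and, for cured
        women, the with-side-effects utility. Failure is established a
        year after the last scheduled injection.
        """
        course = self.ps.course
        given = [k for k in range(3) if s.t + k <= self.horizon - 1]
        inj = [
            CostEvent(Param("cost.botulinum_injection"), s.t + k, Const(course.uptake[k]), label=f"botox_inj{k+1}")
            for k in given
        ]
        sumc = sum(course.cure_contributions[k] for k in given)
        p_cure = Scale(Param(cure_param("botulinum", s.cond)), sumc)
        after = replace(s, t=s.t + 3, botox=True)

        def cure_and_fail(state: _State, extra_costs=()):
            timing = self.node(
                "cure_timing",
                branches=[
                    (
                        Const(course.cure_contributions[k] / sumc),
                        self.cured(state, s.t + k),
                    )
                    for k in given
                ],
            )
            return self.node(
                f"botox@{s.t}" + ("+vd" if extra_costs else ""),
                costs=extra_costs,
                branches=[
                    (p_cure, timing),
                    (Comp(p_cure), on_fail(replace(after, side=state.side))),
                ],
            )

        p_vd = Param("path.voiding_difficulty_after_botox")
        vd_state = replace(s, side=True)
        return self.node(
            f"botox_course@{s.t}",
            costs=inj,
            branches=[
                (
                    p_vd,
                    cure_and_fail(
                        vd_state,
                        extra_costs=[CostEvent(Param("cost.self_cath_training"), s.t, label="self_catheterisation")],
                    ),
                ),
                (Comp(p_vd), cure_and_fail(s)),
            ],
        )

    def neuro_cycle(self, s: _State, on_fail) -> Node:
        """A 12-session neurostimulation course over three months;
        responders need a monthly maintenance session until the end of
        the horizon, costed at one twelfth of the course price."""
        maintenance = []
        for y in range(s.t, self.horizon):
            n = 9 if y == s.t else 12  # months 4-12 of the first year, then monthly
            maintenance.append(
                CostEvent(
                    Scale(Param("cost.neurostimulation_course"), n / 12.0),
                    y + 1,
                    label=f"neurostim_maintenance_y{y}",
                )
            )
        p_cure = Param(cure_param("neurostimulation", s.cond))
        return self.node(
            f"neurostim@{s.t}",
            costs=[CostEvent(Param("cost.neurostimulation_course"), s.t, label="neurostim_course")],
            branches=[
                (p_cure, self.cured(s, s.t, costs=maintenance)),
                (Comp(p_cure), on_fail(replace(s, t=s.t + 1, neuro=True))),
            ],
        )

    # -- stress and mixed management

    def manage_stress(self, s: _State) -> Node:
        return self._memoised(("stress", s), lambda: self._manage_stress(s))

    def _manage_stress(self, s: _State) -> Node:
        if s.t > self.horizon - 1:
            return self.symptomatic(s)
        if s.sling:
            return self.colpo_stage(s)
        p_cure = Param(cure_param("sling", s.cond))
        return self.node(
            f"sling@{s.t}",
            costs=[CostEvent(Param("cost.sling"), s.t, label="sling")],
            branches=[
                (p_cure, self.cured(s, s.t)),
                (Comp(p_cure), self.colpo_stage(replace(s, t=s.t + 1, sling=True))),
            ],
        )

    def colpo_stage(self, s: _State) -> Node:
        """Burch colposuspension, unless overactive-bladder treatment was
        given earlier or the horizon has been reached."""
        if s.t > self.horizon - 1 or s.prior_oab:
            return self.symptomatic(s)
        p_cure = Param(cure_param("colposuspension", s.cond))
        return self.node(
            f"colposuspension@{s.t}",
            costs=[CostEvent(Param("cost.colposuspension"), s.t, label="colposuspension")],
            branches=[(p_cure, self.cured(s, s.t)), (Comp(p_cure), self.symptomatic(s))],
        )

    def manage_mixed(self, s: _State) -> Node:
        return self._memoised(("mixed", s), lambda: self._manage_mixed(s))

    def _manage_mixed(self, s: _State) -> Node:
        if s.t > self.horizon - 1:
            return self.symptomatic(s)
        if s.sling:
            return self.colpo_stage(s)
        if s.botox:
            return self.sling_stage(s)
        p_botox = Param("path.choose_botox_prior_to_sling")
        return self.node(
            f"mixed_choice@{s.t}",
            branches=[
                (p_botox, self.botox_cycle(s, self.after_first_mixed_cycle)),
                (Comp(p_botox), self.sling_stage(s)),
            ],
        )

    def after_first_mixed_cycle(self, s: _State) -> Node:
        if s.t > self.horizon - 1:
            return self.symptomatic(s)
        if s.hook:
            return self.second_test(s)
        return self.sling_stage(s)

    def sling_stage(self, s: _State) -> Node:
        return self._memoised(("sling_stage", s), lambda: self._sling_stage(s))

    def _sling_stage(self, s: _State) -> Node:
        if s.t > self.horizon - 1:
            return self.symptomatic(s)
        p_cure = Param(cure_param("sling", s.cond))
        after = replace(s, t=s.t + 1, sling=True)
        if s.hook:
            cont = self.second_test(after)
        else:
            cont = self.colpo_stage(after)
        return self.node(
            f"sling@{s.t}",
            costs=[CostEvent(Param("cost.sling"), s.t, label="sling")],
            branches=[(p_cure, self.cured(s, s.t)), (Comp(p_cure), cont)],
        )

    # -- the second diagnostic test

    def second_test(self, s: _State) -> Node:
        """The strategy's test for a woman who entered untested and whose
        first treatment cycle failed; management switches to the test
        result, skipping treatments already given (at most two tests)."""
        return self._memoised(("test2", s), lambda: self._second_test(s))

    def _second_test(self, s: _State) -> Node:
        s = replace(s, hook=False)
        if s.t > self.horizon - 1:
            return self.symptomatic(s)
        if self.test == "uds":
            return self.wrap_cost(
                f"second_urodynamics@{s.t}",
                [CostEvent(Param("cost.urodynamics"), s.t, label="urodynamics")],
                self.uds_dx(s),
            )
        return self.wrap_cost(
            f"second_ultrasound@{s.t}",
            [CostEvent(Param("cost.ultrasonography"), s.t, label="ultrasound")],
            self.us_dx(s),
        )


def build_strategy_tree(strategy: str, ps: ParameterSet) -> Node:
    """Build the decision tree of one test-treat strategy.

    Probabilities, costs and utilities remain symbolic; resolve them
    with :func:`evaluate` or :func:`enumerate_paths`.
    """
    return _TreeBuilder(strategy, ps).build()


# ---------------------------------------------------------------------------
# evaluation


def _qaly_prefix(econ: EconSettings) -> np.ndarray:
    """prefix[k] = discounted duration of the first k model years."""
    H = econ.horizon_years
    w = [discount_factor(k + 1, econ.discount_rate) for k in range(H)]
    return np.concatenate([[0.0], np.cumsum(w)])


def evaluate(tree: Node, env: dict, econ: EconSettings) -> StrategyOutcome:
    """Expected discounted cost, QALYs and cure probability by recursive
    rollback. ``env`` maps parameter names to scalars or equally shaped
    arrays (one entry per probabilistic iteration)."""
    prefix = _qaly_prefix(econ)
    H = econ.horizon_years
    rate = econ.discount_rate
    memo: dict[int, tuple] = {}

    def rec(n: Node):
        hit = memo.get(n.id)
        if hit is not None:
            return hit
        cost = 0.0
        for ev in n.costs:
            cost = cost + ev.amount.value(env) * ev.weight.value(env) * discount_factor(ev.year, rate)
        if n.is_terminal:
            o = n.outcome
            u_cond = env[utility_param(o.condition)]
            if o.cured:
                cy = min(o.cure_year, H)
                u_cured = env[
                    "util.cured_with_side_effects" if o.side_effects else "util.cured_no_side_effects"
                ]
                q = u_cond * prefix[cy] + u_cured * (prefix[H] - prefix[cy])
                res = (cost, q, 1.0)
            else:
                res = (cost, u_cond * prefix[H], 0.0)
        else:
            q = 0.0
            success = 0.0
            for prob, child in n.branches:
                p = prob.value(env)
                cc, cq, cs = rec(child)
                cost = cost + p * cc
                q = q + p * cq
                success = success + p * cs
            res = (cost, q, success)
        memo[n.id] = res
        return res

    c, q, s = rec(tree)
    return StrategyOutcome(expected_cost=c, expected_qalys=q, p_success=s)


def enumerate_paths(tree: Node, env: dict, econ: EconSettings) -> list[PathRecord]:
    """All root-to-leaf pathways with scalar parameters resolved.

    The probability-weighted sums over paths reproduce
    :func:`evaluate` (used as a verification oracle in the test suite).
    """
    prefix = _qaly_prefix(econ)
    H = econ.horizon_years
    rate = econ.discount_rate
    paths: list[PathRecord] = []
    stack: set[int] = set()

    def walk(n: Node, prob: float, cost: float, trace: tuple[str, ...]):
        if n.id in stack:
            raise ValueError(f"cycle detected through node {n.label!r}")
        stack.add(n.id)
        for ev in n.costs:
            cost += float(ev.amount.value(env)) * float(ev.weight.value(env)) * discount_factor(ev.year, rate)
        trace = trace + (n.label,)
        if n.is_terminal:
            o = n.outcome
            u_cond = float(env[utility_param(o.condition)])
            if o.cured:
                cy = min(o.cure_year, H)
                u_cured = float(
                    env["util.cured_with_side_effects" if o.side_effects else "util.cured_no_side_effects"]
                )
                q = u_cond * prefix[cy] + u_cured * (prefix[H] - prefix[cy])
            else:
                q = u_cond * prefix[H]
            paths.append(PathRecord(prob, cost, float(q), o.cured, trace))
        else:
            for p_expr, child in n.branches:
                walk(child, prob * float(p_expr.value(env)), cost, trace)
        stack.discard(n.id)

    walk(tree, 1.0, 0.0, ())
    return paths


def accrue_qalys(segments, utilities: dict, econ: EconSettings) -> float:
    """Discounted QALYs of an explicit state timeline.

    ``segments`` is an ordered list of (utility key or value, start_year,
    end_year) tiling [0, horizon] without overlap; the first model year
    is undiscounted and later years compound annually.
    """
    prefix = _qaly_prefix(econ)
    H = econ.horizon_years
    expected = 0
    total = 0.0
    for state, start, end in segments:
        if start != expected:
            raise ValueError(f"segments must tile [0, {H}] contiguously; gap/overlap at year {start}")
        if not (0 <= start < end <= H):
            raise ValueError(f"segment ({start}, {end}) outside [0, {H}]")
        u = utilities[state] if isinstance(state, str) else float(state)
        total += u * (prefix[end] - prefix[start])
        expected = end
    if expected != H:
        raise ValueError(f"segments must extend to the horizon ({H} years)")
    return total


# ---------------------------------------------------------------------------
# audit exports


def export_outline(tree: Node) -> str:
    """Indented text outline of a strategy tree for visual audit."""
    lines: list[str] = []

    def walk(n: Node, depth: int, edge: str):
        head = f"{'  ' * depth}{edge}{n.label}"
        if n.costs:
            head += "  {" + ", ".join(f"{ev.label or ev.amount!r}@y{ev.year}" for ev in n.costs) + "}"
        if n.is_terminal:
            o = n.outcome
            head += f"  -> {'cured' if o.cured else 'symptomatic'}"
            if o.cured:
                head += f"(y{o.cure_year}{', side-effects' if o.side_effects else ''})"
        lines.append(head)
        for prob, child in n.branches:
            walk(child, depth + 1, f"[{prob!r}] ")

    walk(tree, 0, "")
    return "\n".join(lines)


def to_dot(tree: Node) -> str:
    """GraphViz DOT rendering of the tree structure."""
    seen: set[int] = set()
    lines = ["digraph strategy {", "  rankdir=LR;", "  node [shape=box, fontsize=9];"]

    def walk(n: Node):
        if n.id in seen:
            return
        seen.add(n.id)
        shape = "oval" if n.is_terminal else "box"
        lines.append(f'  n{n.id} [label="{n.label}", shape={shape}];')
        for prob, child in n.branches:
            walk(child)
            lines.append(f'  n{n.id} -> n{child.id} [label="{prob!r}", fontsize=8];')

    walk(tree)
    lines.append("}")
    return "\n".join(lines)
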