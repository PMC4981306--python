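"""The complete registry of model inputs and the deterministic scenarios.

Parameters live in a flat name space shared by the tree builder, the
base-case evaluator and the probabilistic sensitivity analysis:

``cure.<treatment>.<condition>``
    probability of subjective cure for a treatment given the woman's true
    urodynamic condition (neurostimulation and the implanted
    neurostimulator pool stress and mixed incontinence into one entry);
``path.<name>``
    treatment-pathway probabilities (treatment choice, voiding
    difficulty, implantation, device follow-up);
``cost.<intervention>``
    unit costs, GBP at the 2012-13 price base;
``util.<state>``
    preference-based utilities of health states;
``acc.*`` / ``hist.mixed_given.<condition>`` / ``prev``
    test accuracy, clinical-history classification and diagnosis mix.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .cohort import CONDITIONS
from .distributions import (
    FittedDistribution,
    beta_dist,
    dirichlet_dist,
    dist_mean,
    gamma_dist,
    point_mass,
)

logger = logging.getLogger(__name__)

TREATMENTS = (
    "botulinum",
    "neurostimulation",
    "implanted_neurostimulator",
    "sling",
    "colposuspension",
)

#: conditions that have treatment-specific cure entries
TREATABLE = ("detrusor_overactivity", "stress_incontinence", "mixed_incontinence")

#: treatments that pool stress and mixed incontinence into one cure entry
_POOLED_STRESS_MIXED = ("neurostimulation", "implanted_neurostimulator")

SCENARIOS = (
    "uds_cost_low",
    "sling_cost_double",
    "cure_utility_low",
    "uds_accuracy_low_plus_diary",
    "expert_low",
    "expert_high",
    "single_test_only",
)

_REQUIRED_COSTS = (
    "urodynamics",
    "ultrasonography",
    "botulinum_injection",
    "neurostimulation_course",
    "sling",
    "pne",
    "implant",
    "implant_followup",
    "colposuspension",
    "self_cath_training",
)

_REQUIRED_UTILITIES = (
    "detrusor_overactivity",
    "stress_incontinence",
    "mixed_incontinence",
    "normal_bladder",
    "low_compliance_or_voiding_dysfunction",
    "cured_no_side_effects",
    "cured_with_side_effects",
)

_REQUIRED_PATHWAY = (
    "choose_botox_prior_to_sling",
    "choose_botox_over_neurostim",
    "voiding_difficulty_after_botox",
    "require_implant_after_pne",
    "implant_revision_lt2y",
    "implant_revision_ge2y",
    "implant_maintenance_ge2y",
    "implant_removal",
)


@dataclass(frozen=True)
class EconSettings:
    discount_rate: float = 0.035
    horizon_years: int = 5
    psa_iterations: int = 10_000
    incidence_per_year: int = 54_000
    research_horizon_years: int = 10
    wtp_grid_success: tuple[float, ...] = tuple(np.arange(0, 100_001, 500.0))
    wtp_grid_qaly: tuple[float, ...] = tuple(np.arange(0, 50_001, 250.0))

    def __post_init__(self) -> None:
        if not (0 <= self.discount_rate < 1):
            raise ValueError(f"discount_rate must be in [0, 1), got {self.discount_rate}")
        for name in ("horizon_years", "psa_iterations", "incidence_per_year", "research_horizon_years"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class BotulinumCourse:
    """Up-to-three yearly injections with drop-out between them."""

    dropout_after_1: float = 0.20
    dropout_after_2: float = 0.08
    cure_contributions: tuple[float, float, float] = (0.34, 0.52, 0.14)

    def __post_init__(self) -> None:
        for d in (self.dropout_after_1, self.dropout_after_2):
            if not (0 <= d <= 1):
                raise ValueError("drop-out rates must be in [0, 1]")
        if abs(sum(self.cure_contributions) - 1.0) > 1e-9:
            raise ValueError("cure contributions must sum to 1")

    @property
    def uptake(self) -> tuple[float, float, float]:
        """Probability of undergoing injections 1, 2 and 3."""
        u2 = 1 - self.dropout_after_1
        return (1.0, u2, u2 * (1 - self.dropout_after_2))


@dataclass
class ParameterSet:
    dists: dict[str, FittedDistribution]
    econ: EconSettings
    course: BotulinumCourse = field(default_factory=BotulinumCourse)
    second_test_enabled: bool = True
    bwt_threshold_mm: float = 5.0
    reference_positive_includes_mixed: bool = False
    expert_cure_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    scenario_settings: dict = field(default_factory=dict)
    price_year: str = "2012-13"

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def cure_param(treatment: str, condition: str) -> str:
    """Flat parameter name of P(cure | treatment, true condition).

    Misdiagnosed women with a normal bladder, low compliance only, or
    voiding dysfunction only use the most conservative elicited estimate
    (the botulinum / stress entry) as a proxy for any intervention.
    """
    if treatment not in TREATMENTS:
        raise KeyError(f"unknown treatment {treatment!r}")
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}")
    if condition not in TREATABLE:
        return "cure.botulinum.stress_incontinence"
    if treatment in _POOLED_STRESS_MIXED and condition in (
        "stress_incontinence",
        "mixed_incontinence",
    ):
        return f"cure.{treatment}.stress_or_mixed"
    return f"cure.{treatment}.{condition}"


def utility_param(condition: str) -> str:
    if condition in ("low_compliance_only", "voiding_dysfunction_only"):
        return "util.low_compliance_or_voiding_dysfunction"
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}")
    return f"util.{condition}"


def _parse_dist(entry: dict, key: str) -> FittedDistribution:
    if not isinstance(entry, dict) or "dist" not in entry:
        raise ValueError(f"{key}: expected a mapping with a 'dist' field, got {entry!r}")
    kind = entry["dist"]
    try:
        if kind == "beta":
            return beta_dist(float(entry["alpha"]), float(entry["beta"]))
        if kind == "gamma":
            return gamma_dist(float(entry["shape"]), float(entry["scale"]))
        if kind == "point":
            return point_mass(float(entry["value"]))
        if kind == "dirichlet":
            conc = entry["concentrations"]
            if isinstance(conc, dict):
                missing = [c for c in CONDITIONS if c not in conc]
                if missing:
                    raise ValueError(f"missing categories {missing}")
                conc = [conc[c] for c in CONDITIONS]
            return dirichlet_dist([float(c) for c in conc])
    except KeyError as exc:
        raise ValueError(f"{key}: missing field {exc}") from exc
    except ValueError as exc:
        raise ValueError(f"{key}: {exc}") from exc
    raise ValueError(f"{key}: unknown distribution kind {kind!r}")


def load_parameters(source=None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a YAML config.

    ``source`` may be a path, a pre-parsed mapping, or ``None`` for the
    packaged default configuration. Synthetic accuracy/prevalence blocks
    (stand-ins for the undeposited primary-study tables) are flagged
    with a logged warning.
    """
    if source is None:
        with resources.files("oabtree.config").joinpath("default.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    elif isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        raw = yaml.safe_load(Path(source).read_text())

    if int(raw.get("schema_version", 1)) != 1:
        raise ValueError(f"unsupported schema_version {raw.get('schema_version')!r}")

    dists: dict[str, FittedDistribution] = {}
    expert_bounds: dict[str, tuple[float, float]] = {}

    def need(section: str) -> dict:
        if section not in raw:
            raise ValueError(f"config missing required section {section!r}")
        return raw[section]

    for treatment, entries in need("cure_probabilities").items():
        if treatment not in TREATMENTS:
            raise ValueError(f"cure_probabilities: unknown treatment {treatment!r}")
        for cond, entry in entries.items():
            key = f"cure.{treatment}.{cond}"
            dists[key] = _parse_dist(entry, key)
            m = dist_mean(dists[key])
            if not (0 < m < 1):
                raise ValueError(f"{key}: mean {m} outside (0, 1)")
            if entry.get("expert"):
                ci = entry.get("ci")
                if not ci or len(ci) != 2:
                    raise ValueError(f"{key}: expert row needs a 'ci: [low, high]' field")
                expert_bounds[key] = (float(ci[0]), float(ci[1]))

    pathway = need("pathway_probabilities")
    for name in _REQUIRED_PATHWAY:
        if name not in pathway:
            raise ValueError(f"pathway_probabilities missing {name!r}")
        key = f"path.{name}"
        dists[key] = _parse_dist(pathway[name], key)

    costs = need("costs")
    for name in _REQUIRED_COSTS:
        if name not in costs:
            raise ValueError(f"costs missing {name!r}")
        key = f"cost.{name}"
        dists[key] = _parse_dist(costs[name], key)
        if dist_mean(dists[key]) <= 0:
            raise ValueError(f"{key}: cost mean must be positive")

    utilities = need("utilities")
    for name in _REQUIRED_UTILITIES:
        if name not in utilities:
            raise ValueError(f"utilities missing {name!r}")
        key = f"util.{name}"
        dists[key] = _parse_dist(utilities[name], key)
        if not (0 < dist_mean(dists[key]) <= 1):
            raise ValueError(f"{key}: utility mean must be in (0, 1]")

    acc = need("accuracy")
    if acc.get("synthetic"):
        logger.warning(
            "accuracy block is a synthetic stand-in for the primary study's "
            "undeposited supplementary tables"
        )
    for name in ("bwt_sensitivity", "bwt_specificity", "uds_sensitivity"):
        if name not in acc:
            raise ValueError(f"accuracy missing {name!r}")
        dists[f"acc.{name}"] = _parse_dist(acc[name], f"acc.{name}")
    hist = acc.get("history_mixed_given", {})
    for cond in CONDITIONS:
        if cond not in hist:
            raise ValueError(f"accuracy.history_mixed_given missing {cond!r}")
        key = f"hist.mixed_given.{cond}"
        dists[key] = _parse_dist(hist[cond], key)

    prev = need("prevalence")
    if prev.get("synthetic"):
        logger.warning("prevalence block is a synthetic stand-in")
    dists["prev"] = _parse_dist(
        {"dist": "dirichlet", "concentrations": prev["concentrations"]}, "prevalence"
    )

    eco = raw.get("economics", {})

    def grid(spec, default):
        if spec is None:
            return default
        return tuple(np.arange(spec["start"], spec["stop"] + spec["step"] / 2, spec["step"], dtype=float))

    econ = EconSettings(
        discount_rate=float(eco.get("discount_rate", 0.035)),
        horizon_years=int(eco.get("horizon_years", 5)),
        psa_iterations=int(eco.get("psa_iterations", 10_000)),
        incidence_per_year=int(eco.get("incidence_per_year", 54_000)),
        research_horizon_years=int(eco.get("research_horizon_years", 10)),
        wtp_grid_success=grid(eco.get("wtp_grid_success"), EconSettings().wtp_grid_success),
        wtp_grid_qaly=grid(eco.get("wtp_grid_qaly"), EconSettings().wtp_grid_qaly),
    )

    course_cfg = raw.get("botulinum_course", {})
    course = BotulinumCourse(
        dropout_after_1=float(course_cfg.get("dropout_after_1", 0.20)),
        dropout_after_2=float(course_cfg.get("dropout_after_2", 0.08)),
        cure_contributions=tuple(course_cfg.get("cure_contributions", (0.34, 0.52, 0.14))),
    )

    options = raw.get("model_options", {})
    return ParameterSet(
        dists=dists,
        econ=econ,
        course=course,
        second_test_enabled=bool(options.get("second_test_enabled", True)),
        bwt_threshold_mm=float(acc.get("bwt_threshold_mm", 5.0)),
        reference_positive_includes_mixed=bool(acc.get("reference_positive_includes_mixed", False)),
        expert_cure_bounds=expert_bounds,
        scenario_settings=raw.get("scenario_settings", {}),
        price_year=str(raw.get("price_year", "2012-13")),
    )


def point_estimates(ps: ParameterSet) -> dict[str, float]:
    """Collapse every distribution to its analytic mean.

    The Dirichlet prevalence expands to one ``prev.<condition>`` entry
    per category. Idempotent and deterministic.
    """
    env: dict[str, float] = {}
    for name, d in ps.dists.items():
        m = dist_mean(d)
        if isinstance(m, tuple):
            for cond, v in zip(CONDITIONS, m):
                env[f"{name}.{cond}"] = float(v)
        else:
            env[name] = float(m)
    return env


def as_point_masses(ps: ParameterSet) -> ParameterSet:
    """Copy of the parameter set with every distribution degenerate at its
    analytic mean (used for deterministic checks of the probabilistic
    machinery)."""
    out = ps.copy()
    for name, d in ps.dists.items():
        out.dists[name] = point_mass(dist_mean(d))
    return out


def expected_botulinum_course_cost(
    unit_cost: float, dropout_after_1: float = 0.20, dropout_after_2: float = 0.08
) -> float:
    """Expected cost of an up-to-three-injection course.

    Every woman receives injection 1; injection 2 with probability
    1 - dropout_after_1 and injection 3 with probability
    (1 - dropout_after_1)(1 - dropout_after_2). Undiscounted.
    """
    if unit_cost <= 0:
        raise ValueError("unit cost must be positive")
    for d in (dropout_after_1, dropout_after_2):
        if not (0 <= d <= 1):
            raise ValueError("drop-out rates must lie in [0, 1]")
    u2 = 1 - dropout_after_1
    return unit_cost * (1 + u2 + u2 * (1 - dropout_after_2))


def apply_scenario(ps: ParameterSet, scenario_id: str) -> ParameterSet:
    """Return a modified copy of the parameter set for one deterministic
    sensitivity scenario. The input is never mutated."""
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}; valid ids: {', '.join(SCENARIOS)}")
    out = ps.copy()
    settings = ps.scenario_settings

    if scenario_id == "uds_cost_low":
        out.dists["cost.urodynamics"] = point_mass(float(settings.get("uds_cost_low_mean", 173)))
    elif scenario_id == "sling_cost_double":
        d = ps.dists["cost.sling"]
        if d.kind == "gamma":
            out.dists["cost.sling"] = gamma_dist(d.params.shape, d.params.scale * 2)
        else:
            out.dists["cost.sling"] = point_mass(2 * float(dist_mean(d)))
    elif scenario_id == "cure_utility_low":
        out.dists["util.cured_no_side_effects"] = point_mass(
            float(settings.get("cured_utility_low", 0.84))
        )
    elif scenario_id == "uds_accuracy_low_plus_diary":
        out.dists["acc.uds_sensitivity"] = point_mass(
            float(settings.get("uds_sensitivity_low", 0.90))
        )
        diary = settings.get("history_with_diary_mixed_given", {})
        for cond in CONDITIONS:
            if cond in diary:
                out.dists[f"hist.mixed_given.{cond}"] = point_mass(float(diary[cond]))
    elif scenario_id in ("expert_low", "expert_high"):
        i = 0 if scenario_id == "expert_low" else 1
        for key, bounds in ps.expert_cure_bounds.items():
            out.dists[key] = point_mass(bounds[i])
    elif scenario_id == "single_test_only":
        out.second_test_enabled = False
    return out
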