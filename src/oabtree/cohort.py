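"""Synthetic cross-sectional cohorts of women with refractory urgency symptoms.

The test-accuracy and prevalence inputs of the decision model come from a
primary cross-sectional study in which every woman received both bladder
ultrasonography (bladder wall thickness, BWT, positive at >= 5 mm) and
reference-standard urodynamics. The individual-level data are not
publicly deposited, so this module generates cohorts with the same
structure and known ground truth: a true urodynamic diagnosis, a BWT
measurement, a clinical-history label (urgency only vs mixed symptoms),
and a baseline utility. Accuracy and prevalence estimated from a
generated cohort feed the model exactly as the study estimates would.

All default numeric values here are synthetic stand-ins, calibrated only
to two in-text anchors of the source setting: detrusor overactivity (DO)
is the most prevalent urodynamic finding, and about 52% of women report
mixed symptoms on clinical history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .distributions import DirichletParams

CONDITIONS = (
    "detrusor_overactivity",
    "stress_incontinence",
    "mixed_incontinence",
    "normal_bladder",
    "low_compliance_only",
    "voiding_dysfunction_only",
)

#: Default true-diagnosis mix (synthetic; DO most prevalent).
DEFAULT_MIX = (0.40, 0.15, 0.15, 0.20, 0.05, 0.05)

#: P(clinical history = mixed | true diagnosis); weighted by DEFAULT_MIX
#: these give an overall mixed-history rate of exactly 0.52.
DEFAULT_P_HISTORY_MIXED = (0.40, 0.70, 0.78, 0.44, 0.50, 0.50)

#: Log-normal BWT per category: (median mm, sigma of log). Right-skewed and
#: strictly positive; DO walls thickest. Implies sensitivity ~0.40 and
#: specificity ~0.79 at the 5 mm threshold.
DEFAULT_BWT = (
    (4.7, 0.25),
    (4.0, 0.25),
    (4.4, 0.25),
    (3.9, 0.25),
    (4.1, 0.25),
    (4.2, 0.25),
)

#: Baseline utility Beta(alpha, beta) per category, matching the reported
#: condition utilities of the modelled population.
DEFAULT_UTILITY = (
    (8.96, 5.98),
    (18.92, 9.75),
    (49.12, 19.29),
    (22.13, 11.61),
    (11.76, 4.05),
    (11.76, 4.05),
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_women: int = 209
    mix: tuple[float, ...] = DEFAULT_MIX
    p_history_mixed: tuple[float, ...] = DEFAULT_P_HISTORY_MIXED
    bwt: tuple[tuple[float, float], ...] = DEFAULT_BWT
    utility: tuple[tuple[float, float], ...] = DEFAULT_UTILITY
    bwt_family: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        if len(self.mix) != len(CONDITIONS):
            raise ValueError(f"mix needs {len(CONDITIONS)} entries")
        if any(p < 0 for p in self.mix) or abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError(f"mix must be a probability vector, got {self.mix}")
        if self.bwt_family not in ("lognormal", "gamma"):
            raise ValueError(f"unsupported BWT family {self.bwt_family!r}")
        if any(s <= 0 or m <= 0 for m, s in self.bwt):
            raise ValueError("BWT locations and scales must be positive")


@dataclass(frozen=True)
class AccuracyEstimate:
    """2x2 accuracy summary of BWT >= threshold against urodynamic DO."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    threshold_mm: float = 5.0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def generate_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Simulate one cohort; reproducible for a given config (incl. seed).

    Returns a data frame with columns ``true_diagnosis``, ``bwt_mm``,
    ``history_label`` and ``baseline_utility``, one row per woman.
    """
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(len(CONDITIONS), size=cfg.n_women, p=np.asarray(cfg.mix))

    bwt = np.empty(cfg.n_women)
    util = np.empty(cfg.n_women)
    for k in range(len(CONDITIONS)):
        m = idx == k
        if not m.any():
            continue
        loc, scale = cfg.bwt[k]
        if cfg.bwt_family == "lognormal":
            bwt[m] = rng.lognormal(math.log(loc), scale, size=m.sum())
        else:  # gamma parameterised by (mean, coefficient of variation)
            shape = 1.0 / scale**2
            bwt[m] = rng.gamma(shape, loc / shape, size=m.sum())
        a, b = cfg.utility[k]
        util[m] = rng.beta(a, b, size=m.sum())

    p_mixed = np.asarray(cfg.p_history_mixed)[idx]
    mixed = rng.random(cfg.n_women) < p_mixed
    return pd.DataFrame(
        {
            "true_diagnosis": pd.Categorical.from_codes(idx, categories=list(CONDITIONS)),
            "bwt_mm": bwt,
            "history_label": np.where(mixed, "mixed", "urgency_only"),
            "baseline_utility": util,
        }
    )


def implied_accuracy(
    cfg: GeneratorConfig,
    threshold_mm: float = 5.0,
    reference_positive: frozenset[str] | set[str] = frozenset({"detrusor_overactivity"}),
) -> tuple[float, float]:
    """Closed-form (sensitivity, specificity) implied by the generator.

    Tail probabilities beyond the threshold come from the per-category
    BWT distribution; specificity pools reference-negative categories by
    their mix weights. Used as the oracle for parameter-recovery tests.
    """
    from scipy import stats as sps

    tails = []
    for (loc, scale) in cfg.bwt:
        if cfg.bwt_family == "lognormal":
            tails.append(sps.lognorm(s=scale, scale=loc).sf(threshold_mm))
        else:
            shape = 1.0 / scale**2
            tails.append(sps.gamma(shape, scale=loc / shape).sf(threshold_mm))
    pos = [c in reference_positive for c in CONDITIONS]
    w = np.asarray(cfg.mix)
    p_pos = np.asarray(tails)
    sens = float((w[pos] * p_pos[pos]).sum() / w[pos].sum())
    neg = [not p for p in pos]
    spec = float((w[neg] * (1 - p_pos[neg])).sum() / w[neg].sum())
    return sens, spec


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    if nobs == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return (float(lo), float(hi))


def estimate_accuracy(
    cohort: pd.DataFrame,
    threshold_mm: float = 5.0,
    reference_positive: frozenset[str] | set[str] = frozenset({"detrusor_overactivity"}),
) -> AccuracyEstimate:
    """2x2 accuracy of the BWT index test against the urodynamic reference.

    Index positive iff ``bwt_mm >= threshold_mm``; reference positive iff
    the true diagnosis is in ``reference_positive``. Wilson 95% intervals
    are attached to each proportion.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    index_pos = cohort["bwt_mm"].to_numpy() >= threshold_mm
    ref_pos = cohort["true_diagnosis"].isin(reference_positive).to_numpy()
    tp = int((index_pos & ref_pos).sum())
    fp = int((index_pos & ~ref_pos).sum())
    fn = int((~index_pos & ref_pos).sum())
    tn = int((~index_pos & ~ref_pos).sum())

    def prop(num, den):
        return num / den if den else float("nan")

    return AccuracyEstimate(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=prop(tp, tp + fn),
        specificity=prop(tn, tn + fp),
        ppv=prop(tp, tp + fp),
        npv=prop(tn, tn + fn),
        sensitivity_ci=_wilson(tp, tp + fn),
        specificity_ci=_wilson(tn, tn + fp),
        ppv_ci=_wilson(tp, tp + fp),
        npv_ci=_wilson(tn, tn + fn),
        threshold_mm=threshold_mm,
    )


def estimate_prevalence(
    cohort: pd.DataFrame,
    stratify_by_history: bool = False,
    *,
    add_one_smoothing: bool = False,
):
    """Dirichlet prevalence over the six urodynamic categories.

    Concentrations are the observed counts (optionally +1 smoothed).
    With ``stratify_by_history`` a dict keyed by history label is
    returned; each stratum must be non-empty.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    offset = 1 if add_one_smoothing else 0

    def counts_to_dirichlet(sub: pd.DataFrame) -> DirichletParams:
        counts = sub["true_diagnosis"].value_counts().reindex(list(CONDITIONS), fill_value=0)
        conc = tuple(float(c + offset) for c in counts)
        if any(c <= 0 for c in conc):
            raise ValueError(
                "zero count in a category; use add_one_smoothing=True for a proper Dirichlet"
            )
        return DirichletParams(conc)

    if not stratify_by_history:
        return counts_to_dirichlet(cohort)
    out = {}
    for label in ("urgency_only", "mixed"):
        sub = cohort[cohort["history_label"] == label]
        if len(sub) == 0:
            raise ValueError(f"history stratum {label!r} is empty")
        out[label] = counts_to_dirichlet(sub)
    return out


def history_mixed_counts(cohort: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per-diagnosis (mixed, urgency_only) history counts."""
    out = {}
    for cond in CONDITIONS:
        sub = cohort[cohort["true_diagnosis"] == cond]
        mixed = int((sub["history_label"] == "mixed").sum())
        out[cond] = (mixed, len(sub) - mixed)
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"true_diagnosis", "bwt_mm", "history_label", "baseline_utility"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"cohort file lacks columns: {sorted(missing)}")
    df["true_diagnosis"] = pd.Categorical(df["true_diagnosis"], categories=list(CONDITIONS))
    return df
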