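"""Propagation of linkage misclassification into apparent screening accuracy.

When cancer status is ascertained by linking a screening roster to a
registry, an imperfect link misclassifies the outcome: a missed link turns
a true case into an apparent non-case (linkage sensitivity Se_m < 1) and a
spurious link turns a non-case into an apparent case (linkage specificity
Sp_m < 1).  Assuming linkage errors are independent of the screening
result, the apparent accuracy of the screening test follows in closed form
from the expected 2x2x2 cross-tabulation of (true disease, screen result,
linked status):

    apparent Se = [p Se_m Se_s + (1-p)(1-Sp_m)(1-Sp_s)]
                  / [p Se_m + (1-p)(1-Sp_m)]
    apparent Sp = [p (1-Se_m)(1-Se_s) + (1-p) Sp_m Sp_s]
                  / [p (1-Se_m) + (1-p) Sp_m]
    apparent PPV = [p Se_s Se_m + (1-p)(1-Sp_s)(1-Sp_m)]
                   / [p Se_s + (1-p)(1-Sp_s)]

with p the disease incidence over the follow-up window, Se_s/Sp_s the true
screening accuracy.  Two boundary identities follow immediately: perfect
linkage sensitivity leaves apparent specificity unchanged, and perfect
linkage specificity leaves apparent sensitivity unchanged.  Cohort size
cancels everywhere — the apparent values depend only on rates.

The same outcome-misclassification algebra attenuates cohort risk ratios
and case-control odds ratios toward the null when linkage specificity is
imperfect; those generalizations are provided here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

__all__ = [
    "ScreeningScenario",
    "MatchingScenario",
    "ApparentAccuracy",
    "UndefinedMetricError",
    "apparent_screening_accuracy",
    "true_ppv",
    "apparent_cohort_rr",
    "apparent_case_control_or",
    "scenario_table",
    "DEFAULT_PREVALENCE",
]

# National average cancer incidence used in the built-in scenarios:
# 775.7 per 100,000 person-years.
DEFAULT_PREVALENCE = 775.7 / 100_000


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for the given scenario."""


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value}")


@dataclass(frozen=True)
class ScreeningScenario:
    """True accuracy of the screening test and disease incidence.

    Fractions, not percents.  ``cohort_size`` is presentational only: the
    apparent accuracies are invariant to it.
    """

    se_s: float
    sp_s: float
    prevalence: float = DEFAULT_PREVALENCE
    cohort_size: int = 1000

    def __post_init__(self) -> None:
        _check_fraction("se_s", self.se_s)
        _check_fraction("sp_s", self.sp_s)
        _check_fraction("prevalence", self.prevalence)


@dataclass(frozen=True)
class MatchingScenario:
    """Linkage (matching) sensitivity and specificity, as fractions."""

    se_m: float
    sp_m: float

    def __post_init__(self) -> None:
        _check_fraction("se_m", self.se_m)
        _check_fraction("sp_m", self.sp_m)


@dataclass(frozen=True)
class ApparentAccuracy:
    """Apparent screening accuracy (percents) under imperfect linkage.

    ``sensitivity_unaffected`` / ``specificity_unaffected`` flag the exact
    boundary identities (Sp_m = 1 leaves sensitivity at its true value;
    Se_m = 1 leaves specificity at its true value), rendered "NA" in the
    scenario table.
    """

    sensitivity: float
    specificity: float
    ppv: float
    sensitivity_unaffected: bool
    specificity_unaffected: bool


def apparent_screening_accuracy(
    s: ScreeningScenario, m: MatchingScenario
) -> ApparentAccuracy:
    """Apparent screening Se/Sp/PPV (percents, 2 decimals) under linkage error."""
    p = s.prevalence
    se_s, sp_s = s.se_s, s.sp_s
    se_m, sp_m = m.se_m, m.sp_m

    linked_pos = p * se_m + (1 - p) * (1 - sp_m)  # apparent cases
    linked_neg = p * (1 - se_m) + (1 - p) * sp_m  # apparent non-cases
    screen_pos = p * se_s + (1 - p) * (1 - sp_s)  # positive screens
    if linked_pos <= 0 or linked_neg <= 0 or screen_pos <= 0:
        raise UndefinedMetricError(
            "degenerate scenario: an apparent-status or screen-positive stratum is empty"
        )

    app_se = (p * se_m * se_s + (1 - p) * (1 - sp_m) * (1 - sp_s)) / linked_pos
    app_sp = (p * (1 - se_m) * (1 - se_s) + (1 - p) * sp_m * sp_s) / linked_neg
    app_ppv = (p * se_s * se_m + (1 - p) * (1 - sp_s) * (1 - sp_m)) / screen_pos

    return ApparentAccuracy(
        sensitivity=round_half_up(100 * app_se, 2),
        specificity=round_half_up(100 * app_sp, 2),
        ppv=round_half_up(100 * app_ppv, 2),
        sensitivity_unaffected=(sp_m == 1.0),
        specificity_unaffected=(se_m == 1.0),
    )


def true_ppv(s: ScreeningScenario, ndigits: int = 1) -> float:
    """True positive predictive value of screening, in percent.

    100 * p*Se_s / (p*Se_s + (1-p)(1-Sp_s)); printed to 1 decimal by
    convention in the scenario table.
    """
    if s.prevalence <= 0:
        raise UndefinedMetricError("PPV undefined at zero prevalence")
    num = s.prevalence * s.se_s
    den = num + (1 - s.prevalence) * (1 - s.sp_s)
    if den == 0:
        raise UndefinedMetricError("no screen positives: PPV undefined")
    return round_half_up(100 * num / den, ndigits)


def _apparent_incidence(incidence: float, m: MatchingScenario) -> float:
    return incidence * m.se_m + (1 - incidence) * (1 - m.sp_m)


def apparent_cohort_rr(
    true_rr: float, baseline_incidence: float, m: MatchingScenario
) -> float:
    """Apparent cohort risk ratio under outcome misclassification by linkage.

    Each arm's apparent incidence is I' = I*Se_m + (1-I)(1-Sp_m).  Reduced
    linkage sensitivity alone (Sp_m = 1) scales both arms equally and
    leaves the risk ratio untouched; reduced linkage specificity adds the
    same false-positive floor to both arms and attenuates the ratio toward 1.
    """
    if not 0 < baseline_incidence < 1:
        raise ValueError("baseline incidence must be in (0, 1)")
    if true_rr <= 0 or true_rr * baseline_incidence > 1:
        raise ValueError("true_rr * baseline_incidence must lie in (0, 1]")
    i0 = baseline_incidence
    i1 = true_rr * baseline_incidence
    a0 = _apparent_incidence(i0, m)
    a1 = _apparent_incidence(i1, m)
    if a0 <= 0:
        raise UndefinedMetricError("apparent baseline incidence is zero")
    return a1 / a0


def apparent_case_control_or(
    true_or: float, control_exposure: float, m: MatchingScenario
) -> float:
    """Apparent case-control odds ratio under exposure misclassification.

    Exposure status obtained by linkage is misclassified identically in the
    case and control arms: e' = e*Se_m + (1-e)(1-Sp_m).  Non-differential
    misclassification attenuates the odds ratio toward 1 (equal arms
    transform equally, so OR = 1 is a fixed point).
    """
    if not 0 < control_exposure < 1:
        raise ValueError("control exposure prevalence must be in (0, 1)")
    if true_or <= 0:
        raise ValueError("true odds ratio must be positive")
    odds_control = control_exposure / (1 - control_exposure)
    odds_case = true_or * odds_control
    case_exposure = odds_case / (1 + odds_case)
    e_case = _apparent_incidence(case_exposure, m)
    e_ctrl = _apparent_incidence(control_exposure, m)
    if not (0 < e_case < 1 and 0 < e_ctrl < 1):
        raise UndefinedMetricError("apparent exposure prevalence degenerate")
    return (e_case / (1 - e_case)) / (e_ctrl / (1 - e_ctrl))


# Built-in scenario grid: (matching Se %, matching Sp %, experimental row?)
# crossed with true screening accuracy (90%, 90%) and (60%, 90%).  The two
# experimental rows carry the accuracies observed in the breast-cancer
# matching experiment; for those, values are printed even where a boundary
# identity applies.
_GRID: tuple[tuple[float, float, bool], ...] = (
    (90.0, 100.0, False),
    (85.0, 100.0, False),
    (50.0, 100.0, False),
    (100.0, 99.99, False),
    (100.0, 99.90, False),
    (100.0, 99.80, False),
    (88.71, 99.80, True),
    (82.26, 100.0, True),
)


def scenario_table(
    scenarios: Sequence[ScreeningScenario] | None = None,
    grid: Sequence[tuple[float, float, bool]] = _GRID,
) -> list[dict]:
    """The 16-row scenario grid of apparent accuracy under linkage error.

    One row per (matching scenario, screening scenario); identity cells are
    reported as None (printed "NA") except in experimental rows.  Columns
    mirror the standard presentation: matching Se/Sp, true and estimated
    screening Se, Sp and PPV.
    """
    if scenarios is None:
        scenarios = (
            ScreeningScenario(se_s=0.9, sp_s=0.9),
            ScreeningScenario(se_s=0.6, sp_s=0.9),
        )
    rows = []
    for s in scenarios:
        for se_m_pct, sp_m_pct, experimental in grid:
            m = MatchingScenario(se_m=se_m_pct / 100, sp_m=sp_m_pct / 100)
            app = apparent_screening_accuracy(s, m)
            show_se = experimental or not app.sensitivity_unaffected
            show_sp = experimental or not app.specificity_unaffected
            rows.append(
                {
                    "matching_sensitivity": se_m_pct,
                    "matching_specificity": sp_m_pct,
                    "screening_sensitivity_true": round_half_up(100 * s.se_s, 2),
                    "screening_sensitivity_estimate": app.sensitivity if show_se else None,
                    "screening_specificity_true": round_half_up(100 * s.sp_s, 2),
                    "screening_specificity_estimate": app.specificity if show_sp else None,
                    "ppv_true": true_ppv(s),
                    "ppv_estimate": app.ppv,
                    "experimental": experimental,
                }
            )
    return rows
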