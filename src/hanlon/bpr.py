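"""Basic Priority Rating (BPR) scoring for health-program prioritization.

The Hanlon method assigns each health problem a Basic Priority Rating on a
0-100 scale from a small set of rated components and ranks problems by that
score.  This module implements the four equations of the method family:

* original Hanlon:      BPR = (A + B) * C / 3 * D
* Vilnius-Dandoy:       BPR = (A + B) * (C + BC) / 6 * D
* Neiger (PEARL as a pre-screen, dropped from the equation):
                        BPR = (A + B) * C / 3
* PAHO-adapted:         BPR = (A + B + E) * C / 5.25 * F

with components

* A  - size of the problem, 0-10 points (prevalence/incidence for disease
       programs; extent of system or coverage deficiency for non-disease
       programs, every program being framed as a problem),
* B  - seriousness, 0-20 points, the sum of four 0-5 factors: urgency (B1),
       severity of consequences (B2), economic loss (B3), and negative
       impact on others (B4, the negative-externality criterion),
* C  - effectiveness of intervention, 0-10 points, either a direct rating
       or the product of efficacy (C1, %) and reach (C2, %),
* D  - PEARL feasibility gate: the product of five binary flags
       (Propriety, Economics, Acceptability, Resources, Legality),
* BC - benefit-cost rating, 0-10 points (Vilnius-Dandoy only),
* E  - inequity, 0-5 points (PAHO only),
* F  - institutional positioning, a 0.67-1.50 multiplier with neutral
       value 1.00 (PAHO only; the bounds are reciprocal, 1/1.5 ~= 0.67).

Each divisor normalizes the maximal attainable product to 100.

On top of the pure equations the module provides the surrounding workflow:
multi-rater panel aggregation (mean components, as in the PAHO pilot
tests), competition ranking, high/medium/low tier stratification,
rank-concordance sensitivity analysis (method comparison, trial F ranges,
one-at-a-time perturbation), a synthetic rater-panel generator for
validation, and a delimiter-separated scoring-template reader/writer.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from statistics import median
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    # configuration / errors
    "METHODS",
    "F_MIN",
    "F_MAX",
    "F_INPUT_TOLERANCE",
    "ValidationError",
    "ConfigError",
    "TemplateError",
    # domain types
    "SeriousnessFactors",
    "Effectiveness",
    "PearlFlags",
    "ComponentScores",
    "BprScore",
    "Program",
    "RaterPanel",
    "PriorityResult",
    "SensitivityReport",
    "PanelScenario",
    "RecoverySummary",
    # scoring
    "effectiveness_value",
    "benefit_cost_from_quotient",
    "pearl_screen",
    "screen_programs",
    "bpr_original",
    "bpr_vilnius",
    "bpr_neiger",
    "bpr_paho",
    "compute_bpr",
    # catalog / fixtures
    "PROGRAM_CATALOG",
    "PILOT_CONSENSUS",
    "pilot_consensus_panel",
    "pilot_template_path",
    # panel aggregation
    "aggregate_panel",
    "rank_results",
    "stratify_tiers",
    "score_panel",
    # sensitivity analysis
    "compare_methods",
    "f_range_experiment",
    "perturb_components",
    # synthetic panels
    "generate_panel",
    "ranking_recovery_experiment",
    # template I/O
    "components_from_mapping",
    "read_template",
    "write_template",
    "write_results",
    "results_table",
]

logger = logging.getLogger("hanlon")

# --------------------------------------------------------------------------
# Configuration: methods, component ranges, tolerances
# --------------------------------------------------------------------------

METHODS = ("original", "vilnius", "neiger", "paho")
MethodName = Literal["original", "vilnius", "neiger", "paho"]

#: Exact institutional-positioning bounds: the maximum multiplier is 1.5 and
#: the minimum is its reciprocal 2/3.  Templates conventionally print the
#: minimum as 0.67, so validation accepts inputs down to 2/3 - 0.005.
F_MIN = 2.0 / 3.0
F_MAX = 1.5
F_INPUT_TOLERANCE = 0.005

#: (low, high) legal range per individually rated quantity.
COMPONENT_RANGES: dict[str, tuple[float, float]] = {
    "A": (0.0, 10.0),
    "B": (0.0, 20.0),
    "B1": (0.0, 5.0),
    "B2": (0.0, 5.0),
    "B3": (0.0, 5.0),
    "B4": (0.0, 5.0),
    "C": (0.0, 10.0),
    "C1": (0.0, 100.0),
    "C2": (0.0, 100.0),
    "E": (0.0, 5.0),
    "F": (F_MIN, F_MAX),
    "BC": (0.0, 10.0),
}

#: Absolute tolerance for bound checks and internal consistency checks.
BOUND_TOL = 1e-9

#: Recommended minimum panel size for an official national scoring session.
RECOMMENDED_MIN_RATERS = 6


class ValidationError(ValueError):
    """A component score violates its legal range or a method precondition."""


class ConfigError(ValueError):
    """An analysis option (tier cutoffs, F bounds, component name) is invalid."""


class TemplateError(ValueError):
    """A scoring template is malformed: missing columns, bad cells, bad ids."""


def _check_range(name: str, value: float, low: float, high: float,
                 *, slack: float = 0.0) -> float:
    value = float(value)
    if not math.isfinite(value) or value < low - slack - BOUND_TOL \
            or value > high + BOUND_TOL:
        raise ValidationError(
            f"{name}={value!r} outside legal range [{low:g}, {high:g}]")
    return value


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriousnessFactors:
    """The four 0-5 seriousness factors whose sum is component B (0-20).

    Attributes
    ----------
    urgency_b1
        Trend of the problem over the previous five years (worsening scores
        high).
    severity_b2
        Premature mortality, disability, quality-of-life loss or service
        burden.
    economic_loss_b3
        Direct and indirect social costs of the problem.
    negative_impact_b4
        Negative impact on other people or countries (negative externality).
    """

    urgency_b1: float
    severity_b2: float
    economic_loss_b3: float
    negative_impact_b4: float

    def __post_init__(self) -> None:
        for name in ("urgency_b1", "severity_b2",
                     "economic_loss_b3", "negative_impact_b4"):
            _check_range(name, getattr(self, name), 0.0, 5.0)

    def total(self) -> float:
        """Component B: the sum of the four factors, in [0, 20]."""
        return (self.urgency_b1 + self.severity_b2
                + self.economic_loss_b3 + self.negative_impact_b4)


@dataclass(frozen=True)
class Effectiveness:
    """Component C (0-10): direct rating or efficacy x reach product.

    Exactly one mode must be populated: either ``direct_rating`` (0-10
    points, the qualitative assessment recommended for non-disease
    programs) or both percentages ``efficacy_c1`` and ``reach_c2``
    (0-100 each), whose product rescales to 0-10.
    """

    direct_rating: float | None = None
    efficacy_c1: float | None = None
    reach_c2: float | None = None

    def __post_init__(self) -> None:
        direct = self.direct_rating is not None
        factored = self.efficacy_c1 is not None or self.reach_c2 is not None
        if direct and factored:
            raise ValidationError(
                "effectiveness must be either a direct_rating or an "
                "efficacy_c1/reach_c2 pair, not both")
        if direct:
            _check_range("direct_rating", self.direct_rating, 0.0, 10.0)
        else:
            if self.efficacy_c1 is None or self.reach_c2 is None:
                raise ValidationError(
                    "factored effectiveness requires both efficacy_c1 and "
                    "reach_c2 (each 0-100%)")
            _check_range("efficacy_c1", self.efficacy_c1, 0.0, 100.0)
            _check_range("reach_c2", self.reach_c2, 0.0, 100.0)

    @property
    def mode(self) -> str:
        return "direct" if self.direct_rating is not None else "factored"

    def value(self) -> float:
        """The 0-10 score entering every BPR equation."""
        if self.direct_rating is not None:
            return float(self.direct_rating)
        return self.efficacy_c1 / 100.0 * self.reach_c2 / 100.0 * 10.0


@dataclass(frozen=True)
class PearlFlags:
    """Component D: five binary feasibility criteria (PEARL).

    Propriety, Economics, Acceptability, Resources, Legality; the product
    gates a program in the original and Vilnius-Dandoy equations and serves
    as a pre-screening filter elsewhere.
    """

    propriety: int
    economics: int
    acceptability: int
    resources: int
    legality: int

    def __post_init__(self) -> None:
        for name in ("propriety", "economics", "acceptability",
                     "resources", "legality"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(
                    f"PEARL flag {name}={v!r} must be binary 0/1")

    def product(self) -> int:
        return (self.propriety * self.economics * self.acceptability
                * self.resources * self.legality)


@dataclass(frozen=True)
class ComponentScores:
    """One program's ratings for every component any BPR method may use.

    ``seriousness`` accepts either the four 0-5 factors or a pre-summed
    total (0-20); when both ``seriousness`` (factors) and
    ``seriousness_total`` are supplied they must agree within 1e-9.
    ``effectiveness`` accepts an :class:`Effectiveness` or a bare 0-10
    direct rating.  ``inequity_e`` / ``positioning_f`` are required by the
    PAHO method only; ``pearl`` by original/Vilnius; ``benefit_cost`` by
    Vilnius.
    """

    size_a: float
    seriousness: SeriousnessFactors | float
    effectiveness: Effectiveness | float
    inequity_e: float | None = None
    positioning_f: float | None = None
    pearl: PearlFlags | None = None
    benefit_cost: float | None = None
    seriousness_total: float | None = None

    def __post_init__(self) -> None:
        _check_range("A", self.size_a, *COMPONENT_RANGES["A"])
        if isinstance(self.seriousness, SeriousnessFactors):
            if self.seriousness_total is not None:
                if abs(self.seriousness.total()
                       - self.seriousness_total) > BOUND_TOL:
                    raise ValidationError(
                        "seriousness factors sum to "
                        f"{self.seriousness.total():g} but seriousness_total="
                        f"{self.seriousness_total:g}; they must agree")
        else:
            _check_range("B", self.seriousness, *COMPONENT_RANGES["B"])
            if self.seriousness_total is not None and \
                    abs(float(self.seriousness)
                        - self.seriousness_total) > BOUND_TOL:
                raise ValidationError(
                    "pre-summed seriousness and seriousness_total disagree")
        if not isinstance(self.effectiveness, Effectiveness):
            object.__setattr__(
                self, "effectiveness",
                Effectiveness(direct_rating=float(self.effectiveness)))
        if self.inequity_e is not None:
            _check_range("E", self.inequity_e, *COMPONENT_RANGES["E"])
        if self.positioning_f is not None:
            # printed templates carry the two-decimal 0.67, below exact 2/3
            _check_range("F", self.positioning_f, F_MIN, F_MAX,
                         slack=F_INPUT_TOLERANCE)
        if self.benefit_cost is not None:
            _check_range("BC", self.benefit_cost, *COMPONENT_RANGES["BC"])

    # -- scalar views used by the equations ---------------------------------
    @property
    def a(self) -> float:
        return float(self.size_a)

    @property
    def b(self) -> float:
        if isinstance(self.seriousness, SeriousnessFactors):
            return self.seriousness.total()
        return float(self.seriousness)

    @property
    def c(self) -> float:
        return self.effectiveness.value()

    @property
    def e(self) -> float | None:
        return None if self.inequity_e is None else float(self.inequity_e)

    @property
    def f(self) -> float | None:
        return None if self.positioning_f is None \
            else float(self.positioning_f)

    @property
    def bc(self) -> float | None:
        return None if self.benefit_cost is None else float(self.benefit_cost)


@dataclass(frozen=True)
class BprScore:
    """A computed Basic Priority Rating: method, 0-100 value, inputs used."""

    method: MethodName
    value: float
    components_used: ComponentScores

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {METHODS}")
        if not (-BOUND_TOL <= self.value <= 100.0 + BOUND_TOL):
            raise ValidationError(
                f"BPR value {self.value!r} outside [0, 100]")


# --------------------------------------------------------------------------
# Scoring operations: the four equations and PEARL screening
# --------------------------------------------------------------------------

def effectiveness_value(e: Effectiveness) -> float:
    """Component C on the 0-10 scale.

    Factored mode returns (C1/100) * (C2/100) * 10; direct mode passes the
    rating through unchanged.
    """
    return e.value()


def benefit_cost_from_quotient(b: float, c: float) -> float:
    """Convenience benefit-cost rating min(B/C, 10) for the Vilnius method.

    The benefit-cost criterion is canonically an independently rated 0-10
    component; this helper derives a rating from the B and C scores for
    users who want the literal quotient reading.  C must be nonzero.
    """
    if c == 0:
        raise ValidationError(
            "cannot derive a benefit-cost rating from C=0; rate it directly")
    return min(float(b) / float(c), 10.0)


def pearl_screen(flags: PearlFlags) -> int:
    """PEARL feasibility gate: the product of the five binary flags.

    Intended as a pre-screening filter applied to a program list before any
    BPR method is run; a single failing criterion eliminates the program.
    """
    return flags.product()


def screen_programs(
    scores: Mapping[str, ComponentScores],
) -> tuple[list[str], list[str]]:
    """Partition program ids into (retained, eliminated) by PEARL.

    Programs without PEARL flags are retained (treated as pre-screened).
    """
    retained, eliminated = [], []
    for pid in scores:
        cs = scores[pid]
        if cs.pearl is not None and pearl_screen(cs.pearl) == 0:
            eliminated.append(pid)
        else:
            retained.append(pid)
    return retained, eliminated


def bpr_original(c: ComponentScores) -> BprScore:
    """Original Hanlon: BPR = (A + B) * C / 3 * D.

    The component product (A+B) * C * D spans 0-300, so dividing by 3
    normalizes to 0-100.  Requires PEARL flags; a zero PEARL product
    annihilates the score.
    """
    if c.pearl is None:
        raise ValidationError(
            "the original Hanlon method requires PEARL flags (component D)")
    value = (c.a + c.b) * c.c / 3.0 * c.pearl.product()
    return BprScore("original", value, c)


def bpr_vilnius(c: ComponentScores) -> BprScore:
    """Vilnius-Dandoy: BPR = (A + B) * (C + BC) / 6 * D.

    BC is the 0-10 benefit-cost rating; with five components the divisor 6
    normalizes the maximum (10+20)*(10+10)/6 to 100.
    """
    if c.pearl is None:
        raise ValidationError(
            "the Vilnius-Dandoy method requires PEARL flags (component D)")
    if c.bc is None:
        raise ValidationError(
            "the Vilnius-Dandoy method requires a benefit_cost rating (0-10)")
    value = (c.a + c.b) * (c.c + c.bc) / 6.0 * c.pearl.product()
    return BprScore("vilnius", value, c)


def bpr_neiger(c: ComponentScores) -> BprScore:
    """Neiger revision: BPR = (A + B) * C / 3, PEARL moved to pre-screening."""
    value = (c.a + c.b) * c.c / 3.0
    return BprScore("neiger", value, c)


def bpr_paho(c: ComponentScores) -> BprScore:
    """PAHO-adapted method: BPR = (A + B + E) * C / 5.25 * F.

    Adds inequity E (0-5) and the institutional-positioning multiplier F
    (0.67-1.50); drops PEARL.  The divisor 5.25 is forced by the maxima:
    (10 + 20 + 5) * 10 * 1.5 / 100 = 5.25.
    """
    if c.e is None:
        raise ValidationError(
            "the PAHO method requires an inequity rating E (0-5)")
    if c.f is None:
        raise ValidationError(
            "the PAHO method requires an institutional-positioning "
            "multiplier F (0.67-1.50)")
    value = (c.a + c.b + c.e) * c.c / 5.25 * c.f
    return BprScore("paho", value, c)


_METHOD_FUNCS = {
    "original": bpr_original,
    "vilnius": bpr_vilnius,
    "neiger": bpr_neiger,
    "paho": bpr_paho,
}

#: Scalar components each method's equation consumes.
METHOD_COMPONENTS: dict[str, tuple[str, ...]] = {
    "original": ("A", "B", "C"),
    "vilnius": ("A", "B", "C", "BC"),
    "neiger": ("A", "B", "C"),
    "paho": ("A", "B", "C", "E", "F"),
}


def compute_bpr(c: ComponentScores, method: MethodName) -> BprScore:
    """Dispatch to one of the four BPR equations by method name."""
    try:
        func = _METHOD_FUNCS[method]
    except KeyError:
        raise ValidationError(
            f"unknown method {method!r}; expected one of {METHODS}") from None
    return func(c)


# --------------------------------------------------------------------------
# Program catalog and pilot-test fixture
# --------------------------------------------------------------------------

ProgramGroup = Literal["disease-oriented", "non-disease-oriented", "unlisted"]


@dataclass(frozen=True)
class Program:
    """A catalog entry: id (e.g. "1.1"), display name, and program group.

    Catalog programs are either disease-oriented or non-disease-oriented;
    "unlisted" marks ad-hoc ids ranked without a catalog entry.
    """

    id: str
    name: str
    group: ProgramGroup

    def __post_init__(self) -> None:
        if self.group not in ("disease-oriented", "non-disease-oriented",
                              "unlisted"):
            raise ValidationError(f"unknown program group {self.group!r}")

    @property
    def label(self) -> str:
        return self.id if self.name == self.id else f"{self.id} {self.name}"


def _prog(pid: str, name: str, group: str) -> Program:
    return Program(pid, name, group)  # type: ignore[arg-type]


#: The 24 programs of the PAHO Strategic Plan 2014-2019: 10 disease-oriented
#: and 14 non-disease-oriented.
PROGRAM_CATALOG: tuple[Program, ...] = (
    _prog("1.1", "HIV/AIDS and STIs", "disease-oriented"),
    _prog("1.2", "Tuberculosis", "disease-oriented"),
    _prog("1.3", "Malaria and other vector-borne diseases "
                 "(including dengue and Chagas)", "disease-oriented"),
    _prog("1.4", "Neglected, tropical, and zoonotic diseases",
          "disease-oriented"),
    _prog("1.5", "Vaccine-preventable diseases (including maintenance of "
                 "polio eradication)", "disease-oriented"),
    _prog("2.1", "Noncommunicable diseases and risk factors",
          "disease-oriented"),
    _prog("2.2", "Mental health and psychoactive substance use disorders",
          "disease-oriented"),
    _prog("2.3", "Violence and injuries", "disease-oriented"),
    _prog("2.4", "Disabilities and rehabilitation", "disease-oriented"),
    _prog("2.5", "Nutrition (poor nutrition)", "disease-oriented"),
    _prog("3.1", "Women, maternal, newborn, child, adolescent, and adult "
                 "health, and sexual and reproductive health",
          "non-disease-oriented"),
    _prog("3.2", "Aging and health", "non-disease-oriented"),
    _prog("3.3", "Gender, equity, human rights, and ethnicity",
          "non-disease-oriented"),
    _prog("3.4", "Social determinants of health", "non-disease-oriented"),
    _prog("3.5", "Health and the environment", "non-disease-oriented"),
    _prog("4.1", "Health governance and financing; national health policies, "
                 "strategies, and plans", "non-disease-oriented"),
    _prog("4.2", "People-centered, integrated, quality health services",
          "non-disease-oriented"),
    _prog("4.3", "Access to medical products and strengthening of regulatory "
                 "capacity", "non-disease-oriented"),
    _prog("4.4", "Health systems information and evidence",
          "non-disease-oriented"),
    _prog("4.5", "Human resources for health", "non-disease-oriented"),
    _prog("5.1", "Alert and response capacities (for IHR)",
          "non-disease-oriented"),
    _prog("5.2", "Epidemic- and pandemic-prone diseases",
          "non-disease-oriented"),
    _prog("5.3", "Emergency risk and crisis management",
          "non-disease-oriented"),
    _prog("5.4", "Food safety", "non-disease-oriented"),
)

_CATALOG_BY_ID = {p.id: p for p in PROGRAM_CATALOG}

#: Mean component scores from the 12-country pilot test (three illustrative
#: programs).  PAHO BPRs: 1.1 -> 27.3 (rank 3), 4.1 -> 38.4 (rank 1),
#: 5.1 -> 37.7 (rank 2).
PILOT_CONSENSUS: dict[str, ComponentScores] = {
    "1.1": ComponentScores(size_a=5.0, seriousness=13.6, effectiveness=6.6,
                           inequity_e=3.1, positioning_f=1.0),
    "4.1": ComponentScores(size_a=8.3, seriousness=13.4, effectiveness=7.1,
                           inequity_e=4.1, positioning_f=1.1),
    "5.1": ComponentScores(size_a=6.2, seriousness=14.4, effectiveness=7.6,
                           inequity_e=3.1, positioning_f=1.1),
}


def pilot_consensus_panel(n_raters: int = 12) -> "RaterPanel":
    """The pilot-test illustration as a panel of identical rater sheets.

    Every rater enters the published mean components, so aggregation
    recovers them exactly and the PAHO BPRs come out 27.3 / 38.4 / 37.7.
    """
    raters = [f"rater{i + 1:02d}" for i in range(n_raters)]
    sheets = {r: dict(PILOT_CONSENSUS) for r in raters}
    return RaterPanel(raters=raters, sheets=sheets)


def pilot_template_path() -> Path:
    """Path of the packaged single-sheet CSV with the pilot consensus means."""
    return Path(resources.files("hanlon").joinpath(
        "data", "pilot_consensus_template.csv"))


# --------------------------------------------------------------------------
# Panel aggregation, ranking, tier stratification
# --------------------------------------------------------------------------

@dataclass
class RaterPanel:
    """A rater x program x component score matrix.

    ``sheets`` maps rater id -> program id -> :class:`ComponentScores`.
    When ``catalog`` is None, program entries are resolved against the
    packaged catalog and unknown ids become "unlisted" programs.
    """

    raters: list[str]
    sheets: dict[str, dict[str, ComponentScores]]
    catalog: Sequence[Program] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.sheets) - set(self.raters)
        if unknown:
            raise ValidationError(
                f"sheets reference raters not in the panel: {sorted(unknown)}")
        if self.catalog is not None:
            ids = {p.id for p in self.catalog}
            for rater, sheet in self.sheets.items():
                bad = set(sheet) - ids
                if bad:
                    raise ValidationError(
                        f"rater {rater!r} scored programs not in the "
                        f"catalog: {sorted(bad)}")

    def program_ids(self) -> list[str]:
        """All scored program ids, in catalog order then lexicographic."""
        scored: set[str] = set()
        for sheet in self.sheets.values():
            scored.update(sheet)
        ordered = [p.id for p in (self.catalog or PROGRAM_CATALOG)
                   if p.id in scored]
        extras = sorted(scored - set(ordered))
        return ordered + extras

    def program(self, pid: str) -> Program:
        for p in (self.catalog or PROGRAM_CATALOG):
            if p.id == pid:
                return p
        return Program(pid, pid, "unlisted")


@dataclass(frozen=True)
class PriorityResult:
    """One program's aggregated outcome: mean components, BPR, rank, tier."""

    program: Program
    mean_components: ComponentScores
    bpr: BprScore
    rank: int
    tier: Literal["high", "medium", "low"] | None = None


def _mean(values: Sequence[float]) -> float:
    # fsum: correctly-rounded sum, so rater permutations are bit-identical;
    # a unanimous panel averages to exactly the common value
    if values[0] == min(values) == max(values):
        return float(values[0])
    return math.fsum(values) / len(values)


_STATISTICS = {"mean": _mean, "median": lambda v: float(median(v))}


def _cell_value(cs: ComponentScores, comp: str) -> float | None:
    """Scalar value of one named component on a sheet, or None if unrated."""
    if comp == "A":
        return cs.a
    if comp == "B":
        return cs.b
    if comp in ("B1", "B2", "B3", "B4"):
        if not isinstance(cs.seriousness, SeriousnessFactors):
            return None
        return {"B1": cs.seriousness.urgency_b1,
                "B2": cs.seriousness.severity_b2,
                "B3": cs.seriousness.economic_loss_b3,
                "B4": cs.seriousness.negative_impact_b4}[comp]
    if comp == "C":
        return cs.c
    if comp == "E":
        return cs.e
    if comp == "F":
        return cs.f
    if comp == "BC":
        return cs.bc
    raise ConfigError(
        f"unknown component {comp!r}; expected one of "
        "A, B, B1-B4, C, E, F, BC")


def aggregate_panel(
    panel: RaterPanel,
    method: MethodName = "paho",
    *,
    statistic: Literal["mean", "median"] = "mean",
    missing: Literal["strict", "skip"] = "strict",
    iteration: Literal["by_program", "by_component"] = "by_program",
) -> dict[str, ComponentScores]:
    """Aggregate rater sheets into per-program consensus components.

    Each component required by ``method`` is averaged arithmetically over
    contributing raters (``statistic="median"`` for a robust alternative).
    Under the default strict policy every rater must have rated every
    required component of every program; ``missing="skip"`` instead drops a
    rater from the cells it left blank (logging contributing counts).
    Seriousness is averaged factor-wise when every contributing rater
    supplied the four factors, otherwise on the 0-20 total; effectiveness
    is averaged on its 0-10 value; PEARL flags aggregate by unanimity (a
    flag is 1 only if all contributing raters rated it 1).

    ``iteration`` selects whether programs ("horizontally") or components
    ("vertically") form the outer loop; both orders give bit-identical
    results, mirroring the rater's free choice of scoring order.
    """
    if not panel.raters or not any(panel.sheets.values()):
        raise ValidationError("cannot aggregate an empty panel")
    if method not in METHODS:
        raise ValidationError(
            f"unknown method {method!r}; expected one of {METHODS}")
    agg = _STATISTICS[statistic]
    required = METHOD_COMPONENTS[method]
    pids = panel.program_ids()

    def collect(pid: str, comp: str) -> list[float]:
        values, absentees = [], []
        for rater in panel.raters:
            cs = panel.sheets.get(rater, {}).get(pid)
            v = None if cs is None else _cell_value(cs, comp)
            if v is None:
                absentees.append(rater)
            else:
                values.append(v)
        if absentees and comp in required:
            if missing == "strict":
                raise ValidationError(
                    f"rater {absentees[0]!r} has no score for component "
                    f"{comp} of program {pid!r} (strict missing-data policy)")
            logger.info("program %s component %s: %d/%d raters contributed",
                        pid, comp, len(values), len(panel.raters))
        return values

    cells: dict[tuple[str, str], float] = {}
    b_factorwise: dict[str, bool] = {}
    comps_order = ["A", "B1", "B2", "B3", "B4", "B", "C", "E", "F", "BC"]

    def aggregate_cell(pid: str, comp: str) -> None:
        if comp in ("B1", "B2", "B3", "B4"):
            vals = collect(pid, comp)
            n_b = len(collect(pid, "B"))
            # factor-wise only when every contributing B came as factors
            if vals and len(vals) == n_b:
                cells[(pid, comp)] = agg(vals)
                b_factorwise[pid] = True
            return
        if comp == "B" and b_factorwise.get(pid):
            return
        vals = collect(pid, comp)
        if comp in required and not vals:
            raise ValidationError(
                f"no rater scored component {comp} of program {pid!r}")
        if vals and (comp in required
                     or len(vals) == len(panel.raters)):
            cells[(pid, comp)] = agg(vals)

    if iteration == "by_program":
        for pid in pids:
            for comp in comps_order:
                aggregate_cell(pid, comp)
    elif iteration == "by_component":
        for comp in comps_order:
            for pid in pids:
                aggregate_cell(pid, comp)
    else:
        raise ConfigError(
            f"iteration must be 'by_program' or 'by_component', "
            f"got {iteration!r}")

    out: dict[str, ComponentScores] = {}
    for pid in pids:
        if b_factorwise.get(pid):
            seriousness: SeriousnessFactors | float = SeriousnessFactors(
                cells[(pid, "B1")], cells[(pid, "B2")],
                cells[(pid, "B3")], cells[(pid, "B4")])
        else:
            seriousness = cells[(pid, "B")]
        pearl = _aggregate_pearl(panel, pid)
        out[pid] = ComponentScores(
            size_a=cells[(pid, "A")],
            seriousness=seriousness,
            effectiveness=cells[(pid, "C")],
            inequity_e=cells.get((pid, "E")),
            positioning_f=cells.get((pid, "F")),
            benefit_cost=cells.get((pid, "BC")),
            pearl=pearl,
        )
    return out


def _aggregate_pearl(panel: RaterPanel, pid: str) -> PearlFlags | None:
    """Unanimity aggregation: a flag passes only if every rater passed it."""
    flags = [panel.sheets[r][pid].pearl for r in panel.raters
             if pid in panel.sheets.get(r, {})]
    rated = [f for f in flags if f is not None]
    if not rated or len(rated) != len(flags):
        return None
    return PearlFlags(
        propriety=min(f.propriety for f in rated),
        economics=min(f.economics for f in rated),
        acceptability=min(f.acceptability for f in rated),
        resources=min(f.resources for f in rated),
        legality=min(f.legality for f in rated),
    )


def rank_results(
    scores: Mapping[str, BprScore],
    *,
    catalog: Sequence[Program] | None = None,
    mean_components: Mapping[str, ComponentScores] | None = None,
) -> list[PriorityResult]:
    """Order programs by descending BPR with competition ranking for ties.

    Tied programs share the minimum rank and the next rank is skipped
    (1, 1, 3, ...); equal-BPR programs are ordered by program id so output
    is deterministic.
    """
    if not scores:
        return []
    lookup = {p.id: p for p in (catalog or PROGRAM_CATALOG)}
    ordered = sorted(scores, key=lambda pid: (-scores[pid].value, pid))
    results: list[PriorityResult] = []
    rank = 0
    prev_value: float | None = None
    for pos, pid in enumerate(ordered, start=1):
        value = scores[pid].value
        if prev_value is None or value != prev_value:
            rank = pos
            prev_value = value
        program = lookup.get(pid, Program(pid, pid, "unlisted"))
        comps = (mean_components or {}).get(
            pid, scores[pid].components_used)
        results.append(PriorityResult(
            program=program, mean_components=comps,
            bpr=scores[pid], rank=rank))
    return results


TierCutoffs = str | tuple[float, float]


def stratify_tiers(
    results: Sequence[PriorityResult],
    cutoffs: TierCutoffs = "tertile",
) -> list[PriorityResult]:
    """Assign each ranked program to a high / medium / low priority tier.

    ``cutoffs="tertile"`` (default) splits the ranked list into three
    near-equal blocks, earlier ranks filling the high tier first (a
    remainder enlarges high, then medium).  Explicit BPR thresholds are a
    ``(high_min, medium_min)`` pair with high_min > medium_min: BPR >=
    high_min is high, >= medium_min is medium, below is low.
    """
    if not isinstance(cutoffs, str):
        high_min, medium_min = cutoffs
        if not high_min > medium_min:
            raise ConfigError(
                f"tier thresholds must be strictly decreasing, got "
                f"high_min={high_min} <= medium_min={medium_min}")
    elif cutoffs != "tertile":
        raise ConfigError(
            f"unknown tier cutoff specification {cutoffs!r}; use 'tertile' "
            "or an explicit (high_min, medium_min) threshold pair")
    results = sorted(results, key=lambda r: (r.rank, r.program.id))
    n = len(results)
    if n == 0:
        return []
    if cutoffs == "tertile":
        base, rem = divmod(n, 3)
        sizes = (base + (rem >= 1), base + (rem >= 2), base)
        tiers: list[str] = (["high"] * sizes[0] + ["medium"] * sizes[1]
                            + ["low"] * sizes[2])
        return [replace(r, tier=t) for r, t in zip(results, tiers)]
    out = []
    for r in results:
        v = r.bpr.value
        tier = "high" if v >= high_min else \
            "medium" if v >= medium_min else "low"
        out.append(replace(r, tier=tier))
    return out


def score_panel(
    panel: RaterPanel,
    method: MethodName = "paho",
    *,
    tiers: TierCutoffs = "tertile",
    statistic: Literal["mean", "median"] = "mean",
    missing: Literal["strict", "skip"] = "strict",
    iteration: Literal["by_program", "by_component"] = "by_program",
    aggregate_scores: bool = False,
) -> list[PriorityResult]:
    """End-to-end panel scoring: aggregate, score, rank, stratify.

    The canonical pipeline averages components first and computes one BPR
    from the mean components (matching how the pilot-test illustration
    presents mean components alongside a single BPR).  With
    ``aggregate_scores=True`` a per-rater BPR is computed and averaged
    instead; because the equations are nonlinear the two generally differ,
    and this variant is non-canonical.
    """
    if not any(panel.sheets.get(r) for r in panel.raters):
        return []
    if len(panel.raters) < RECOMMENDED_MIN_RATERS:
        logger.warning(
            "panel has %d rater(s); official national sessions convene a "
            "minimum of %d experts", len(panel.raters),
            RECOMMENDED_MIN_RATERS)
    means = aggregate_panel(panel, method, statistic=statistic,
                            missing=missing, iteration=iteration)
    scores: dict[str, BprScore] = {}
    for pid, comps in means.items():
        if aggregate_scores:
            per_rater = [compute_bpr(panel.sheets[r][pid], method).value
                         for r in panel.raters
                         if pid in panel.sheets.get(r, {})]
            scores[pid] = BprScore(method, _mean(per_rater), comps)
        else:
            scores[pid] = compute_bpr(comps, method)
    ranked = rank_results(scores, catalog=panel.catalog,
                          mean_components=means)
    return stratify_tiers(ranked, tiers)


# --------------------------------------------------------------------------
# Sensitivity analysis: method concordance, F-range trials, perturbations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityReport:
    """Concordance between two rankings of the same program set.

    ``per_program`` maps program id -> (delta BPR, delta rank), deltas being
    scenario B minus scenario A.  Concordance uses Spearman's rho and
    Kendall's tau-b on the two rank vectors; identical rankings give 1.0.
    """

    label: str
    spearman_rho: float
    kendall_tau: float
    max_rank_shift: int
    per_program: dict[str, tuple[float, int]]
    ranking_a: dict[str, int]
    ranking_b: dict[str, int]
    n_clamped: int = 0

    def to_rows(self) -> list[dict[str, object]]:
        """Flat rows (one per program) for tabular export."""
        return [{
            "scenario": self.label, "program": pid,
            "rank_a": self.ranking_a[pid], "rank_b": self.ranking_b[pid],
            "delta_bpr": self.per_program[pid][0],
            "delta_rank": self.per_program[pid][1],
        } for pid in sorted(self.ranking_a)]


def _rank_values(values: Mapping[str, float]) -> dict[str, int]:
    """Competition ranking of raw score values (descending, id tiebreak)."""
    ordered = sorted(values, key=lambda pid: (-values[pid], pid))
    ranks: dict[str, int] = {}
    prev: float | None = None
    rank = 0
    for pos, pid in enumerate(ordered, start=1):
        if prev is None or values[pid] != prev:
            rank = pos
            prev = values[pid]
        ranks[pid] = rank
    return ranks


def _build_report(
    label: str,
    bpr_a: Mapping[str, float],
    bpr_b: Mapping[str, float],
    rank_a: Mapping[str, int],
    rank_b: Mapping[str, int],
    *,
    n_clamped: int = 0,
) -> SensitivityReport:
    if set(rank_a) != set(rank_b):
        raise ConfigError("the two scenarios rank different program sets")
    pids = sorted(rank_a)
    va = [rank_a[p] for p in pids]
    vb = [rank_b[p] for p in pids]
    if len(pids) < 2 or va == vb:
        # scipy returns nan for constant inputs; identical rankings are
        # perfectly concordant by definition
        rho = tau = 1.0
    else:
        rho = float(stats.spearmanr(va, vb).statistic)
        tau = float(stats.kendalltau(va, vb).statistic)
    deltas = {p: (bpr_b[p] - bpr_a[p], rank_b[p] - rank_a[p]) for p in pids}
    return SensitivityReport(
        label=label, spearman_rho=rho, kendall_tau=tau,
        max_rank_shift=max(abs(d[1]) for d in deltas.values()),
        per_program=deltas, ranking_a=dict(rank_a), ranking_b=dict(rank_b),
        n_clamped=n_clamped)


def _concordance_report(
    label: str,
    results_a: Sequence[PriorityResult],
    results_b: Sequence[PriorityResult],
    *,
    n_clamped: int = 0,
) -> SensitivityReport:
    return _build_report(
        label,
        {r.program.id: r.bpr.value for r in results_a},
        {r.program.id: r.bpr.value for r in results_b},
        {r.program.id: r.rank for r in results_a},
        {r.program.id: r.rank for r in results_b},
        n_clamped=n_clamped)


def compare_methods(
    panel: RaterPanel,
    method_a: MethodName,
    method_b: MethodName,
    **score_kwargs,
) -> SensitivityReport:
    """Rank the panel under two BPR methods and report rank concordance.

    Both methods must be computable from the panel's components (PEARL and
    benefit-cost supplied where the method needs them).  A tau of 1 means
    the methods order programs identically; methods that differ only by a
    positive monotone rescaling always reach tau = 1.
    """
    res_a = score_panel(panel, method_a, **score_kwargs)
    res_b = score_panel(panel, method_b, **score_kwargs)
    return _concordance_report(f"{method_a} vs {method_b}", res_a, res_b)


def _remap_f(f: float, f_min: float, f_max: float) -> float:
    """Piecewise-linear remap of F from [2/3, 1.5] onto [f_min, f_max].

    F = 1.00 (the neutral multiplier) is a fixed point: [2/3, 1] maps
    linearly onto [f_min, 1] and [1, 1.5] onto [1, f_max].
    """
    f = min(max(f, F_MIN), F_MAX)
    if f >= 1.0:
        return 1.0 + (f - 1.0) * (f_max - 1.0) / (F_MAX - 1.0)
    return 1.0 - (1.0 - f) * (1.0 - f_min) / (1.0 - F_MIN)


def f_range_experiment(
    panel: RaterPanel,
    f_bounds_list: Sequence[tuple[float, float]],
    **score_kwargs,
) -> list[SensitivityReport]:
    """Rank shifts induced by trial institutional-positioning ranges.

    The multiplier's canonical range is 0.67-1.50; the trial range
    0.50-2.00 (a halving to a doubling effect) was rejected during pilot
    testing as overwhelming the other components.  For each reciprocal
    bound pair (f_min, f_max) this rescales every program's F from the
    canonical interval onto the trial interval (keeping F=1 neutral) and
    compares the resulting PAHO ranking with the F-neutral baseline
    (F set to 1 everywhere).
    """
    for f_min, f_max in f_bounds_list:
        if f_max <= 0 or abs(f_min - 1.0 / f_max) > F_INPUT_TOLERANCE:
            raise ConfigError(
                f"F bounds ({f_min}, {f_max}) are not reciprocal: a "
                "multiplier range must satisfy f_min = 1/f_max")
    means = aggregate_panel(panel, "paho", **{
        k: v for k, v in score_kwargs.items()
        if k in ("statistic", "missing", "iteration")})
    # F-independent part of the PAHO score, per program; trial scores are
    # base * remapped F, computed directly so that trial bounds wider than
    # the canonical range (e.g. 2.00) are representable
    base = {pid: compute_bpr(replace(cs, positioning_f=1.0), "paho").value
            for pid, cs in means.items()}
    base_ranks = _rank_values(base)
    reports = []
    for f_min, f_max in f_bounds_list:
        trial = {pid: base[pid] * _remap_f(means[pid].f, f_min, f_max)
                 for pid in base}
        reports.append(_build_report(
            f"F range [{f_min:g}, {f_max:g}] vs F=1",
            base, trial, base_ranks, _rank_values(trial)))
    return reports


def perturb_components(
    panel: RaterPanel,
    component: str,
    delta: float,
    *,
    method: MethodName = "paho",
    raters: Sequence[str] | None = None,
    **score_kwargs,
) -> SensitivityReport:
    """One-at-a-time robustness check: shift one component for every program.

    Adds ``delta`` to the named component (A, B, B1-B4, C, E, F or BC) on
    every sheet of the selected raters (default: all), clamping to the
    component's legal range and counting clamped cells, then reports rank
    shifts of the perturbed panel against the original.
    """
    if component not in COMPONENT_RANGES:
        raise ConfigError(
            f"unknown component {component!r}; expected one of "
            f"{sorted(COMPONENT_RANGES)}")
    target = set(raters if raters is not None else panel.raters)
    unknown = target - set(panel.raters)
    if unknown:
        raise ConfigError(f"unknown raters: {sorted(unknown)}")
    low, high = COMPONENT_RANGES[component]
    n_clamped = 0

    def shift(cs: ComponentScores) -> ComponentScores:
        nonlocal n_clamped
        current = _cell_value(cs, component)
        if current is None:
            raise ValidationError(
                f"component {component} is not rated on every targeted sheet")
        moved = current + delta
        clamped = min(max(moved, low), high)
        if clamped != moved:
            n_clamped += 1
        if component == "A":
            return replace(cs, size_a=clamped)
        if component == "B":
            return replace(cs, seriousness=clamped, seriousness_total=None)
        if component in ("B1", "B2", "B3", "B4"):
            fields = {"B1": "urgency_b1", "B2": "severity_b2",
                      "B3": "economic_loss_b3", "B4": "negative_impact_b4"}
            return replace(cs, seriousness=replace(
                cs.seriousness, **{fields[component]: clamped}))
        if component == "C":
            return replace(
                cs, effectiveness=Effectiveness(direct_rating=clamped))
        if component == "E":
            return replace(cs, inequity_e=clamped)
        if component == "F":
            return replace(cs, positioning_f=clamped)
        return replace(cs, benefit_cost=clamped)

    perturbed_sheets = {
        rater: {pid: (shift(cs) if rater in target else cs)
                for pid, cs in sheet.items()}
        for rater, sheet in panel.sheets.items()}
    perturbed = RaterPanel(raters=list(panel.raters),
                           sheets=perturbed_sheets, catalog=panel.catalog)
    res_a = score_panel(panel, method, **score_kwargs)
    res_b = score_panel(perturbed, method, **score_kwargs)
    return _concordance_report(
        f"{component} {delta:+g}", res_a, res_b, n_clamped=n_clamped)


# --------------------------------------------------------------------------
# Synthetic rater panels
# --------------------------------------------------------------------------

@dataclass
class PanelScenario:
    """Generating model for a synthetic rater panel.

    Each rater's score for each rated quantity is the panel's true
    (consensus) value plus independent Gaussian noise, truncated to the
    quantity's legal range — the simplest model of rater disagreement on a
    bounded rating scale.  ``noise_sd`` is the rater standard deviation in
    rating points, a scalar applied to every point-scaled quantity
    (efficacy/reach percentages use 10x; the positioning multiplier F gets
    noise on the log scale, sd = noise_sd * 0.05, so its reciprocal bounds
    are treated symmetrically) or a per-component mapping.  With
    ``integer_ratings`` point scores round to whole points and F to two
    decimals, emulating hand-filled sheets.  Identical seed and scenario
    reproduce the panel bit for bit.
    """

    true_components: dict[str, ComponentScores]
    n_raters: int = 12
    noise_sd: float | Mapping[str, float] = 1.0
    integer_ratings: bool = False
    catalog: Sequence[Program] | None = None
    seed: int = 0

    def sd(self, comp: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            base = float(self.noise_sd.get(comp, self.noise_sd.get("*", 0.0)))
            return base
        base = float(self.noise_sd)
        if comp in ("C1", "C2"):
            return base * 10.0
        if comp == "F":
            return base * 0.05
        return base


def _noisy(rng: np.random.Generator, true: float, sd: float,
           low: float, high: float, *, integer: bool) -> float:
    v = true + rng.normal(0.0, sd) if sd > 0 else true
    v = min(max(v, low), high)
    if integer:
        v = float(round(v))
    return v


def generate_panel(scenario: PanelScenario) -> RaterPanel:
    """Draw a synthetic rater panel from a :class:`PanelScenario`.

    Scores are generated rater by rater in a fixed component order, so a
    given seed always yields the same panel.
    """
    if scenario.n_raters < 1:
        raise ValidationError("a panel needs at least one rater")
    for pid, cs in scenario.true_components.items():
        if not isinstance(cs, ComponentScores):
            raise ValidationError(
                f"true components of program {pid!r} must be ComponentScores")
    rng = np.random.default_rng(scenario.seed)
    integer = scenario.integer_ratings
    raters = [f"rater{i + 1:02d}" for i in range(scenario.n_raters)]
    sheets: dict[str, dict[str, ComponentScores]] = {}
    for rater in raters:
        sheet: dict[str, ComponentScores] = {}
        for pid, true in scenario.true_components.items():
            a = _noisy(rng, true.a, scenario.sd("A"), 0, 10, integer=integer)
            if isinstance(true.seriousness, SeriousnessFactors):
                t = true.seriousness
                seriousness: SeriousnessFactors | float = SeriousnessFactors(
                    *[_noisy(rng, v, scenario.sd(k), 0, 5, integer=integer)
                      for k, v in (("B1", t.urgency_b1),
                                   ("B2", t.severity_b2),
                                   ("B3", t.economic_loss_b3),
                                   ("B4", t.negative_impact_b4))])
            else:
                seriousness = _noisy(rng, true.b, scenario.sd("B"),
                                     0, 20, integer=integer)
            if true.effectiveness.mode == "factored":
                eff = Effectiveness(
                    efficacy_c1=_noisy(rng, true.effectiveness.efficacy_c1,
                                       scenario.sd("C1"), 0, 100,
                                       integer=integer),
                    reach_c2=_noisy(rng, true.effectiveness.reach_c2,
                                    scenario.sd("C2"), 0, 100,
                                    integer=integer))
            else:
                eff = Effectiveness(direct_rating=_noisy(
                    rng, true.c, scenario.sd("C"), 0, 10, integer=integer))
            e = None if true.e is None else _noisy(
                rng, true.e, scenario.sd("E"), 0, 5, integer=integer)
            if true.f is None:
                f = None
            else:
                sd_f = scenario.sd("F")
                logf = math.log(true.f) + (rng.normal(0.0, sd_f)
                                           if sd_f > 0 else 0.0)
                f = round(min(max(math.exp(logf), F_MIN), F_MAX), 2)
            bc = None if true.bc is None else _noisy(
                rng, true.bc, scenario.sd("BC"), 0, 10, integer=integer)
            sheet[pid] = ComponentScores(
                size_a=a, seriousness=seriousness, effectiveness=eff,
                inequity_e=e, positioning_f=f, benefit_cost=bc,
                pearl=true.pearl)
        sheets[rater] = sheet
    return RaterPanel(raters=raters, sheets=sheets, catalog=scenario.catalog)


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of how well noisy panels recover a true ranking."""

    n_replicates: int
    rank_accuracy: tuple[float, ...]  # per replicate: fraction of exact ranks
    mean_rank_accuracy: float
    sd_rank_accuracy: float
    top_tier_recovery: float  # fraction of replicates recovering the high set


def ranking_recovery_experiment(
    scenario: PanelScenario,
    n_replicates: int,
    *,
    method: MethodName = "paho",
) -> RecoverySummary:
    """Estimate ranking recovery under the scenario's noise level.

    The true ranking is computed from the scenario's consensus components
    (tied true BPRs are rejected — perturb the scenario to break them).
    Each replicate draws a fresh panel with a child seed, scores it, and
    records the fraction of programs whose recovered rank equals the true
    rank plus whether the high-priority tertile set is recovered exactly.
    """
    true_scores = {pid: compute_bpr(cs, method)
                   for pid, cs in scenario.true_components.items()}
    values = sorted(s.value for s in true_scores.values())
    if any(b - a < BOUND_TOL for a, b in zip(values, values[1:])):
        raise ValidationError(
            "true components imply tied BPRs; perturb the scenario so the "
            "true ranking is strict")
    true_ranked = stratify_tiers(rank_results(
        true_scores, catalog=scenario.catalog))
    true_rank = {r.program.id: r.rank for r in true_ranked}
    true_high = {r.program.id for r in true_ranked if r.tier == "high"}

    child_seeds = np.random.SeedSequence(scenario.seed).generate_state(
        n_replicates) % (2 ** 31)
    accuracies: list[float] = []
    top_hits = 0
    n_prog = len(true_rank)
    for seed in child_seeds:
        panel = generate_panel(replace(scenario, seed=int(seed)))
        got = score_panel(panel, method)
        got_rank = {r.program.id: r.rank for r in got}
        got_high = {r.program.id for r in got if r.tier == "high"}
        accuracies.append(sum(got_rank[p] == true_rank[p]
                              for p in true_rank) / n_prog)
        top_hits += got_high == true_high
    acc = np.asarray(accuracies)
    return RecoverySummary(
        n_replicates=n_replicates,
        rank_accuracy=tuple(accuracies),
        mean_rank_accuracy=float(acc.mean()),
        sd_rank_accuracy=float(acc.std(ddof=1)) if n_replicates > 1 else 0.0,
        top_tier_recovery=top_hits / n_replicates)


# --------------------------------------------------------------------------
# Scoring-template I/O (delimiter-separated text)
# --------------------------------------------------------------------------

#: Canonical template column order.  PEARL columns are prefixed to avoid a
#: clash with component E.
TEMPLATE_COLUMNS = (
    "rater", "group", "program_id", "program_name",
    "A", "B1", "B2", "B3", "B4", "B", "C", "C1", "C2", "E", "F", "BC",
    "pearl_p", "pearl_e", "pearl_a", "pearl_r", "pearl_l",
)

_REQUIRED_TEMPLATE_COLUMNS: dict[str, list[tuple[str, ...]]] = {
    # each entry: at least one column of every inner tuple-group must exist
    "original": [("A",), ("B", "B1"), ("C", "C1"),
                 ("pearl_p",), ("pearl_e",), ("pearl_a",), ("pearl_r",),
                 ("pearl_l",)],
    "vilnius": [("A",), ("B", "B1"), ("C", "C1"), ("BC",),
                ("pearl_p",), ("pearl_e",), ("pearl_a",), ("pearl_r",),
                ("pearl_l",)],
    "neiger": [("A",), ("B", "B1"), ("C", "C1")],
    "paho": [("A",), ("B", "B1"), ("C", "C1"), ("E",), ("F",)],
}

_PEARL_COLS = ("pearl_p", "pearl_e", "pearl_a", "pearl_r", "pearl_l")
_FACTOR_COLS = ("B1", "B2", "B3", "B4")


def _fmt(value: float | int | None) -> str:
    if value is None:
        return ""
    if isinstance(value, int) or float(value).is_integer():
        return str(int(value))
    return repr(float(value))  # shortest repr round-trips exactly


def _row_from_components(cs: ComponentScores) -> dict[str, str]:
    row: dict[str, str] = {}
    row["A"] = _fmt(cs.size_a)
    if isinstance(cs.seriousness, SeriousnessFactors):
        s = cs.seriousness
        row.update(B1=_fmt(s.urgency_b1), B2=_fmt(s.severity_b2),
                   B3=_fmt(s.economic_loss_b3),
                   B4=_fmt(s.negative_impact_b4), B="")
    else:
        row.update(B=_fmt(cs.seriousness), B1="", B2="", B3="", B4="")
    if cs.effectiveness.mode == "direct":
        row.update(C=_fmt(cs.effectiveness.direct_rating), C1="", C2="")
    else:
        row.update(C="", C1=_fmt(cs.effectiveness.efficacy_c1),
                   C2=_fmt(cs.effectiveness.reach_c2))
    row["E"] = _fmt(cs.inequity_e)
    row["F"] = _fmt(cs.positioning_f)
    row["BC"] = _fmt(cs.benefit_cost)
    if cs.pearl is not None:
        p = cs.pearl
        row.update(pearl_p=str(p.propriety), pearl_e=str(p.economics),
                   pearl_a=str(p.acceptability), pearl_r=str(p.resources),
                   pearl_l=str(p.legality))
    else:
        row.update({c: "" for c in _PEARL_COLS})
    return row


def _parse_cell(raw: str | None, column: str, line: int) -> float | None:
    if raw is None or raw.strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise TemplateError(
            f"line {line}, column {column}: cannot parse {raw!r} as a "
            "number") from None


def _components_from_row(row: Mapping[str, str], line: int,
                         has: set[str]) -> ComponentScores:
    def cell(col: str) -> float | None:
        return _parse_cell(row.get(col), col, line) if col in has else None

    a = cell("A")
    if a is None:
        raise TemplateError(f"line {line}: component A is empty")
    factors = {c: cell(c) for c in _FACTOR_COLS}
    n_factors = sum(v is not None for v in factors.values())
    b_total = cell("B")
    if n_factors == 4:
        seriousness: SeriousnessFactors | float = SeriousnessFactors(
            factors["B1"], factors["B2"], factors["B3"], factors["B4"])
    elif n_factors > 0:
        missing = [c for c, v in factors.items() if v is None]
        raise TemplateError(
            f"line {line}: seriousness factors incomplete (missing "
            f"{', '.join(missing)})")
    elif b_total is not None:
        seriousness = b_total
    else:
        raise TemplateError(
            f"line {line}: neither B nor the B1-B4 factors are filled in")
    c_direct, c1, c2 = cell("C"), cell("C1"), cell("C2")
    if c_direct is not None:
        eff = Effectiveness(direct_rating=c_direct)
    elif c1 is not None or c2 is not None:
        eff = Effectiveness(efficacy_c1=c1, reach_c2=c2)
    else:
        raise TemplateError(
            f"line {line}: neither C nor the C1/C2 pair is filled in")
    pearl_cells = [cell(c) for c in _PEARL_COLS]
    if all(v is not None for v in pearl_cells):
        for col, v in zip(_PEARL_COLS, pearl_cells):
            if v not in (0.0, 1.0):
                raise TemplateError(
                    f"line {line}, column {col}: PEARL flags are binary "
                    f"0/1, got {v!r}")
        pearl = PearlFlags(*[int(v) for v in pearl_cells])
    elif any(v is not None for v in pearl_cells):
        raise TemplateError(
            f"line {line}: PEARL flags incomplete (all five of P/E/A/R/L "
            "must be filled or all empty)")
    else:
        pearl = None
    try:
        return ComponentScores(
            size_a=a, seriousness=seriousness, effectiveness=eff,
            inequity_e=cell("E"), positioning_f=cell("F"),
            benefit_cost=cell("BC"), pearl=pearl,
            seriousness_total=b_total if n_factors == 4 else None)
    except ValidationError as err:
        raise TemplateError(f"line {line}: {err}") from err


def components_from_mapping(d: Mapping[str, object]) -> ComponentScores:
    """Build :class:`ComponentScores` from a plain mapping.

    Recognized keys: A, B or B1-B4, C or C1/C2, E, F, BC, and pearl
    (a 5-element P/E/A/R/L sequence).  Used by declarative scenario files.
    """
    def num(key: str) -> float | None:
        v = d.get(key)
        return None if v is None else float(v)  # type: ignore[arg-type]

    if all(num(k) is not None for k in _FACTOR_COLS):
        seriousness: SeriousnessFactors | float = SeriousnessFactors(
            num("B1"), num("B2"), num("B3"), num("B4"))
    elif num("B") is not None:
        seriousness = num("B")
    else:
        raise ValidationError("mapping needs B or all of B1-B4")
    if num("C") is not None:
        eff = Effectiveness(direct_rating=num("C"))
    else:
        eff = Effectiveness(efficacy_c1=num("C1"), reach_c2=num("C2"))
    pearl_raw = d.get("pearl")
    pearl = None
    if pearl_raw is not None:
        flags = [int(v) for v in pearl_raw]  # type: ignore[union-attr]
        if len(flags) != 5:
            raise ValidationError("pearl must list the five P/E/A/R/L flags")
        pearl = PearlFlags(*flags)
    if num("A") is None:
        raise ValidationError("mapping needs component A")
    return ComponentScores(
        size_a=num("A"), seriousness=seriousness, effectiveness=eff,
        inequity_e=num("E"), positioning_f=num("F"),
        benefit_cost=num("BC"), pearl=pearl)


def read_template(
    path: str | Path,
    method: MethodName | None = None,
    *,
    catalog: Sequence[Program] | None = None,
) -> RaterPanel:
    """Read a scoring template (UTF-8, comma-separated, ``#`` metadata lines).

    A ``rater`` column distinguishes the sheets of a multi-rater panel; if
    absent the file is a single sheet.  When ``method`` is given, the
    columns it requires must be present and every cell is range-validated;
    errors cite the offending line and column.  Program ids are matched
    against ``catalog`` (default: the packaged 24-program catalog) and
    unknown ids are reported in the log but retained as unlisted programs.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    data_lines: list[tuple[int, str]] = []  # (1-based file line, text)
    metadata: dict[str, str] = {}
    for i, text in enumerate(lines, start=1):
        if text.startswith("#"):
            body = text.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                metadata[k.strip()] = v.strip()
            continue
        if text.strip():
            data_lines.append((i, text))
    if not data_lines:
        raise TemplateError(f"{path}: no data rows")
    reader = csv.DictReader(io.StringIO(
        "\n".join(text for _, text in data_lines)))
    has = set(reader.fieldnames or [])
    if "program_id" not in has:
        raise TemplateError(f"{path}: missing required column 'program_id'")
    if method is not None:
        if method not in METHODS:
            raise TemplateError(
                f"unknown method {method!r}; expected one of {METHODS}")
        for group in _REQUIRED_TEMPLATE_COLUMNS[method]:
            if not any(col in has for col in group):
                raise TemplateError(
                    f"{path}: the {method} method requires column "
                    f"{' or '.join(group)}")
    sheets: dict[str, dict[str, ComponentScores]] = {}
    raters: list[str] = []
    for (line_no, _), row in zip(data_lines[1:], reader):
        rater = (row.get("rater") or "").strip() or "sheet"
        pid = (row.get("program_id") or "").strip()
        if not pid:
            raise TemplateError(f"line {line_no}: empty program_id")
        cs = _components_from_row(row, line_no, has)
        if rater not in sheets:
            sheets[rater] = {}
            raters.append(rater)
        if pid in sheets[rater]:
            raise TemplateError(
                f"line {line_no}: duplicate program {pid!r} for rater "
                f"{rater!r}")
        sheets[rater][pid] = cs
    cat = tuple(catalog) if catalog is not None else PROGRAM_CATALOG
    known = {p.id for p in cat}
    unknown_ids = sorted({pid for sheet in sheets.values()
                          for pid in sheet} - known)
    if unknown_ids:
        logger.warning("%s: program ids not in the catalog: %s",
                       path.name, ", ".join(unknown_ids))
    panel = RaterPanel(raters=raters, sheets=sheets, catalog=None)
    panel.catalog = cat if not unknown_ids else None
    if metadata:
        logger.info("%s metadata: %s", path.name, metadata)
    return panel


def write_template(
    panel: RaterPanel,
    path: str | Path,
    *,
    method: MethodName | None = None,
    label: str | None = None,
) -> Path:
    """Write a panel as a scoring template; ``read_template`` round-trips it.

    Only columns actually used by some sheet are emitted (plus the id
    columns); header metadata goes into leading ``#`` lines.
    """
    path = Path(path)
    rows: list[dict[str, str]] = []
    for rater in panel.raters:
        sheet = panel.sheets.get(rater, {})
        for pid in panel.program_ids():
            if pid not in sheet:
                continue
            program = panel.program(pid)
            row = {"rater": rater, "group": program.group,
                   "program_id": pid, "program_name": program.name}
            row.update(_row_from_components(sheet[pid]))
            rows.append(row)
    used = [c for c in TEMPLATE_COLUMNS
            if c in ("rater", "group", "program_id", "program_name")
            or any(r.get(c, "") != "" for r in rows)]
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("# template: hanlon-bpr scoring sheet\n")
        if method:
            fh.write(f"# method: {method}\n")
        if label:
            fh.write(f"# label: {label}\n")
        writer = csv.DictWriter(fh, fieldnames=used, extrasaction="ignore")
        writer.writeheader()
        writer.writerows(rows)
    return path


def write_results(
    results: Sequence[PriorityResult],
    path: str | Path,
) -> Path:
    """Write ranked results as CSV, ordered by rank then program id.

    Columns: Group, Program, A, B, C, E, F, BPR (1 decimal), BPR_full
    (machine precision), Ranking, Tier.  Tied programs share a Ranking
    value.
    """
    if not results:
        raise ValidationError("cannot write an empty result list")
    path = Path(path)
    ordered = sorted(results, key=lambda r: (r.rank, r.program.id))
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Group", "Program", "A", "B", "C", "E", "F",
                         "BPR", "BPR_full", "Ranking", "Tier"])
        for r in ordered:
            cs = r.mean_components
            writer.writerow([
                r.program.group, r.program.label,
                _fmt(cs.a), _fmt(round(cs.b, 12)), _fmt(round(cs.c, 12)),
                _fmt(cs.e), _fmt(cs.f),
                f"{r.bpr.value:.1f}", repr(r.bpr.value),
                r.rank, r.tier or ""])
    return path


def results_table(results: Sequence[PriorityResult]) -> str:
    """Human-readable results table (fixed-width text)."""
    ordered = sorted(results, key=lambda r: (r.rank, r.program.id))
    header = f"{'Program':<44} {'BPR':>6} {'Rank':>4}  Tier"
    lines = [header, "-" * len(header)]
    for r in ordered:
        label = r.program.label
        if len(label) > 43:
            label = label[:40] + "..."
        lines.append(f"{label:<44} {r.bpr.value:>6.1f} {r.rank:>4}  "
                     f"{r.tier or '-'}")
    return "\n".join(lines)
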