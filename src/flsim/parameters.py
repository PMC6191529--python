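"""Model parameterization: distributions, unit costs, utilities, transitions.

Every quantity the simulator consumes lives in a :class:`ParameterSet`, built
either from the packaged default configuration (the follicular-lymphoma
parameterization shipped as ``data/default_fl.yaml``) or from a user YAML that
overrides any subset of it.

Conventions
-----------
* Times are stored in **days** internally (1 year = 365.25 days); ages in years.
* Beta and Dirichlet parameters are raw counts where derived from registry
  frequencies; the point estimate of a Beta is ``alpha / (alpha + beta)``.
* Parameters marked ``fixture: true`` are documented placeholders for values
  that could not be estimated here (see docs/methods.md); nothing downstream
  treats them as ground truth.
"""

from __future__ import annotations

import copy
import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .survival import TTESpec

logger = logging.getLogger("flsim")

DAYS_PER_YEAR = 365.25

#: initial-management categories, in the fixed Dirichlet component order
MANAGEMENT_CATEGORIES = (
    "chemotherapy",
    "radiotherapy_ia",
    "radiotherapy_other",
    "ww",
    "not_treated",
)

#: health phases carrying a utility weight
UTILITY_PHASES = (
    "pretreatment",
    "not_treated",
    "ww",
    "first_line_treatment",
    "first_remission",
    "subsequent_treatment",
    "subsequent_remission",
)


class ParameterSchemaError(ValueError):
    """A configuration value violates the documented schema."""


# ---------------------------------------------------------------------------
# distribution parameters
# ---------------------------------------------------------------------------

@dataclass
class BetaParam:
    """A Beta(alpha, beta) proportion; ``point`` overrides the mean when set
    (used to carry a probabilistic-sensitivity-analysis draw)."""

    alpha: float
    beta: float
    point: float | None = None

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ParameterSchemaError(
                f"Beta parameters must be >= 0, got ({self.alpha}, {self.beta})"
            )
        if self.alpha + self.beta == 0:
            raise ParameterSchemaError("Beta(0, 0) is undefined")

    def mean(self) -> float:
        if self.point is not None:
            return self.point
        return self.alpha / (self.alpha + self.beta)

    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    def draw(self, rng) -> float:
        if self.alpha == 0:
            return 0.0
        if self.beta == 0:
            return 1.0
        return float(rng.beta(self.alpha, self.beta))

    def to_dict(self):
        d = {"alpha": self.alpha, "beta": self.beta}
        if self.point is not None:
            d["point"] = self.point
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(float(d["alpha"]), float(d["beta"]),
                   None if d.get("point") is None else float(d["point"]))


@dataclass
class DirichletParam:
    """A Dirichlet over the fixed management-category order."""

    alphas: tuple
    point: tuple | None = None

    def __post_init__(self):
        self.alphas = tuple(float(a) for a in self.alphas)
        if any(a < 0 for a in self.alphas):
            raise ParameterSchemaError(f"Dirichlet alphas must be >= 0: {self.alphas}")
        if not any(a > 0 for a in self.alphas):
            raise ParameterSchemaError("Dirichlet needs >= 1 positive weight")

    def probs(self) -> np.ndarray:
        if self.point is not None:
            return np.asarray(self.point, dtype=float)
        a = np.asarray(self.alphas)
        return a / a.sum()

    def draw(self, rng) -> np.ndarray:
        a = np.asarray(self.alphas)
        out = np.zeros_like(a)
        pos = a > 0
        out[pos] = rng.dirichlet(a[pos])
        return out

    def to_dict(self):
        d = {"alphas": list(self.alphas)}
        if self.point is not None:
            d["point"] = list(self.point)
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(tuple(d["alphas"]),
                   None if d.get("point") is None else tuple(d["point"]))


# ---------------------------------------------------------------------------
# age-band table
# ---------------------------------------------------------------------------

@dataclass
class AgeBand:
    lower: float          # years, inclusive
    upper: float          # years (inf for the open top band)
    label: str
    male: BetaParam
    management: DirichletParam
    ww_rituximab: BetaParam

    def to_dict(self):
        return {
            "lower": self.lower,
            "upper": None if np.isinf(self.upper) else self.upper,
            "label": self.label,
            "male": self.male.to_dict(),
            "management": self.management.to_dict(),
            "ww_rituximab": self.ww_rituximab.to_dict(),
        }

    @classmethod
    def from_dict(cls, d):
        upper = d.get("upper")
        return cls(
            lower=float(d["lower"]),
            upper=np.inf if upper is None else float(upper),
            label=str(d["label"]),
            male=BetaParam.from_dict(d["male"]),
            management=DirichletParam.from_dict(d["management"]),
            ww_rituximab=BetaParam.from_dict(d["ww_rituximab"]),
        )


@dataclass
class AgeBandTable:
    bands: list

    def band_for(self, age: float) -> AgeBand:
        # the printed "<=30" label owns the boundary age 30; interior bands
        # are [lo, hi); the top band is open-ended
        if age <= self.bands[0].upper:
            return self.bands[0]
        for band in self.bands[1:]:
            if age < band.upper:
                return band
        return self.bands[-1]

    def to_dict(self):
        return [b.to_dict() for b in self.bands]

    @classmethod
    def from_dict(cls, lst):
        return cls([AgeBand.from_dict(d) for d in lst])


# ---------------------------------------------------------------------------
# utilities and costs
# ---------------------------------------------------------------------------

@dataclass
class UtilityTable:
    values: dict  # phase -> BetaParam

    def utility(self, phase: str) -> float:
        if phase not in self.values:
            raise KeyError(f"no utility defined for phase {phase!r}")
        return self.values[phase].mean()

    def to_dict(self):
        return {k: v.to_dict() for k, v in self.values.items()}

    @classmethod
    def from_dict(cls, d):
        return cls({k: BetaParam.from_dict(v) for k, v in d.items()})


@dataclass
class CostTable:
    """Unit costs in 2016 GBP."""

    inpatient_spell: float
    excess_bed_day: float
    outpatient_first_single: float
    outpatient_first_multi: float
    outpatient_followup_single: float
    outpatient_followup_multi: float
    radiotherapy_planning: float
    radiotherapy_fraction: float
    chemo_cycle: dict          # regimen -> per-cycle cost
    autograft_sct: float
    allogeneic_sct: float
    diagnostic_workup: float   # fixture bundle (biopsy, scans, ECG, ECHO)
    rituximab_administration: float
    end_of_life_daily: float   # fixture
    gbp_to_usd: float

    def to_dict(self):
        d = self.__dict__.copy()
        d["chemo_cycle"] = dict(self.chemo_cycle)
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: (dict(v) if k == "chemo_cycle" else float(v))
                      for k, v in d.items()})


@dataclass
class DlbclAddon:
    """Expected post-transformation cost / survival booked on exit to the
    aggressive-lymphoma model (fixture magnitudes)."""

    cost: float
    life_years: float
    qalys: float
    fixture: bool = True

    def to_dict(self):
        return {"cost": self.cost, "life_years": self.life_years,
                "qalys": self.qalys, "fixture": self.fixture}

    @classmethod
    def from_dict(cls, d):
        return cls(float(d["cost"]), float(d["life_years"]),
                   float(d["qalys"]), bool(d.get("fixture", True)))


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------

@dataclass
class ParameterSet:
    age_spec: TTESpec                  # years
    age_min: float
    max_age: float
    age_bands: AgeBandTable
    stage_ia: BetaParam                # fixture prevalence of stage IA
    flipi: DirichletParam              # reporting covariate only (fixture)
    transitions: dict                  # key -> TTESpec (days)
    utilities: UtilityTable
    costs: CostTable
    discount_rate: float
    sct_prob: BetaParam                # per entry to a line >= 2
    sct_autograft_prob: BetaParam
    regimen_mix: dict                  # line (int) -> {regimen: weight}
    cycles_default: int
    cycles_per_regimen: dict
    rt_fractions_ia: int
    rt_fractions_palliative: int
    monitoring_visits_per_year: float
    induction_administrations: int
    dlbcl_addon: DlbclAddon
    incidence_per_year: float
    transition_fits: dict = field(default_factory=dict, compare=False)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "age": {"spec": self.age_spec.to_dict(), "min": self.age_min,
                    "max": self.max_age},
            "age_bands": self.age_bands.to_dict(),
            "stage_ia": self.stage_ia.to_dict(),
            "flipi": self.flipi.to_dict(),
            "transitions": {k: v.to_dict() for k, v in self.transitions.items()},
            "utilities": self.utilities.to_dict(),
            "costs": self.costs.to_dict(),
            "discount_rate": self.discount_rate,
            "sct": {"prob": self.sct_prob.to_dict(),
                    "autograft_prob": self.sct_autograft_prob.to_dict()},
            "regimens": {"mix": {str(k): dict(v) for k, v in self.regimen_mix.items()},
                         "cycles_default": self.cycles_default,
                         "cycles_per_regimen": dict(self.cycles_per_regimen)},
            "radiotherapy": {"fractions_ia": self.rt_fractions_ia,
                             "fractions_palliative": self.rt_fractions_palliative},
            "monitoring_visits_per_year": self.monitoring_visits_per_year,
            "induction_administrations": self.induction_administrations,
            "dlbcl_addon": self.dlbcl_addon.to_dict(),
            "incidence_per_year": self.incidence_per_year,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        try:
            return cls(
                age_spec=TTESpec.from_dict(d["age"]["spec"]),
                age_min=float(d["age"]["min"]),
                max_age=float(d["age"]["max"]),
                age_bands=AgeBandTable.from_dict(d["age_bands"]),
                stage_ia=BetaParam.from_dict(d["stage_ia"]),
                flipi=DirichletParam.from_dict(d["flipi"]),
                transitions={k: TTESpec.from_dict(v)
                             for k, v in d["transitions"].items()},
                utilities=UtilityTable.from_dict(d["utilities"]),
                costs=CostTable.from_dict(d["costs"]),
                discount_rate=float(d["discount_rate"]),
                sct_prob=BetaParam.from_dict(d["sct"]["prob"]),
                sct_autograft_prob=BetaParam.from_dict(d["sct"]["autograft_prob"]),
                regimen_mix={int(k): dict(v)
                             for k, v in d["regimens"]["mix"].items()},
                cycles_default=int(d["regimens"]["cycles_default"]),
                cycles_per_regimen=dict(d["regimens"].get("cycles_per_regimen", {})),
                rt_fractions_ia=int(d["radiotherapy"]["fractions_ia"]),
                rt_fractions_palliative=int(d["radiotherapy"]["fractions_palliative"]),
                monitoring_visits_per_year=float(d["monitoring_visits_per_year"]),
                induction_administrations=int(d["induction_administrations"]),
                dlbcl_addon=DlbclAddon.from_dict(d["dlbcl_addon"]),
                incidence_per_year=float(d["incidence_per_year"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ParameterSchemaError):
                raise
            raise ParameterSchemaError(f"malformed parameter config: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True,
                              default_flow_style=False)

    def cycles_for(self, regimen: str) -> int:
        return int(self.cycles_per_regimen.get(regimen, self.cycles_default))

    def copy(self) -> "ParameterSet":
        ps = copy.deepcopy(self)
        ps.transition_fits = dict(self.transition_fits)
        return ps


# ---------------------------------------------------------------------------
# loading, defaults, validation
# ---------------------------------------------------------------------------

def _default_dict() -> dict:
    from importlib import resources

    text = resources.files("flsim").joinpath("data/default_fl.yaml").read_text()
    return yaml.safe_load(text)


def default_fl_parameters() -> ParameterSet:
    """The packaged follicular-lymphoma default parameterization."""
    return ParameterSet.from_dict(_default_dict())


def _merge(base: dict, override: dict, path: str = "") -> dict:
    """Deep-merge override into base, rejecting unknown keys."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ParameterSchemaError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            # leaf dicts with free-form keys (chemo costs, regimen mixes,
            # transitions, utilities) replace entry-wise without key checks
            if key in ("chemo_cycle", "cycles_per_regimen", "transitions",
                       "utilities", "mix", "coefficients"):
                merged = copy.deepcopy(base[key])
                merged.update(val)
                out[key] = merged
            else:
                out[key] = _merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
            logger.info("parameter override: %s = %r", here, val)
    return out


def load_parameters(config_text: str | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from YAML text layered over the defaults.

    An empty / ``None`` config returns the defaults. Unknown keys or malformed
    distributions raise :class:`ParameterSchemaError` naming the offending path.
    """
    base = _default_dict()
    if config_text:
        override = yaml.safe_load(io.StringIO(config_text))
        if override is None:
            override = {}
        if not isinstance(override, dict):
            raise ParameterSchemaError("top-level config must be a mapping")
        base = _merge(base, override)
    return ParameterSet.from_dict(base)


def validate_parameters(ps: ParameterSet) -> list:
    """Return a list of invariant violations (empty iff the set is valid)."""
    from .pathway import REQUIRED_TRANSITIONS

    violations = []

    bands = ps.age_bands.bands
    if not bands:
        violations.append("age_bands: empty")
    else:
        if bands[0].lower != ps.age_min:
            violations.append(
                f"age_bands[0].lower = {bands[0].lower}, expected {ps.age_min}")
        for prev, cur in zip(bands, bands[1:]):
            if cur.lower != prev.upper:
                violations.append(
                    f"age_bands: gap between {prev.label} and {cur.label}")
        if not np.isinf(bands[-1].upper):
            violations.append("age_bands: last band must be open-ended")

    for phase, bp in ps.utilities.values.items():
        if not (bp.alpha > 0 and bp.beta > 0):
            violations.append(f"utilities.{phase}: alpha and beta must be > 0")
        if not 0.0 <= bp.mean() <= 1.0:
            violations.append(
                f"utilities.{phase}: point estimate {bp.mean():.3f} outside [0, 1]")
    for phase in UTILITY_PHASES:
        if phase not in ps.utilities.values:
            violations.append(f"utilities: missing phase {phase!r}")

    for key in REQUIRED_TRANSITIONS:
        if key not in ps.transitions:
            violations.append(f"transitions: missing TTESpec for {key!r}")

    for name, value in ps.costs.to_dict().items():
        if name == "chemo_cycle":
            for reg, c in value.items():
                if c < 0:
                    violations.append(f"costs.chemo_cycle.{reg}: negative cost {c}")
        elif name == "gbp_to_usd":
            if value <= 0:
                violations.append(f"costs.gbp_to_usd: must be > 0, got {value}")
        elif value < 0:
            violations.append(f"costs.{name}: negative cost {value}")

    if ps.discount_rate < 0:
        violations.append(f"discount_rate: must be >= 0, got {ps.discount_rate}")
    if ps.dlbcl_addon.cost < 0 or ps.dlbcl_addon.life_years < 0 \
            or ps.dlbcl_addon.qalys < 0:
        violations.append("dlbcl_addon: values must be >= 0")
    if not ps.age_min < ps.max_age:
        violations.append("age: require age_min < max_age")
    for line, mix in ps.regimen_mix.items():
        if not mix or sum(mix.values()) <= 0:
            violations.append(f"regimens.mix.{line}: needs positive weights")
        for reg in mix:
            if reg not in ps.costs.chemo_cycle:
                violations.append(
                    f"regimens.mix.{line}: regimen {reg!r} has no unit cost")
    return violations


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis draws
# ---------------------------------------------------------------------------

_PSA_WARNED: set = set()


def draw_psa_parameters(ps: ParameterSet, rng) -> ParameterSet:
    """One second-order parameter draw.

    Beta proportions and Dirichlet management mixes are redrawn from their
    count distributions; utilities from their Betas; transition coefficients
    from multivariate normals when a fitted covariance is attached
    (``ps.transition_fits``). Transitions without an attached fit fall back to
    their point values with a once-per-key logged warning.
    """
    from .survival import draw_coefficient_uncertainty

    new = ps.copy()
    new.stage_ia = replace(ps.stage_ia, point=ps.stage_ia.draw(rng))
    new.sct_prob = replace(ps.sct_prob, point=ps.sct_prob.draw(rng))
    new.sct_autograft_prob = replace(
        ps.sct_autograft_prob, point=ps.sct_autograft_prob.draw(rng))
    new.age_bands = AgeBandTable([
        replace(
            band,
            male=replace(band.male, point=band.male.draw(rng)),
            management=replace(band.management,
                               point=tuple(band.management.draw(rng))),
            ww_rituximab=replace(band.ww_rituximab,
                                 point=band.ww_rituximab.draw(rng)),
        )
        for band in ps.age_bands.bands
    ])
    new.utilities = UtilityTable({
        phase: replace(bp, point=bp.draw(rng))
        for phase, bp in ps.utilities.values.items()
    })
    transitions = {}
    for key, spec in ps.transitions.items():
        fit = ps.transition_fits.get(key)
        if fit is not None:
            params = draw_coefficient_uncertainty(fit, rng)
            transitions[key] = replace(spec, params=tuple(params))
        else:
            if key not in _PSA_WARNED:
                _PSA_WARNED.add(key)
                logger.warning(
                    "PSA: no uncertainty distribution for transition %r; "
                    "using point values", key)
            transitions[key] = spec
    new.transitions = transitions
    return new
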