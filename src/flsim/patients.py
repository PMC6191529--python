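"""Baseline attribute generation for simulated patients.

Age at diagnosis is drawn from a Weibull (shape 5.57, scale 69.33 years,
mean 64.0) truncated by rejection to the modelled range [18, 100]; sex and
initial management are drawn conditionally on the patient's age band from
Beta / Dirichlet count distributions. Watch-and-wait patients additionally
receive an induction-rituximab decision from the band's Beta.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import MANAGEMENT_CATEGORIES, ParameterSet
from .survival import draw_time

FLIPI_CATEGORIES = ("low", "intermediate", "high")


@dataclass
class PatientAttributes:
    age: float                 # years at diagnosis, in [18, 100]
    sex: str                   # "male" / "female"
    stage_ia: bool
    flipi: str
    management: str            # one of MANAGEMENT_CATEGORIES, with "ww"
    ww_rituximab: bool = False  # induction rituximab during W&W (base case 2%)

    def covariates(self) -> dict:
        """Covariate dictionary for AFT linear predictors."""
        return {
            "age": self.age,
            "male": 1.0 if self.sex == "male" else 0.0,
            "stage_ia": 1.0 if self.stage_ia else 0.0,
        }


def sample_age(ps: ParameterSet, rng) -> float:
    """Rejection-sample the age-at-diagnosis Weibull into [age_min, max_age]."""
    while True:
        age = draw_time(ps.age_spec, rng)
        if ps.age_min <= age <= ps.max_age:
            return age


def sample_sex(age: float, ps: ParameterSet, rng) -> str:
    band = ps.age_bands.band_for(age)
    return "male" if rng.random() < band.male.mean() else "female"


def assign_initial_management(age: float, stage_ia: bool, ps: ParameterSet, rng):
    """Draw the initial-management category for one patient.

    Returns ``(management, ww_rituximab, stage_ia)``. Drawing localized
    radiotherapy forces stage IA (the treatment is only given for IA disease).
    """
    band = ps.age_bands.band_for(age)
    probs = band.management.probs()
    idx = int(rng.choice(len(MANAGEMENT_CATEGORIES), p=probs / probs.sum()))
    management = MANAGEMENT_CATEGORIES[idx]
    ww_rituximab = False
    if management == "radiotherapy_ia":
        stage_ia = True
    elif management == "ww":
        ww_rituximab = rng.random() < band.ww_rituximab.mean()
    return management, ww_rituximab, stage_ia


def sample_patient(ps: ParameterSet, rng) -> PatientAttributes:
    """Sample one complete set of baseline attributes."""
    age = sample_age(ps, rng)
    sex = sample_sex(age, ps, rng)
    stage_ia = rng.random() < ps.stage_ia.mean()
    flipi = FLIPI_CATEGORIES[int(rng.choice(len(FLIPI_CATEGORIES),
                                            p=ps.flipi.probs()))]
    management, ww_rituximab, stage_ia = assign_initial_management(
        age, stage_ia, ps, rng)
    return PatientAttributes(age=age, sex=sex, stage_ia=stage_ia, flipi=flipi,
                             management=management, ww_rituximab=ww_rituximab)
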