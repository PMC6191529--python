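"""Synthetic patient-level registry generation and calibration.

The population-based registry that parameterized the model is confidential,
so this module emulates its observational structure from a known
("true") :class:`ParameterSet`: patients accrue at a constant rate over an
accrual window (default 7 years, 740 patients), are followed for a further
period (default 4 years), and every per-transition observation is
administratively right-censored at the end of follow-up. Competing events
censor each other: when a phase is exited by one event, the other candidate
events of that phase contribute right-censored rows at the same sojourn time.

``calibrate`` then replays the study's estimation workflow on the registry:
censored maximum-likelihood fits of all six parametric families per
transition with AIC selection, and Beta / Dirichlet attribute distributions
re-estimated as raw observed counts. The round trip (simulate a registry,
calibrate, re-simulate) is the package's parameter-recovery harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import accumulate_outcomes
from .parameters import (DAYS_PER_YEAR, MANAGEMENT_CATEGORIES, AgeBand,
                         AgeBandTable, BetaParam, DirichletParam, ParameterSet)
from .pathway import MAX_LINE_PARAMS, REQUIRED_TRANSITIONS, simulate_patient
from .patients import sample_patient
from .survival import fit_all_families, km_sup_distance, kaplan_meier, survival_function

logger = logging.getLogger("flsim")

_PHASE_CANDIDATE_KEYS = {
    "pretreatment": ("pretreatment_to_management",),
    "ww": ("ww_to_treatment", "ww_to_transform", "ww_to_death"),
    "end_of_life": ("end_of_life_death",),
}

_WINNER_KEY = {
    ("ww", "start-treatment"): "ww_to_treatment",
    ("ww", "transform"): "ww_to_transform",
    ("ww", "die"): "ww_to_death",
    ("treatment", "respond"): "response",
    ("treatment", "refractory-next-treatment"): "refractory",
    ("treatment", "die"): "death",
    ("treatment", "transform"): "transform",
    ("remission", "relapse"): "relapse",
    ("remission", "transform"): "transform",
    ("remission", "die"): "death",
    ("end_of_life", "die"): "end_of_life_death",
}


@dataclass
class RegistryData:
    attributes: pd.DataFrame    # one row per patient
    transitions: pd.DataFrame   # flat per-transition rows (time, event flag)
    censor_days: float          # administrative end of follow-up (calendar)
    trajectories: list = field(default_factory=list, repr=False)


def _phase_visits(traj):
    """Reconstruct (phase, line, t_entry, t_exit, exit_event) visits."""
    visits = []
    phase, line, t_entry = "pretreatment", 0, 0.0
    for rec in traj.records:
        if rec.event in ("diagnosis", "sct", "induction-dose",
                         "maintenance-dose"):
            continue
        visits.append((phase, line, t_entry, rec.time_days, rec.event))
        if rec.event == "horizon-truncate" or rec.phase_to in (
                "dead", "transformed_exit"):
            break
        phase = rec.phase_to
        line = rec.detail.get("line", 0)
        t_entry = rec.time_days
    return visits


def _candidate_keys(phase, line):
    if phase in _PHASE_CANDIDATE_KEYS:
        return _PHASE_CANDIDATE_KEYS[phase]
    lk = min(line, MAX_LINE_PARAMS)
    if phase == "treatment":
        return tuple(f"treatment{lk}_{ev}"
                     for ev in ("response", "refractory", "death", "transform"))
    if phase == "remission":
        return tuple(f"remission{lk}_{ev}"
                     for ev in ("relapse", "death", "transform"))
    raise ValueError(phase)


def _winner_key(phase, line, event):
    if phase == "pretreatment":
        return "pretreatment_to_management"
    name = _WINNER_KEY[(phase, event)]
    if phase in ("treatment", "remission"):
        return f"{phase}{min(line, MAX_LINE_PARAMS)}_{name}"
    return name


def generate_registry(true_ps: ParameterSet, n: int = 740,
                      accrual_years: float = 7.0,
                      followup_years: float = 4.0,
                      seed: int = 0,
                      keep_trajectories: bool = False) -> RegistryData:
    """Simulate an administratively censored registry from known parameters.

    Entries are uniform over the accrual window; each patient's trajectory is
    truncated at the calendar end of follow-up
    (``accrual_years + followup_years`` after the window opens).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.SeedSequence(seed)
    entry_ss, *patient_ss = master.spawn(n + 1)
    entry_rng = np.random.default_rng(entry_ss)
    censor_days = (accrual_years + followup_years) * DAYS_PER_YEAR
    entries = np.sort(entry_rng.uniform(0, accrual_years * DAYS_PER_YEAR, n))

    attr_rows, trans_rows, trajs = [], [], []
    for pid, (entry, ss) in enumerate(zip(entries, patient_ss)):
        rng = np.random.default_rng(ss)
        attrs = sample_patient(true_ps, rng)
        horizon = censor_days - entry
        traj = simulate_patient(attrs, true_ps, rng, horizon_days=horizon)
        attr_rows.append({
            "patient_id": pid, "entry_days": entry, "age": attrs.age,
            "sex": attrs.sex, "stage_ia": attrs.stage_ia, "flipi": attrs.flipi,
            "management": attrs.management, "ww_rituximab": attrs.ww_rituximab,
        })
        for phase, line, t0, t1, event in _phase_visits(traj):
            sojourn = t1 - t0
            if sojourn <= 0:
                continue
            win = None if event == "horizon-truncate" else _winner_key(
                phase, line, event)
            for key in _candidate_keys(phase, line):
                trans_rows.append({
                    "patient_id": pid, "transition": key,
                    "time_days": sojourn, "event": int(key == win),
                })
        if keep_trajectories:
            trajs.append(traj)
    return RegistryData(
        attributes=pd.DataFrame(attr_rows),
        transitions=pd.DataFrame(trans_rows),
        censor_days=censor_days,
        trajectories=trajs,
    )


def _recount_bands(base_table: AgeBandTable, attrs: pd.DataFrame):
    bands = []
    for band in base_table.bands:
        if np.isinf(band.upper):
            in_band = attrs["age"] > band.lower
        elif band.lower == base_table.bands[0].lower:
            in_band = attrs["age"] <= band.upper
        else:
            in_band = (attrs["age"] > band.lower) & (attrs["age"] <= band.upper)
        sub = attrs[in_band]
        if len(sub) == 0:
            logger.warning("calibrate: no patients in band %s; keeping prior",
                           band.label)
            bands.append(band)
            continue
        male = int((sub["sex"] == "male").sum())
        mgmt = tuple(int((sub["management"] == cat).sum())
                     for cat in MANAGEMENT_CATEGORIES)
        ww = sub[sub["management"] == "ww"]
        ritux = int(ww["ww_rituximab"].sum())
        bands.append(AgeBand(
            lower=band.lower, upper=band.upper, label=band.label,
            male=BetaParam(male, len(sub) - male),
            management=(DirichletParam(mgmt) if any(mgmt)
                        else band.management),
            ww_rituximab=(BetaParam(ritux, len(ww) - ritux) if len(ww)
                          else band.ww_rituximab),
        ))
    return AgeBandTable(bands)


def calibrate(registry: RegistryData, base_ps: ParameterSet,
              min_events: int = 2, keys=None):
    """Fit all six families per observed transition and re-estimate attribute
    counts; returns ``(fitted_ps, selection_reports)``.

    Transitions with fewer than ``min_events`` observed events keep the prior
    (fixture) specification, with a logged warning. ``keys`` restricts fitting
    to a subset of transitions (all observed ones by default).
    """
    if len(registry.transitions) == 0:
        raise ValueError("empty registry")
    fitted = base_ps.copy()
    fitted.age_bands = _recount_bands(base_ps.age_bands, registry.attributes)

    reports = {}
    for key, chunk in registry.transitions.groupby("transition"):
        if keys is not None and key not in keys:
            continue
        times = chunk["time_days"].to_numpy(dtype=float)
        events = chunk["event"].to_numpy(dtype=int)
        if events.sum() < min_events:
            logger.warning("calibrate: %s has %d events (< %d); keeping prior",
                           key, int(events.sum()), min_events)
            continue
        report = fit_all_families(times, events)
        reports[key] = report
        fitted.transitions[key] = report.best.spec()
        fitted.transition_fits[key] = report.best
    return fitted, reports


def recovery_report(true_ps: ParameterSet, fitted_ps: ParameterSet,
                    registry: RegistryData | None = None,
                    horizon_years: float = 10.0) -> pd.DataFrame:
    """Per-transition comparison of generating and recovered specifications.

    Reports the selected vs generating family, the sup distance between the
    two survival curves on [0, horizon], the maximum relative parameter error
    when the families coincide, and (when the registry is supplied) the sup
    distance between the fitted curve and the registry Kaplan-Meier.
    """
    grid = np.linspace(1.0, horizon_years * DAYS_PER_YEAR, 400)
    rows = []
    for key in REQUIRED_TRANSITIONS:
        true_spec = true_ps.transitions[key]
        fit_spec = fitted_ps.transitions[key]
        sup = float(np.max(np.abs(survival_function(true_spec, grid)
                                  - survival_function(fit_spec, grid))))
        if fit_spec.family == true_spec.family:
            rel = max(abs(a - b) / abs(b) if b != 0 else abs(a - b)
                      for a, b in zip(fit_spec.params, true_spec.params))
        else:
            rel = np.nan
        row = {"transition": key, "true_family": true_spec.family,
               "fitted_family": fit_spec.family,
               "recovered": key in fitted_ps.transition_fits,
               "sup_distance": sup, "max_rel_param_error": rel}
        if registry is not None:
            chunk = registry.transitions[
                registry.transitions["transition"] == key]
            if len(chunk) and chunk["event"].sum() > 0:
                km = kaplan_meier(chunk["time_days"].to_numpy(),
                                  chunk["event"].to_numpy())
                row["km_sup_distance"] = km_sup_distance(
                    km, fit_spec, t_max=horizon_years * DAYS_PER_YEAR)
            else:
                row["km_sup_distance"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_means(ps: ParameterSet, n: int, seed: int,
                 include_dlbcl: bool = False) -> dict:
    """Mean lifetime discounted cost / LY / QALY of a freshly simulated cohort
    (one iteration); the round-trip recovery metric."""
    master = np.random.SeedSequence(seed)
    cost = ly = qaly = 0.0
    for ss in master.spawn(n):
        rng = np.random.default_rng(ss)
        traj = simulate_patient(sample_patient(ps, rng), ps, rng)
        out = accumulate_outcomes(traj, ps, include_dlbcl=include_dlbcl)
        cost += out.cost
        ly += out.life_years
        qaly += out.qalys
    return {"cost": cost / n, "life_years": ly / n, "qalys": qaly / n}
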