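"""Costing, discounting and QALY accounting for simulated trajectories.

Continuous accrual (life-years, QALYs, monitoring and end-of-life care) over
an interval ``[t0, t1]`` (years) is discounted with the closed form

    w(t0, t1; r) = ((1+r)^(-t0) - (1+r)^(-t1)) / ln(1+r)

which reduces to ``t1 - t0`` when ``r = 0``. Point costs at time ``t`` are
weighted ``(1+r)^(-t)``. The default annual rate is 3.5%.

Resource-use decisions (which regimen, how many fractions, transplant type,
rituximab administrations) are made by the pathway engine and carried on the
trajectory's event records; this module only prices and discounts them, so a
trajectory can be re-costed under different unit costs or discount rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .parameters import DAYS_PER_YEAR, ParameterSet
from .pathway import PatientTrajectory

#: utility phases that accrue routine monitoring visits
_MONITORED_PHASES = ("ww", "first_remission", "subsequent_remission")


def discount_weight(t0: float, t1: float, rate: float) -> float:
    """Discounted duration of the interval ``[t0, t1]`` (times in years)."""
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0.0:
        return t1 - t0
    ln1r = math.log1p(rate)
    return ((1.0 + rate) ** (-t0) - (1.0 + rate) ** (-t1)) / ln1r


def point_weight(t: float, rate: float) -> float:
    """Discount factor for a point cost at time ``t`` (years)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return (1.0 + rate) ** (-t)


def convert_currency(gbp: float, rate: float, round_to_unit: bool = False):
    """GBP -> USD at the configured exchange rate (default 1.2505)."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    usd = gbp * rate
    return float(round(usd)) if round_to_unit else usd


@dataclass
class Outcomes:
    """Discounted and undiscounted outcomes for one trajectory."""

    cost: float
    cost_undiscounted: float
    life_years: float
    life_years_undiscounted: float
    qalys: float
    qalys_undiscounted: float
    cost_usd: float
    phase_costs: dict = field(default_factory=dict)
    includes_dlbcl: bool = False


def _treatment_start_cost(detail: dict, ps: ParameterSet) -> float:
    modality = detail["modality"]
    if modality == "chemotherapy":
        return detail["cycles"] * ps.costs.chemo_cycle[detail["regimen"]]
    # radiotherapy: planning plus per-fraction cost
    return (ps.costs.radiotherapy_planning
            + detail["fractions"] * ps.costs.radiotherapy_fraction)


def accumulate_outcomes(traj: PatientTrajectory, ps: ParameterSet,
                        rate: float | None = None,
                        horizon_years: float | None = None,
                        include_dlbcl: bool = False) -> Outcomes:
    """Price a trajectory and accrue (Q)ALYs, optionally restricted to a
    finite horizon (restricted means: censoring, not forced death)."""
    r = ps.discount_rate if rate is None else rate
    h_days = math.inf if horizon_years is None else horizon_years * DAYS_PER_YEAR

    cost_d = cost_u = 0.0
    phase_costs: dict = {}

    def book(label, t_days, amount):
        nonlocal cost_d, cost_u
        if t_days > h_days or amount == 0.0:
            return
        cost_u += amount
        cost_d += amount * point_weight(t_days / DAYS_PER_YEAR, r)
        phase_costs[label] = phase_costs.get(label, 0.0) + amount

    book("diagnosis", 0.0, ps.costs.diagnostic_workup)
    for rec in traj.records:
        if rec.event == "sct":
            book("sct", rec.time_days,
                 ps.costs.autograft_sct if rec.detail["sct_type"] == "autograft"
                 else ps.costs.allogeneic_sct)
        elif rec.event in ("induction-dose", "maintenance-dose"):
            book("rituximab_monotherapy", rec.time_days,
                 ps.costs.rituximab_administration)
        elif "modality" in rec.detail:
            book("treatment", rec.time_days, _treatment_start_cost(rec.detail, ps))

    ly_d = ly_u = q_d = q_u = 0.0
    monitoring_annual = ps.monitoring_visits_per_year * \
        ps.costs.outpatient_followup_single
    eol_annual = ps.costs.end_of_life_daily * DAYS_PER_YEAR
    for phase, t0, t1 in traj.segments:
        t1 = min(t1, h_days)
        if t1 <= t0:
            continue
        y0, y1 = t0 / DAYS_PER_YEAR, t1 / DAYS_PER_YEAR
        w = discount_weight(y0, y1, r)
        dur = y1 - y0
        u = ps.utilities.utility(phase)
        ly_d += w
        ly_u += dur
        q_d += u * w
        q_u += u * dur
        if phase in _MONITORED_PHASES:
            amt = monitoring_annual
        elif phase == "not_treated":
            amt = eol_annual
        else:
            amt = 0.0
        if amt:
            cost_u += amt * dur
            cost_d += amt * w
            phase_costs["supportive_care"] = \
                phase_costs.get("supportive_care", 0.0) + amt * dur

    applied_dlbcl = False
    if include_dlbcl and traj.transform_time_days is not None \
            and traj.transform_time_days <= h_days:
        ty = traj.transform_time_days / DAYS_PER_YEAR
        pw = point_weight(ty, r)
        addon = ps.dlbcl_addon
        cost_u += addon.cost
        cost_d += addon.cost * pw
        ly_u += addon.life_years
        ly_d += addon.life_years * pw
        q_u += addon.qalys
        q_d += addon.qalys * pw
        phase_costs["dlbcl"] = phase_costs.get("dlbcl", 0.0) + addon.cost
        applied_dlbcl = True

    return Outcomes(
        cost=cost_d, cost_undiscounted=cost_u,
        life_years=ly_d, life_years_undiscounted=ly_u,
        qalys=q_d, qalys_undiscounted=q_u,
        cost_usd=convert_currency(cost_d, ps.costs.gbp_to_usd),
        phase_costs=phase_costs,
        includes_dlbcl=applied_dlbcl,
    )


def cost_in_window(traj: PatientTrajectory, ps: ParameterSet,
                   entry_time_days: float, window_start_days: float,
                   window_end_days: float, include_dlbcl: bool = False) -> float:
    """Undiscounted cost a patient accrues inside an absolute calendar window.

    Used by the prevalence (open-cohort) analysis: point costs are booked when
    their calendar time falls in the window; continuously accruing costs are
    prorated by overlap. ``entry_time_days`` is the patient's diagnosis date
    on the calendar axis of the window.
    """
    lo = window_start_days - entry_time_days   # window on the patient clock
    hi = window_end_days - entry_time_days
    if hi <= 0:
        return 0.0
    total = 0.0
    if lo <= 0.0 <= hi:
        total += ps.costs.diagnostic_workup
    for rec in traj.records:
        if not (lo <= rec.time_days <= hi):
            continue
        if rec.event == "sct":
            total += (ps.costs.autograft_sct
                      if rec.detail["sct_type"] == "autograft"
                      else ps.costs.allogeneic_sct)
        elif rec.event in ("induction-dose", "maintenance-dose"):
            total += ps.costs.rituximab_administration
        elif "modality" in rec.detail:
            total += _treatment_start_cost(rec.detail, ps)
    monitoring_annual = ps.monitoring_visits_per_year * \
        ps.costs.outpatient_followup_single
    for phase, t0, t1 in traj.segments:
        o0, o1 = max(t0, lo), min(t1, hi)
        if o1 <= o0:
            continue
        if phase in _MONITORED_PHASES:
            total += monitoring_annual * (o1 - o0) / DAYS_PER_YEAR
        elif phase == "not_treated":
            total += ps.costs.end_of_life_daily * (o1 - o0)
    if include_dlbcl and traj.transform_time_days is not None \
            and lo <= traj.transform_time_days <= hi:
        total += ps.dlbcl_addon.cost
    return total
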