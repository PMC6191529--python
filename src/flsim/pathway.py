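"""Discrete-event pathway engine.

Each patient is advanced from diagnosis through the remitting-relapsing
pathway by sampling a time for every event that can happen next in the
current health phase and taking the earliest (a competing-risks race),
until death, transformation to aggressive disease (an absorbing exit),
age 100, or a configured horizon.

Phases and legal moves::

    pretreatment -> {W&W, first-line treatment, end-of-life}
    W&W          -> {first-line treatment, transform, death}
    treatment L  -> {remission L (response), treatment L+1 (refractory),
                     transform, death}
    remission L  -> {treatment L+1 (relapse), transform, death}
    end-of-life  -> {death}

Treatment lines beyond the third reuse line-3 parameters. Stem cell
transplant can occur (once) on entry to any line >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import DAYS_PER_YEAR, ParameterSet
from .patients import PatientAttributes
from .survival import apply_hazard_ratio, sample_time

#: transition keys every valid ParameterSet must provide
REQUIRED_TRANSITIONS = tuple(
    ["pretreatment_to_management", "ww_to_treatment", "ww_to_transform",
     "ww_to_death", "end_of_life_death"]
    + [f"treatment{line}_{ev}" for line in (1, 2, 3)
       for ev in ("response", "refractory", "death", "transform")]
    + [f"remission{line}_{ev}" for line in (1, 2, 3)
       for ev in ("relapse", "death", "transform")]
)

#: tie-break priority when sampled times coincide exactly (higher wins)
_EVENT_PRIORITY = {
    "die": 5,
    "transform": 4,
    "respond": 3,
    "relapse": 2,
    "refractory-next-treatment": 2,
    "start-treatment": 2,
    "start-management": 1,
}

MAX_LINE_PARAMS = 3  # lines beyond the third reuse line-3 parameters

SUBGROUPS = ("ww_only", "first_line_only", "second_line_plus_sct",
             "second_line_plus_no_sct", "not_treated")


@dataclass
class EventRecord:
    time_days: float
    phase_from: str | None
    event: str
    phase_to: str
    detail: dict = field(default_factory=dict)


@dataclass
class PatientTrajectory:
    attributes: PatientAttributes
    records: list                    # ordered EventRecords
    segments: list                   # (utility_phase, t0_days, t1_days)
    terminal_status: str             # dead / transformed_exit / censored_*
    terminal_time_days: float
    max_line: int
    had_sct: bool
    sct_type: str | None = None
    transform_time_days: float | None = None

    def sojourn_days(self) -> dict:
        out: dict = {}
        for phase, t0, t1 in self.segments:
            out[phase] = out.get(phase, 0.0) + (t1 - t0)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"time_days": r.time_days, "phase_from": r.phase_from,
             "event": r.event, "phase_to": r.phase_to, **r.detail}
            for r in self.records
        ]
        return pd.DataFrame(rows)


@dataclass
class PhaseState:
    phase: str            # pretreatment / ww / treatment / remission / end_of_life
    line: int = 0
    had_sct: bool = False

    @property
    def line_key(self) -> int:
        return min(self.line, MAX_LINE_PARAMS)


def advance_line(state: PhaseState) -> PhaseState:
    """Move the state onto the next treatment line (parameters capped at 3)."""
    return PhaseState(phase="treatment", line=state.line + 1,
                      had_sct=state.had_sct)


def utility_phase(state: PhaseState) -> str:
    if state.phase == "pretreatment":
        return "pretreatment"
    if state.phase == "ww":
        return "ww"
    if state.phase == "end_of_life":
        return "not_treated"
    if state.phase == "treatment":
        return "first_line_treatment" if state.line == 1 else "subsequent_treatment"
    if state.phase == "remission":
        return "first_remission" if state.line == 1 else "subsequent_remission"
    raise ValueError(state.phase)


def competing_event(candidates, rng, covariates=None):
    """Race the candidate events; return ``(event_name, elapsed_days)``.

    ``candidates`` is an ordered list of ``(event_name, TTESpec)``. One
    uniform variate is consumed per candidate, in list order, so draws are
    reproducible for a given generator state. Exact ties are broken by the
    fixed event priority (death > transformation > response > relapse).
    """
    if not candidates:
        raise ValueError("phase has no candidate events configured")
    best_name, best_t = None, np.inf
    for name, spec in candidates:
        u = rng.uniform(1e-15, 1.0)
        t = sample_time(spec, u, covariates=covariates)
        if t < best_t or (t == best_t and
                          _EVENT_PRIORITY.get(name, 0) >
                          _EVENT_PRIORITY.get(best_name, 0)):
            best_name, best_t = name, t
    return best_name, float(best_t)


def _phase_candidates(state: PhaseState, ps: ParameterSet, hr_overrides):
    """Ordered candidate (event, spec) list for the current phase."""
    trans = ps.transitions

    def spec_for(key):
        s = trans[key]
        h = hr_overrides.get(key)
        return apply_hazard_ratio(s, h) if h else s

    if state.phase == "ww":
        return [("start-treatment", spec_for("ww_to_treatment")),
                ("transform", spec_for("ww_to_transform")),
                ("die", spec_for("ww_to_death"))]
    if state.phase == "treatment":
        lk = state.line_key
        return [("respond", spec_for(f"treatment{lk}_response")),
                ("refractory-next-treatment", spec_for(f"treatment{lk}_refractory")),
                ("transform", spec_for(f"treatment{lk}_transform")),
                ("die", spec_for(f"treatment{lk}_death"))]
    if state.phase == "remission":
        lk = state.line_key
        return [("relapse", spec_for(f"remission{lk}_relapse")),
                ("transform", spec_for(f"remission{lk}_transform")),
                ("die", spec_for(f"remission{lk}_death"))]
    if state.phase == "end_of_life":
        return [("die", spec_for("end_of_life_death"))]
    raise ValueError(f"no candidates for phase {state.phase!r}")


def _dose_records(t_start, t_stop, interval_days, max_doses, first_offset,
                  label):
    """Administration records every ``interval_days`` while in the phase.

    A dose falling exactly on the stop boundary (e.g. the final maintenance
    dose at the 24-month cap) is included; times are computed directly from
    the index so float accumulation cannot drop it.
    """
    records = []
    for j in range(max_doses):
        t = t_start + first_offset + j * interval_days
        if t - t_stop > 1e-9:
            break
        records.append(EventRecord(t, None, label, "", {}))
    return records


def simulate_patient(attrs: PatientAttributes, ps: ParameterSet, rng,
                     scenario=None, scenario_rng=None,
                     horizon_days: float | None = None) -> PatientTrajectory:
    """Simulate one patient from diagnosis to death, exit, age 100 or horizon.

    ``scenario`` (a :class:`flsim.scenarios.ScenarioSpec`) modifies eligible
    patients' transitions and books extra rituximab administrations; scenario
    take-up decisions consume ``scenario_rng`` so that the main event stream
    is unchanged for patients the scenario does not touch.
    """
    age_cap_days = (ps.max_age - attrs.age) * DAYS_PER_YEAR
    t_max = age_cap_days if horizon_days is None else min(age_cap_days,
                                                          horizon_days)
    cap_is_age = age_cap_days <= (np.inf if horizon_days is None else horizon_days)

    hr_overrides: dict = {}
    extra_records: list = []
    induction_uptake = False
    maintenance_uptake = False
    if scenario is not None:
        if scenario_rng is None:
            raise ValueError("scenario requires a dedicated scenario_rng")
        u_take = scenario_rng.random()   # always consumed: stream stability
        if scenario.kind == "induction_ww":
            eligible = attrs.management == "ww" and not attrs.ww_rituximab
            induction_uptake = eligible and u_take < scenario.uptake
            if induction_uptake:
                hr_overrides["ww_to_treatment"] = scenario.hazard_ratio
        elif scenario.kind == "maintenance":
            maintenance_uptake = u_take < scenario.uptake
            if maintenance_uptake:
                for line in (1, 2, 3):
                    hr_overrides[f"remission{line}_relapse"] = scenario.hazard_ratio
        else:
            raise ValueError(f"unknown scenario kind {scenario.kind!r}")

    records = [EventRecord(0.0, None, "diagnosis", "pretreatment",
                           {"management": attrs.management})]
    segments: list = []
    state = PhaseState(phase="pretreatment")
    t = 0.0
    status = None
    sct_type = None
    transform_time = None
    max_line = 0

    def truncate(at):
        nonlocal status, t
        segments.append((utility_phase(state), t, at))
        status = "censored_age_100" if cap_is_age else "censored_horizon"
        records.append(EventRecord(at, state.phase, "horizon-truncate",
                                   "censored"))
        t = at

    for _ in range(100000):
        if state.phase == "pretreatment":
            u = rng.uniform(1e-15, 1.0)
            dt = sample_time(ps.transitions["pretreatment_to_management"], u)
            t_next = t + dt
            if t_next > t_max:
                truncate(t_max)
                break
            segments.append(("pretreatment", t, t_next))
            if attrs.management == "not_treated":
                records.append(EventRecord(t_next, "pretreatment",
                                           "start-end-of-life", "end_of_life"))
                state = PhaseState(phase="end_of_life")
            elif attrs.management == "ww":
                records.append(EventRecord(t_next, "pretreatment", "start-ww",
                                           "ww"))
                state = PhaseState(phase="ww")
                n_ind = ps.induction_administrations
                if attrs.ww_rituximab or induction_uptake:
                    extra_records.append(("induction", t_next, n_ind))
            else:
                state = _start_treatment_line(
                    records, t_next, "pretreatment", "start-treatment",
                    PhaseState(phase="ww"), attrs, ps, rng)
                max_line = max(max_line, state.line)
            t = t_next
            continue

        event, dt = competing_event(
            _phase_candidates(state, ps, hr_overrides), rng,
            covariates=attrs.covariates())
        t_next = t + dt
        if state.phase == "remission" and maintenance_uptake:
            # doses accrue over the realized (possibly truncated) sojourn
            extra_records.append(("maintenance", t, min(t_next, t_max)))
        if t_next > t_max:
            truncate(t_max)
            break
        phase_label = utility_phase(state)
        segments.append((phase_label, t, t_next))

        if event == "die":
            records.append(EventRecord(t_next, state.phase, "die", "dead"))
            status = "dead"
            t = t_next
            break
        if event == "transform":
            records.append(EventRecord(t_next, state.phase, "transform",
                                       "transformed_exit"))
            status = "transformed_exit"
            transform_time = t_next
            t = t_next
            break
        if event == "respond":
            new_state = PhaseState(phase="remission", line=state.line,
                                   had_sct=state.had_sct)
            records.append(EventRecord(t_next, state.phase, "respond",
                                       "remission", {"line": state.line}))
            state = new_state
        elif event in ("start-treatment", "relapse", "refractory-next-treatment"):
            state = _start_treatment_line(records, t_next, state.phase, event,
                                          state, attrs, ps, rng)
            max_line = max(max_line, state.line)
            if state.had_sct and sct_type is None:
                sct_type = records[-1].detail.get("sct_type")
        else:  # pragma: no cover - guarded by _phase_candidates
            raise AssertionError(f"illegal event {event!r} in {state.phase!r}")
        t = t_next
    else:  # pragma: no cover
        raise AssertionError("trajectory failed to terminate")

    # book rituximab administration schedules (clipped at the terminal time)
    for kind, t0, arg in extra_records:
        if kind == "induction":
            records.extend(_dose_records(t0, min(t, t_max), 7.0, int(arg), 0.0,
                                         "induction-dose"))
        else:  # maintenance: one dose every 2 months, max 24 months
            month = DAYS_PER_YEAR / 12.0
            records.extend(_dose_records(t0, min(arg, t0 + 24 * month),
                                         2 * month, 12, 2 * month,
                                         "maintenance-dose"))
    records.sort(key=lambda r: (r.time_days,
                                0 if r.event in ("diagnosis",) else 1))

    sct_records = [r for r in records if r.event == "sct"]
    return PatientTrajectory(
        attributes=attrs,
        records=records,
        segments=segments,
        terminal_status=status,
        terminal_time_days=min(t, t_max) if status else t_max,
        max_line=max_line,
        had_sct=bool(sct_records),
        sct_type=sct_records[0].detail["sct_type"] if sct_records else None,
        transform_time_days=transform_time,
    )


def _start_treatment_line(records, t, phase_from, event, state, attrs, ps, rng):
    """Enter the next treatment line, booking therapy and SCT decisions."""
    new_state = advance_line(state)
    line = new_state.line
    if line == 1 and attrs.management == "radiotherapy_ia":
        detail = {"line": line, "modality": "radiotherapy_ia",
                  "fractions": ps.rt_fractions_ia}
    elif line == 1 and attrs.management == "radiotherapy_other":
        detail = {"line": line, "modality": "radiotherapy_palliative",
                  "fractions": ps.rt_fractions_palliative}
    else:
        mix = ps.regimen_mix[min(line, MAX_LINE_PARAMS)]
        regs = sorted(mix)
        w = np.array([mix[r] for r in regs], dtype=float)
        regimen = regs[int(rng.choice(len(regs), p=w / w.sum()))]
        detail = {"line": line, "modality": "chemotherapy", "regimen": regimen,
                  "cycles": ps.cycles_for(regimen)}
    records.append(EventRecord(t, phase_from, event
                               if event != "start-treatment" else event,
                               "treatment", detail))
    if line >= 2 and not new_state.had_sct:
        if rng.random() < ps.sct_prob.mean():
            sct_type = ("autograft"
                        if rng.random() < ps.sct_autograft_prob.mean()
                        else "allogeneic")
            records.append(EventRecord(t, "treatment", "sct", "treatment",
                                       {"sct_type": sct_type}))
            new_state.had_sct = True
    return new_state


def classify_pathway(traj: PatientTrajectory) -> str:
    """Assign the trajectory to exactly one reporting subgroup.

    The five labels partition any cohort: untreated palliative patients;
    patients who never started therapy (watch-and-wait throughout, including
    the rare trajectory censored before management began); first-line only;
    and second-line-plus with / without a stem cell transplant.
    """
    if traj.attributes.management == "not_treated":
        return "not_treated"
    if traj.max_line == 0:
        return "ww_only"
    if traj.max_line == 1:
        return "first_line_only"
    return "second_line_plus_sct" if traj.had_sct else "second_line_plus_no_sct"
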