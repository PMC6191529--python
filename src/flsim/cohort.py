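"""Cohort orchestration: incidence and prevalence analyses and PSA.

Two analysis modes mirror the two policy questions:

* **incidence** — a closed cohort of newly diagnosed patients (default 1860,
  the expected UK annual case load) followed from diagnosis over horizons of
  5-30 years and lifetime (death or age 100), reporting per-subgroup mean
  discounted cost, life-years and QALYs with 95% percentile intervals across
  Monte Carlo iterations;
* **prevalence** — an open cohort with constant-rate arrivals at the annual
  incidence; after a burn-in (default 30 years) the undiscounted cost accrued
  by everyone alive during a 1-year observation window estimates the annual
  national burden.

Probabilistic sensitivity analysis redraws every second-order parameter
(Beta / Dirichlet / multivariate-normal survival coefficients) once per
iteration before the first-order patient draws.

Reproducibility contract: all randomness descends from the master seed via
``numpy.random.SeedSequence`` spawning — one stream per iteration, two per
patient (pathway and scenario decisions), so scenario uptake never perturbs
the event stream of unaffected patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import accumulate_outcomes, cost_in_window, point_weight
from .parameters import DAYS_PER_YEAR, ParameterSet, draw_psa_parameters
from .pathway import SUBGROUPS, classify_pathway, simulate_patient
from .patients import sample_patient

#: standard reporting horizons in years; None denotes lifetime
DEFAULT_HORIZONS = (5, 10, 15, 20, 25, 30, None)


@dataclass
class SimulationConfig:
    mode: str = "incidence"
    cohort_size: int = 1860
    iterations: int = 1000
    horizons_years: tuple = DEFAULT_HORIZONS
    burn_in_years: float = 30.0
    window_years: float = 1.0
    seed: int = 0
    include_dlbcl: bool = True
    psa: bool = False
    deterministic_arrivals: bool = False

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if self.burn_in_years < 0:
            raise ValueError("burn_in_years must be >= 0")
        for h in self.horizons_years:
            if h is not None and h <= 0:
                raise ValueError("horizons must be positive")

    def signature(self) -> tuple:
        return (self.mode, self.cohort_size, self.iterations,
                self.burn_in_years, self.window_years, self.seed,
                self.include_dlbcl, self.psa, self.deterministic_arrivals)


@dataclass
class CohortSummary:
    """Per-subgroup, per-horizon means with 95% percentile intervals."""

    table: pd.DataFrame
    per_iteration: pd.DataFrame
    config: SimulationConfig

    def row(self, subgroup: str, horizon=None) -> pd.Series:
        key = "lifetime" if horizon is None else horizon
        t = self.table
        hit = t[(t["subgroup"] == subgroup) & (t["horizon"] == key)]
        if hit.empty:
            raise KeyError((subgroup, horizon))
        return hit.iloc[0]


@dataclass
class PrevalenceResult:
    annual_costs: np.ndarray          # per iteration, GBP (undiscounted)
    annual_costs_fl_only: np.ndarray
    alive_counts: np.ndarray          # mean in-system count per iteration
    config_signature: tuple = field(default_factory=tuple)

    @property
    def mean_annual_cost(self):
        return float(np.mean(self.annual_costs))

    @property
    def min_annual_cost(self):
        return float(np.min(self.annual_costs))

    @property
    def max_annual_cost(self):
        return float(np.max(self.annual_costs))

    @property
    def mean_alive(self):
        return float(np.mean(self.alive_counts))


def _patient_rngs(iter_ss, n):
    kids = iter_ss.spawn(2 * n)
    for i in range(n):
        yield (np.random.default_rng(kids[2 * i]),
               np.random.default_rng(kids[2 * i + 1]))


def _addon_contribution(traj, ps, rate, h_days):
    """(cost, ly, qaly) triples, discounted and undiscounted, for the
    transformation add-on inside the horizon."""
    tt = traj.transform_time_days
    if tt is None or tt > h_days:
        return 0.0, 0.0, 0.0
    pw = point_weight(tt / DAYS_PER_YEAR, rate)
    a = ps.dlbcl_addon
    return a.cost * pw, a.life_years * pw, a.qalys * pw


def _simulate_iteration(ps, config, scenario, iter_ss):
    """One cohort of first-order draws; returns per-(horizon, subgroup) rows."""
    horizons = config.horizons_years
    acc: dict = {}
    for main_rng, scen_rng in _patient_rngs(iter_ss, config.cohort_size):
        attrs = sample_patient(ps, main_rng)
        traj = simulate_patient(attrs, ps, main_rng, scenario=scenario,
                                scenario_rng=scen_rng if scenario else None)
        group = classify_pathway(traj)
        for h in horizons:
            out = accumulate_outcomes(traj, ps, horizon_years=h,
                                      include_dlbcl=False)
            h_days = np.inf if h is None else h * DAYS_PER_YEAR
            ac, aly, aq = _addon_contribution(traj, ps, ps.discount_rate, h_days)
            key = ("lifetime" if h is None else h, group)
            bucket = acc.setdefault(key, np.zeros(7))
            bucket += (1, out.cost, out.life_years, out.qalys,
                       out.cost + ac, out.life_years + aly, out.qalys + aq)
    return acc


_COLS = ("n", "cost_fl", "ly_fl", "qaly_fl", "cost_total", "ly_total",
         "qaly_total")


def run_incidence_cohort(ps: ParameterSet, config: SimulationConfig,
                         scenario=None) -> CohortSummary:
    """Closed-cohort simulation across the configured horizons.

    With ``config.psa`` every iteration first takes a second-order parameter
    draw; otherwise iterations differ only in first-order Monte Carlo noise.
    """
    master = np.random.SeedSequence(config.seed)
    psa_ss, *iter_ss = master.spawn(config.iterations + 1)
    psa_rng = np.random.default_rng(psa_ss)

    rows = []
    for it in range(config.iterations):
        ps_it = draw_psa_parameters(ps, psa_rng) if config.psa else ps
        scen_it = scenario
        if scenario is not None and config.psa:
            scen_it = scenario.with_drawn_hr(psa_rng)
        acc = _simulate_iteration(ps_it, config, scen_it, iter_ss[it])
        for (h, group), v in acc.items():
            rows.append({"iteration": it, "horizon": h, "subgroup": group,
                         **dict(zip(_COLS, v))})
    per_it = pd.DataFrame(rows)

    # aggregate rows: cohort total and the "treated" union
    extra = []
    for (it, h), chunk in per_it.groupby(["iteration", "horizon"]):
        for label, members in (
                ("total", SUBGROUPS),
                ("treated", ("first_line_only", "second_line_plus_sct",
                             "second_line_plus_no_sct"))):
            sub = chunk[chunk["subgroup"].isin(members)]
            n = sub["n"].sum()
            if n == 0:
                continue
            row = {"iteration": it, "horizon": h, "subgroup": label, "n": n}
            for c in _COLS[1:]:
                row[c] = sub[c].sum()
            extra.append(row)
    per_it = pd.concat([per_it, pd.DataFrame(extra)], ignore_index=True)

    # per-patient means within each iteration, then summarize across iterations
    for c in _COLS[1:]:
        per_it[c + "_mean"] = per_it[c] / per_it["n"]

    out_rows = []
    for (h, group), chunk in per_it.groupby(["horizon", "subgroup"]):
        row = {"horizon": h, "subgroup": group,
               "n_mean": chunk["n"].mean(),
               "n_lo": chunk["n"].quantile(0.025),
               "n_hi": chunk["n"].quantile(0.975)}
        for c in _COLS[1:]:
            vals = chunk[c + "_mean"]
            row[c + "_mean"] = vals.mean()
            row[c + "_lo"] = vals.quantile(0.025)
            row[c + "_hi"] = vals.quantile(0.975)
        out_rows.append(row)
    table = pd.DataFrame(out_rows).sort_values(
        ["horizon", "subgroup"], key=lambda s: s.astype(str)).reset_index(drop=True)
    return CohortSummary(table=table, per_iteration=per_it, config=config)


def run_psa(ps: ParameterSet, config: SimulationConfig,
            scenario=None) -> CohortSummary:
    """Probabilistic sensitivity analysis (second-order draws per iteration)."""
    cfg = SimulationConfig(**{**config.__dict__, "psa": True})
    return run_incidence_cohort(ps, cfg, scenario=scenario)


def run_prevalence(ps: ParameterSet, config: SimulationConfig,
                   scenario=None, n_alive_samples: int = 5) -> PrevalenceResult:
    """Open-cohort simulation of the annual treatment burden.

    Patients arrive at the annual incidence rate (Poisson by default,
    deterministic spacing when ``config.deterministic_arrivals``) over
    burn-in + window; the result collects all costs accrued inside the
    observation window by anyone alive during it, plus the mean in-system
    patient count over the window.
    """
    rate = ps.incidence_per_year
    total_years = config.burn_in_years + config.window_years
    w0 = config.burn_in_years * DAYS_PER_YEAR
    w1 = total_years * DAYS_PER_YEAR
    sample_ts = np.linspace(w0, w1, n_alive_samples + 2)[1:-1]

    master = np.random.SeedSequence(config.seed)
    psa_ss, *iter_ss = master.spawn(config.iterations + 1)
    psa_rng = np.random.default_rng(psa_ss)

    costs, costs_fl, alive_means = [], [], []
    for it in range(config.iterations):
        ps_it = draw_psa_parameters(ps, psa_rng) if config.psa else ps
        scen_it = scenario
        if scenario is not None and config.psa:
            scen_it = scenario.with_drawn_hr(psa_rng)
        arr_ss, pat_ss = iter_ss[it].spawn(2)
        arr_rng = np.random.default_rng(arr_ss)
        if config.deterministic_arrivals:
            n_arr = int(round(rate * total_years))
            entries = (np.arange(n_arr) + 0.5) / rate * DAYS_PER_YEAR
        else:
            n_arr = int(arr_rng.poisson(rate * total_years))
            entries = np.sort(arr_rng.uniform(0, w1, size=n_arr))
        total = total_fl = 0.0
        alive = np.zeros_like(sample_ts)
        for entry, (main_rng, scen_rng) in zip(
                entries, _patient_rngs(pat_ss, n_arr)):
            traj = simulate_patient(
                sample_patient(ps_it, main_rng), ps_it, main_rng,
                scenario=scen_it, scenario_rng=scen_rng if scen_it else None)
            c_fl = cost_in_window(traj, ps_it, entry, w0, w1,
                                  include_dlbcl=False)
            c_tot = cost_in_window(traj, ps_it, entry, w0, w1,
                                   include_dlbcl=config.include_dlbcl)
            total += c_tot
            total_fl += c_fl
            exit_t = entry + traj.terminal_time_days
            alive += (entry <= sample_ts) & (sample_ts < exit_t)
        costs.append(total)
        costs_fl.append(total_fl)
        alive_means.append(float(alive.mean()))
    return PrevalenceResult(
        annual_costs=np.asarray(costs),
        annual_costs_fl_only=np.asarray(costs_fl),
        alive_counts=np.asarray(alive_means),
        config_signature=config.signature(),
    )
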