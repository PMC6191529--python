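"""Parametric time-to-event toolkit.

Six families are supported for modelling times between clinical events
(normal truncated at zero, exponential, Weibull, gamma, log-normal and
log-logistic), with

* closed-form survival, quantile and inverse-transform sampling,
* proportional-hazards transforms implemented exactly as ``S(t)**h``,
* censored maximum-likelihood fitting with AIC/BIC family selection,
* Kaplan-Meier estimation (delegated to :mod:`lifelines`), and
* multivariate-normal coefficient-uncertainty draws on the fitting scale.

Parameterizations are frozen as follows (``t >= 0`` throughout):

================  ==================  =========================================
family            params              survival function
================  ==================  =========================================
``exponential``   ``(rate,)``         ``exp(-rate*t)``
``weibull``       ``(shape, scale)``  ``exp(-(t/scale)**shape)``
``gamma``         ``(shape, scale)``  ``1 - P(shape, t/scale)`` (regularized)
``lognormal``     ``(mu, sigma)``     ``1 - Phi((ln t - mu)/sigma)``
``loglogistic``   ``(shape, scale)``  ``1 / (1 + (t/scale)**shape)``
``normal``        ``(mu, sigma)``     left-truncated at 0, renormalized
================  ==================  =========================================

An optional accelerated-failure-time linear predictor ``eta`` rescales time
(``T = T0 * exp(eta)``); a hazard ratio ``h`` raises the survival function to
the power ``h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats

FAMILIES = ("normal", "exponential", "weibull", "gamma", "lognormal", "loglogistic")

#: number of free parameters per family
N_PARAMS = {
    "normal": 2,
    "exponential": 1,
    "weibull": 2,
    "gamma": 2,
    "lognormal": 2,
    "loglogistic": 2,
}

# which entries of the parameter vector are strictly positive and therefore
# optimized / perturbed on the log scale (mu of normal/lognormal may be any sign)
_LOG_SCALE_MASK = {
    "normal": (False, True),
    "exponential": (True,),
    "weibull": (True, True),
    "gamma": (True, True),
    "lognormal": (False, True),
    "loglogistic": (True, True),
}


class UndefinedMeanError(ValueError):
    """The analytic mean of the distribution does not exist (is infinite)."""


class FitError(RuntimeError):
    """Censored maximum-likelihood fitting failed."""


@dataclass
class TTESpec:
    """A parametric time-to-event specification.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : tuple of float
        Family-specific parameter vector (documented order, module docstring).
    coefficients : dict, optional
        AFT covariate coefficients; the linear predictor ``eta = sum(b*x)``
        multiplies event times by ``exp(eta)``.
    hazard_ratio : float
        Multiplicative hazard effect, applied exactly as ``S(t)**h``.
    fixture : bool
        True when the parameters are documented placeholders rather than
        values estimated from data.
    """

    family: str
    params: tuple
    coefficients: dict = field(default_factory=dict)
    hazard_ratio: float = 1.0
    fixture: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.params = tuple(float(p) for p in self.params)
        if len(self.params) != N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {N_PARAMS[self.family]} parameters, "
                f"got {len(self.params)}"
            )
        for i, positive in enumerate(_LOG_SCALE_MASK[self.family]):
            if positive and self.params[i] <= 0:
                raise ValueError(
                    f"{self.family} parameter {i} must be > 0, got {self.params[i]}"
                )
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")

    # -- helpers -----------------------------------------------------------
    def linear_predictor(self, covariates=None) -> float:
        if not self.coefficients or covariates is None:
            return 0.0
        return float(sum(b * covariates.get(k, 0.0) for k, b in self.coefficients.items()))

    def to_dict(self) -> dict:
        d = {"family": self.family, "params": list(self.params)}
        if self.coefficients:
            d["coefficients"] = dict(self.coefficients)
        if self.hazard_ratio != 1.0:
            d["hazard_ratio"] = self.hazard_ratio
        if self.fixture:
            d["fixture"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TTESpec":
        return cls(
            family=d["family"],
            params=tuple(d["params"]),
            coefficients=dict(d.get("coefficients", {})),
            hazard_ratio=float(d.get("hazard_ratio", 1.0)),
            fixture=bool(d.get("fixture", False)),
        )


# ---------------------------------------------------------------------------
# baseline survival / inverse survival per family (no HR, no covariates)
# ---------------------------------------------------------------------------

def _base_sf(family, params, t):
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (lam,) = params
        return np.exp(-lam * t)
    if family == "weibull":
        k, s = params
        return np.exp(-((t / s) ** k))
    if family == "gamma":
        k, s = params
        return special.gammaincc(k, t / s)
    if family == "lognormal":
        mu, sg = params
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (np.log(np.maximum(t, 1e-300)) - mu) / sg, -np.inf)
        return special.ndtr(-z)
    if family == "loglogistic":
        k, s = params
        return 1.0 / (1.0 + (t / s) ** k)
    if family == "normal":
        mu, sg = params
        z0 = special.ndtr(mu / sg)  # P(X > 0) for untruncated normal
        return special.ndtr(-(t - mu) / sg) / z0
    raise ValueError(family)


def _base_isf(family, params, p):
    """Inverse baseline survival: t with S0(t) = p, for p in (0, 1]."""
    p = np.asarray(p, dtype=float)
    if family == "exponential":
        (lam,) = params
        return -np.log(p) / lam
    if family == "weibull":
        k, s = params
        return s * (-np.log(p)) ** (1.0 / k)
    if family == "gamma":
        k, s = params
        return s * special.gammainccinv(k, p)
    if family == "lognormal":
        mu, sg = params
        # -ndtri(p) == ndtri(1-p) but stays accurate for p near 0
        return np.exp(mu - sg * special.ndtri(p))
    if family == "loglogistic":
        k, s = params
        return s * ((1.0 - p) / p) ** (1.0 / k)
    if family == "normal":
        mu, sg = params
        z0 = special.ndtr(mu / sg)
        return mu - sg * special.ndtri(p * z0)
    raise ValueError(family)


def _base_logpdf(family, params, t):
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        (lam,) = params
        return math.log(lam) - lam * t
    if family == "weibull":
        k, s = params
        return stats.weibull_min.logpdf(t, k, scale=s)
    if family == "gamma":
        k, s = params
        return stats.gamma.logpdf(t, k, scale=s)
    if family == "lognormal":
        mu, sg = params
        return stats.lognorm.logpdf(t, sg, scale=math.exp(mu))
    if family == "loglogistic":
        k, s = params
        return stats.fisk.logpdf(t, k, scale=s)
    if family == "normal":
        mu, sg = params
        return stats.norm.logpdf(t, mu, sg) - math.log(special.ndtr(mu / sg))
    raise ValueError(family)


def _base_logsf(family, params, t):
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(_base_sf(family, params, t), 1e-300))


# ---------------------------------------------------------------------------
# public spec-level operations
# ---------------------------------------------------------------------------

def survival_function(spec: TTESpec, t, covariates=None):
    """S(t) for the spec, with hazard ratio applied as ``S0(t)**h``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    m = math.exp(spec.linear_predictor(covariates))
    s0 = _base_sf(spec.family, spec.params, t / m)
    out = s0 ** spec.hazard_ratio
    return float(out) if out.ndim == 0 else out


def quantile(spec: TTESpec, p, covariates=None):
    """Time t such that ``survival_function(spec, t) == p``."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("survival probability must be in (0, 1]")
    m = math.exp(spec.linear_predictor(covariates))
    t = m * _base_isf(spec.family, spec.params, p ** (1.0 / spec.hazard_ratio))
    out = np.maximum(t, 0.0)
    return float(out) if out.ndim == 0 else out


def sample_time(spec: TTESpec, u, covariates=None):
    """Inverse-transform sample: solve ``S(t)**h = u`` for ``u ~ U(0,1)``.

    Deterministic in ``u``; monotone decreasing (u near 1 gives small times).
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must be in the open interval (0, 1)")
    return quantile(spec, u, covariates=covariates)


def draw_time(spec: TTESpec, rng, covariates=None) -> float:
    """Random draw using one uniform variate from ``rng``."""
    return float(sample_time(spec, rng.uniform(1e-15, 1.0), covariates=covariates))


def distribution_mean(spec: TTESpec) -> float:
    """Analytic mean of the baseline distribution (hazard ratio 1).

    Raises
    ------
    UndefinedMeanError
        If the mean does not exist (log-logistic shape <= 1).
    """
    fam, p = spec.family, spec.params
    if spec.hazard_ratio != 1.0:
        # exact only where PH folds into the family; otherwise integrate
        if fam == "exponential":
            return 1.0 / (p[0] * spec.hazard_ratio)
        if fam == "weibull":
            k, s = p
            return s * spec.hazard_ratio ** (-1.0 / k) * math.gamma(1 + 1.0 / k)
        from scipy.integrate import quad

        val, _ = quad(lambda t: survival_function(spec, t), 0, np.inf, limit=200)
        return val
    if fam == "exponential":
        return 1.0 / p[0]
    if fam == "weibull":
        k, s = p
        return s * math.gamma(1 + 1.0 / k)
    if fam == "gamma":
        k, s = p
        return k * s
    if fam == "lognormal":
        mu, sg = p
        return math.exp(mu + sg * sg / 2.0)
    if fam == "loglogistic":
        k, s = p
        if k <= 1:
            raise UndefinedMeanError(
                f"log-logistic mean undefined for shape {k} <= 1"
            )
        b = math.pi / k
        return s * b / math.sin(b)
    if fam == "normal":
        mu, sg = p
        a = -mu / sg
        return mu + sg * stats.norm.pdf(a) / special.ndtr(-a)
    raise ValueError(fam)


def apply_hazard_ratio(spec: TTESpec, h: float) -> TTESpec:
    """Return a spec whose survival is ``S(t)**h``.

    For the exponential and Weibull families the transform folds exactly into
    the parameters; other families carry ``h`` symbolically.
    """
    if h <= 0:
        raise ValueError("hazard ratio must be > 0")
    if h == 1.0:
        return spec
    if spec.family == "exponential":
        (lam,) = spec.params
        return replace(spec, params=(lam * h,))
    if spec.family == "weibull":
        k, s = spec.params
        return replace(spec, params=(k, s * h ** (-1.0 / k)))
    return replace(spec, hazard_ratio=spec.hazard_ratio * h)


# ---------------------------------------------------------------------------
# censored maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Result of a censored maximum-likelihood fit.

    ``cov`` is the coefficient covariance on the fitting (transformed) scale:
    strictly positive parameters are fitted as logs, so uncertainty draws made
    on that scale map back to valid parameter vectors.
    """

    family: str
    params: tuple
    log_likelihood: float
    aic: float
    bic: float
    cov: np.ndarray
    n: int
    n_events: int
    converged: bool = True

    @property
    def k(self) -> int:
        return N_PARAMS[self.family]

    def spec(self, fixture: bool = False) -> TTESpec:
        return TTESpec(self.family, self.params, fixture=fixture)

    def transformed_params(self) -> np.ndarray:
        return _to_transformed(self.family, np.asarray(self.params))


def _to_transformed(family, params):
    mask = _LOG_SCALE_MASK[family]
    return np.array([math.log(p) if m else p for p, m in zip(params, mask)])


def _from_transformed(family, theta):
    mask = _LOG_SCALE_MASK[family]
    return tuple(math.exp(v) if m else float(v) for v, m in zip(theta, mask))


def _neg_loglik(theta, family, t_event, t_cens):
    params = _from_transformed(family, theta)
    ll = 0.0
    if t_event.size:
        lp = _base_logpdf(family, params, t_event)
        if not np.all(np.isfinite(lp)):
            return 1e12
        ll += float(np.sum(lp))
    if t_cens.size:
        ls = _base_logsf(family, params, t_cens)
        ll += float(np.sum(ls))
    if not math.isfinite(ll):
        return 1e12
    return -ll


def _moment_start(family, times, events):
    """Method-of-moments starting values from the event times."""
    te = times[events == 1]
    if te.size == 0:
        te = times
    m = float(np.mean(te))
    v = float(np.var(te)) or (0.25 * m * m) or 1.0
    sd = math.sqrt(v)
    if family == "exponential":
        return [(1.0 / m,)]
    if family == "weibull":
        cv = sd / m
        k0 = max(0.3, min(10.0, cv ** (-1.086)))  # standard CV approximation
        return [(k0, m / math.gamma(1 + 1 / k0)), (1.0, m)]
    if family == "gamma":
        k0 = max(0.1, m * m / v)
        return [(k0, v / m), (1.0, m)]
    if family == "lognormal":
        lt = np.log(te)
        return [(float(np.mean(lt)), max(float(np.std(lt)), 0.05))]
    if family == "loglogistic":
        lt = np.log(te)
        sg = max(float(np.std(lt)), 0.05)
        return [(math.sqrt(3) / sg * 0.55, float(np.exp(np.median(lt))))]
    if family == "normal":
        return [(m, sd)]
    raise ValueError(family)


def fit_censored(times, events, family: str) -> FitResult:
    """Fit one parametric family to right-censored data by maximum likelihood.

    Parameters
    ----------
    times : array-like
        Positive observation times (time to event or censoring).
    events : array-like
        1 = event observed, 0 = right-censored.
    family : str
        One of :data:`FAMILIES`.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    n = times.size
    d = int(events.sum())
    if d < 2:
        raise FitError(f"cannot fit with {d} events (need >= 2)")
    t_event = times[events == 1]
    t_cens = times[events == 0]

    if family == "exponential":
        # closed-form MLE under right censoring: rate = events / total exposure
        total = float(times.sum())
        lam = d / total
        ll = d * math.log(lam) - lam * total
        cov = np.array([[1.0 / d]])  # var of log(rate)
        k = 1
        return FitResult(family, (lam,), ll, 2 * k - 2 * ll,
                         k * math.log(n) - 2 * ll, cov, n, d)

    best = None
    for start in _moment_start(family, times, events):
        theta0 = _to_transformed(family, np.asarray(start))
        res = optimize.minimize(
            _neg_loglik, theta0, args=(family, t_event, t_cens),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000},
        )
        res2 = optimize.minimize(
            _neg_loglik, res.x, args=(family, t_event, t_cens), method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        cand = res2 if res2.fun <= res.fun else res
        if best is None or cand.fun < best.fun:
            best = cand
    if best is None or best.fun >= 1e11:
        raise FitError(f"{family} fit did not converge")

    theta = best.x
    ll = -float(best.fun)
    k = N_PARAMS[family]
    hess = _fd_hessian(lambda th: _neg_loglik(th, family, t_event, t_cens), theta)
    cov = _safe_inverse(hess, k)
    params = _from_transformed(family, theta)
    return FitResult(family, params, ll, 2 * k - 2 * ll,
                     k * math.log(n) - 2 * ll, cov, n, d,
                     converged=bool(best.success or abs(best.fun) < 1e11))


def _fd_hessian(f, x, rel_step=1e-4):
    """Central finite-difference Hessian (observed information of -logL)."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def _safe_inverse(hess, k):
    try:
        cov = np.linalg.inv(hess)
        # symmetrize and clip tiny negative eigenvalues from FD noise
        cov = 0.5 * (cov + cov.T)
        w, v = np.linalg.eigh(cov)
        if np.any(w < 0):
            w = np.clip(w, 0.0, None)
            cov = v @ np.diag(w) @ v.T
        return cov
    except np.linalg.LinAlgError:
        return np.full((k, k), np.nan)


# ---------------------------------------------------------------------------
# family selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """AIC-ranked family selection with the BIC ranking alongside."""

    fits: list
    aic_ranking: list  # family names, best first
    bic_ranking: list

    @property
    def best(self) -> FitResult:
        by_name = {f.family: f for f in self.fits}
        return by_name[self.aic_ranking[0]]


def select_family(fits) -> SelectionReport:
    """Rank candidate fits by AIC (BIC reported alongside).

    Ties are broken by fewer parameters, then by the fixed family order of
    :data:`FAMILIES`. All fits must be on the same data (same n, same events).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    ns = {(f.n, f.n_events) for f in fits}
    if len(ns) > 1:
        raise ValueError("fits are not on the same data (n or events differ)")

    def key(crit):
        return lambda f: (getattr(f, crit), f.k, FAMILIES.index(f.family))

    aic_rank = [f.family for f in sorted(fits, key=key("aic"))]
    bic_rank = [f.family for f in sorted(fits, key=key("bic"))]
    return SelectionReport(fits=fits, aic_ranking=aic_rank, bic_ranking=bic_rank)


def fit_all_families(times, events, families=FAMILIES):
    """Fit every requested family, skipping ones that fail to converge."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_censored(times, events, fam))
        except (FitError, ValueError):
            continue
    if not fits:
        raise FitError("no family could be fitted")
    return select_family(fits)


def draw_coefficient_uncertainty(fit: FitResult, rng):
    """One multivariate-normal parameter draw on the fitting scale.

    The draw is made around the transformed estimate using ``fit.cov`` and
    mapped back to the natural scale, so positive parameters stay positive.
    """
    cov = np.asarray(fit.cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariance is not finite")
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if np.any(w < -1e-10):
        raise ValueError("covariance is not positive semi-definite")
    theta = fit.transformed_params()
    if np.allclose(cov, 0):
        return fit.params
    draw = rng.multivariate_normal(theta, cov, method="eigh")
    return _from_transformed(fit.family, draw)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class StepSurvival:
    """A product-limit (Kaplan-Meier) step survival function."""

    times: np.ndarray      # ordered distinct event times
    survival: np.ndarray   # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray

    def evaluate(self, t):
        """Step-function value S(t) (right-continuous)."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:      # no events observed: S is identically 1
            s = np.ones_like(t)
        else:
            idx = np.searchsorted(self.times, t, side="right") - 1
            s = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return float(s) if s.ndim == 0 else s

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.events}
        )


def kaplan_meier(times, events) -> StepSurvival:
    """Product-limit estimator (censored-at-event-time counted at risk)."""
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    mask = tab["observed"].values > 0
    t = tab.index.values[mask].astype(float)
    sf = kmf.survival_function_at_times(t).values
    return StepSurvival(
        times=t,
        survival=np.asarray(sf, dtype=float),
        at_risk=tab["at_risk"].values[mask].astype(int),
        events=tab["observed"].values[mask].astype(int),
    )


def km_sup_distance(km: StepSurvival, spec: TTESpec, t_max=None) -> float:
    """Sup distance between a KM curve and a parametric survival function."""
    ts = km.times if t_max is None else km.times[km.times <= t_max]
    if ts.size == 0:
        return 0.0
    return float(np.max(np.abs(km.evaluate(ts) - survival_function(spec, ts))))
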