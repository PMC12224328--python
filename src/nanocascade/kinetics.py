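"""Cascade kinetics of a single bifunctional catalyst.

A glucose-oxidase-like reaction produces H2O2 from glucose following
hyperbolic Michaelis-Menten saturation, and a catalase-like reaction
decomposes H2O2 following sigmoidal (Hill / allosteric) saturation, both
on the same particle surface.  Because the half-saturation constants of
the two reactions differ by orders of magnitude, the bulk H2O2
concentration relaxes to a steady state: with a constant glucose supply
the production rate is pseudo-zero-order (rate constant ``k1``) while
decomposition, far below its K0.5, is first order (``k2``), giving

    d[H2O2]/dt = k1 - k2 [H2O2]   =>   [H2O2]_ss = k1 / k2.

Internal units are fixed: concentrations in mM, time in minutes,
catalyst loading in mg/mL.  Rates therefore come out in mM/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.integrate import solve_ivp

__all__ = [
    "MMKinetics",
    "HillKinetics",
    "CascadeModel",
    "PseudoOrderRates",
    "AssayTimeCourse",
    "RatePoint",
    "FitResult",
    "mm_rate",
    "hill_rate",
    "estimate_initial_rates",
    "fit_mm",
    "fit_hill",
    "simulate_cascade",
    "pseudo_order_reduction",
    "steady_state_analytic",
    "steady_state_scan",
]


@dataclass(frozen=True)
class MMKinetics:
    """Michaelis-Menten parameters, ``v = Vmax * S / (Km + S)``.

    ``v_max`` is the maximal rate (mM/min) at the reference catalyst
    loading ``ref_catalyst_conc`` (mg/mL); ``k_m`` is the substrate
    concentration (mM) at half-maximal rate.
    """

    v_max: float
    k_m: float
    ref_catalyst_conc: float = 0.1

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError(f"v_max must be > 0, got {self.v_max}")
        if self.k_m <= 0:
            raise ValueError(f"k_m must be > 0, got {self.k_m}")
        if self.ref_catalyst_conc <= 0:
            raise ValueError("ref_catalyst_conc must be > 0")


@dataclass(frozen=True)
class HillKinetics:
    """Hill (allosteric sigmoidal) parameters, ``v = Vmax * S^h / (K0.5^h + S^h)``."""

    v_max: float
    k_half: float
    hill_h: float = 1.0
    ref_catalyst_conc: float = 0.1

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError(f"v_max must be > 0, got {self.v_max}")
        if self.k_half <= 0:
            raise ValueError(f"k_half must be > 0, got {self.k_half}")
        if self.hill_h <= 0:
            raise ValueError(f"hill_h must be > 0, got {self.hill_h}")
        if self.ref_catalyst_conc <= 0:
            raise ValueError("ref_catalyst_conc must be > 0")


@dataclass(frozen=True)
class CascadeModel:
    """Coupled production/decomposition of H2O2 on one catalyst.

    ``production`` converts glucose to H2O2 (Michaelis-Menten);
    ``decomposition`` removes H2O2 (Hill).  The catalyst exponents set
    how each rate scales with catalyst loading C relative to its
    reference: rate ∝ (C/ref)^exponent.  Equal exponents make the
    steady state catalyst-independent (k1/k2 cancellation); the default
    (1, 0.5) reproduces the observed linear growth of steady-state H2O2
    with catalyst loading, where decomposition lags behind production.
    """

    production: MMKinetics
    decomposition: HillKinetics
    production_catalyst_exponent: float = 1.0
    decomposition_catalyst_exponent: float = 0.5

    def __post_init__(self) -> None:
        if self.production_catalyst_exponent < 0:
            raise ValueError("production_catalyst_exponent must be >= 0")
        if self.decomposition_catalyst_exponent < 0:
            raise ValueError("decomposition_catalyst_exponent must be >= 0")


@dataclass(frozen=True)
class PseudoOrderRates:
    """Pseudo-zero-order production ``k1`` (mM/min) and first-order decomposition ``k2`` (1/min)."""

    k1: float
    k2: float
    first_order_exact: bool = True

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError("k1 must be >= 0")
        if self.k2 < 0:
            raise ValueError("k2 must be >= 0")


@dataclass
class AssayTimeCourse:
    """Concentration series sampled at assay time points (minutes, mM)."""

    times: np.ndarray
    glucose: np.ndarray | None = None
    h2o2: np.ndarray | None = None
    catalyst_conc: float = 0.1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        for name in ("glucose", "h2o2"):
            series = getattr(self, name)
            if series is not None:
                series = np.asarray(series, dtype=float)
                if series.shape != self.times.shape:
                    raise ValueError(f"{name} length must match times")
                if np.any(series < 0):
                    raise ValueError(f"{name} concentrations must be >= 0")
                setattr(self, name, series)


@dataclass(frozen=True)
class RatePoint:
    """One initial-rate measurement: substrate concentration (mM) and rate (mM/min)."""

    substrate_conc: float
    initial_rate: float
    increasing_substrate: bool = False

    def __post_init__(self) -> None:
        if self.substrate_conc < 0:
            raise ValueError("substrate_conc must be >= 0")


@dataclass
class FitResult:
    """Nonlinear least-squares outcome with asymptotic standard errors."""

    params: MMKinetics | HillKinetics
    stderr: dict[str, float]
    r_squared: float
    converged: bool
    message: str = ""

    def as_dict(self) -> dict:
        out = {
            "converged": self.converged,
            "r_squared": self.r_squared,
            "stderr": dict(self.stderr),
            "message": self.message,
        }
        p = self.params
        if isinstance(p, MMKinetics):
            out["model"] = "michaelis-menten"
            out["v_max_mM_per_min"] = p.v_max
            out["k_m_mM"] = p.k_m
        else:
            out["model"] = "hill"
            out["v_max_mM_per_min"] = p.v_max
            out["k_half_mM"] = p.k_half
            out["hill_h"] = p.hill_h
        return out


def _catalyst_ratio(ref: float, catalyst_conc: float) -> float:
    if catalyst_conc < 0:
        raise ValueError("catalyst_conc must be >= 0")
    return catalyst_conc / ref


def mm_rate(params: MMKinetics, substrate, catalyst_conc: float | None = None):
    """Michaelis-Menten rate at substrate concentration ``substrate`` (mM).

    The rate scales linearly with catalyst loading relative to the
    parameter set's reference; ``catalyst_conc=None`` means reference.
    Monotone nondecreasing in S, bounded by the scaled ``v_max``.
    """
    s = np.asarray(substrate, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate must be >= 0")
    scale = 1.0 if catalyst_conc is None else _catalyst_ratio(params.ref_catalyst_conc, catalyst_conc)
    v = params.v_max * scale * s / (params.k_m + s)
    return float(v) if np.isscalar(substrate) else v


def hill_rate(params: HillKinetics, substrate, catalyst_conc: float | None = None):
    """Hill (allosteric sigmoidal) rate; reduces to :func:`mm_rate` at h = 1."""
    s = np.asarray(substrate, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate must be >= 0")
    scale = 1.0 if catalyst_conc is None else _catalyst_ratio(params.ref_catalyst_conc, catalyst_conc)
    sh = np.power(s, params.hill_h)
    v = params.v_max * scale * sh / (params.k_half ** params.hill_h + sh)
    return float(v) if np.isscalar(substrate) else v


def estimate_initial_rates(
    courses: list[AssayTimeCourse], substrate: str = "glucose"
) -> list[RatePoint]:
    """Initial consumption rates from short-incubation time courses.

    Consumed substrate (c0 - c(t)) is regressed on time through the
    origin (consumption is definitionally zero at t = 0); the slope is
    the closed-form ``sum(t*y) / sum(t^2)`` over the t > 0 points.  The
    t = 0 concentration labels the point.  A course whose substrate
    rises over time yields a flagged point rather than an error.
    """
    if substrate not in ("glucose", "h2o2"):
        raise ValueError("substrate must be 'glucose' or 'h2o2'")
    points = []
    for course in courses:
        series = getattr(course, substrate)
        if series is None:
            raise ValueError(f"course has no {substrate} series")
        t = course.times
        if t[0] != 0:
            raise ValueError("time courses must include a t=0 point")
        if len(t) < 3:
            raise ValueError("need at least 2 time points beyond t=0")
        c0 = series[0]
        tt, consumed = t[1:], c0 - series[1:]
        slope = float(np.sum(tt * consumed) / np.sum(tt * tt))
        rising = slope < 0
        if rising:
            warnings.warn(
                f"substrate increases over time at S0={c0} mM; rate flagged",
                stacklevel=2,
            )
        points.append(
            RatePoint(substrate_conc=float(c0), initial_rate=slope, increasing_substrate=rising)
        )
    return points


def _nls_fit(model_fn, s, v, p0, bounds, names) -> tuple[np.ndarray, dict, float, bool, str]:
    try:
        popt, pcov = optimize.curve_fit(
            model_fn, s, v, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        return np.array(p0), {n: np.nan for n in names}, np.nan, False, str(exc)
    resid = v - model_fn(s, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return popt, dict(zip(names, se)), r2, True, "converged"


def _fit_inputs(points: list[RatePoint], min_distinct: int):
    s = np.array([p.substrate_conc for p in points], dtype=float)
    v = np.array([p.initial_rate for p in points], dtype=float)
    if len(np.unique(s)) < min_distinct:
        raise ValueError(
            f"need >= {min_distinct} distinct substrate concentrations, "
            f"got {len(np.unique(s))}"
        )
    return s, v


def _saturation_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    # v_max0 = 1.2 x max observed rate; K0 = substrate nearest half-max rate
    v_max0 = 1.2 * float(v.max()) if v.max() > 0 else 1.0
    k0 = float(s[np.argmin(np.abs(v - v.max() / 2))])
    return v_max0, max(k0, 1e-6)


def fit_mm(points: list[RatePoint], ref_catalyst_conc: float = 0.1) -> FitResult:
    """Fit the Michaelis-Menten law to initial-rate points.

    Requires >= 3 distinct substrate concentrations.  Non-convergence is
    reported explicitly in the returned :class:`FitResult`.
    """
    s, v = _fit_inputs(points, 3)
    v_max0, k0 = _saturation_init(s, v)

    def model(ss, v_max, k_m):
        return v_max * ss / (k_m + ss)

    popt, se, r2, ok, msg = _nls_fit(
        model, s, v, [v_max0, k0], ([1e-12, 1e-12], [np.inf, np.inf]), ["v_max", "k_m"]
    )
    params = MMKinetics(
        v_max=max(popt[0], 1e-12), k_m=max(popt[1], 1e-12), ref_catalyst_conc=ref_catalyst_conc
    )
    return FitResult(params=params, stderr=se, r_squared=r2, converged=ok, message=msg)


def fit_hill(
    points: list[RatePoint],
    ref_catalyst_conc: float = 0.1,
    fix_h: float | None = None,
) -> FitResult:
    """Fit the Hill law to initial-rate points.

    Requires >= 4 distinct substrate concentrations.  ``fix_h`` pins the
    Hill slope (``fix_h=1`` reproduces :func:`fit_mm`).  h is otherwise
    free within (0.1, 10].
    """
    s, v = _fit_inputs(points, 4 if fix_h is None else 3)
    v_max0, k0 = _saturation_init(s, v)

    if fix_h is not None:
        def model(ss, v_max, k_half):
            return v_max * ss**fix_h / (k_half**fix_h + ss**fix_h)

        popt, se, r2, ok, msg = _nls_fit(
            model, s, v, [v_max0, k0], ([1e-12, 1e-12], [np.inf, np.inf]), ["v_max", "k_half"]
        )
        h = fix_h
        se["hill_h"] = 0.0
    else:
        def model(ss, v_max, k_half, h):
            return v_max * ss**h / (k_half**h + ss**h)

        popt, se, r2, ok, msg = _nls_fit(
            model, s, v, [v_max0, k0, 1.5],
            ([1e-12, 1e-12, 0.1], [np.inf, np.inf, 10.0]), ["v_max", "k_half", "hill_h"]
        )
        h = max(float(popt[2]), 0.1)
    params = HillKinetics(
        v_max=max(popt[0], 1e-12), k_half=max(popt[1], 1e-12),
        hill_h=h, ref_catalyst_conc=ref_catalyst_conc,
    )
    return FitResult(params=params, stderr=se, r_squared=r2, converged=ok, message=msg)


def simulate_cascade(
    model: CascadeModel,
    catalyst_conc: float,
    glucose0: float,
    h2o2_0: float,
    t_end: float,
    glucose_depletion: bool = True,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate the cascade ODE over ``[0, t_end]`` minutes.

    d[H]/dt = P(G)·(C/ref)^a − D(H)·(C/ref)^b with P the
    Michaelis-Menten production law and D the Hill decomposition law;
    glucose is consumed at rate P when ``glucose_depletion`` is on,
    otherwise held constant (continuous supply).  Returns
    ``(t, glucose, h2o2)`` arrays; the state never goes negative.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if glucose0 < 0 or h2o2_0 < 0:
        raise ValueError("initial concentrations must be >= 0")
    prod = model.production
    dec = model.decomposition
    cp = _catalyst_ratio(prod.ref_catalyst_conc, catalyst_conc) ** model.production_catalyst_exponent
    cd = _catalyst_ratio(dec.ref_catalyst_conc, catalyst_conc) ** model.decomposition_catalyst_exponent

    def rhs(_t, y):
        g = max(y[0], 0.0)
        h = max(y[1], 0.0)
        p = cp * prod.v_max * g / (prod.k_m + g)
        hh = h ** dec.hill_h
        d = cd * dec.v_max * hh / (dec.k_half ** dec.hill_h + hh)
        dg = -p if glucose_depletion else 0.0
        return [dg, p - d]

    sol = solve_ivp(
        rhs, (0.0, t_end), [glucose0, h2o2_0], method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol, dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"cascade integration failed: {sol.message}")
    glucose = np.clip(sol.y[0], 0.0, None)
    h2o2 = np.clip(sol.y[1], 0.0, None)
    return sol.t, glucose, h2o2


def pseudo_order_reduction(
    model: CascadeModel, catalyst_conc: float, glucose: float
) -> PseudoOrderRates:
    """Reduce the cascade to pseudo-order rate constants at fixed glucose.

    ``k1`` is the production rate at the given glucose; ``k2`` is the
    slope of the decomposition law at H -> 0, exact only for Hill slope
    h = 1 (for h != 1 the same formula is returned with
    ``first_order_exact=False`` and a warning).
    """
    if glucose < 0:
        raise ValueError("glucose must be >= 0")
    prod, dec = model.production, model.decomposition
    cp = _catalyst_ratio(prod.ref_catalyst_conc, catalyst_conc) ** model.production_catalyst_exponent
    cd = _catalyst_ratio(dec.ref_catalyst_conc, catalyst_conc) ** model.decomposition_catalyst_exponent
    k1 = cp * prod.v_max * glucose / (prod.k_m + glucose)
    k2 = cd * dec.v_max / dec.k_half
    exact = dec.hill_h == 1.0
    if not exact:
        warnings.warn(
            f"first-order reduction is only exact at h=1 (model has h={dec.hill_h})",
            stacklevel=2,
        )
    return PseudoOrderRates(k1=k1, k2=k2, first_order_exact=exact)


def steady_state_analytic(rates: PseudoOrderRates) -> float:
    """Steady-state H2O2 concentration ``k1/k2`` (mM)."""
    if rates.k2 <= 0:
        raise ValueError("no steady state: k2 must be > 0")
    return rates.k1 / rates.k2


@dataclass
class SteadyStateScan:
    """Steady-state H2O2 vs catalyst loading with a straight-line summary."""

    catalyst_concs: np.ndarray
    steady_h2o2: np.ndarray
    converged: np.ndarray
    slope: float = field(default=np.nan)
    intercept: float = field(default=np.nan)
    r_squared: float = field(default=np.nan)


def steady_state_scan(
    model: CascadeModel,
    catalyst_concs,
    glucose: float,
    t_end: float = 120.0,
    dhdt_tol: float = 1e-6,
) -> SteadyStateScan:
    """Terminal H2O2 of the cascade ODE across catalyst loadings.

    Each loading is integrated (constant glucose supply) to ``t_end``
    minutes; convergence means |dH/dt| < ``dhdt_tol`` mM/min at the end.
    A straight line of steady H2O2 vs loading summarizes the scan.
    """
    cs = np.asarray(catalyst_concs, dtype=float)
    hs = np.empty_like(cs)
    conv = np.zeros(cs.shape, dtype=bool)
    for i, c in enumerate(cs):
        t, g, h = simulate_cascade(
            model, c, glucose0=glucose, h2o2_0=0.0, t_end=t_end, glucose_depletion=False
        )
        hs[i] = h[-1]
        # terminal derivative from the rate laws directly
        prod, dec = model.production, model.decomposition
        cp = _catalyst_ratio(prod.ref_catalyst_conc, c) ** model.production_catalyst_exponent
        cd = _catalyst_ratio(dec.ref_catalyst_conc, c) ** model.decomposition_catalyst_exponent
        p = cp * prod.v_max * glucose / (prod.k_m + glucose)
        d = cd * hill_rate(dec, float(h[-1]))
        conv[i] = abs(p - d) < dhdt_tol
    scan = SteadyStateScan(catalyst_concs=cs, steady_h2o2=hs, converged=conv)
    if len(cs) >= 2 and np.ptp(cs) > 0:
        res = stats.linregress(cs, hs)
        scan.slope = float(res.slope)
        scan.intercept = float(res.intercept)
        scan.r_squared = float(res.rvalue**2)
    return scan
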