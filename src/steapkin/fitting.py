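"""Single-trace and secondary fits.

* ``fit_multiexponential`` — 1-3 exponential phases (rise or decay) with a
  floated baseline, fitted by variable projection: the nonlinear search runs
  over log rate constants only, with amplitudes and offset solved linearly
  at each iterate.  Multistart over log-spaced rate seeds makes recovery
  robust without hand-tuned initial guesses.
* ``select_phase_count`` — AIC-based phase-count selection with a 2-unit
  parsimony margin.
* ``fit_hyperbolic`` — saturation of k_obs with substrate,
  k_obs = Vmax [S] / (KM + [S]).
* ``fit_linear_kobs`` — ordinary least squares of k_obs vs [S], yielding
  k_on (slope), k_off (intercept) and K_D = k_off / k_on.
* ``fit_bli`` — per-trace monophasic fits giving Req, then a dose-response
  fit Req = Rmax [A] / (K_D + [A]).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .synth import BLISeries, TimeCourse, TitrationTable

__all__ = [
    "ExponentialPhase",
    "MultiExpFit",
    "HyperbolicFit",
    "LinearKobsFit",
    "DoseResponseFit",
    "FitError",
    "RateCollapseWarning",
    "NoCurvatureWarning",
    "NonMonotoneReqWarning",
    "fit_multiexponential",
    "select_phase_count",
    "fit_hyperbolic",
    "fit_linear_kobs",
    "compute_kd",
    "fit_bli",
]


class FitError(RuntimeError):
    """Fit did not converge; carries the best residual found."""

    def __init__(self, message: str, best_sse: float | None = None):
        super().__init__(message)
        self.best_sse = best_sse


class RateCollapseWarning(UserWarning):
    """Two fitted rate constants collapsed; fewer phases are warranted."""


class NoCurvatureWarning(UserWarning):
    """Saturation data show no curvature; KM is unbounded."""


class NonMonotoneReqWarning(UserWarning):
    """Equilibrium responses not monotone in analyte concentration."""


@dataclass(frozen=True)
class ExponentialPhase:
    k_obs: float       # s^-1
    amplitude: float   # AU, signed
    fraction: float    # percent of total |amplitude|


@dataclass(frozen=True)
class MultiExpFit:
    phases: tuple[ExponentialPhase, ...]  # ordered fast -> slow
    offset: float
    direction: str
    n_points: int
    residual_sse: float
    stderr: dict = field(default_factory=dict, compare=False)
    window_s: tuple[float, float] = (0.0, np.inf)
    aic: float = np.nan

    @property
    def k_obs(self) -> tuple[float, ...]:
        return tuple(p.k_obs for p in self.phases)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(p.fraction for p in self.phases)


def _basis(t: np.ndarray, ks: np.ndarray, direction: str) -> np.ndarray:
    """Design matrix [1, phase_1(t), ..., phase_n(t)]."""
    e = np.exp(-np.outer(t, ks))
    cols = (1.0 - e) if direction == "rise" else e
    return np.column_stack([np.ones_like(t), cols])


def _varpro_residual(log_k: np.ndarray, t: np.ndarray, y: np.ndarray,
                     direction: str) -> tuple[np.ndarray, np.ndarray]:
    # clip optimizer excursions that would overflow exp()
    X = _basis(t, np.exp(np.clip(log_k, -700.0, 700.0)), direction)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ coef - y, coef


def fit_multiexponential(tc: TimeCourse, n_phases: int,
                         window_s: tuple[float, float] | float | None = None,
                         direction: str = "rise") -> MultiExpFit:
    """Least-squares multi-exponential fit with a floated offset.

    Model: offset + sum_i a_i (1 - e^{-k_i t}) for rising traces, or
    offset + sum_i a_i e^{-k_i t} for decaying traces.  Phases are returned
    ordered fast to slow; fractions are |a_i| / sum_j |a_j| x 100.
    """
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    if not 1 <= n_phases <= 3:
        raise ValueError("n_phases must be in 1..3")
    t_all, y_all = tc.time_s, tc.absorbance
    if window_s is None:
        lo, hi = float(t_all[0]), float(t_all[-1])
    elif np.isscalar(window_s):
        lo, hi = float(t_all[0]), float(window_s)
    else:
        lo, hi = float(window_s[0]), float(window_s[1])
    if lo < t_all[0] or (np.isfinite(hi) and hi > t_all[-1] * (1 + 1e-12)):
        raise ValueError("fit window must lie within the data range")
    mask = (t_all >= lo) & (t_all <= hi)
    t, y = t_all[mask], y_all[mask]
    if t.size < 5 * (2 * n_phases + 1):
        raise ValueError(
            f"need >= {5 * (2 * n_phases + 1)} points in window, have {t.size}"
        )

    t_min = t[0] if t[0] > 0 else t[1]
    k_lo, k_hi = 1.0 / (10.0 * t[-1]), 10.0 / t_min
    n_seed = {1: 8, 2: 6, 3: 5}[n_phases]
    seeds = np.log(np.geomspace(k_lo, k_hi, n_seed))
    # a phase that has fully decayed before the first sample is unobservable
    # (it aliases into the offset); such minima are kept only as a fallback
    k_observable = np.log(100.0) / t_min
    best_valid, best_any = None, None
    for combo in itertools.combinations(seeds, n_phases):
        try:
            res = least_squares(
                lambda lk: _varpro_residual(lk, t, y, direction)[0],
                x0=np.asarray(combo), method="lm",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(res.cost * 2.0)
        if best_any is None or sse < best_any[0]:
            best_any = (sse, res)
        if np.all(res.x <= np.log(k_observable)) and \
                (best_valid is None or sse < best_valid[0]):
            best_valid = (sse, res)
    best = best_valid if best_valid is not None else best_any
    if best is None:
        raise FitError("multi-exponential fit failed from every start")
    sse, res = best
    ks = np.exp(res.x)
    _, coef = _varpro_residual(res.x, t, y, direction)
    offset, amps = float(coef[0]), np.asarray(coef[1:], dtype=float)

    # order fast -> slow, ties broken by larger |amplitude| first
    order = np.lexsort((-np.abs(amps), -ks))
    ks, amps = ks[order], amps[order]
    for i in range(n_phases - 1):
        if abs(ks[i] - ks[i + 1]) <= 0.01 * max(ks[i], ks[i + 1]):
            warnings.warn(
                f"fitted rates {ks[i]:.4g} and {ks[i + 1]:.4g} s^-1 are within"
                f" 1%; consider n_phases={n_phases - 1}",
                RateCollapseWarning, stacklevel=2,
            )
    total = np.abs(amps).sum()
    fracs = (np.abs(amps) / total * 100.0) if total > 0 \
        else np.full(n_phases, 100.0 / n_phases)
    stderr = _multiexp_stderr(t, y, ks, amps, offset, direction, sse)
    n = t.size
    # floor the SSE at the numerical noise of the data scale so that
    # noiseless fits of nested models compare as equivalent under AIC
    sse_floor = n * (1e-10 * max(1.0, float(np.abs(y).max()))) ** 2
    aic = n * np.log(max(sse, sse_floor) / n) + 2 * (2 * n_phases + 1)
    phases = tuple(ExponentialPhase(float(k), float(a), float(f))
                   for k, a, f in zip(ks, amps, fracs))
    return MultiExpFit(phases, offset, direction, n, sse, stderr,
                       (lo, hi), float(aic))


def _multiexp_stderr(t, y, ks, amps, offset, direction, sse) -> dict:
    """Jacobian-based standard errors for (k_i, a_i, offset)."""
    n, p = t.size, 2 * ks.size + 1
    if n <= p:
        return {}
    e = np.exp(-np.outer(t, ks))
    phase = (1.0 - e) if direction == "rise" else e
    sign = 1.0 if direction == "rise" else -1.0
    J = np.column_stack(
        [sign * amps[i] * t * e[:, i] for i in range(ks.size)]
        + [phase[:, i] for i in range(ks.size)]
        + [np.ones_like(t)]
    )
    try:
        cov = np.linalg.inv(J.T @ J) * sse / (n - p)
    except np.linalg.LinAlgError:
        return {}
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    out = {f"k_obs_{i + 1}": float(se[i]) for i in range(ks.size)}
    out.update({f"amplitude_{i + 1}": float(se[ks.size + i])
                for i in range(ks.size)})
    out["offset"] = float(se[-1])
    return out


def select_phase_count(tc: TimeCourse, max_phases: int = 3,
                       direction: str = "rise",
                       window_s=None) -> int:
    """Smallest phase count within 2 AIC units of the best fit."""
    if not 1 <= max_phases <= 3:
        raise ValueError("max_phases must be in 1..3")
    aics: dict[int, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RateCollapseWarning)
        for n in range(1, max_phases + 1):
            try:
                aics[n] = fit_multiexponential(tc, n, window_s, direction).aic
            except (FitError, ValueError):
                continue
    if not aics:
        raise FitError("no phase count could be fitted")
    best = min(aics.values())
    return min(n for n, a in aics.items() if a <= best + 2.0)


@dataclass(frozen=True)
class HyperbolicFit:
    vmax: float  # s^-1
    km: float    # uM
    stderr: dict = field(default_factory=dict, compare=False)
    residual_sse: float = np.nan

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("fitted Vmax and KM must be positive")


def fit_hyperbolic(series: TitrationTable) -> HyperbolicFit:
    """Fit k_obs = Vmax [S] / (KM + [S]) to a titration table."""
    s, k = series.substrate_uM, series.k_obs
    if np.unique(s).size < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")

    def f(x, vmax, km):
        return vmax * x / (km + x)

    p0 = (float(k.max() * 1.5), float(np.median(s)))
    popt, pcov = curve_fit(f, s, k, p0=p0,
                           bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                           xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000)
    vmax, km = popt
    resid = k - f(s, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if km > 10.0 * s.max() or (np.isfinite(se[1]) and se[1] > abs(km)):
        warnings.warn(
            "titration shows no curvature over the sampled range; "
            "KM is effectively unbounded", NoCurvatureWarning, stacklevel=2,
        )
    return HyperbolicFit(float(vmax), float(km),
                         {"vmax": float(se[0]), "km": float(se[1])},
                         float(resid @ resid))


@dataclass(frozen=True)
class LinearKobsFit:
    k_on: float   # M^-1 s^-1 (slope)
    k_off: float  # s^-1 (intercept)
    kd_uM: float
    stderr: dict = field(default_factory=dict, compare=False)
    residual_sse: float = np.nan

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")
        expected = self.k_off / self.k_on * 1e6
        if abs(self.kd_uM - expected) > 1e-9 * max(abs(expected), 1.0):
            raise ValueError("kd_uM inconsistent with k_off / k_on")


def compute_kd(k_on: float, k_off: float) -> float:
    """Dissociation constant K_D = k_off / k_on, reported in uM."""
    if k_on <= 0:
        raise ValueError("k_on must be > 0")
    if k_off < 0:
        raise ValueError("k_off must be >= 0")
    return k_off / k_on * 1e6


def fit_linear_kobs(series: TitrationTable) -> LinearKobsFit:
    """OLS of k_obs (s^-1) on [S] (uM): slope -> k_on, intercept -> k_off."""
    s, k = series.substrate_uM, series.k_obs
    if s.size < 2:
        raise ValueError("need >= 2 points")
    if s.size == 2:
        warnings.warn("only two points: line passes through both, "
                      "zero residual", UserWarning, stacklevel=2)
    X = np.column_stack([np.ones_like(s), s])
    coef, *_ = np.linalg.lstsq(X, k, rcond=None)
    intercept, slope_per_uM = float(coef[0]), float(coef[1])
    if slope_per_uM <= 0:
        raise FitError("fitted slope is non-positive: the pseudo-first-order"
                       " binding model is invalid for these data")
    k_on = slope_per_uM * 1e6  # per M
    if intercept < 0:
        warnings.warn(
            f"fitted intercept (k_off) is negative ({intercept:.3g} s^-1);"
            " the off-rate is indistinguishable from zero at this noise"
            " level and the derived K_D is unreliable",
            UserWarning, stacklevel=2)
    resid = k - X @ coef
    sse = float(resid @ resid)
    stderr: dict = {}
    if s.size > 2:
        cov = np.linalg.inv(X.T @ X) * sse / (s.size - 2)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        stderr = {"k_off": float(se[0]), "k_on": float(se[1] * 1e6)}
    return LinearKobsFit(k_on, intercept, intercept / k_on * 1e6,
                         stderr, sse)


@dataclass(frozen=True)
class DoseResponseFit:
    kd_uM: float
    rmax: float
    stderr: dict = field(default_factory=dict, compare=False)
    req: np.ndarray | None = None        # fitted Req per analyte conc
    analyte_uM: np.ndarray | None = None
    k_obs: np.ndarray | None = None      # association k_obs per conc

    def __post_init__(self) -> None:
        if self.kd_uM <= 0:
            raise ValueError("fitted K_D must be positive")


def _fit_monophasic_rise(t: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Fit R(t) = Req (1 - e^{-k t}); returns (Req, k_obs)."""
    def resid(log_k):
        x = 1.0 - np.exp(-np.exp(log_k[0]) * t)
        denom = x @ x
        req = (x @ r) / denom if denom > 0 else 0.0
        return req * x - r

    span = t[-1] - t[0]
    best = None
    for k0 in np.geomspace(0.1 / span, 100.0 / span, 6):
        res = least_squares(resid, x0=[np.log(k0)], method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        sse = float(res.cost)
        if best is None or sse < best[0]:
            best = (sse, res)
    k = float(np.exp(best[1].x[0]))
    x = 1.0 - np.exp(-k * t)
    req = float((x @ r) / (x @ x))
    return req, k


def fit_bli(series: BLISeries) -> DoseResponseFit:
    """Monophasic per-trace fits give Req; dose-response fit gives K_D, Rmax."""
    conc = series.analyte_uM
    if conc.size < 4:
        raise ValueError("need >= 4 analyte concentrations")
    req = np.empty(conc.size)
    kobs = np.empty(conc.size)
    for j in range(conc.size):
        req[j], kobs[j] = _fit_monophasic_rise(series.time_assoc_s,
                                               series.association[:, j])
    order = np.argsort(conc)
    d = np.diff(req[order])
    scale = max(np.abs(req).max(), 1e-12)
    if np.any(d < -0.05 * scale):
        warnings.warn(
            "Req is non-monotone in analyte concentration beyond noise; "
            "possible non-specific binding", NonMonotoneReqWarning,
            stacklevel=2,
        )

    def dose(a, rmax, kd):
        return rmax * a / (kd + a)

    p0 = (float(req.max() * 1.2), float(np.median(conc)))
    popt, pcov = curve_fit(dose, conc, req, p0=p0,
                           bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                           xtol=1e-15, ftol=1e-15, max_nfev=20000)
    rmax, kd = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return DoseResponseFit(float(kd), float(rmax),
                           {"rmax": float(se[0]), "kd": float(se[1])},
                           req, conc, kobs)
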