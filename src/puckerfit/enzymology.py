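"""Pre-steady-state kinetics and tight-binding affinity fitting.

Two models cover the incision kinetics of an AP endonuclease acting on an
abasic substrate:

* multiple turnover (substrate excess) shows burst behaviour,
  ``product = A * (1 - exp(-k_obs * t)) + v_ss * t``, where the exponential
  amplitude A (nM) reflects the actively bound enzyme, k_obs (1/s) is the
  first-order rate of the chemistry step and v_ss (nM/s) the steady-state
  velocity; the steady-state rate constant is derived as k_ss = v_ss / A,
  never fitted;
* single turnover (enzyme excess) drops the linear phase,
  ``product = A * (1 - exp(-k_obs * t))``.

Equilibrium binding titrations (EMSA-style) are fit with the quadratic
tight-binding isotherm, valid when the probe concentration is comparable
to the dissociation constant:

    AB = (A_T + B_T + K_D - sqrt((A_T + B_T + K_D)^2 - 4 A_T B_T)) / 2

with A_T the total protein, B_T the total probe DNA and AB the complex,
all in nM. Fraction bound is AB / B_T.

The fitters are scikit-learn style estimators (``fit`` / ``predict`` /
``get_params``) over 1-D time or concentration inputs; the module-level
``fit_*`` functions are thin wrappers returning frozen result records.
Units are fixed throughout: seconds, nM, 1/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (FitConvergenceError, InsufficientDataError,
                         UnidentifiableFitWarning)

# replicate-wise refits provide parameter errors once this many replicates
# are available (standard deviation of the mean across replicate fits)
_MIN_REPLICATES_FOR_SEM = 3


# ---------------------------------------------------------------- models

def burst_model_eval(amplitude, k_obs, v_ss, t):
    """Biphasic burst model: A*(1 - exp(-k_obs*t)) + v_ss*t, in nM."""
    t = np.asarray(t, dtype=float)
    out = amplitude * (1.0 - np.exp(-k_obs * t)) + v_ss * t
    return out if out.ndim else float(out)


def single_turnover_eval(amplitude, k_obs, t):
    """Single-exponential model: A*(1 - exp(-k_obs*t)), in nM."""
    return burst_model_eval(amplitude, k_obs, 0.0, t)


def quadratic_bound_eval(a_total, b_total, k_d):
    """Complex concentration AB from the quadratic tight-binding isotherm.

    Solves the mass-action equilibrium (A_T - AB)(B_T - AB) = K_D * AB in
    closed form; the product form 2*A_T*B_T / (s + sqrt(s^2 - 4*A_T*B_T))
    avoids the catastrophic cancellation of the textbook difference form
    when K_D >> A_T*B_T. Guarantees 0 <= AB <= min(A_T, B_T).
    """
    a_total = np.asarray(a_total, dtype=float)
    b_total = np.asarray(b_total, dtype=float)
    if np.any(a_total < 0) or np.any(b_total < 0):
        raise ValueError("total concentrations must be >= 0")
    if np.any(np.asarray(k_d) <= 0):
        raise ValueError("K_D must be > 0")
    s = a_total + b_total + k_d
    disc = np.sqrt(np.maximum(s * s - 4.0 * a_total * b_total, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(s + disc > 0, 2.0 * a_total * b_total / (s + disc), 0.0)
    return ab if ab.ndim else float(ab)


def quadratic_bound_bisect(a_total: float, b_total: float, k_d: float,
                           tol: float = 1e-14) -> float:
    """Numeric root of (A_T-AB)(B_T-AB) = K_D*AB on [0, min(A_T, B_T)].

    Independent bracketing-solver check of the closed form; used as an
    oracle in tests, not in production fits.
    """
    hi = min(a_total, b_total)
    if hi == 0.0:
        return 0.0

    def f(ab):
        return (a_total - ab) * (b_total - ab) - k_d * ab

    return brentq(f, 0.0, hi, xtol=tol * max(hi, 1.0), rtol=8.9e-16)


# ----------------------------------------------------------- data records

@dataclass(frozen=True)
class TimeCourse:
    """Product-formation data: time (s), product (nM), replicate ids."""

    t: np.ndarray
    product: np.ndarray
    replicate: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.product, dtype=float)
        r = np.asarray(self.replicate, dtype=int)
        if not (t.shape == p.shape == r.shape) or t.ndim != 1:
            raise ValueError("t, product and replicate must be equal-length 1-D")
        if np.any(t < 0):
            raise ValueError("timepoints must be >= 0")
        if np.any(p < 0):
            raise ValueError("product concentrations must be >= 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "product", p)
        object.__setattr__(self, "replicate", r)

    @classmethod
    def from_csv(cls, path) -> "TimeCourse":
        df = pd.read_csv(path)
        required = {"t", "product", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise InsufficientDataError(
                f"time-course file {path} lacks column(s) {sorted(missing)}"
            )
        return cls(df["t"].to_numpy(), df["product"].to_numpy(),
                   df["replicate"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "product": self.product,
                      "replicate": self.replicate}).to_csv(path, index=False)

    @property
    def n_replicates(self) -> int:
        return len(np.unique(self.replicate))


@dataclass(frozen=True)
class Titration:
    """Binding titration: total protein (nM) vs fraction of probe bound."""

    a_total: np.ndarray
    fraction_bound: np.ndarray
    b_total: float

    def __post_init__(self):
        a = np.asarray(self.a_total, dtype=float)
        f = np.asarray(self.fraction_bound, dtype=float)
        if a.shape != f.shape or a.ndim != 1:
            raise ValueError("a_total and fraction_bound must match in length")
        if np.any(a < 0):
            raise ValueError("total protein concentrations must be >= 0")
        if self.b_total <= 0:
            raise ValueError("b_total must be > 0")
        object.__setattr__(self, "a_total", a)
        object.__setattr__(self, "fraction_bound", f)

    @classmethod
    def from_csv(cls, path, b_total: float) -> "Titration":
        df = pd.read_csv(path)
        missing = {"a_total", "fraction_bound"} - set(df.columns)
        if missing:
            raise InsufficientDataError(
                f"titration file {path} lacks column(s) {sorted(missing)}"
            )
        return cls(df["a_total"].to_numpy(),
                   df["fraction_bound"].to_numpy(), b_total)

    def to_csv(self, path) -> None:
        pd.DataFrame({"a_total": self.a_total,
                      "fraction_bound": self.fraction_bound}
                     ).to_csv(path, index=False)


@dataclass(frozen=True)
class BurstFitResult:
    """Fitted burst parameters with uncertainties; k_ss derived, not fitted."""

    amplitude: float            # A, nM
    k_obs: float                # 1/s
    v_ss: float                 # nM/s (0 for single turnover)
    k_ss: float                 # v_ss / amplitude, 1/s (nan for single turnover)
    stderr: dict = field(compare=False)
    rss: float = field(compare=False, default=float("nan"))
    rmse: float = field(compare=False, default=float("nan"))
    n_points: int = 0
    n_replicates: int = 0
    model: str = "multiple_turnover"


@dataclass(frozen=True)
class BindingFitResult:
    """Fitted apparent dissociation constant from a titration."""

    k_d_app: float              # nM
    stderr: dict = field(compare=False)
    scale: float = 1.0
    rss: float = field(compare=False, default=float("nan"))
    rmse: float = field(compare=False, default=float("nan"))
    n_points: int = 0
    model: str = "quadratic_tight_binding"


@dataclass(frozen=True)
class FoldChange:
    """A reference/test rate ratio, optionally carrying a '>' bound."""

    value: float
    is_lower_bound: bool = False

    def __str__(self) -> str:
        prefix = "> " if self.is_lower_bound else ""
        return f"{prefix}{self.value:.1f}-fold"


def fold_change(reference_rate: float, test_rate: float,
                reference_is_lower_bound: bool = False) -> FoldChange:
    """Ratio reference/test; a lower-bound reference yields a '>' bound.

    Used to express how much slower one substrate is turned over than
    another (e.g. a ribose vs deoxyribose abasic site).
    """
    if reference_rate <= 0 or test_rate <= 0:
        raise ValueError("rates must be > 0 to form a fold change")
    return FoldChange(reference_rate / test_rate,
                      is_lower_bound=reference_is_lower_bound)


# ------------------------------------------------------------- estimators

def _as_1d_times(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError(f"expected 1-D input, got shape {X.shape}")
    return X


class BurstKineticsModel(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of the (biphasic) burst model.

    Parameters
    ----------
    steady_state : bool, default True
        Fit the full biphasic model A*(1-exp(-k_obs*t)) + v_ss*t. When
        False, v_ss is fixed at 0 (single-turnover regime).
    min_timepoints : int, default 5
        Minimum distinct timepoints required.

    Attributes (after ``fit``)
    --------------------------
    amplitude_, k_obs_, v_ss_ : fitted parameters (nM, 1/s, nM/s).
    k_ss_ : v_ss_/amplitude_, derived exactly (nan without steady state).
    stderr_ : dict of parameter standard errors; from replicate-wise refits
        (SD of the mean) with >= 3 replicates, else from the pooled-fit
        covariance.
    residuals_, rss_, rmse_ : pooled-fit residual summary.
    """

    def __init__(self, steady_state: bool = True, min_timepoints: int = 5):
        self.steady_state = steady_state
        self.min_timepoints = min_timepoints

    # -- internal single-dataset fit -------------------------------------
    def _initial_guess(self, t, y):
        y_max = float(np.max(y))
        t_max = float(np.max(t))
        if self.steady_state:
            # terminal (steady-state) segment: upper half of the time range
            tail = t >= 0.5 * t_max
            if tail.sum() >= 2 and np.ptp(t[tail]) > 0:
                v0, a0 = np.polyfit(t[tail], y[tail], 1)
            else:
                v0, a0 = 0.0, y_max
            v0 = max(v0, 1e-9)
            a0 = np.clip(a0, 1e-6 * max(y_max, 1.0), None)
        else:
            v0 = 0.0
            a0 = max(y_max, 1e-9)
        # early phase: log-linearise 1 - y_corr/A
        y_corr = y - v0 * t
        frac = np.clip(y_corr / a0, None, 0.95)
        early = (frac > 0.05) & (frac < 0.95) & (t > 0)
        if early.sum() >= 2 and np.ptp(t[early]) > 0:
            k0 = -np.polyfit(t[early], np.log1p(-frac[early]), 1)[0]
        else:
            k0 = 1.0 / max(np.median(t[t > 0]), 1e-6)
        k0 = float(np.clip(k0, 1e-6, 1e6))
        return float(a0), k0, float(v0)

    def _fit_arrays(self, t, y):
        a0, k0, v0 = self._initial_guess(t, y)
        if self.steady_state:
            def f(tt, a, k, v):
                return burst_model_eval(a, k, v, tt)
            p0 = [a0, k0, v0]
            bounds = ([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf])
        else:
            def f(tt, a, k):
                return single_turnover_eval(a, k, tt)
            p0 = [a0, k0]
            bounds = ([1e-12, 1e-12], [np.inf, np.inf])
        try:
            popt, pcov = curve_fit(f, t, y, p0=p0, bounds=bounds,
                                   maxfev=20000)
        except RuntimeError as exc:
            raise FitConvergenceError(f"burst fit did not converge: {exc}")
        return popt, pcov, f

    def fit(self, X, y, replicate=None):
        t = _as_1d_times(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("time and product arrays must match in length")
        n_params = 3 if self.steady_state else 2
        distinct = np.unique(t)
        if distinct.size < max(self.min_timepoints, n_params + 1):
            raise InsufficientDataError(
                f"need >= {max(self.min_timepoints, n_params + 1)} distinct "
                f"timepoints, got {distinct.size}"
            )
        if np.all(y <= 0):
            raise InsufficientDataError("product signal is identically zero")
        if np.ptp(y) < 1e-12 * max(np.max(np.abs(y)), 1.0):
            raise InsufficientDataError(
                "product signal is flat; amplitude unidentifiable"
            )

        popt, pcov, f = self._fit_arrays(t, y)
        self.amplitude_, self.k_obs_ = float(popt[0]), float(popt[1])
        self.v_ss_ = float(popt[2]) if self.steady_state else 0.0
        self.k_ss_ = self.v_ss_ / self.amplitude_ if self.steady_state \
            else float("nan")

        pooled_se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        names = ["amplitude", "k_obs", "v_ss"][:len(popt)]
        stderr = dict(zip(names, map(float, pooled_se)))
        if self.steady_state:
            # delta-method error for the derived ratio k_ss = v_ss/A
            g = np.zeros(3)
            g[0] = -self.v_ss_ / self.amplitude_ ** 2
            g[2] = 1.0 / self.amplitude_
            stderr["k_ss"] = float(np.sqrt(max(g @ pcov @ g, 0.0)))
        self.error_source_ = "pooled_covariance"

        replicate = None if replicate is None else np.asarray(replicate)
        if replicate is not None:
            reps = np.unique(replicate)
            if reps.size >= _MIN_REPLICATES_FOR_SEM:
                per_rep = []
                for r in reps:
                    mask = replicate == r
                    try:
                        popt_r, _, _ = self._fit_arrays(t[mask], y[mask])
                    except FitConvergenceError:
                        continue
                    row = list(popt_r)
                    if self.steady_state:
                        row.append(popt_r[2] / popt_r[0])  # k_ss
                    per_rep.append(row)
                if len(per_rep) >= _MIN_REPLICATES_FOR_SEM:
                    arr = np.array(per_rep)
                    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
                    keys = names + (["k_ss"] if self.steady_state else [])
                    stderr = dict(zip(keys, map(float, sem)))
                    self.error_source_ = "replicate_sem"

        self.stderr_ = stderr
        self.residuals_ = y - f(t, *popt)
        self.rss_ = float(np.sum(self.residuals_ ** 2))
        self.rmse_ = float(np.sqrt(self.rss_ / t.size))
        self.n_points_ = int(t.size)
        self.n_replicates_ = int(np.unique(replicate).size) \
            if replicate is not None else 1
        return self

    def predict(self, X):
        t = _as_1d_times(X)
        return burst_model_eval(self.amplitude_, self.k_obs_, self.v_ss_, t)


class TightBindingModel(BaseEstimator, RegressorMixin):
    """Least-squares fit of the quadratic tight-binding isotherm.

    Parameters
    ----------
    b_total : float
        Total probe (DNA) concentration in nM; known, not fitted.
    fit_scale : bool, default False
        Also fit a saturation amplitude (gel quantification may not reach
        exactly 1.0); otherwise the scale is fixed at 1.
    min_points : int, default 5
        Minimum titration points required.

    Attributes (after ``fit``)
    --------------------------
    kd_app_ : apparent dissociation constant, nM.
    scale_ : fitted or fixed saturation amplitude.
    stderr_ : parameter standard errors from the fit covariance.
    """

    def __init__(self, b_total: float = 2.0, fit_scale: bool = False,
                 min_points: int = 5):
        self.b_total = b_total
        self.fit_scale = fit_scale
        self.min_points = min_points

    def fit(self, X, y):
        a_t = _as_1d_times(X)
        frac = np.asarray(y, dtype=float)
        if frac.shape != a_t.shape:
            raise ValueError("a_total and fraction arrays must match")
        if self.b_total <= 0:
            raise ValueError("b_total must be > 0")
        if np.unique(a_t).size < self.min_points:
            raise InsufficientDataError(
                f"need >= {self.min_points} distinct titration points, "
                f"got {np.unique(a_t).size}"
            )
        nonzero = frac[a_t > 0]
        if nonzero.size:
            if np.max(frac) < 0.5:
                warnings.warn(
                    "titration never reaches half-saturation; K_D,app is "
                    "poorly identified (extend the protein range)",
                    UnidentifiableFitWarning, stacklevel=2)
            elif np.min(nonzero) > 0.5:
                warnings.warn(
                    "every nonzero-protein point is above half-saturation; "
                    "K_D,app is poorly identified (add low-protein points)",
                    UnidentifiableFitWarning, stacklevel=2)

        # initial K_D: protein concentration at half of the max signal
        half = 0.5 * max(np.max(frac), 1e-9)
        above = a_t[frac >= half]
        kd0 = float(np.clip(np.min(above) if above.size else np.max(a_t),
                            1e-6, None))

        if self.fit_scale:
            def f(a, kd, scale):
                return scale * quadratic_bound_eval(a, self.b_total, kd) \
                    / self.b_total
            p0, bounds = [kd0, 1.0], ([1e-9, 0.1], [np.inf, 1.5])
        else:
            def f(a, kd):
                return quadratic_bound_eval(a, self.b_total, kd) \
                    / self.b_total
            p0, bounds = [kd0], ([1e-9], [np.inf])
        try:
            popt, pcov = curve_fit(f, a_t, frac, p0=p0, bounds=bounds,
                                   maxfev=20000)
        except RuntimeError as exc:
            raise FitConvergenceError(f"binding fit did not converge: {exc}")

        self.kd_app_ = float(popt[0])
        self.scale_ = float(popt[1]) if self.fit_scale else 1.0
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        names = ["k_d_app"] + (["scale"] if self.fit_scale else [])
        self.stderr_ = dict(zip(names, map(float, se)))
        self.residuals_ = frac - f(a_t, *popt)
        self.rss_ = float(np.sum(self.residuals_ ** 2))
        self.rmse_ = float(np.sqrt(self.rss_ / a_t.size))
        self.n_points_ = int(a_t.size)
        return self

    def predict(self, X):
        a_t = _as_1d_times(X)
        return self.scale_ * quadratic_bound_eval(
            a_t, self.b_total, self.kd_app_) / self.b_total


# ---------------------------------------------------------- fit wrappers

def _check_decade_span(t: np.ndarray) -> None:
    pos = t[t > 0]
    if pos.size and np.max(pos) / np.min(pos) < 10.0:
        warnings.warn(
            "timepoints span less than one decade; burst and steady-state "
            "phases may not separate", UnidentifiableFitWarning, stacklevel=3)


def fit_multiple_turnover(tc: TimeCourse) -> BurstFitResult:
    """Fit the biphasic burst model to pooled replicate data."""
    _check_decade_span(tc.t)
    est = BurstKineticsModel(steady_state=True).fit(
        tc.t, tc.product, replicate=tc.replicate)
    return BurstFitResult(
        amplitude=est.amplitude_, k_obs=est.k_obs_, v_ss=est.v_ss_,
        k_ss=est.k_ss_, stderr=est.stderr_, rss=est.rss_, rmse=est.rmse_,
        n_points=est.n_points_, n_replicates=est.n_replicates_,
        model="multiple_turnover")


def fit_single_turnover(tc: TimeCourse) -> BurstFitResult:
    """Fit the single-exponential model to pooled replicate data."""
    _check_decade_span(tc.t)
    est = BurstKineticsModel(steady_state=False).fit(
        tc.t, tc.product, replicate=tc.replicate)
    return BurstFitResult(
        amplitude=est.amplitude_, k_obs=est.k_obs_, v_ss=0.0,
        k_ss=float("nan"), stderr=est.stderr_, rss=est.rss_, rmse=est.rmse_,
        n_points=est.n_points_, n_replicates=est.n_replicates_,
        model="single_turnover")


def fit_kd_app(titr: Titration, fit_scale: bool = False) -> BindingFitResult:
    """Fit the apparent dissociation constant to a titration."""
    est = TightBindingModel(b_total=titr.b_total, fit_scale=fit_scale).fit(
        titr.a_total, titr.fraction_bound)
    return BindingFitResult(
        k_d_app=est.kd_app_, stderr=est.stderr_, scale=est.scale_,
        rss=est.rss_, rmse=est.rmse_, n_points=est.n_points_)
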