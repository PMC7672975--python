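"""S-shaped growth-curve models for cluster profiles (Richards family).

The Richards model is the four-parameter asymmetric sigmoid

    P(t) = M / [1 + alpha * exp(-M beta t)]^gamma
    alpha = [ (M / P0)^(1/gamma) - 1 ] * exp(M beta t0)

with M the upper asymptote, beta the intrinsic growth rate, gamma the
asymmetry about the inflection point, and (t0, P0) the initial condition.
The logistic model is the gamma = 1 special case; the Gompertz model
(the gamma -> infinity limit, reparametrized) is fitted as

    P(t) = M * exp( ln(P0 / M) * exp(-M beta (t - t0)) ).

Fitting follows the statsmodels convention: build a
:class:`GrowthCurveModel` from data (or a :class:`~capsim.profiles.ClusterProfile`),
call :meth:`~GrowthCurveModel.fit`, inspect the returned
:class:`GrowthCurveResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitFailureError, InsufficientDataError
from .profiles import ClusterProfile, delay_time, log_phase_slope

__all__ = ["GrowthCurveModel", "GrowthCurveResults", "fit_growth_curve",
           "select_best", "richards_curve"]

FAMILIES = ("richards", "logistic", "gompertz")


def richards_curve(t: np.ndarray, M: float, beta: float, gamma: float,
                   P0: float, t0: float = 0.0) -> np.ndarray:
    """Evaluate the Richards sigmoid in an overflow-safe form."""
    t = np.asarray(t, dtype=float)
    P0 = min(P0, 0.999 * M)
    # log of alpha*exp(-M beta t) = log((M/P0)^(1/gamma) - 1) + M beta (t0 - t)
    log_term = np.log(np.expm1(np.log(M / P0) / gamma))
    z = log_term + M * beta * (t0 - t)
    return M * np.exp(-gamma * np.logaddexp(0.0, z))


def gompertz_curve(t: np.ndarray, M: float, beta: float, P0: float,
                   t0: float = 0.0) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    P0 = min(P0, 0.999 * M)
    return M * np.exp(np.log(P0 / M) * np.exp(-M * beta * (t - t0)))


class GrowthCurveModel:
    """Least-squares sigmoid fit of a time series.

    Parameters
    ----------
    times, values : array-like
        Sample times (min) and non-negative signal values; >= 6 points.
    family : {"richards", "logistic", "gompertz"}

    The initial time ``t0`` is fixed to the first sample and the initial
    value ``P0`` to ``max(first value, 1e-3 * M)`` so the curve is defined
    when the first observation is exactly zero.  M is bounded to
    ``[max/2, 2 max]``; beta and gamma are optimized in log space.
    """

    def __init__(self, times, values, family: str = "richards"):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if len(self.times) < 6:
            raise InsufficientDataError("growth-curve fitting needs >= 6 points")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        self.family = family
        self.t0 = float(self.times[0])

    @classmethod
    def from_profile(cls, profile: ClusterProfile,
                     family: str = "richards") -> "GrowthCurveModel":
        model = cls(profile.times, profile.values, family=family)
        model.profile = profile
        return model

    # -- model evaluation ---------------------------------------------------
    def _p0(self, M: float) -> float:
        return max(float(self.values[0]), 1e-3 * M)

    def predict(self, params: np.ndarray, t: np.ndarray | None = None
                ) -> np.ndarray:
        """Curve values for parameter vector (M, beta[, gamma])."""
        t = self.times if t is None else np.asarray(t, dtype=float)
        M, beta = params[0], params[1]
        P0 = self._p0(M)
        if self.family == "richards":
            return richards_curve(t, M, beta, params[2], P0, self.t0)
        if self.family == "logistic":
            return richards_curve(t, M, beta, 1.0, P0, self.t0)
        return gompertz_curve(t, M, beta, P0, self.t0)

    # -- fitting ------------------------------------------------------------
    def fit(self, n_starts: int = 8) -> "GrowthCurveResults":
        vmax = float(self.values.max())
        if vmax <= 0:
            raise FitFailureError("all-zero profile cannot be fitted")
        t_span = float(self.times[-1] - self.times[0]) or 1.0

        has_gamma = self.family == "richards"

        def residuals(theta):
            M = theta[0]
            beta = np.exp(theta[1])
            params = [M, beta] + ([np.exp(theta[2])] if has_gamma else [])
            return self.predict(np.asarray(params)) - self.values

        lo = [vmax / 2.0, np.log(1e-6 / (vmax * t_span))]
        hi = [2.0 * vmax, np.log(1e3 / (vmax * t_span))]
        if has_gamma:
            lo.append(np.log(1e-2))
            hi.append(np.log(1e2))

        # multi-start grid over growth rate (and asymmetry)
        rate_starts = np.geomspace(1.0 / t_span, 50.0 / t_span, 4)
        gamma_starts = [0.5, 2.0] if has_gamma else [None]
        starts = []
        for r in rate_starts:
            for g in gamma_starts:
                th = [vmax, np.log(r / vmax)]
                if g is not None:
                    th.append(np.log(g))
                starts.append(np.asarray(th))
        starts = starts[:max(n_starts, 1)]

        best = None
        failures = []
        for theta0 in starts:
            try:
                res = least_squares(residuals, theta0, bounds=(lo, hi),
                                    method="trf", xtol=1e-12, ftol=1e-12)
            except Exception as exc:  # singular Jacobian etc.
                failures.append(str(exc))
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitFailureError(
                f"no start converged for family {self.family!r}: {failures}"
            )

        M = float(best.x[0])
        beta = float(np.exp(best.x[1]))
        gamma = float(np.exp(best.x[2])) if has_gamma else \
            (1.0 if self.family == "logistic" else float("inf"))
        P0 = self._p0(M)
        fitted = self.predict(np.asarray(
            [M, beta] + ([gamma] if has_gamma else [])))
        ss_res = float(np.sum((self.values - fitted) ** 2))
        ss_tot = float(np.sum((self.values - self.values.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        if self.family == "gompertz":
            alpha = float("nan")
        else:
            alpha = float(((M / P0) ** (1.0 / gamma) - 1.0)
                          * np.exp(M * beta * self.t0))
        return GrowthCurveResults(model=self, family=self.family, M=M,
                                  beta=beta, gamma=gamma, alpha=alpha, P0=P0,
                                  t0=self.t0, r_squared=r2,
                                  n_obs=len(self.times))


@dataclass
class GrowthCurveResults:
    """Fitted sigmoid parameters with goodness of fit and derived metrics."""

    model: GrowthCurveModel
    family: str
    M: float
    beta: float
    gamma: float
    alpha: float
    P0: float
    t0: float
    r_squared: float
    n_obs: int

    def predict(self, t=None) -> np.ndarray:
        params = [self.M, self.beta]
        if self.family == "richards":
            params.append(self.gamma)
        return self.model.predict(np.asarray(params), t)

    def fitted_profile(self) -> ClusterProfile:
        src = getattr(self.model, "profile", None)
        roi = src.roi if src is not None else None
        from .profiles import ROISpec
        roi = roi or ROISpec("fit", (0.0, 0.0), 1.0)
        return ClusterProfile(roi=roi, times=self.model.times,
                              values=self.predict())

    def delay_time(self, threshold_frac: float = 0.05) -> float:
        return delay_time(self.fitted_profile(), threshold_frac)

    def log_phase_slope(self, band=(0.15, 0.85)) -> float:
        return log_phase_slope(self.fitted_profile(), band)

    def summary(self) -> str:
        lines = [
            f"Growth-curve fit ({self.family}), n = {self.n_obs}",
            f"  M (asymptote)     : {self.M:.6g}",
            f"  beta (growth)     : {self.beta:.6g}",
            f"  gamma (asymmetry) : {self.gamma:.6g}",
            f"  alpha             : {self.alpha:.6g}",
            f"  P0 @ t0={self.t0:g}  : {self.P0:.6g}",
            f"  R^2               : {self.r_squared:.6f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted curve on a dense grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.times
        dense = np.linspace(t[0], t[-1], 10 * len(t))
        ax.plot(t, self.model.values, "o", ms=3, label="observed")
        ax.plot(dense, self.predict(dense), "-",
                label=f"{self.family} fit (R²={self.r_squared:.4f})")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax


def fit_growth_curve(profile: ClusterProfile,
                     family: str = "richards") -> GrowthCurveResults:
    """Convenience wrapper: fit one family to a profile."""
    return GrowthCurveModel.from_profile(profile, family).fit()


def select_best(profile: ClusterProfile) -> GrowthCurveResults:
    """Fit all families and return the highest-R² result."""
    results = []
    errors = []
    for family in FAMILIES:
        try:
            results.append(fit_growth_curve(profile, family))
        except FitFailureError as exc:
            errors.append(str(exc))
    if not results:
        raise FitFailureError(f"every family failed: {errors}")
    return max(results, key=lambda r: r.r_squared)
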