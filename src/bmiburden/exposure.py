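"""Continuous BMI exposure distributions.

A stratum's BMI distribution is represented by a two-parameter log-normal
truncated to the physiologically plausible range (10, 80) kg/m^2.  Two
parameters are exactly identified by the two tail prevalences the prevalence
model estimates: P(BMI >= 25) and P(BMI >= 30).  ``fit_distribution`` solves
that two-equation system by root-finding, starting from the closed-form
untruncated solution.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

from .errors import ConvergenceError, DomainError

SUPPORT = (10.0, 80.0)

_LOG25 = np.log(25.0)
_LOG30 = np.log(30.0)
_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _interval_prob(a: float, b: float) -> float:
    """P(a < Z < b) for standard normal Z, stable in both tails."""
    if a > 0:
        return float(norm.sf(a) - norm.sf(b))
    return float(norm.cdf(b) - norm.cdf(a))


@dataclass
class ExposureDistribution:
    """Log-normal BMI distribution truncated to ``support``.

    ``mu`` and ``sigma`` are the parameters of the underlying (untruncated)
    log-normal; all probabilities refer to the truncated distribution.
    """

    mu: float
    sigma: float
    support: tuple[float, float] = SUPPORT
    family: str = "lognormal"
    target_p25: float | None = None
    target_p30: float | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise DomainError("sigma must be positive")
        lo, hi = self.support
        if not (0 < lo < hi):
            raise DomainError("support must satisfy 0 < lower < upper")
        self._zlo = (np.log(lo) - self.mu) / self.sigma
        self._zhi = (np.log(hi) - self.mu) / self.sigma
        self._flo = norm.cdf(self._zlo)
        self._fhi = norm.cdf(self._zhi)
        self._mass = _interval_prob(self._zlo, self._zhi)
        if self._mass <= 0:
            raise DomainError("no probability mass inside the support")

    # -- distribution functions ----------------------------------------
    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (np.log(np.clip(x, self.support[0], self.support[1])) - self.mu) / self.sigma
        out = (norm.cdf(z) - self._flo) / self._mass
        out = np.where(x <= self.support[0], 0.0, out)
        out = np.where(x >= self.support[1], 1.0, out)
        return out if out.ndim else float(out)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x > self.support[0]) & (x < self.support[1])
        xs = np.where(inside, x, 25.0)  # placeholder to avoid log warnings
        z = (np.log(xs) - self.mu) / self.sigma
        dens = norm.pdf(z) / (xs * self.sigma * self._mass)
        out = np.where(inside, dens, 0.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        z = norm.ppf(self._flo + q * self._mass)
        out = np.exp(self.mu + self.sigma * z)
        return out if out.ndim else float(out)

    def tail_probability(self, threshold: float) -> float:
        """P(X >= threshold) on the truncated distribution."""
        lo, hi = self.support
        if not (lo <= threshold <= hi):
            raise DomainError(
                f"threshold {threshold} outside support ({lo}, {hi})"
            )
        z = (np.log(threshold) - self.mu) / self.sigma
        return min(max(_interval_prob(z, self._zhi) / self._mass, 0.0), 1.0)

    def mean(self) -> float:
        # closed-form truncated log-normal mean
        e = np.exp(self.mu + 0.5 * self.sigma**2)
        num = norm.cdf(self._zhi - self.sigma) - norm.cdf(self._zlo - self.sigma)
        return float(e * num / self._mass)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.ppf(rng.uniform(size=n))

    def _pdf_scalar(self, x: float) -> float:
        # fast path for adaptive quadrature (no array machinery)
        lo, hi = self.support
        if x <= lo or x >= hi:
            return 0.0
        z = (math.log(x) - self.mu) / self.sigma
        return math.exp(-0.5 * z * z) / (
            x * self.sigma * _SQRT_2PI * self._mass
        )

    def expected_rr(self, rr, unity_below: float | None = None) -> float:
        """E[RR(X)] by adaptive quadrature (absolute tolerance 1e-10).

        If ``unity_below`` is given, RR is taken to be exactly 1 below that
        point (the TMREL normalization), so that region contributes its
        probability mass analytically and only the risk-bearing tail is
        integrated numerically.
        """
        lo, hi = self.support
        a, base = lo, 0.0
        if unity_below is not None and lo < unity_below < hi:
            a = unity_below
            base = 1.0 - self.tail_probability(a)
        pts = [p for p in (20.0, 21.0, 25.0, 30.0, 40.0) if a < p < hi]
        with warnings.catch_warnings():
            # near-zero risk-bearing mass triggers benign roundoff warnings
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, _ = integrate.quad(
                lambda x: self._pdf_scalar(x) * float(rr(x)),
                a, hi, points=pts, limit=200, epsabs=1e-10, epsrel=1e-10,
            )
        if not np.isfinite(val):
            raise ConvergenceError("expected relative risk integral is non-finite")
        return float(base + val)

    @property
    def achieved_p25(self) -> float:
        return self.tail_probability(25.0)

    @property
    def achieved_p30(self) -> float:
        return self.tail_probability(30.0)


@dataclass
class PointMassExposure:
    """Degenerate exposure concentrated at a single BMI value.

    Useful as an analytic oracle: the PAF of a point mass at x with relative
    risk r = RR(x) is (r - 1) / r in closed form.
    """

    location: float

    def expected_rr(self, rr) -> float:
        return float(rr(self.location))

    def tail_probability(self, threshold: float) -> float:
        return 1.0 if self.location >= threshold else 0.0


# ----------------------------------------------------------------------
def lognormal_params_from_tails(p25: float, p30: float) -> tuple[float, float]:
    """Closed-form (mu, sigma) of an *untruncated* log-normal with the given
    tail probabilities at 25 and 30 kg/m^2."""
    z1 = norm.isf(p25)  # (log 25 - mu) / sigma
    z2 = norm.isf(p30)
    sigma = (_LOG30 - _LOG25) / (z2 - z1)
    mu = _LOG25 - sigma * z1
    return float(mu), float(sigma)


def _validate_targets(p25: float, p30: float):
    if not (0.0 < p30 < p25 < 1.0):
        raise DomainError(
            "targets must satisfy 0 < p30 < p25 < 1 "
            "(obesity cannot exceed overweight-or-obesity); "
            f"got p25={p25}, p30={p30}"
        )


def feasible_p30_max(p25: float, support: tuple[float, float] = SUPPORT) -> float:
    """Largest P(X>=30) a truncated log-normal can pair with P(X>=25)=p25.

    The truncation bounds the achievable tail pairs: in the sigma -> inf
    limit the family degenerates to densities proportional to exp(lam*log x)
    on the support, which trace the feasibility boundary.  Pairs with p30 at
    or above this bound cannot be matched by any member of the family.
    """
    lo, hi = np.log(support[0]), np.log(support[1])

    def frac_above(lam, thr):
        if abs(lam) < 1e-12:
            return (hi - thr) / (hi - lo)
        num = np.exp(lam * (hi - lo)) - np.exp(lam * (thr - lo))
        den = np.exp(lam * (hi - lo)) - 1.0
        return num / den

    lam = optimize.brentq(
        lambda l: frac_above(l, _LOG25) - p25, -200.0, 200.0, xtol=1e-13
    )
    return float(frac_above(lam, _LOG30))


def fit_distribution(
    p25: float,
    p30: float,
    family: str = "lognormal",
    support: tuple[float, float] = SUPPORT,
    project_infeasible: bool = False,
) -> ExposureDistribution:
    """Solve {P(X>=25)=p25, P(X>=30)=p30} for the family's two parameters.

    The targets are matched on the *truncated* distribution.  Starts from the
    closed-form untruncated solution and polishes by root-finding; residuals
    are guaranteed below 1e-9 or a ConvergenceError is raised.

    Truncation makes some tail pairs unattainable (see
    :func:`feasible_p30_max`).  With ``project_infeasible`` such a pair is
    projected onto the feasible region by reducing p30 (keeping p25) just
    inside the boundary; the returned object's ``target_p30`` retains the
    original request so the projection is visible in achieved-vs-target
    residuals.
    """
    if family != "lognormal":
        raise DomainError(f"unknown exposure family {family!r}")
    _validate_targets(p25, p30)

    def mu_matching_p25(sigma):
        # tail_probability(25) is increasing in mu at fixed sigma; when the
        # mass underflows entirely to one side, report the limiting value
        def f(mu):
            try:
                d = ExposureDistribution(mu, sigma, support)
            except DomainError:
                return (1.0 if mu > _LOG25 else 0.0) - p25
            return d.tail_probability(25.0) - p25

        return optimize.brentq(f, -300.0, 300.0, xtol=1e-12)

    def attempt(p30_fit, ladder=True):
        def residual(params):
            mu, log_sigma = params
            try:
                d = ExposureDistribution(mu, float(np.exp(log_sigma)), support)
            except DomainError:
                return np.array([1.0, 1.0])
            return np.array(
                [d.tail_probability(25.0) - p25,
                 d.tail_probability(30.0) - p30_fit]
            )

        # Closed-form untruncated start, then a fixed-point refinement:
        # express the truncated targets as equivalent untruncated tails
        # under the current parameters and reapply the closed form.  This
        # converges even when the truncation removes substantial mass.
        mu0, sigma0 = lognormal_params_from_tails(p25, p30_fit)
        with np.errstate(all="ignore"):
            for _ in range(100):
                zlo = norm.cdf((np.log(support[0]) - mu0) / sigma0)
                zhi = norm.cdf((np.log(support[1]) - mu0) / sigma0)
                u25 = min(max(p25 * (zhi - zlo) + (1.0 - zhi), 1e-12), 1 - 1e-12)
                u30 = min(max(p30_fit * (zhi - zlo) + (1.0 - zhi), 1e-12), 1 - 1e-12)
                if not u30 < u25 or not np.isfinite(mu0 + sigma0):
                    mu0, sigma0 = lognormal_params_from_tails(p25, p30_fit)
                    break
                mu1, sigma1 = lognormal_params_from_tails(u25, u30)
                if abs(mu1 - mu0) < 1e-12 and abs(sigma1 - sigma0) < 1e-12:
                    mu0, sigma0 = mu1, sigma1
                    break
                mu0, sigma0 = mu1, sigma1

        def solve_from(x0):
            sol = optimize.root(residual, x0, method="hybr", tol=1e-13)
            res = residual(sol.x)
            if np.max(np.abs(res)) > 1e-9:
                sol = optimize.least_squares(
                    residual, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15
                )
                res = residual(sol.x)
            return sol.x, res

        def starts():
            yield np.array([mu0, np.log(sigma0)])
            if not ladder:
                return
            # fallback ladder for near-degenerate (large sigma) solutions
            for sig in (1.0, 2.0, 5.0, 10.0, 20.0):
                try:
                    yield np.array([mu_matching_p25(sig), np.log(sig)])
                except ValueError:
                    continue

        best_x, best_res = None, np.array([np.inf, np.inf])
        with np.errstate(all="ignore"):
            for x0 in starts():
                x, res = solve_from(x0)
                if np.max(np.abs(res)) < np.max(np.abs(best_res)):
                    best_x, best_res = x, res
                if np.max(np.abs(best_res)) <= 1e-9:
                    break
        return best_x, best_res

    p30_fit = p30
    best_x, best_res = attempt(p30, ladder=False)
    if np.max(np.abs(best_res)) > 1e-9:
        # only now pay for the feasibility boundary: the truncated family
        # cannot reach every tail pair (see feasible_p30_max)
        bound = feasible_p30_max(p25, support)
        if p30 >= bound:
            if not project_infeasible:
                raise ConvergenceError(
                    "targets are infeasible for the truncated log-normal family",
                    diagnostics={"targets": (p25, p30), "p30_feasible_max": bound},
                )
            p30_fit = 0.995 * bound
        best_x, best_res = attempt(p30_fit)
    if np.max(np.abs(best_res)) > 1e-9:
        raise ConvergenceError(
            "distribution fit did not reach tolerance",
            diagnostics={
                "residuals": best_res.tolist(),
                "targets": (p25, p30),
                "fitted_targets": (p25, p30_fit),
            },
        )
    dist = ExposureDistribution(
        float(best_x[0]), float(np.exp(best_x[1])), support,
        target_p25=p25, target_p30=p30,
    )
    return dist


def fit_distribution_table(frame, p25_col="p25", p30_col="p30") -> list[ExposureDistribution]:
    """Fit one distribution per row of a (p25, p30) table, with caching of
    repeated target pairs."""
    cache: dict[tuple[float, float], ExposureDistribution] = {}
    out = []
    for p25, p30 in zip(frame[p25_col].to_numpy(), frame[p30_col].to_numpy()):
        key = (round(float(p25), 12), round(float(p30), 12))
        if key not in cache:
            cache[key] = fit_distribution(float(p25), float(p30))
        out.append(cache[key])
    return out
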