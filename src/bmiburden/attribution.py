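"""Population attributable fractions and attributable years of life lost.

PAF for a continuous exposure with density f and relative-risk curve RR
normalized to 1 on the theoretical minimum risk exposure level (TMREL):

    PAF = (E[RR] - 1) / E[RR] = 1 - 1 / E[RR]

since the counterfactual in which everyone above the TMREL is moved to the
TMREL has expected relative risk exactly 1.  Attributable YLL rates are the
PAF times the total cause-specific YLL rate, per draw.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .draws import STRATUM_KEYS, DrawMatrix, population_weights
from .errors import ConvergenceError, DomainError, SchemaError


@dataclass(frozen=True)
class Tmrel:
    """Theoretical minimum risk exposure level, an interval in kg/m^2.

    Curves are normalized to RR = 1 for all BMI at or below the interval's
    upper bound; risk accumulates only above it.
    """

    lower: float = 20.0
    upper: float = 21.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise DomainError("TMREL lower bound must be below the upper bound")


class RiskCurve:
    """Continuous relative-risk function of BMI for one cause.

    Stored as a grid of (BMI, RR) values with monotone piecewise-cubic
    (PCHIP) interpolation; RR is identically 1 at and below the TMREL upper
    bound, and >= 1 everywhere above it.
    """

    def __init__(self, cause: str, grid: np.ndarray, values: np.ndarray,
                 tmrel: Tmrel = Tmrel()):
        grid = np.asarray(grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape:
            raise DomainError("grid and values must be 1-D arrays of equal length")
        if np.any(np.diff(grid) <= 0):
            raise DomainError("grid must be strictly increasing")
        if np.any(values < 1.0 - 1e-9):
            raise DomainError(f"curve {cause!r}: RR < 1 violates TMREL normalization")
        below = grid <= tmrel.upper + 1e-12
        if not np.allclose(values[below], 1.0, atol=1e-9):
            raise DomainError(f"curve {cause!r}: RR != 1 at/below the TMREL")
        self.cause = cause
        self.grid = grid
        self.values = values
        self.tmrel = tmrel
        self._interp = PchipInterpolator(grid, values, extrapolate=False)
        # cubic coefficients for a cheap scalar path inside quadrature loops
        self._c = self._interp.c
        self._x0 = float(grid[0])
        self._xn = float(grid[-1])

    def __call__(self, x):
        if np.ndim(x) == 0:
            return self._scalar(float(x))
        x = np.asarray(x, dtype=float)
        out = self._interp(np.clip(x, self.grid[0], self.grid[-1]))
        out = np.where(x <= self.grid[0], 1.0, out)
        out = np.where(x >= self.grid[-1], self.values[-1], out)
        return out

    def _scalar(self, x: float) -> float:
        if x <= self._x0 or x <= self.tmrel.upper:
            return 1.0
        if x >= self._xn:
            return float(self.values[-1])
        i = int(np.searchsorted(self.grid, x, side="right")) - 1
        i = min(max(i, 0), self._c.shape[1] - 1)
        dx = x - self.grid[i]
        c = self._c
        return float(((c[0, i] * dx + c[1, i]) * dx + c[2, i]) * dx + c[3, i])


def make_risk_curve(
    cause: str,
    form: str,
    params: tuple[float, ...],
    tmrel: Tmrel = Tmrel(),
    grid_step: float = 0.1,
    support: tuple[float, float] = (10.0, 80.0),
) -> RiskCurve:
    """Construct a synthetic relative-risk curve.

    Forms (h = max(BMI - tmrel.upper, 0)):
      - ``loglinear``: RR = exp(beta * h), beta >= 0
      - ``jshaped``:   RR = exp(b1 * h + b2 * h^2), b1, b2 >= 0
    """
    grid = np.arange(support[0], support[1] + grid_step / 2, grid_step)
    h = np.maximum(grid - tmrel.upper, 0.0)
    if form == "loglinear":
        (beta,) = params
        if beta < 0:
            raise DomainError("loglinear slope must be >= 0 (RR >= 1 above TMREL)")
        values = np.exp(beta * h)
    elif form == "jshaped":
        b1, b2 = params
        if b1 < 0 or b2 < 0:
            raise DomainError("jshaped coefficients must be >= 0")
        values = np.exp(b1 * h + b2 * h * h)
    else:
        raise DomainError(f"unknown risk-curve form {form!r}")
    return RiskCurve(cause, grid, values, tmrel)


def compute_paf(dist, curve: RiskCurve) -> float:
    """PAF = 1 - 1/E[RR(X)] for one exposure distribution and one curve.

    ``dist`` may be any object exposing ``expected_rr`` (continuous exposure
    distributions integrate by adaptive quadrature; point masses evaluate
    the curve directly).
    """
    if abs(float(curve(curve.tmrel.upper)) - 1.0) > 1e-9:
        raise DomainError("risk curve is not normalized to 1 at the TMREL")
    try:
        mean_rr = dist.expected_rr(curve, unity_below=curve.tmrel.upper)
    except TypeError:
        mean_rr = dist.expected_rr(curve)
    if not np.isfinite(mean_rr):
        raise ConvergenceError("mean relative risk is non-finite")
    if mean_rr < 1.0 - 1e-9:
        raise DomainError("mean relative risk below 1; curve violates normalization")
    mean_rr = max(mean_rr, 1.0)
    return float(1.0 - 1.0 / mean_rr)


@dataclass
class PafResult:
    """Attributable-burden draws: PAF, YLL rate per 100,000, and YLL count."""

    paf: DrawMatrix
    rate: DrawMatrix
    count: DrawMatrix


def attributable_ylls(
    paf: DrawMatrix, ylls: pd.DataFrame, population: pd.DataFrame
) -> PafResult:
    """Multiply cause-specific PAF draws by total YLL rates.

    ``paf`` is keyed by stratum + cause; ``ylls`` holds one total YLL rate
    per (stratum, cause), per 100,000; ``population`` one population per
    stratum.  Per draw: attributable rate = PAF x total rate, attributable
    count = rate x population / 100,000.
    """
    key_cols = [c for c in paf.key_columns if c != "cause"]
    merged = paf.keys.merge(
        ylls[key_cols + ["cause", "yll_rate"]], on=key_cols + ["cause"], how="left"
    )
    if merged["yll_rate"].isna().any():
        bad = merged[merged["yll_rate"].isna()].iloc[0]
        raise SchemaError(
            f"missing YLL rate for stratum/cause {bad[key_cols + ['cause']].to_dict()}"
        )
    if (merged["yll_rate"] < 0).any():
        raise SchemaError("negative total YLL rate")
    pop = population_weights(paf.keys[key_cols], population)
    total = merged["yll_rate"].to_numpy(dtype=float)
    rate = paf.values * total[:, None]
    count = rate * pop[:, None] / 1e5
    return PafResult(
        paf=paf,
        rate=paf.copy_with(rate, "attributable_yll_rate"),
        count=paf.copy_with(count, "attributable_yll_count"),
    )
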