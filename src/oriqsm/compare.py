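"""Linear-regression comparison of susceptibility estimates across methods.

Used to compare, e.g., COSMOS bulk susceptibility against external-field
chi_i across specimens, or the same quantity between scanning sessions.
Ordinary least squares of y on x with t-based confidence intervals; a slope
near 1 indicates agreement, a non-zero intercept a constant reference-medium
offset between the two measurements.  OLS ignores errors in x (a documented
caveat, not corrected for).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["RegressionResult", "compare_estimates"]


@dataclass
class RegressionResult:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "r2": self.r2,
            "n": self.n,
        }


def compare_estimates(x, y, level: float = 0.95) -> RegressionResult:
    """OLS regression of paired estimates y on x with t-based CIs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=1.0 - level)
    return RegressionResult(
        slope=float(res.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(res.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        r2=float(res.rsquared),
        n=len(x),
    )
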