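"""Electrophysiology summary statistics: fold activation and the Hill
concentration–inhibition fit with IC50 (x_1/2) extraction.

The dose–response model is the standard 4-parameter Hill curve

    %inh(x) = base + (max − base) / (1 + (x_half / x)^rate)

with base = 0 % and max = 100 % fixed by default (freed by flag), so that
%inh(x_half) = 50 % and x_half is the half-maximal inhibitory concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import gmean

__all__ = ["FoldActivationResult", "DoseResponseFit", "fold_activation",
           "hill_curve", "hill_fit"]


@dataclass
class FoldActivationResult:
    I_basal: float
    I_activated: float
    FA: float


@dataclass
class DoseResponseFit:
    base: float
    max: float
    x_half: float          # µM
    rate: float            # Hill coefficient
    x_half_stderr: float
    rate_stderr: float
    residuals: np.ndarray

    def predict(self, x) -> np.ndarray:
        return hill_curve(np.asarray(x, dtype=float), self.base, self.max,
                          self.x_half, self.rate)


def fold_activation(I_basal: float, I_activated: float) -> FoldActivationResult:
    """FA = I_activated / I_basal (currents in the same units)."""
    if I_basal == 0:
        raise ValueError("fold activation undefined for zero basal current")
    return FoldActivationResult(I_basal=I_basal, I_activated=I_activated,
                                FA=I_activated / I_basal)


def hill_curve(x, base, max_, x_half, rate):
    return base + (max_ - base) / (1.0 + (x_half / x) ** rate)


def hill_fit(
    doses,
    inhibition,
    free_ends: bool = False,
    rate_bounds: tuple[float, float] = (0.3, 5.0),
) -> DoseResponseFit:
    """Nonlinear least-squares Hill fit of % inhibition vs dose (µM).

    Initialization: x_half at the geometric mean of the doses, rate = 1.
    Requires ≥ 4 distinct doses, all positive; inhibition values outside
    [−10, 110] % are rejected as implausible.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if np.any(x <= 0):
        raise ValueError("doses must be positive")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct doses")
    if np.any(y < -10) or np.any(y > 110):
        raise ValueError("inhibition values outside [-10, 110] %")
    x0 = float(gmean(x))
    if free_ends:
        p0 = [0.0, 100.0, x0, 1.0]
        lb = [-10.0, 50.0, 1e-9, rate_bounds[0]]
        ub = [50.0, 110.0, np.inf, rate_bounds[1]]
        fun = hill_curve
    else:
        p0 = [x0, 1.0]
        lb = [1e-9, rate_bounds[0]]
        ub = [np.inf, rate_bounds[1]]

        def fun(x, x_half, rate):
            return hill_curve(x, 0.0, 100.0, x_half, rate)

    try:
        popt, pcov = curve_fit(fun, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"Hill fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    if free_ends:
        base, max_, x_half, rate = popt
        x_half_err, rate_err = perr[2], perr[3]
    else:
        base, max_ = 0.0, 100.0
        x_half, rate = popt
        x_half_err, rate_err = perr[0], perr[1]
    resid = y - hill_curve(x, base, max_, x_half, rate)
    return DoseResponseFit(base=float(base), max=float(max_), x_half=float(x_half),
                           rate=float(rate), x_half_stderr=float(x_half_err),
                           rate_stderr=float(rate_err), residuals=resid)
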