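"""Real-time PCR standard-curve mathematics.

The quantification cycle Ct is linear in log10 of the starting template
amount: Ct = slope·log10(conc) + intercept.  The per-cycle amplification
efficiency follows from the slope as E = 10^(−1/slope) − 1 (slope −3.3219
is perfect doubling, 100%).  An assay qualifies as high-efficiency when
R² ≥ 0.98 and the slope lies in [−3.6, −3.1], boundaries inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CtObservation:
    log10_conc: float  # log10 CFU/mL
    ct: float          # cycles

    def __post_init__(self) -> None:
        if not (np.isfinite(self.log10_conc) and np.isfinite(self.ct)):
            raise ValueError("non-finite Ct observation")
        if self.ct <= 0:
            raise ValueError("Ct must be positive")


@dataclass(frozen=True)
class StandardCurveFit:
    slope: float          # cycles per log10 unit (negative for real assays)
    intercept: float      # cycles
    r_squared: float
    n_points: int

    @property
    def efficiency_pct(self) -> float:
        return efficiency_from_slope(self.slope)

    @property
    def high_efficiency(self) -> bool:
        return qualify_high_efficiency(self)


def fit_standard_curve(observations: Sequence[CtObservation]) -> StandardCurveFit:
    """Ordinary least squares of Ct on log10 concentration."""
    if len(observations) < 3:
        raise ValueError("standard curve needs ≥3 points")
    x = np.array([o.log10_conc for o in observations])
    y = np.array([o.ct for o in observations])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 concentration")
    res = stats.linregress(x, y)
    return StandardCurveFit(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue) ** 2,
                            n_points=len(observations))


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency percent, (10^(−1/slope) − 1)·100."""
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def qualify_high_efficiency(fit: StandardCurveFit) -> bool:
    """R² ≥ 0.98 and slope within [−3.6, −3.1], inclusive."""
    return fit.r_squared >= 0.98 and -3.6 <= fit.slope <= -3.1


def quantify(fit: StandardCurveFit, ct: float) -> float:
    """Invert the curve: log10 concentration for an observed Ct."""
    if fit.slope == 0:
        raise ValueError("cannot invert a flat standard curve")
    if not np.isfinite(ct):
        raise ValueError("non-finite Ct")
    return (ct - fit.intercept) / fit.slope


def predict_ct(fit: StandardCurveFit, log10_conc: float) -> float:
    return fit.slope * log10_conc + fit.intercept


def simulate_ct(true_slope: float, true_intercept: float,
                log10_concs: Iterable[float], noise_sd: float,
                seed: int) -> list[CtObservation]:
    """Synthetic dilution-series readout: linear response + Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    out = []
    for x in log10_concs:
        ct = true_slope * x + true_intercept + rng.normal(0.0, noise_sd)
        out.append(CtObservation(log10_conc=float(x), ct=float(ct)))
    return out


def fit_table(fit: StandardCurveFit):
    import pandas as pd
    return pd.DataFrame([{
        "slope": round(fit.slope, 4),
        "intercept": round(fit.intercept, 4),
        "r_squared": round(fit.r_squared, 4),
        "efficiency_pct": round(fit.efficiency_pct, 1),
        "high_efficiency": fit.high_efficiency,
        "n_points": fit.n_points,
    }])
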