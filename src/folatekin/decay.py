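"""First-order biostability kinetics of the cytosolic conjugate.

The conjugate concentration measured in the cytosol at increasing times
after administration decays exponentially, C(t) = C0 * exp(-k t).  The fit
is log-linear ordinary least squares of ln C on t (matching the first-order
reading of desk-scale data); a nonlinear exponential fit is available behind
a flag.  The half-life is t_1/2 = ln 2 / k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .errors import FitError, InputError

__all__ = [
    "DecaySeries",
    "DecayFit",
    "fit_first_order",
    "simulate_decay",
    "PAPER_TIMEPOINTS_MIN",
]

#: Standard sampling times of the biostability assay, minutes.
PAPER_TIMEPOINTS_MIN: tuple[float, ...] = (20.0, 40.0, 60.0, 120.0, 240.0)


@dataclass
class DecaySeries:
    """Concentration-time observations, possibly over several replicates.

    ``data`` has columns ``time_min, concentration_uM, replicate``; times are
    strictly increasing within each replicate.
    """

    data: pd.DataFrame
    provenance: str = "measured"

    REQUIRED = ("time_min", "concentration_uM", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InputError(f"decay table missing column(s): {', '.join(missing)}")
        for rep, grp in self.data.groupby("replicate"):
            t = grp["time_min"].to_numpy(float)
            if not np.all(np.diff(t) > 0):
                raise InputError(
                    f"times must be strictly increasing within replicate {rep!r}"
                )


@dataclass(frozen=True)
class DecayFit:
    """First-order fit: rate constant k (1/min), C0 (uM), half-life (min)."""

    k: float
    k_se: float
    C0: float
    t_half: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.k > 0 and not math.isclose(self.t_half, math.log(2) / self.k):
            raise InputError("t_half must equal ln(2)/k")


def fit_first_order(series: DecaySeries, nonlinear: bool = False) -> DecayFit:
    """Fit C(t) = C0 * exp(-k t); k = -slope of the ln C vs t OLS line.

    Replicates are pooled into a single fit (fit each replicate's sub-series
    separately for per-replicate estimates).  Non-positive concentrations
    cannot enter a log-linear fit and are excluded with a warning; at least
    3 valid points are required.  ``nonlinear=True`` refines the log-linear
    estimates by unweighted nonlinear least squares on the original scale.
    """
    df = series.data
    bad = df["concentration_uM"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} non-positive concentration(s)",
            stacklevel=2,
        )
        df = df[~bad]
    if len(df) < 3:
        raise FitError("need at least 3 positive-concentration timepoints")

    t = df["time_min"].to_numpy(float)
    logc = np.log(df["concentration_uM"].to_numpy(float))
    with np.errstate(divide="ignore", invalid="ignore"):  # constant series
        fit = sm.OLS(logc, sm.add_constant(t)).fit()
        k = -float(fit.params[1])
        k_se = float(fit.bse[1])
        c0 = math.exp(float(fit.params[0]))
        r2 = float(fit.rsquared)

    if nonlinear:
        popt, pcov = curve_fit(
            lambda tt, c0_, k_: c0_ * np.exp(-k_ * tt),
            t,
            df["concentration_uM"].to_numpy(float),
            p0=(c0, k),
        )
        c0, k = float(popt[0]), float(popt[1])
        k_se = float(np.sqrt(pcov[1, 1]))
        resid = df["concentration_uM"].to_numpy(float) - popt[0] * np.exp(-popt[1] * t)
        ss_tot = np.sum(
            (df["concentration_uM"].to_numpy(float) - df["concentration_uM"].mean())
            ** 2
        )
        r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else float("nan")

    # a fitted total log-change below 1e-12 over the observed window is
    # numerical noise, not decay (e.g. an exactly constant series)
    if abs(k) * (t.max() - t.min()) < 1e-12:
        k = 0.0
    t_half = math.log(2) / k if k > 0 else math.inf
    return DecayFit(k=k, k_se=k_se, C0=c0, t_half=t_half, r_squared=r2, n=len(df))


def simulate_decay(
    C0: float,
    k: float,
    times=PAPER_TIMEPOINTS_MIN,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
    n_replicates: int = 1,
) -> DecaySeries:
    """Simulate exponential decay with multiplicative log-normal noise.

    Each observation is C0*exp(-k t)*exp(sigma*z - sigma^2/2) with
    sigma = noise_cv and z ~ N(0,1) (mean-preserving to first order), so
    noise never produces negative concentrations.
    """
    times = np.asarray(list(times), float)
    if times.size == 0:
        raise InputError("empty times")
    if k < 0 or noise_cv < 0:
        raise InputError("k and noise_cv must be >= 0")
    if C0 <= 0:
        raise InputError("C0 must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        c = C0 * np.exp(-k * times)
        if noise_cv > 0:
            z = rng.standard_normal(times.size)
            c = c * np.exp(noise_cv * z - 0.5 * noise_cv**2)
        rows.append(
            pd.DataFrame(
                {"time_min": times, "concentration_uM": c, "replicate": rep}
            )
        )
    tag = "simulated" if isinstance(seed, np.random.Generator) else f"simulated(seed={seed})"
    return DecaySeries(pd.concat(rows, ignore_index=True), provenance=tag)
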