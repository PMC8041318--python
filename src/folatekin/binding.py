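"""Competitive displacement of a radiolabeled folate tracer from its receptor.

A labeled tracer (e.g. tritiated folic acid) and an unlabeled competitor
bind the same cell-surface receptor (folate receptor alpha).  In the tracer
limit — tracer and receptor concentrations negligible next to the
dissociation constants — the fraction of tracer displaced at competitor
concentration c is f = (c/Kd_c)/(1 + c/Kd_c), so the displacement odds
f/(1-f) equal c/Kd_c and the ratio of two competitors' binding constants at
equal dose is the ratio of their displacement odds.  The difference in
standard binding free energies follows as ddG = R T ln(ratio).

Outside the tracer limit the module solves the full two-ligand/one-receptor
mass balance numerically (receptor depletion shifts displacement curves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import InputError, SolverError
from .units import R_GAS

__all__ = [
    "BindingSystem",
    "DisplacementPair",
    "bound_tracer_fraction",
    "displacement",
    "infer_K_ratio",
    "delta_G_from_ratio",
    "DEFAULT_TEMPERATURE_K",
]

#: Default temperature for free-energy conversion, K.
DEFAULT_TEMPERATURE_K: float = 298.15


@dataclass(frozen=True)
class BindingSystem:
    """Receptor R with tracer T (Kd_tracer) and competitor C (Kd_competitor).

    All concentrations and dissociation constants in the same unit (nM by
    convention); only ratios matter to the solver.
    """

    Kd_tracer: float
    Kd_competitor: float
    tracer_conc: float
    competitor_conc: float
    receptor_total: float

    def __post_init__(self) -> None:
        if self.Kd_tracer <= 0 or self.Kd_competitor <= 0:
            raise InputError("dissociation constants must be > 0")
        if self.tracer_conc <= 0 or self.receptor_total <= 0:
            raise InputError("tracer_conc and receptor_total must be > 0")
        if self.competitor_conc < 0:
            raise InputError("competitor_conc must be >= 0")


@dataclass(frozen=True)
class DisplacementPair:
    """Tracer displacement fractions by two competitors at equal dose."""

    displacement_a: float
    displacement_b: float
    competitor_conc: float | None = None  # uM, informational
    temperature: float = DEFAULT_TEMPERATURE_K  # K

    def __post_init__(self) -> None:
        for name in ("displacement_a", "displacement_b"):
            f = getattr(self, name)
            if not 0 <= f < 1:
                raise InputError(f"{name} must lie in [0, 1), got {f}")


def _solve_free_receptor(sys: BindingSystem) -> float:
    """Free receptor concentration from the coupled mass balance (brentq)."""

    def resid(r_free: float) -> float:
        t_free = sys.tracer_conc / (1.0 + r_free / sys.Kd_tracer)
        c_free = sys.competitor_conc / (1.0 + r_free / sys.Kd_competitor)
        return (
            r_free * (1.0 + t_free / sys.Kd_tracer + c_free / sys.Kd_competitor)
            - sys.receptor_total
        )

    lo, hi = 0.0, sys.receptor_total
    try:
        return brentq(resid, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise SolverError(f"receptor mass balance failed to bracket: {exc}")


def bound_tracer_fraction(sys: BindingSystem) -> float:
    """Fraction of total tracer bound to the receptor at equilibrium."""
    r_free = _solve_free_receptor(sys)
    t_free = sys.tracer_conc / (1.0 + r_free / sys.Kd_tracer)
    return (r_free * t_free / sys.Kd_tracer) / sys.tracer_conc


def displacement(sys: BindingSystem) -> float:
    """Fraction of tracer binding displaced relative to the competitor-free system."""
    baseline = bound_tracer_fraction(
        BindingSystem(
            Kd_tracer=sys.Kd_tracer,
            Kd_competitor=sys.Kd_competitor,
            tracer_conc=sys.tracer_conc,
            competitor_conc=0.0,
            receptor_total=sys.receptor_total,
        )
    )
    return 1.0 - bound_tracer_fraction(sys) / baseline


def infer_K_ratio(
    pair: DisplacementPair,
    receptor_total: float | None = None,
    tracer_conc: float | None = None,
    Kd_tracer: float | None = None,
) -> float:
    """Ratio of the two competitors' binding constants (a over b).

    Default tracer-limit route: ratio = odds(f_a)/odds(f_b) with
    odds(f) = f/(1-f); valid when tracer and receptor are dilute relative to
    all Kd values.  Supplying ``receptor_total``, ``tracer_conc`` and
    ``Kd_tracer`` (same unit as the competitor dose) switches to a full
    mass-balance inversion: each displacement is inverted numerically for
    the competitor Kd and the Kd ratio (b over a, i.e. affinity ratio a/b)
    returned.
    """
    f_a, f_b = pair.displacement_a, pair.displacement_b
    if f_b == 0 and f_a == 0:
        return 1.0
    if f_b == 0:
        raise InputError("displacement_b = 0 gives an unbounded ratio")

    full = (receptor_total, tracer_conc, Kd_tracer)
    if any(v is not None for v in full):
        if any(v is None for v in full):
            raise InputError(
                "full-equilibrium inversion needs receptor_total, tracer_conc "
                "and Kd_tracer together"
            )
        if pair.competitor_conc is None:
            raise InputError("full-equilibrium inversion needs competitor_conc")
        kd_a = _invert_kd(f_a, pair.competitor_conc, receptor_total, tracer_conc, Kd_tracer)
        kd_b = _invert_kd(f_b, pair.competitor_conc, receptor_total, tracer_conc, Kd_tracer)
        return kd_b / kd_a

    return (f_a / (1.0 - f_a)) / (f_b / (1.0 - f_b))


def _invert_kd(
    f: float, c: float, receptor_total: float, tracer_conc: float, kd_tracer: float
) -> float:
    """Competitor Kd reproducing displacement f in the full mass balance."""
    if f <= 0:
        raise InputError("cannot invert a zero displacement for a finite Kd")

    def resid(log_kd: float) -> float:
        sys = BindingSystem(
            Kd_tracer=kd_tracer,
            Kd_competitor=math.exp(log_kd),
            tracer_conc=tracer_conc,
            competitor_conc=c,
            receptor_total=receptor_total,
        )
        return displacement(sys) - f

    lo, hi = math.log(c) - 25.0, math.log(c) + 25.0
    try:
        return math.exp(brentq(resid, lo, hi, maxiter=200))
    except ValueError as exc:
        raise SolverError(f"Kd inversion failed to bracket displacement {f}: {exc}")


def delta_G_from_ratio(ratio: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free-energy difference ddG = R T ln(ratio), in kJ/mol."""
    if ratio <= 0:
        raise InputError("ratio must be > 0")
    if temperature <= 0:
        raise InputError("temperature must be > 0")
    return R_GAS * temperature * math.log(ratio) / 1000.0
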