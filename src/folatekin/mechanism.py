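"""Coupled-equilibrium inhibition kinetics of human thymidylate synthase (hTS).

hTS is a homodimer that equilibrates between an inactive conformation (II)
and an active dUMP-bound conformation (AA).  A difunctional folate-peptide
inhibitor i can act along two routes: its peptide end binds the
monomer-monomer interface of the inactive dimer (IiI), and its folate end
competes with the mTHF substrate s at the catalytic pockets of the active
dUMP complex (AAi, iAA), the latter still able to bind substrate into a
non-productive ternary complex (iAAs).  Under fast equilibration the scheme
is six coupled dissociation equilibria (all constants in uM):

    1.  AA  <->  II + d      K1 = [II][d]/[AA]        (d = dUMP, fixed)
    2.  II + i  <->  IiI     K2 = [II][i]/[IiI]       (interface binding)
    3.  AA + i  <->  AAi     K3                        (occupied-monomer pocket)
    4.  AA + i  <->  iAA     K4                        (other monomer pocket)
    5.  AA + s  <->  AAs     K5                        (productive complex)
    6.  iAA + s <->  iAAs    K6                        (non-productive ternary)

Only AAs turns over, so v = Vmax * [AAs]/E_total.  Summing the species gives
the closed-form rate law, which has the linear mixed-inhibition shape

    v = Vmax * s / ( Km_app (1 + i/Ki) + s (1 + i/Ki') )

with Km_app = K5 (1 + K1/d),  Ki' = K4 K6 / K5  and the exact slope constant

    1/Ki = [ K1/(d K2) + 1/K3 + 1/K4 ] / (1 + K1/d).

When d >> K1 (the assays run at d/K1 ~ 15) the prefactor is ~1 and the
composite relation reduces to 1/Ki = 1/K3 + 1/K4 + K1/(d K2), the form used
by :func:`infer_micro_constants` to convert apparent constants read off
double-reciprocal (Lineweaver-Burk) secondary plots into microscopic ones.

The module provides the closed-form rate law, an independent numerical
species-balance oracle that does NOT assume the tracer-enzyme limit, dataset
simulation, double-reciprocal primary/secondary fitting, a reproducible
mixed-vs-competitive classification, and apparent -> microscopic inference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .errors import FitError, InputError, ParameterDomainError, SolverError

__all__ = [
    "MechanismParams",
    "AssayCondition",
    "SpeciesState",
    "RateDataset",
    "LineFit",
    "ReciprocalFits",
    "InhibitionSummary",
    "MicroConstants",
    "rate_law",
    "species_balance_oracle",
    "simulate_rates",
    "grid_design",
    "fig_lr_design",
    "double_reciprocal_fit",
    "classify_and_extract",
    "infer_micro_constants",
    "DEFAULT_DUMP_UM",
    "DEFAULT_D_OVER_K1",
]

#: Fixed dUMP concentration of the standard assay design, uM.
DEFAULT_DUMP_UM: float = 140.0
#: Ratio [dUMP]/K1 that holds in the standard assays.
DEFAULT_D_OVER_K1: float = 15.0

SPECIES = ("II", "AA", "AAs", "IiI", "AAi", "iAA", "iAAs")


@dataclass(frozen=True)
class MechanismParams:
    """Microscopic constants of the six-equilibrium scheme plus catalytic scale.

    All equilibrium constants are dissociation constants in uM.  ``K2`` and
    ``K6`` may be ``math.inf`` to switch off the interface-binding and
    non-productive-ternary paths respectively (their reciprocals enter the
    rate law, so the limit is exact).  ``K5`` is the substrate
    half-saturation of the productive AA -> AAs step (also exposed as
    :attr:`Ks`).  ``Vmax`` is the maximum initial rate at saturating
    substrate and zero inhibitor, in the same (arbitrary) units as the
    observed rates.
    """

    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    K6: float
    Vmax: float

    def __post_init__(self) -> None:
        for name in ("K1", "K3", "K4", "K5", "Vmax"):
            v = getattr(self, name)
            if not (v > 0) or math.isinf(v):
                raise ParameterDomainError(f"{name} must be finite and > 0, got {v}")
        for name in ("K2", "K6"):
            v = getattr(self, name)
            if not v > 0:
                raise ParameterDomainError(f"{name} must be > 0 (inf allowed), got {v}")

    @property
    def Ks(self) -> float:
        """Substrate half-saturation of the productive step (alias of K5)."""
        return self.K5

    def km_app(self, d: float) -> float:
        """Apparent Michaelis constant at dUMP concentration ``d`` (uM)."""
        return self.K5 * (1.0 + self.K1 / d)

    def ki_app(self, d: float) -> float:
        """Exact apparent slope inhibition constant Ki at dUMP ``d`` (uM)."""
        inv = (self.K1 / (d * self.K2) + 1.0 / self.K3 + 1.0 / self.K4) / (
            1.0 + self.K1 / d
        )
        return math.inf if inv == 0 else 1.0 / inv

    def ki_prime(self) -> float:
        """Apparent intercept inhibition constant Ki' = K4*K6/K5 (uM)."""
        if math.isinf(self.K6):
            return math.inf
        return self.K4 * self.K6 / self.K5

    @classmethod
    def from_apparent(
        cls,
        km_app: float,
        vmax: float,
        ki: float,
        ki_prime: float = math.inf,
        *,
        d: float = DEFAULT_DUMP_UM,
        d_over_K1: float = DEFAULT_D_OVER_K1,
        interface_share: float = 0.0,
    ) -> "MechanismParams":
        """Build microscopic constants that reproduce given apparent constants.

        ``interface_share`` is the fraction of 1/Ki carried by the
        interface-binding term K1/(d*K2); the catalytic-pocket share is split
        equally between K3 and K4.  The construction is exact: the returned
        parameters satisfy ``ki_app(d) == ki`` and ``ki_prime() == ki_prime``
        up to floating-point rounding.
        """
        if not 0.0 <= interface_share < 1.0:
            raise InputError("interface_share must be in [0, 1)")
        if ki <= 0 or km_app <= 0 or vmax <= 0:
            raise ParameterDomainError("km_app, vmax and ki must be positive")
        K1 = d / d_over_K1
        K5 = km_app / (1.0 + K1 / d)
        inv_total = (1.0 + K1 / d) / ki  # = K1/(d K2) + 1/K3 + 1/K4
        if interface_share > 0:
            K2 = K1 / (d * interface_share * inv_total)
        else:
            K2 = math.inf
        K34 = 2.0 / ((1.0 - interface_share) * inv_total)
        K6 = math.inf if math.isinf(ki_prime) else ki_prime * K5 / K34
        return cls(K1=K1, K2=K2, K3=K34, K4=K34, K5=K5, K6=K6, Vmax=vmax)


@dataclass(frozen=True)
class AssayCondition:
    """One assay point: substrate s (mTHF), dUMP d, inhibitor i, all uM."""

    s: float
    d: float = DEFAULT_DUMP_UM
    i: float = 0.0

    def __post_init__(self) -> None:
        if self.s < 0 or self.i < 0:
            raise InputError(f"s and i must be >= 0, got s={self.s}, i={self.i}")
        if self.d <= 0:
            raise InputError(f"d must be > 0, got {self.d}")


@dataclass(frozen=True)
class SpeciesState:
    """Fractional abundances of the seven enzyme species (per total enzyme)."""

    II: float
    AA: float
    AAs: float
    IiI: float
    AAi: float
    iAA: float
    iAAs: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in SPECIES}

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())


@dataclass
class RateDataset:
    """Initial-rate observations over a (substrate, inhibitor) grid.

    ``data`` has columns ``substrate_uM, inhibitor_uM, dump_uM, rate``; every
    record shares the single dUMP concentration of the fixed-[dUMP] design.
    ``provenance`` is ``"measured"`` or ``"simulated(seed=...)"``.
    """

    data: pd.DataFrame
    provenance: str = "measured"

    REQUIRED = ("substrate_uM", "inhibitor_uM", "dump_uM", "rate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InputError(f"rate table missing column(s): {', '.join(missing)}")
        d = self.data["dump_uM"].unique()
        if len(d) != 1:
            raise InputError(
                f"fixed-[dUMP] design requires one dUMP level, found {sorted(d)}"
            )
        if (self.data["rate"] < 0).any():
            raise InputError("rates must be >= 0")

    @property
    def dump_uM(self) -> float:
        return float(self.data["dump_uM"].iloc[0])

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class LineFit:
    """An ordinary least-squares line y = intercept + slope * x."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    cov_slope_intercept: float
    slope_pvalue: float
    n: int

    @property
    def df_resid(self) -> int:
        return self.n - 2


@dataclass
class ReciprocalFits:
    """Primary double-reciprocal fits and their secondary replots.

    ``primary`` maps each inhibitor level to the OLS line of 1/v on 1/s.
    ``slope_line`` and ``intercept_line`` are the secondary OLS lines of the
    primary slopes and intercepts on inhibitor concentration.
    """

    primary: dict[float, LineFit]
    slope_line: LineFit
    intercept_line: LineFit
    dump_uM: float

    @property
    def inhibitor_levels(self) -> list[float]:
        return sorted(self.primary)


@dataclass(frozen=True)
class InhibitionSummary:
    """Apparent inhibition constants and the inhibition-mode call.

    ``mode`` is ``"competitive"`` (slope effect only), ``"mixed"`` (slope and
    intercept effects) or ``"none"`` (no inhibitor dependence detected).
    ``Kiprime_app`` is present only for mixed inhibition.  ``low_confidence``
    flags calls made from a 2-level design via the relative-change rule
    rather than a t-test.
    """

    mode: Literal["competitive", "mixed", "none"]
    Ki_app: float | None = None
    Ki_app_se: float | None = None
    Kiprime_app: float | None = None
    Kiprime_app_se: float | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.mode == "competitive" and self.Kiprime_app is not None:
            raise InputError("competitive mode must not carry Ki'_app")
        if self.Ki_app is not None and not self.Ki_app > 0:
            raise InputError("Ki_app must be > 0")


@dataclass(frozen=True)
class MicroConstants:
    """Microscopic constants inferred from apparent ones.

    ``inv34`` is the 1/K3 + 1/K4 term (uM^-1); ``hmean34 = 2/inv34`` is the
    harmonic mean of the two catalytic-pocket constants.  When ``inv34 <= 0``
    the interface-binding correction already accounts for the whole observed
    inhibition and ``interface_only`` is set.
    """

    K2_est: float | None = None
    K2_est_se: float | None = None
    inv34: float | None = None
    hmean34: float | None = None
    Kiprime_composite: float | None = None
    interface_only: bool = False


# ---------------------------------------------------------------------------
# rate law and species-balance oracle
# ---------------------------------------------------------------------------

def rate_law(cond: AssayCondition, p: MechanismParams) -> float:
    """Closed-form initial rate of the six-equilibrium scheme (tracer enzyme).

    Evaluates v = Vmax*(s/K5)/D with denominator
    D = 1 + K1/d + i*(K1/(d K2) + 1/K3 + 1/K4) + s/K5 + i*s/(K4 K6),
    i.e. the linear mixed-inhibition apparent form.  Reduces to
    Michaelis-Menten v = Vmax*s/(Km_app + s) at i = 0.
    """
    s, d, i = cond.s, cond.d, cond.i
    inv_k2 = 0.0 if math.isinf(p.K2) else 1.0 / p.K2
    inv_k6 = 0.0 if math.isinf(p.K6) else 1.0 / p.K6
    denom = (
        1.0
        + p.K1 / d
        + i * (p.K1 * inv_k2 / d + 1.0 / p.K3 + 1.0 / p.K4)
        + s / p.K5
        + i * s * inv_k6 / p.K4
    )
    return p.Vmax * (s / p.K5) / denom


def _species_from_free(p: MechanismParams, ii: float, d: float, s: float, i: float):
    """Concentrations of the seven species given free [II] and free ligands."""
    inv_k2 = 0.0 if math.isinf(p.K2) else 1.0 / p.K2
    inv_k6 = 0.0 if math.isinf(p.K6) else 1.0 / p.K6
    aa = ii * d / p.K1
    return {
        "II": ii,
        "AA": aa,
        "AAs": aa * s / p.K5,
        "IiI": ii * i * inv_k2,
        "AAi": aa * i / p.K3,
        "iAA": aa * i / p.K4,
        "iAAs": aa * i * inv_k6 / p.K4 * s,
    }


def species_balance_oracle(
    cond: AssayCondition,
    p: MechanismParams,
    total_enzyme: float,
    rtol: float = 1e-10,
) -> tuple[SpeciesState, float]:
    """Numerically solve the full mass balance of the scheme.

    ``cond`` gives TOTAL ligand concentrations (uM); ``total_enzyme`` is the
    total enzyme concentration (uM).  No tracer-enzyme assumption is made:
    ligand depletion by complex formation is part of the balance.  Each
    enzyme complex is counted as sequestering one molecule of each bound
    ligand.  Returns the species fractions (per total enzyme) and the rate
    Vmax * fraction(AAs).

    Raises :class:`SolverError` with a residual report if the relative
    conservation residuals exceed ``rtol``.
    """
    if total_enzyme <= 0:
        raise InputError("total_enzyme must be > 0")
    s_tot, d_tot, i_tot = cond.s, cond.d, cond.i
    if d_tot <= 0:
        raise InputError("d must be > 0")

    # unknowns: log free [II], log free d, and (when present) log free s, i
    has_s, has_i = s_tot > 0, i_tot > 0

    def unpack(x):
        ii, d = math.exp(x[0]), math.exp(x[1])
        k = 2
        if has_s:
            s = math.exp(x[k]); k += 1
        else:
            s = 0.0
        i = math.exp(x[k]) if has_i else 0.0
        return ii, d, s, i

    def residuals(x):
        ii, d, s, i = unpack(x)
        sp = _species_from_free(p, ii, d, s, i)
        res = [
            (sum(sp.values()) - total_enzyme) / total_enzyme,
            (d + sum(sp[k] for k in ("AA", "AAs", "AAi", "iAA", "iAAs")) - d_tot)
            / d_tot,
        ]
        if has_s:
            res.append((s + sp["AAs"] + sp["iAAs"] - s_tot) / s_tot)
        if has_i:
            res.append(
                (i + sp["IiI"] + sp["AAi"] + sp["iAA"] + sp["iAAs"] - i_tot) / i_tot
            )
        return res

    x0 = [math.log(total_enzyme / 4.0), math.log(d_tot)]
    if has_s:
        x0.append(math.log(s_tot))
    if has_i:
        x0.append(math.log(i_tot))

    sol = least_squares(residuals, x0, xtol=2.3e-16, ftol=2.3e-16,
                        gtol=2.3e-16, method="lm")
    res = residuals(sol.x)
    if max(abs(r) for r in res) > rtol:
        raise SolverError(
            f"species balance did not converge below rtol={rtol}", residuals=res
        )
    ii, d, s, i = unpack(sol.x)
    sp = _species_from_free(p, ii, d, s, i)
    fractions = {k: v / total_enzyme for k, v in sp.items()}
    state = SpeciesState(**fractions)
    return state, p.Vmax * state.AAs


# ---------------------------------------------------------------------------
# simulation and assay designs
# ---------------------------------------------------------------------------

def grid_design(
    substrate_levels: Sequence[float],
    inhibitor_levels: Sequence[float],
    d: float = DEFAULT_DUMP_UM,
) -> list[AssayCondition]:
    """Full factorial design over substrate and inhibitor levels at fixed d."""
    if len(substrate_levels) == 0 or len(inhibitor_levels) == 0:
        raise InputError("design grids must be non-empty")
    return [
        AssayCondition(s=float(s), d=float(d), i=float(i))
        for i in inhibitor_levels
        for s in substrate_levels
    ]


#: Default mTHF substrate levels (uM) bracketing the default apparent Km.
DEFAULT_SUBSTRATE_LEVELS: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0)


def fig_lr_design(
    substrate_levels: Sequence[float] = DEFAULT_SUBSTRATE_LEVELS,
    d: float = DEFAULT_DUMP_UM,
) -> list[AssayCondition]:
    """The standard LR-peptide assay grid: [i] = 0, 25, 50, 100 uM at fixed d."""
    return grid_design(substrate_levels, (0.0, 25.0, 50.0, 100.0), d=d)


def simulate_rates(
    p: MechanismParams,
    design: Sequence[AssayCondition],
    noise_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> RateDataset:
    """Simulate a rate dataset on a design with multiplicative Gaussian noise.

    Each observed rate is ``rate_law(cond, p) * (1 + noise_cv * z)`` with
    z ~ N(0, 1); negative draws are clipped to zero (they are dropped with a
    warning downstream).  Reproducible for a fixed integer seed.
    """
    if len(design) == 0:
        raise InputError("empty design")
    if noise_cv < 0:
        raise InputError("noise_cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.array([rate_law(c, p) for c in design])
    if noise_cv > 0:
        v = v * (1.0 + noise_cv * rng.standard_normal(len(v)))
        v = np.clip(v, 0.0, None)
    df = pd.DataFrame(
        {
            "substrate_uM": [c.s for c in design],
            "inhibitor_uM": [c.i for c in design],
            "dump_uM": [c.d for c in design],
            "rate": v,
        }
    )
    tag = "simulated" if isinstance(seed, np.random.Generator) else f"simulated(seed={seed})"
    return RateDataset(df, provenance=tag)


# ---------------------------------------------------------------------------
# double-reciprocal analysis
# ---------------------------------------------------------------------------

def _ols_line(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> LineFit:
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    with np.errstate(divide="ignore", invalid="ignore"):  # exact 2-point lines
        fit = model.fit()
        cov = np.asarray(fit.cov_params())
        bse = fit.bse
        pvals = fit.pvalues
    return LineFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(bse[1]),
        intercept_se=float(bse[0]),
        cov_slope_intercept=float(cov[0, 1]),
        slope_pvalue=float(pvals[1]),
        n=len(x),
    )


def double_reciprocal_fit(data: RateDataset, weighted: bool = False) -> ReciprocalFits:
    """Primary 1/v-vs-1/s OLS per inhibitor level plus secondary replots.

    Zero-rate records are excluded with a warning.  Each inhibitor level
    needs at least 3 distinct substrate levels.  ``weighted=True`` applies
    1/v^4 weights (weighting proportional to rate variance on the reciprocal
    scale); the default matches unweighted least-squares lines.
    """
    df = data.data
    bad = df["rate"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} record(s) with non-positive rate",
            stacklevel=2,
        )
        df = df[~bad]
    if df.empty:
        raise FitError("no usable records after excluding non-positive rates")

    primary: dict[float, LineFit] = {}
    for i_level, grp in df.groupby("inhibitor_uM", sort=True):
        if grp["substrate_uM"].nunique() < 3:
            raise FitError(
                f"inhibitor level {i_level} uM has fewer than 3 substrate levels"
            )
        x = 1.0 / grp["substrate_uM"].to_numpy(float)
        y = 1.0 / grp["rate"].to_numpy(float)
        w = grp["rate"].to_numpy(float) ** 4 if weighted else None
        primary[float(i_level)] = _ols_line(x, y, weights=w)

    if len(primary) < 2:
        raise FitError("secondary replots need at least 2 inhibitor levels")
    levels = np.array(sorted(primary))
    slopes = np.array([primary[i].slope for i in levels])
    intercepts = np.array([primary[i].intercept for i in levels])
    slope_line = _ols_line(levels, slopes)
    intercept_line = _ols_line(levels, intercepts)
    return ReciprocalFits(
        primary=primary,
        slope_line=slope_line,
        intercept_line=intercept_line,
        dump_uM=data.dump_uM,
    )


def _ratio_with_se(num: float, den: float, se_num: float, se_den: float,
                   cov: float) -> tuple[float, float]:
    """Delta-method SE for num/den with covariance between the two."""
    r = num / den
    var = (r ** 2) * (
        (se_num / num) ** 2 + (se_den / den) ** 2 - 2.0 * cov / (num * den)
    )
    return r, math.sqrt(max(var, 0.0))


#: Relative intercept change below which inhibitor dependence is treated as
#: numerically zero (noise-free data yields 0/0 t statistics otherwise).
_ZERO_GUARD = 1e-9
#: Relative-change threshold for the 2-level (exact-line) classification rule.
_TWO_LEVEL_THRESHOLD = 0.05


def classify_and_extract(fits: ReciprocalFits, alpha: float = 0.05) -> InhibitionSummary:
    """Call the inhibition mode and extract apparent constants.

    The slope replot gives Ki_app = intercept/slope of the slope-vs-i line;
    the intercept replot gives Ki'_app analogously.  The mode is mixed when
    the intercept-vs-i slope differs from zero (two-sided t-test at
    ``alpha``; with only two inhibitor levels the line is exact and a >5%
    relative intercept change over the inhibitor range substitutes for the
    test, flagged low-confidence).  A non-positive slope replot slope means
    no inhibitor dependence at all: "no inhibition detected".
    """
    sl = fits.slope_line
    il = fits.intercept_line
    i_range = max(fits.inhibitor_levels) - min(fits.inhibitor_levels)
    slope_rel_change = (
        sl.slope * i_range / sl.intercept if sl.intercept > 0 else math.inf
    )
    if sl.slope <= 0 or slope_rel_change < _ZERO_GUARD:
        return InhibitionSummary(mode="none")

    ki, ki_se = _ratio_with_se(
        sl.intercept, sl.slope, sl.intercept_se, sl.slope_se, sl.cov_slope_intercept
    )

    baseline = il.intercept if il.intercept != 0 else np.finfo(float).tiny
    rel_change = il.slope * i_range / baseline

    low_confidence = False
    if abs(rel_change) < _ZERO_GUARD or il.slope <= 0:
        mixed = False
    elif len(fits.inhibitor_levels) <= 2:
        mixed = rel_change > _TWO_LEVEL_THRESHOLD
        low_confidence = True
    else:
        mixed = il.slope_pvalue < alpha

    if not mixed:
        return InhibitionSummary(
            mode="competitive", Ki_app=ki, Ki_app_se=ki_se,
            low_confidence=low_confidence,
        )
    kip, kip_se = _ratio_with_se(
        il.intercept, il.slope, il.intercept_se, il.slope_se, il.cov_slope_intercept
    )
    return InhibitionSummary(
        mode="mixed",
        Ki_app=ki,
        Ki_app_se=ki_se,
        Kiprime_app=kip,
        Kiprime_app_se=kip_se,
        low_confidence=low_confidence,
    )


# ---------------------------------------------------------------------------
# apparent -> microscopic inference
# ---------------------------------------------------------------------------

def infer_micro_constants(
    summary: InhibitionSummary,
    d: float = DEFAULT_DUMP_UM,
    d_over_K1: float = DEFAULT_D_OVER_K1,
    K2_ref: float | None = None,
) -> MicroConstants:
    """Convert apparent constants to microscopic ones via the composite relations.

    For a peptide whose only inhibition route is interface binding,
    Ki_app = d*K2/K1, so ``K2_est = Ki_app / (d/K1)``.  For a difunctional
    conjugate, 1/Ki_app = 1/K3 + 1/K4 + K1/(d*K2); supplying the
    peptide-derived ``K2_ref`` isolates the catalytic-pocket term
    ``inv34 = 1/Ki_app - 1/(d_over_K1*K2_ref)`` and its harmonic mean
    ``hmean34 = 2/inv34``.  A non-positive ``inv34`` means interface binding
    alone explains the observed inhibition.
    """
    if d_over_K1 <= 0:
        raise InputError("d_over_K1 must be > 0")
    if summary.Ki_app is None:
        raise InputError("summary carries no Ki_app (mode 'none')")
    ki = summary.Ki_app
    kip = summary.Kiprime_app

    if K2_ref is None:
        k2 = ki / d_over_K1
        k2_se = summary.Ki_app_se / d_over_K1 if summary.Ki_app_se is not None else None
        return MicroConstants(K2_est=k2, K2_est_se=k2_se, Kiprime_composite=kip)

    if K2_ref <= 0:
        raise InputError("K2_ref must be > 0")
    inv34 = 1.0 / ki - 1.0 / (d_over_K1 * K2_ref)
    if inv34 <= 0:
        return MicroConstants(
            inv34=inv34, Kiprime_composite=kip, interface_only=True
        )
    return MicroConstants(
        inv34=inv34, hmean34=2.0 / inv34, Kiprime_composite=kip
    )
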