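"""Subcellular compartmentalization of a folate-peptide conjugate.

After incubating cells with the conjugate, differential lysis and
centrifugation separate the extracellular medium, the endocytic vesicles and
the cytosol; LC-MS/MS gives the conjugate mass in each fraction.  This
module converts those masses into molar concentrations per compartment using
the cell count and the compartment volume fractions, handles the
charge-state arithmetic that ties the measured m/z of multiply protonated
ions to the neutral mass, and implements the fluorometric and single-cell
concentration back-calculations used as orthogonal checks.

A useful output is the vesicle/cytosol concentration ratio

    ratio = (m_ves / m_cyt) * (f_cyt / f_ves)

in which the conjugate molar mass cancels exactly, making the ratio robust
to any uncertainty in the neutral mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .errors import InputError
from .units import PROTON_MASS_DA, mol_per_l_to_um, ng_to_mol

__all__ = [
    "CompartmentGeometry",
    "FractionMeasurement",
    "ConjugateIdentity",
    "FluorometricReading",
    "neutral_mass_from_mz",
    "predict_mz",
    "compartment_volume",
    "fraction_concentration",
    "vesicle_cytosol_ratio",
    "fluorometric_concentration",
    "single_cell_concentration",
    "PAPER_CONSISTENT_CALIBRATION",
]

FractionLabel = Literal["extracellular", "cytosolic", "vesicles"]
_FRACTIONS = ("extracellular", "cytosolic", "vesicles")


@dataclass(frozen=True)
class CompartmentGeometry:
    """Cell count and compartment volumes of a fractionation experiment.

    Defaults describe the standard ovarian-cancer-cell experiment: 2e6 lysed
    cells of 2 pL each, with cytosol and endocytic vesicles occupying 60%
    and 2.5% of the cell volume.  ``external_volume`` is the extracellular
    medium volume; the 3.0 mL default is back-implied by the reported
    extracellular mass/concentration pair (10,200 ng at 2.38 uM) and should
    be overridden with the actual incubation volume when known.
    """

    n_cells: float = 2e6
    cell_volume: float = 2e-12  # L
    cytosol_fraction: float = 0.60
    vesicle_fraction: float = 0.025
    external_volume: float = 3.0e-3  # L

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InputError("n_cells must be >= 1")
        if not (0 < self.cytosol_fraction < 1 and 0 < self.vesicle_fraction < 1):
            raise InputError("volume fractions must lie in (0, 1)")
        if self.cytosol_fraction + self.vesicle_fraction >= 1:
            raise InputError("cytosol and vesicle fractions must sum below 1")
        if self.cell_volume <= 0 or self.external_volume <= 0:
            raise InputError("volumes must be > 0")

    @property
    def cytosol_volume_per_cell(self) -> float:
        return self.cell_volume * self.cytosol_fraction


@dataclass(frozen=True)
class FractionMeasurement:
    """Conjugate mass (ng) measured in one subcellular fraction."""

    fraction: FractionLabel
    mass: float  # ng
    temperature: float | None = None  # degrees C
    uncertainty: float | None = None  # ng

    def __post_init__(self) -> None:
        if self.fraction not in _FRACTIONS:
            raise InputError(
                f"unknown fraction {self.fraction!r}; expected one of {_FRACTIONS}"
            )
        if self.mass < 0:
            raise InputError("mass must be >= 0")


@dataclass(frozen=True)
class ConjugateIdentity:
    """Neutral mass of the conjugate, optionally with its observed charge states.

    ``charge_states`` is a list of (z, m/z) pairs; on construction each pair
    is checked for consistency with ``neutral_mass`` within 0.05 Da.
    """

    neutral_mass: float  # Da
    charge_states: tuple[tuple[int, float], ...] = ()
    proton_mass: float = PROTON_MASS_DA

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise InputError("neutral_mass must be > 0")
        for z, mz in self.charge_states:
            implied = neutral_mass_from_mz(mz, z, self.proton_mass)
            if abs(implied - self.neutral_mass) > 0.05 * z:
                raise InputError(
                    f"charge state z={z}, m/z={mz} implies neutral mass "
                    f"{implied:.4f} Da, inconsistent with {self.neutral_mass:.4f}"
                )

    @classmethod
    def from_charge_states(
        cls,
        charge_states: Iterable[tuple[int, float]],
        proton_mass: float = PROTON_MASS_DA,
    ) -> "ConjugateIdentity":
        """Average the neutral masses implied by each observed charge state."""
        states = tuple((int(z), float(mz)) for z, mz in charge_states)
        if not states:
            raise InputError("need at least one (z, m/z) pair")
        masses = [neutral_mass_from_mz(mz, z, proton_mass) for z, mz in states]
        return cls(
            neutral_mass=sum(masses) / len(masses),
            charge_states=states,
            proton_mass=proton_mass,
        )


@dataclass(frozen=True)
class FluorometricReading:
    """Paired treated/control fluorescence intensities, in kcounts.

    ``calibration_factor`` converts a treated-minus-control signal
    difference into a cytosolic concentration (kcounts per uM); it is
    instrument- and protocol-specific and must be determined by spiking
    known conjugate amounts into control lysates.
    """

    emission_treated: float
    emission_control: float
    excitation_treated: float
    excitation_control: float
    calibration_factor: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "emission_treated",
            "emission_control",
            "excitation_treated",
            "excitation_control",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")


#: Calibration factor (kcounts per uM) back-derived from the reported
#: 87 kcount emission difference corresponding to 20.2 uM; a documented
#: stand-in for the unreported instrument calibration, not a measured value.
PAPER_CONSISTENT_CALIBRATION: float = 87.0 / 20.2


def neutral_mass_from_mz(mz: float, z: int, proton_mass: float = PROTON_MASS_DA) -> float:
    """Neutral mass M = z*(m/z - m_proton) of an [M + zH]^z+ ion."""
    if z < 1:
        raise InputError(f"charge must be >= 1, got {z}")
    if mz <= proton_mass:
        raise InputError(f"m/z must exceed the proton mass, got {mz}")
    return z * (mz - proton_mass)


def predict_mz(neutral_mass: float, z: int, proton_mass: float = PROTON_MASS_DA) -> float:
    """Predicted m/z = (M + z*m_proton)/z of the [M + zH]^z+ ion."""
    if neutral_mass <= 0:
        raise InputError("neutral_mass must be > 0")
    if z < 1:
        raise InputError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * proton_mass) / z


def compartment_volume(geom: CompartmentGeometry, fraction: str) -> float:
    """Total volume (L) of a compartment across all cells in the sample."""
    if fraction == "cytosolic":
        return geom.n_cells * geom.cell_volume * geom.cytosol_fraction
    if fraction == "vesicles":
        return geom.n_cells * geom.cell_volume * geom.vesicle_fraction
    if fraction == "extracellular":
        return geom.external_volume
    raise InputError(
        f"unknown fraction {fraction!r}; expected one of {_FRACTIONS}"
    )


def fraction_concentration(
    m: FractionMeasurement, conj: ConjugateIdentity, volume: float
) -> float:
    """Molar concentration (uM) of the conjugate in a compartment.

    C = (mass / M) / V with mass in ng, M in Da and V in L.
    """
    if volume <= 0:
        raise InputError("volume must be > 0")
    mol = ng_to_mol(m.mass, conj.neutral_mass)
    return mol_per_l_to_um(mol / volume)


def vesicle_cytosol_ratio(
    m_ves: float, m_cyt: float, geom: CompartmentGeometry
) -> float:
    """Vesicle/cytosol concentration ratio from the two fraction masses (ng).

    Equals (m_ves/m_cyt)*(cytosol_fraction/vesicle_fraction); the conjugate
    molar mass and the cell count cancel exactly.
    """
    if m_cyt <= 0:
        raise InputError("cytosolic mass must be > 0 for a defined ratio")
    if m_ves < 0:
        raise InputError("vesicle mass must be >= 0")
    return (m_ves / m_cyt) * (geom.cytosol_fraction / geom.vesicle_fraction)


def fluorometric_concentration(
    r: FluorometricReading, geom: CompartmentGeometry | None = None
) -> dict[str, float]:
    """Cytosolic concentration (uM) from treated-minus-control fluorescence.

    Returns one value per channel (``emission`` and ``excitation``).  The
    calibration factor is taken to refer to the same cell count/geometry as
    the reading; when a ``geom`` differing from the calibration conditions
    applies, rescale the factor by the cytosolic-volume ratio beforehand.
    Negative signal differences (blank variability) are clamped to zero with
    a warning.
    """
    if r.calibration_factor is None or r.calibration_factor <= 0:
        raise InputError("a positive calibration_factor is required")
    out: dict[str, float] = {}
    for channel, treated, control in (
        ("emission", r.emission_treated, r.emission_control),
        ("excitation", r.excitation_treated, r.excitation_control),
    ):
        diff = treated - control
        if diff < 0:
            warnings.warn(
                f"{channel} treated signal below control ({diff:.3g} kcounts); "
                "reporting 0 uM",
                stacklevel=2,
            )
            diff = 0.0
        out[channel] = diff / r.calibration_factor
    return out


def single_cell_concentration(
    sample_concentration: float,
    dilution_volume: float,
    n_cells: float,
    cytosol_volume_per_cell: float = 1.2e-12,
) -> float:
    """Cytosolic concentration (uM) per cell from a diluted-lysate measurement.

    The pooled cytosol of ``n_cells`` cells is diluted to ``dilution_volume``
    (L) and its conjugate concentration ``sample_concentration`` (mol/L)
    interpolated from a calibration curve.  The per-cell cytosolic
    concentration is then

        C = sample_concentration * dilution_volume
            / (n_cells * cytosol_volume_per_cell).
    """
    if n_cells <= 0:
        raise InputError("n_cells must be > 0")
    if dilution_volume <= 0 or cytosol_volume_per_cell <= 0:
        raise InputError("volumes must be > 0")
    if sample_concentration < 0:
        raise InputError("sample_concentration must be >= 0")
    conc_m = sample_concentration * dilution_volume / (
        n_cells * cytosol_volume_per_cell
    )
    return mol_per_l_to_um(conc_m)
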