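"""Synthetic assay data with the statistical structure the analyses assume.

One :class:`ScenarioConfig` states the whole simulated world: the
initial-rate grid (four inhibitor levels at fixed 140 uM dUMP over five
substrate levels), the five-timepoint biostability series, the Table-style
fraction masses at 37 and 4 degrees C, a two-competitor displacement pair,
and a combinations x cell-lines growth-inhibition panel spanning the three
interaction classes.  :func:`generate_scenario` renders every table the
pipeline consumes, reproducibly under one seed, and keeps the generating
truths in a sidecar dictionary so that recovery tests (and blind tests, when
the sidecar is withheld) are possible without any external data.

Default noise levels are bench-plausible choices, stated here rather than
taken from any measurement: 5% CV on rates, 10% CV on decay concentrations,
5 percentage points (truncated to [0, 100]) on growth inhibitions, and
exact masses/displacements.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mechanism as mech
from .decay import PAPER_TIMEPOINTS_MIN, simulate_decay
from .errors import InputError

__all__ = ["ScenarioConfig", "ScenarioBundle", "generate_scenario", "write_fixtures"]


@dataclass
class ScenarioConfig:
    """Declarative description of one synthetic experiment bundle."""

    seed: int = 0

    # initial-rate assay (grid at fixed dUMP)
    substrate_levels: tuple[float, ...] = mech.DEFAULT_SUBSTRATE_LEVELS
    inhibitor_levels: tuple[float, ...] = (0.0, 25.0, 50.0, 100.0)
    dump_uM: float = mech.DEFAULT_DUMP_UM
    rate_noise_cv: float = 0.05
    # generating apparent constants (mixed-type conjugate truth)
    km_app: float = 20.0
    vmax: float = 1.0
    ki_app: float = 40.0
    ki_prime_app: float = 44.0
    interface_share: float = 0.4

    # biostability decay
    decay_C0_uM: float = 18.5
    decay_k_per_min: float = 3.5e-3
    decay_times_min: tuple[float, ...] = PAPER_TIMEPOINTS_MIN
    decay_noise_cv: float = 0.10
    decay_replicates: int = 1

    # compartment fraction masses, ng (37 C / 4 C as in the standard assay)
    fraction_masses_ng: dict = field(
        default_factory=lambda: {
            37.0: {"extracellular": 10200.0, "cytosolic": 60.2, "vesicles": 34.4},
            4.0: {"extracellular": 19300.0, "cytosolic": 31.6, "vesicles": 18.6},
        }
    )

    # displacement pair (tracer-limit world): dose in units of Kd_a
    displacement_a: float = 0.80
    displacement_b: float = 0.40
    competitor_uM: float = 5.0

    # combination panel: {cell_line: {(drug_b, dose_b): true SQ}}
    combination_sq: dict = field(
        default_factory=lambda: {
            "IGROV-1": {
                ("cDDP", 1.0): 1.16, ("cDDP", 2.5): 1.02, ("cDDP", 5.0): 0.85,
                ("5-FU", 5.0): 1.05, ("5-FU", 10.0): 0.95, ("5-FU", 15.0): 1.12,
                ("RTX", 10.0): 1.00, ("RTX", 15.0): 0.92, ("RTX", 20.0): 0.88,
            },
            "A2780": {
                ("cDDP", 1.0): 0.75, ("cDDP", 2.5): 0.85, ("cDDP", 5.0): 0.96,
                ("5-FU", 5.0): 0.90, ("5-FU", 10.0): 0.95, ("5-FU", 15.0): 1.00,
                ("RTX", 10.0): 0.85, ("RTX", 15.0): 0.92, ("RTX", 20.0): 0.97,
            },
        }
    )
    drug_a: str = "FA-LR"
    dose_a: float = 0.25  # uM
    inhibition_a_pct: float = 30.0
    inhibition_b_pct: float = 25.0
    inhibition_noise_pp: float = 5.0

    def __post_init__(self) -> None:
        if len(self.substrate_levels) == 0 or len(self.inhibitor_levels) == 0:
            raise InputError("assay grids must be non-empty")
        for name in ("rate_noise_cv", "decay_noise_cv", "inhibition_noise_pp"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    def mechanism_params(self) -> mech.MechanismParams:
        return mech.MechanismParams.from_apparent(
            km_app=self.km_app,
            vmax=self.vmax,
            ki=self.ki_app,
            ki_prime=self.ki_prime_app,
            d=self.dump_uM,
            interface_share=self.interface_share,
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "combination_sq" in raw:
            raw["combination_sq"] = {
                cell: {(d, float(dose)): sq for (d, dose), sq in _decode_keys(v)}
                for cell, v in raw["combination_sq"].items()
            }
        for key in ("substrate_levels", "inhibitor_levels", "decay_times_min"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "fraction_masses_ng" in raw:
            raw["fraction_masses_ng"] = {
                float(t): dict(v) for t, v in raw["fraction_masses_ng"].items()
            }
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["combination_sq"] = {
            cell: {f"{drug}@{dose}": sq for (drug, dose), sq in v.items()}
            for cell, v in self.combination_sq.items()
        }
        for key in ("substrate_levels", "inhibitor_levels", "decay_times_min"):
            raw[key] = list(raw[key])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _decode_keys(mapping):
    for key, sq in mapping.items():
        if isinstance(key, str):
            drug, dose = key.rsplit("@", 1)
            yield (drug, float(dose)), sq
        else:
            yield tuple(key), sq


@dataclass
class ScenarioBundle:
    """All generated tables plus the sidecar of generating truths."""

    rates: pd.DataFrame
    decay: pd.DataFrame
    fractions: pd.DataFrame
    displacement: pd.DataFrame
    combinations: pd.DataFrame
    truth: dict


def generate_scenario(cfg: ScenarioConfig) -> ScenarioBundle:
    """Render every pipeline input table from one scenario config."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_rates, rng_decay, rng_comb = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    params = cfg.mechanism_params()
    design = mech.grid_design(cfg.substrate_levels, cfg.inhibitor_levels, cfg.dump_uM)
    rates = mech.simulate_rates(params, design, cfg.rate_noise_cv, rng_rates).data

    decay = simulate_decay(
        cfg.decay_C0_uM,
        cfg.decay_k_per_min,
        cfg.decay_times_min,
        cfg.decay_noise_cv,
        rng_decay,
        n_replicates=cfg.decay_replicates,
    ).data

    frac_rows = [
        {"fraction": frac, "mass_ng": mass, "temperature_C": temp}
        for temp, masses in cfg.fraction_masses_ng.items()
        for frac, mass in masses.items()
    ]
    fractions = pd.DataFrame(frac_rows)

    displacement = pd.DataFrame(
        [
            {"label": "a", "displacement_fraction": cfg.displacement_a,
             "competitor_uM": cfg.competitor_uM},
            {"label": "b", "displacement_fraction": cfg.displacement_b,
             "competitor_uM": cfg.competitor_uM},
        ]
    )

    comb_rows = []
    for cell, combos in cfg.combination_sq.items():
        for (drug_b, dose_b), sq_true in combos.items():
            a, b = cfg.inhibition_a_pct, cfg.inhibition_b_pct
            combined = sq_true * (a + b)
            if cfg.inhibition_noise_pp > 0:
                noise = rng_comb.normal(0.0, cfg.inhibition_noise_pp, size=3)
                a, b, combined = (
                    float(np.clip(v + e, 0.0, 100.0))
                    for v, e in zip((a, b, combined), noise)
                )
            comb_rows.append(
                {
                    "cell_line": cell,
                    "drug_a": cfg.drug_a,
                    "dose_a": cfg.dose_a,
                    "drug_b": drug_b,
                    "dose_b": dose_b,
                    "inh_a_pct": a,
                    "inh_b_pct": b,
                    "inh_combined_pct": combined,
                }
            )
    combinations = pd.DataFrame(comb_rows)

    truth = {
        "seed": cfg.seed,
        "mechanism": {
            "km_app": cfg.km_app,
            "vmax": cfg.vmax,
            "ki_app": cfg.ki_app,
            "ki_prime_app": cfg.ki_prime_app,
            "micro": {
                k: getattr(params, k) for k in ("K1", "K2", "K3", "K4", "K5", "K6")
            },
        },
        "decay": {"C0_uM": cfg.decay_C0_uM, "k_per_min": cfg.decay_k_per_min},
        "binding": {
            "K_ratio": (cfg.displacement_a / (1 - cfg.displacement_a))
            / (cfg.displacement_b / (1 - cfg.displacement_b)),
        },
        "combination_sq": {
            cell: {f"{drug}@{dose}": sq for (drug, dose), sq in combos.items()}
            for cell, combos in cfg.combination_sq.items()
        },
    }
    return ScenarioBundle(
        rates=rates,
        decay=decay,
        fractions=fractions,
        displacement=displacement,
        combinations=combinations,
        truth=truth,
    )


def write_fixtures(bundle: ScenarioBundle, out_dir) -> dict[str, Path]:
    """Write the bundle as the delimited-text fixture set plus truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("rates", "decay", "fractions", "displacement", "combinations"):
        path = out / f"{name}.csv"
        getattr(bundle, name).to_csv(path, index=False)
        paths[name] = path
    truth_path = out / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
    paths["truth"] = truth_path
    return paths
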