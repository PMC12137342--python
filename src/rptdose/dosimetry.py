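"""Organ absorbed doses from time-integrated activity via self-dosing spheres.

Each organ is modeled as an isolated unit-density sphere that absorbs all of
its own charged-particle energy (absorbed fraction φ = 1 for alphas and
electrons — ranges are short against organ dimensions) while photons, by
default, escape (φ = 0). The absorbed dose per decay (the sphere S value) is

    S = Σ_class φ_class · Δ_class[MeV] · 1.602176634e-13 [J/MeV] / m[kg]   (Gy/decay)

and the organ dose sums S over every radioactive chain member weighted by its
cumulated decays per parent decay — the complete decay chain contributes, with
daughters deposited where the parent decayed (no redistribution), and RBE = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .biodist_io import BiodistStudy
from .kinetics import TimeIntegratedActivity, build_tac, trapezoid_tia
from .nuclide_chain import (
    PARTICLE_CLASSES,
    DecayChain,
    Nuclide,
    cumulated_decays_per_parent_decay,
)

__all__ = [
    "OrganReference",
    "DoseFactor",
    "DoseResult",
    "load_organ_references",
    "allometric_mass",
    "sphere_dose_factor",
    "organ_dose",
    "dose_table",
    "tumor_to_normal_ratios",
]

MEV_TO_J = 1.602176634e-13
PHOTON_MODELS = ("escape", "local", "table")

#: Density assumed when converting caliper tumor volume to mass.
TISSUE_DENSITY_G_PER_CM3 = 1.0


@dataclass(frozen=True)
class OrganReference:
    """Reference organ mass and its allometric scaling to a given body mass."""

    organ: str
    reference_mass_g: float
    reference_body_mass_g: float
    allometric_exponent: float = 1.0

    def __post_init__(self):
        if not (self.reference_mass_g > 0 and self.reference_body_mass_g > 0):
            raise ValueError(f"{self.organ}: reference masses must be > 0")
        if not 0.0 <= self.allometric_exponent <= 2.0:
            raise ValueError(f"{self.organ}: allometric exponent outside [0, 2]")


@dataclass(frozen=True)
class DoseFactor:
    """Sphere S value: Gy per decay in a target of ``target_mass_kg``."""

    nuclide: str
    target_mass_kg: float
    gy_per_decay: float
    breakdown: dict[str, float]  # particle class → Gy per decay


@dataclass(frozen=True)
class DoseResult:
    """Absorbed dose for one organ at one injected activity.

    ``contributions_gy[nuclide][particle class]`` sums to ``total_dose_gy``.
    ``conventions`` records the rise/tail/aggregation/photon/daughter options
    the number depends on.
    """

    organ: str
    dose_gy_per_bq: float
    injected_bq: float
    total_dose_gy: float
    contributions_gy: dict[str, dict[str, float]]
    mass_g: float
    rbe: float = 1.0
    conventions: dict = field(default_factory=dict)


def load_organ_references(path=None) -> dict[str, OrganReference]:
    """Load the packaged (or a user) reference-organ table."""
    if path is None:
        text = resources.files("rptdose.data").joinpath("organ_reference.yaml").read_text()
    else:
        text = open(path, encoding="utf-8").read()
    doc = yaml.safe_load(text)
    body = float(doc["reference_body_mass_g"])
    default_exp = float(doc.get("default_allometric_exponent", 1.0))
    return {
        organ: OrganReference(
            organ=organ,
            reference_mass_g=float(rec["reference_mass_g"]),
            reference_body_mass_g=body,
            allometric_exponent=float(rec.get("allometric_exponent", default_exp)),
        )
        for organ, rec in doc["organs"].items()
    }


def allometric_mass(ref: OrganReference, body_mass_g: float) -> float:
    """reference_mass × (body_mass / reference_body_mass)^exponent."""
    if not body_mass_g > 0:
        raise ValueError(f"body mass must be > 0, got {body_mass_g}")
    return ref.reference_mass_g * (body_mass_g / ref.reference_body_mass_g) ** ref.allometric_exponent


def _photon_phi_from_table(mass_g: float) -> float:
    text = resources.files("rptdose.data").joinpath("photon_absorbed_fractions.yaml").read_text()
    doc = yaml.safe_load(text)
    masses = np.asarray(doc["masses_g"], float)
    phi = np.asarray(doc["phi_photon"], float)
    if not masses[0] <= mass_g <= masses[-1]:
        raise ValueError(
            f"photon_model='table' has no absorbed fraction for mass {mass_g} g "
            f"(table covers {masses[0]}–{masses[-1]} g)"
        )
    return float(np.interp(math.log(mass_g), np.log(masses), phi))


def sphere_dose_factor(nuclide: Nuclide, mass_g: float, photon_model: str = "escape") -> DoseFactor:
    """Self-dosing-sphere Gy per decay for one nuclide in a target of ``mass_g``."""
    if not mass_g > 0:
        raise ValueError(f"mass must be > 0, got {mass_g}")
    if photon_model not in PHOTON_MODELS:
        raise ValueError(f"unknown photon_model {photon_model!r}; expected one of {PHOTON_MODELS}")
    mass_kg = mass_g / 1000.0
    phi = {"alpha": 1.0, "electron": 1.0}
    if photon_model == "escape":
        phi["photon"] = 0.0
    elif photon_model == "local":
        phi["photon"] = 1.0
    else:
        phi["photon"] = _photon_phi_from_table(mass_g)
    breakdown = {
        cls: phi[cls] * nuclide.energy_MeV[cls] * MEV_TO_J / mass_kg for cls in PARTICLE_CLASSES
    }
    return DoseFactor(
        nuclide=nuclide.name,
        target_mass_kg=mass_kg,
        gy_per_decay=sum(breakdown.values()),
        breakdown=breakdown,
    )


def organ_dose(
    tia: TimeIntegratedActivity,
    chain: DecayChain,
    mass_g: float,
    injected_bq: float,
    daughter_mode: str = "equilibrium",
    photon_model: str = "escape",
) -> DoseResult:
    """Organ absorbed dose over the complete decay chain.

    Cumulated parent decays per gram = tia × injected activity; each chain
    member contributes its branching-weighted decay count times its sphere
    dose factor. Linear in both ``tia`` and ``injected_bq``; RBE = 1.
    """
    if tia.tia < 0 or injected_bq < 0:
        raise ValueError("tia and injected activity must be ≥ 0")
    n_decays = cumulated_decays_per_parent_decay(chain, mode=daughter_mode)
    parent_decays_per_g = tia.tia * injected_bq
    parent_decays_total = parent_decays_per_g * mass_g
    contributions: dict[str, dict[str, float]] = {}
    total = 0.0
    for nuc in chain.radioactive_members:
        df = sphere_dose_factor(nuc, mass_g, photon_model=photon_model)
        per_class = {
            cls: parent_decays_total * n_decays[nuc.name] * df.breakdown[cls]
            for cls in PARTICLE_CLASSES
        }
        contributions[nuc.name] = per_class
        total += sum(per_class.values())
    conventions = dict(tia.conventions or {})
    conventions.update({"photon_model": photon_model, "daughter_mode": daughter_mode, "rbe": 1.0})
    return DoseResult(
        organ=tia.organ,
        dose_gy_per_bq=total / injected_bq if injected_bq > 0 else 0.0,
        injected_bq=injected_bq,
        total_dose_gy=total,
        contributions_gy=contributions,
        mass_g=mass_g,
        rbe=1.0,
        conventions=conventions,
    )


def _organ_mass(study: BiodistStudy, organ: str, refs: dict[str, OrganReference] | None) -> float:
    """Mean measured organ mass from the study rows, falling back to the
    allometric reference table (tumors always use measured mass)."""
    rows = study.for_organ(organ)
    measured = [m.organ_mass_g for m in rows if m.organ_mass_g > 0]
    if organ != "tumor" and refs and organ in refs:
        bodies = [m.body_mass_g for m in rows if m.body_mass_g]
        ref = refs[organ]
        body = float(np.mean(bodies)) if bodies else ref.reference_body_mass_g
        return allometric_mass(ref, body)
    if measured:
        return float(np.mean(measured))
    raise ValueError(f"no mass available for organ {organ!r}")


def dose_table(
    study: BiodistStudy,
    chain: DecayChain,
    injected_bq_list,
    refs: dict[str, OrganReference] | None = None,
    rise_model: str = "zero_at_injection",
    aggregation: str = "mean",
    daughter_mode: str = "equilibrium",
    photon_model: str = "escape",
) -> list[DoseResult]:
    """One :class:`DoseResult` per organ × injected activity.

    Organs with fewer than two time points are skipped (they cannot be
    integrated); results are deterministic given the options, and exactly
    linear in injected activity.
    """
    parent = chain.parent
    results: list[DoseResult] = []
    for organ in study.organs:
        timepoints = {m.time_h for m in study.for_organ(organ)}
        if len(timepoints) < 2:
            warnings.warn(f"organ {organ!r} has < 2 time points; skipped", stacklevel=2)
            continue
        if aggregation != "mean":
            raise ValueError("dose_table aggregates across animals; use aggregation='mean'")
        tac = build_tac(study, organ, parent, aggregation="mean")
        tia = trapezoid_tia(tac, lambda_tail=parent.decay_constant, rise_model=rise_model)
        mass = _organ_mass(study, organ, refs)
        for injected in injected_bq_list:
            results.append(
                organ_dose(
                    tia, chain, mass, injected,
                    daughter_mode=daughter_mode, photon_model=photon_model,
                )
            )
    return results


def tumor_to_normal_ratios(table: list[DoseResult], tumor_organ: str = "tumor") -> dict[str, float]:
    """dose(tumor) / dose(organ) at matching injected activity.

    A zero normal-organ dose is reported as ``inf`` with a warning rather than
    raising; the ratio for the tumor itself is 1.
    """
    by_injected: dict[float, dict[str, float]] = {}
    for r in table:
        by_injected.setdefault(r.injected_bq, {})[r.organ] = r.total_dose_gy
    out: dict[str, float] = {}
    for injected, doses in by_injected.items():
        if tumor_organ not in doses:
            raise ValueError(f"tumor organ {tumor_organ!r} absent from dose table")
        tumor = doses[tumor_organ]
        for organ, dose in doses.items():
            if dose == 0.0:
                warnings.warn(f"organ {organ!r} has zero dose; ratio reported as inf", stacklevel=2)
                out[organ] = math.inf
            else:
                out[organ] = tumor / dose
    return out
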