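"""Radioactive decay chains: data model, Bateman solutions, and decay bookkeeping.

The administered radionuclides in this toolkit are a simple beta emitter
(¹⁷⁷Lu, stable daughter) and ²²⁵Ac, whose decay proceeds through a short-lived
series (²²¹Fr → ²¹⁷At → ²¹³Bi → {²¹³Po | ²⁰⁹Tl} → ²⁰⁹Pb → ²⁰⁹Bi stable).
Because every ²²⁵Ac daughter has a half-life of hours or less against a ~10 d
parent, the chain reaches secular equilibrium quickly and each parent decay is
eventually matched by (branching-weighted) daughter decays deposited locally.

Decay data are read from a versioned YAML file (see ``data/nuclides.yaml`` for
the schema); the file, not the code, is the source of truth for half-lives,
branching fractions and mean energies per decay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "DecayDataError",
    "Nuclide",
    "DecayChain",
    "load_chain",
    "validate_nuclide_records",
    "bateman_activities",
    "activity_coefficients",
    "equilibrium_ratios",
    "cumulated_decays_per_parent_decay",
    "DEFAULT_NUCLIDE_DATA",
]

#: Particle classes tracked for energy bookkeeping.
PARTICLE_CLASSES = ("alpha", "electron", "photon")

#: Relative closeness of two decay constants below which the Bateman product
#: form is treated as degenerate and perturbed (see `_regularized_lambdas`).
DEGENERACY_TOL = 1e-12
DEGENERACY_PERTURBATION = 1e-9

_BRANCHING_SUM_TOL = 1e-9

DEFAULT_NUCLIDE_DATA = "packaged"


class DecayDataError(ValueError):
    """Invalid or inconsistent nuclide data."""


@dataclass(frozen=True)
class Nuclide:
    """Physical decay data for one nuclide.

    ``half_life_s`` is ``math.inf`` for a stable nuclide. ``branches`` maps
    daughter names to branching fractions; a stable nuclide has none.
    ``energy_MeV`` gives mean energy emitted per decay by particle class.
    """

    name: str
    half_life_s: float
    branches: tuple[tuple[str, float], ...]
    energy_MeV: Mapping[str, float]

    @property
    def stable(self) -> bool:
        return math.isinf(self.half_life_s)

    @property
    def decay_constant(self) -> float:
        """λ = ln2 / T½ in 1/s (0 for stable)."""
        if self.stable:
            return 0.0
        return math.log(2.0) / self.half_life_s

    def total_energy_MeV(self) -> float:
        return sum(self.energy_MeV[c] for c in PARTICLE_CLASSES)

    def validate(self) -> None:
        if self.stable:
            if self.branches:
                raise DecayDataError(f"{self.name}: stable nuclide must have no branches")
            if self.total_energy_MeV() != 0.0:
                raise DecayDataError(f"{self.name}: stable nuclide must have zero energies")
            return
        if not self.half_life_s > 0:
            raise DecayDataError(f"{self.name}: half-life must be > 0, got {self.half_life_s}")
        if not self.branches:
            raise DecayDataError(f"{self.name}: radioactive nuclide must list daughters")
        total = sum(f for _, f in self.branches)
        if abs(total - 1.0) > _BRANCHING_SUM_TOL:
            raise DecayDataError(
                f"{self.name}: branching fractions sum to {total!r}, expected 1 ± {_BRANCHING_SUM_TOL}"
            )
        for daughter, frac in self.branches:
            if not 0.0 <= frac <= 1.0:
                raise DecayDataError(f"{self.name}→{daughter}: branching fraction {frac} outside [0, 1]")
        for cls in PARTICLE_CLASSES:
            if self.energy_MeV.get(cls, 0.0) < 0.0:
                raise DecayDataError(f"{self.name}: negative {cls} energy")


@dataclass(frozen=True)
class DecayChain:
    """A decay series rooted at the administered radionuclide.

    ``nuclides`` is ordered root-first; every non-stable member's daughters are
    also members. The graph is a DAG with exactly one root.
    """

    root: str
    nuclides: tuple[Nuclide, ...]
    data_version: str = "unversioned"
    _by_name: dict[str, Nuclide] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_by_name", {n.name: n for n in self.nuclides})

    def __getitem__(self, name: str) -> Nuclide:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def parent(self) -> Nuclide:
        return self._by_name[self.root]

    @property
    def radioactive_members(self) -> tuple[Nuclide, ...]:
        return tuple(n for n in self.nuclides if not n.stable)

    def paths_to(self, name: str) -> list[list[Nuclide]]:
        """All decay paths root → ``name`` (a branched chain may have several)."""
        if name not in self._by_name:
            raise DecayDataError(f"unknown nuclide {name!r} in chain rooted at {self.root}")
        out: list[list[Nuclide]] = []

        def walk(path: list[Nuclide]):
            node = path[-1]
            if node.name == name:
                out.append(list(path))
                return
            for daughter, frac in node.branches:
                if frac > 0.0:
                    walk(path + [self._by_name[daughter]])

        walk([self.parent])
        return out

    def energy_per_parent_decay_MeV(self) -> dict[str, float]:
        """Mean MeV deposited per parent decay by particle class, summed over
        the whole chain at equilibrium (local deposition)."""
        n_decays = cumulated_decays_per_parent_decay(self, mode="equilibrium")
        totals = {cls: 0.0 for cls in PARTICLE_CLASSES}
        for nuc in self.radioactive_members:
            for cls in PARTICLE_CLASSES:
                totals[cls] += n_decays[nuc.name] * nuc.energy_MeV[cls]
        return totals


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def _read_records(data_path) -> tuple[str, list[dict]]:
    if data_path == DEFAULT_NUCLIDE_DATA:
        text = resources.files("rptdose.data").joinpath("nuclides.yaml").read_text()
    else:
        text = Path(data_path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "nuclides" not in doc:
        raise DecayDataError("nuclide data file must be a mapping with a 'nuclides' list")
    return str(doc.get("data_version", "unversioned")), doc["nuclides"]


def validate_nuclide_records(records: Iterable[dict]) -> dict[str, Nuclide]:
    """Validate raw records against the schema and invariants.

    Raises :class:`DecayDataError` naming the offending record. Returns a
    name → :class:`Nuclide` map.
    """
    out: dict[str, Nuclide] = {}
    for rec in records:
        name = rec.get("name")
        if not name:
            raise DecayDataError(f"record without a name: {rec!r}")
        if name in out:
            raise DecayDataError(f"duplicate nuclide record {name!r}")
        hl = rec.get("half_life_s")
        half_life = math.inf if hl is None else float(hl)
        branches = tuple(
            (b["daughter"], float(b["fraction"]))
            for b in rec.get("branches", [])
            if b["daughter"] != "STABLE"
        )
        energies = {cls: float(rec.get("energy_MeV", {}).get(cls, 0.0)) for cls in PARTICLE_CLASSES}
        nuc = Nuclide(name=name, half_life_s=half_life, branches=branches, energy_MeV=energies)
        nuc.validate()
        out[name] = nuc
    return out


def load_chain(root_name: str, data_path=DEFAULT_NUCLIDE_DATA) -> DecayChain:
    """Load the full decay chain reachable from ``root_name``.

    ``data_path`` is a nuclide-data YAML file, or ``"packaged"`` for the data
    shipped with the package. Raises :class:`DecayDataError` for an unknown
    nuclide, a daughter missing from the file, cyclic data, or records that
    fail validation.
    """
    version, records = _read_records(data_path)
    table = validate_nuclide_records(records)
    if root_name not in table:
        raise DecayDataError(f"unknown nuclide {root_name!r} in data file (version {version})")

    ordered: list[Nuclide] = []
    seen: set[str] = set()
    in_progress: set[str] = set()

    def visit(name: str):
        if name in in_progress:
            raise DecayDataError(f"cyclic decay data involving {name!r}")
        if name in seen:
            return
        if name not in table:
            raise DecayDataError(f"daughter {name!r} missing from data file")
        in_progress.add(name)
        nuc = table[name]
        ordered.append(nuc)
        seen.add(name)
        for daughter, _ in nuc.branches:
            visit(daughter)
        in_progress.discard(name)

    visit(root_name)
    return DecayChain(root=root_name, nuclides=tuple(ordered), data_version=version)


# ---------------------------------------------------------------------------
# Bateman solution with branching
# ---------------------------------------------------------------------------

def _regularized_lambdas(lambdas: list[float]) -> list[float]:
    """Perturb near-equal decay constants to avoid the removable singularity
    in the Bateman product form.

    Pairs with relative difference < ``DEGENERACY_TOL`` are split by
    ``DEGENERACY_PERTURBATION`` relative — far below any physical uncertainty —
    with a warning.
    """
    out = list(lambdas)
    for i in range(len(out)):
        for j in range(i):
            if abs(out[i] - out[j]) < DEGENERACY_TOL * abs(out[j]):
                warnings.warn(
                    "near-degenerate decay constants perturbed by "
                    f"{DEGENERACY_PERTURBATION:g} relative",
                    stacklevel=3,
                )
                out[i] = out[j] * (1.0 + DEGENERACY_PERTURBATION * (j + 1))
    return out


def _activity_terms(chain: DecayChain) -> dict[str, list[tuple]]:
    """Exponential-sum terms ``(c_k, λ_k)`` per radioactive member, computed
    in extended (long double) precision.

    The Bateman product form suffers catastrophic cancellation for chains
    whose decay constants span many orders of magnitude (the ²²⁵Ac series
    spans ~10¹¹) at times where a late member's activity is still tiny;
    80-bit intermediates keep the summed activity accurate to ~1e-8 relative.
    """
    ld = np.longdouble
    ln2 = np.log(ld(2.0))
    lam_root = ln2 / ld(chain.parent.half_life_s)
    coeffs: dict[str, list[tuple]] = {}
    for nuc in chain.radioactive_members:
        terms: list[tuple] = []
        for path in chain.paths_to(nuc.name):
            lambdas = _regularized_lambdas([ln2 / ld(p.half_life_s) for p in path])
            branch_product = ld(1.0)
            for a, b in zip(path[:-1], path[1:]):
                branch_product *= ld(dict(a.branches)[b.name])
            n = len(lambdas)
            # A_n = λ_n N_n; N_1(0) = A_0/λ_1 with A_0 = 1
            prefactor = branch_product * (lambdas[-1] / lam_root)
            for lam in lambdas[:-1]:
                prefactor *= lam
            for i in range(n):
                denom = ld(1.0)
                for j in range(n):
                    if j != i:
                        denom *= lambdas[j] - lambdas[i]
                # a single-member path has coefficient exactly 1
                terms.append((prefactor / denom if n > 1 else ld(1.0), lambdas[i]))
        coeffs[nuc.name] = terms
    return coeffs


def activity_coefficients(chain: DecayChain) -> dict[str, list[tuple[float, float]]]:
    """Exponential-sum representation of chain activities.

    Returns, for each radioactive member ``n``, coefficient pairs
    ``(c_k, λ_k)`` such that per unit parent activity at t=0 (pure parent),

        A_n(t) = Σ_k c_k · exp(−λ_k · t).

    Branch points are handled by summing the classic Bateman solution over all
    root→n decay paths, each weighted by its product of branching fractions.
    """
    return {
        name: [(float(c), float(lam)) for c, lam in terms]
        for name, terms in _activity_terms(chain).items()
    }


def bateman_activities(chain: DecayChain, parent_activity_0: float, t: float) -> dict[str, float]:
    """Analytic chain activities (Bq) at time ``t`` (s) for a pure parent at t=0.

    Generalizes the Bateman solution to branched chains; the alternating-sign
    exponential sums are evaluated in extended precision (see
    :func:`_activity_terms`). Activities are clamped at 0 against residual
    rounding; the parent follows ``parent_activity_0 · 2^(−t/T½)`` exactly.
    """
    if t < 0:
        raise ValueError(f"t must be ≥ 0, got {t}")
    t_ld = np.longdouble(t)
    out: dict[str, float] = {}
    for name, terms in _activity_terms(chain).items():
        a = sum(c * np.exp(-lam * t_ld) for c, lam in terms)
        out[name] = max(float(a), 0.0) * parent_activity_0
    return out


def equilibrium_ratios(chain: DecayChain) -> dict[str, float]:
    """Activity ratio of each chain member to the parent at secular equilibrium.

    Requires every daughter half-life to be shorter than the parent's. The
    exact asymptotic ratio for a daughter d along one path is
    ``Π branching × Π_{i≠root} λ_i/(λ_i − λ_root)`` (summed over paths); the
    λ-correction is negligible when T½(daughter) ≪ T½(parent).
    """
    lam_root = chain.parent.decay_constant
    out = {chain.root: 1.0}
    for nuc in chain.radioactive_members:
        if nuc.name == chain.root:
            continue
        if nuc.half_life_s >= chain.parent.half_life_s:
            raise DecayDataError(
                f"no secular equilibrium: {nuc.name} half-life ≥ parent {chain.root}"
            )
        ratio = 0.0
        for path in chain.paths_to(nuc.name):
            branch_product = 1.0
            for a, b in zip(path[:-1], path[1:]):
                branch_product *= dict(a.branches)[b.name]
            corr = 1.0
            for member in path[1:]:
                lam = member.decay_constant
                corr *= lam / (lam - lam_root)
            ratio += branch_product * corr
        out[nuc.name] = ratio
    return out


def cumulated_decays_per_parent_decay(chain: DecayChain, mode: str = "equilibrium") -> dict[str, float]:
    """Number of decays of each chain member per decay of the parent.

    With daughters deposited locally (no redistribution), each parent decay is
    eventually matched by the branching-weighted number of decays of every
    descendant. ``mode="equilibrium"`` returns the branching products directly;
    ``mode="bateman"`` integrates the Bateman activities over [0, ∞) — the two
    agree to numerical precision and the agreement is a consistency check.
    """
    if mode == "equilibrium":
        out = {}
        for nuc in chain.radioactive_members:
            out[nuc.name] = sum(
                math.prod(dict(a.branches)[b.name] for a, b in zip(p[:-1], p[1:]))
                for p in chain.paths_to(nuc.name)
            )
        return out
    if mode == "bateman":
        lam_root = chain.parent.decay_constant
        # ∫A_n dt = Σ c_k/λ_k per unit parent activity; parent decays = 1/λ_root.
        return {
            name: sum(c / lam for c, lam in terms) * lam_root
            for name, terms in activity_coefficients(chain).items()
        }
    raise ValueError(f"unknown mode {mode!r}; expected 'equilibrium' or 'bateman'")
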