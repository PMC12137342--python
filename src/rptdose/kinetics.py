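"""Time–activity curves and time-integrated activity (residence time per gram).

The integration convention follows the study method: trapezoids between the
sampled time points, an optional rise segment from injection to the first
sample, and an analytic tail beyond the last sample that assumes pure
physical decay of the administered parent (no further biological clearance).

The integrand is the *physical* activity concentration per unit injected
activity — %IA/g values (which are decay-corrected) are multiplied back by
2^(−t/T½) in :func:`build_tac`, so the tail model and the samples describe
the same physically decaying quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biodist_io import BiodistStudy, BiodistValidationError
from .nuclide_chain import Nuclide

__all__ = [
    "TimeActivityCurve",
    "TimeIntegratedActivity",
    "build_tac",
    "trapezoid_tia",
    "analytic_tia_exponential",
]

RISE_MODELS = ("zero_at_injection", "flat")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Physical activity concentration per unit injected activity over time.

    ``conc`` is fraction of injected activity per gram (%IA/g ÷ 100, decayed
    back to physical activity); ``times_s`` strictly increasing.
    """

    organ: str
    times_s: np.ndarray
    conc: np.ndarray
    n_animals: np.ndarray
    animal_id: str | None = None

    def __post_init__(self):
        t, c = np.asarray(self.times_s, float), np.asarray(self.conc, float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.organ}: times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError(f"{self.organ}: negative concentration")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "conc", c)


@dataclass(frozen=True)
class TimeIntegratedActivity:
    """∫ conc dt in s·(fraction IA per gram) and the tail's share of it."""

    organ: str
    tia: float
    tail_fraction: float
    conventions: dict | None = None

    def __post_init__(self):
        if self.tia < 0 or not 0.0 <= self.tail_fraction <= 1.0:
            raise ValueError("tia must be ≥ 0 and tail_fraction in [0, 1]")


def build_tac(
    study: BiodistStudy,
    organ: str,
    nuclide: Nuclide,
    aggregation: str = "mean",
) -> TimeActivityCurve | list[TimeActivityCurve]:
    """Per-organ time–activity curve(s) from a study.

    ``aggregation="mean"`` averages %IA/g across animals at each time point
    (the group design of n per time point); ``"per_animal"`` returns one curve
    per animal. Decay-corrected %IA/g is converted to physical concentration:
    conc(t) = (%IA/g / 100) × 2^(−t/T½).
    """
    rows = study.for_organ(organ)
    if not rows:
        raise BiodistValidationError(f"organ {organ!r} not present in study")

    def curve(measurements, animal_id=None):
        by_time: dict[float, list[float]] = {}
        for m in measurements:
            by_time.setdefault(m.time_h, []).append(m.pct_ia_per_g)
        if len(by_time) < 2:
            raise BiodistValidationError(
                f"organ {organ!r}: {len(by_time)} time point(s), need ≥ 2 for integration"
            )
        times_h = np.array(sorted(by_time), float)
        pct = np.array([float(np.mean(by_time[t])) for t in times_h])
        n = np.array([len(by_time[t]) for t in times_h])
        times_s = times_h * 3600.0
        conc = pct / 100.0 * 2.0 ** (-times_s / nuclide.half_life_s)
        return TimeActivityCurve(organ=organ, times_s=times_s, conc=conc, n_animals=n, animal_id=animal_id)

    if aggregation == "mean":
        return curve(rows)
    if aggregation == "per_animal":
        by_animal: dict[str, list] = {}
        for m in rows:
            by_animal.setdefault(m.animal_id, []).append(m)
        return [curve(ms, animal_id=a) for a, ms in sorted(by_animal.items())]
    raise ValueError(f"unknown aggregation {aggregation!r}")


def trapezoid_tia(
    tac: TimeActivityCurve,
    lambda_tail: float,
    rise_model: str = "zero_at_injection",
) -> TimeIntegratedActivity:
    """Trapezoidal time-integrated activity with an analytic physical tail.

    tia = rise segment + trapezoids over the samples + conc(t_last)/λ_tail.
    ``rise_model="zero_at_injection"`` runs linearly from (0, 0) to the first
    sample (an IV agent starts at zero tissue concentration); ``"flat"`` holds
    conc(t₁) back to t=0.
    """
    if not lambda_tail > 0:
        raise ValueError(f"lambda_tail must be > 0, got {lambda_tail}")
    if rise_model not in RISE_MODELS:
        raise ValueError(f"unknown rise_model {rise_model!r}; expected one of {RISE_MODELS}")

    t, c = tac.times_s, tac.conc
    t0, c0 = t[0], c[0]
    if t0 > 0:
        rise = 0.5 * t0 * c0 if rise_model == "zero_at_injection" else t0 * c0
    else:
        rise = 0.0
    body = float(np.trapezoid(c, t))
    tail = c[-1] / lambda_tail
    tia = rise + body + tail
    return TimeIntegratedActivity(
        organ=tac.organ,
        tia=tia,
        tail_fraction=tail / tia if tia > 0 else 0.0,
        conventions={"rise_model": rise_model, "lambda_tail_per_s": lambda_tail},
    )


def analytic_tia_exponential(c0: float, lam: float) -> float:
    """Closed-form ∫₀^∞ c0·e^(−λt) dt = c0/λ (oracle for the trapezoid path)."""
    if not lam > 0:
        raise ValueError(f"λ must be > 0, got {lam}")
    return c0 / lam
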