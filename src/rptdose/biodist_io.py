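"""Ex vivo biodistribution studies: %IA/g bookkeeping and study I/O.

A biodistribution study is one row per animal × organ × time point carrying
the percent injected activity per gram (%IA/g, decay-corrected to injection
time) and the excised organ mass. Files are plain CSV (comma, UTF-8, dot
decimal, header required) with times in hours; internally everything is SI
(seconds, Bq, grams for tissue masses).

Also provided: the decay-correction and %IA/g primitives, the
secular-equilibrium counting-wait model for ²²⁵Ac samples (tissues are held
so the counted daughter, ²¹³Bi, grows into equilibrium before gamma
counting), and the caliper ellipsoid tumor-volume formula.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .nuclide_chain import DecayChain, Nuclide, bateman_activities, equilibrium_ratios

__all__ = [
    "BiodistValidationError",
    "BiodistMeasurement",
    "BiodistStudy",
    "read_biodist_csv",
    "write_biodist_csv",
    "decay_correct",
    "percent_ia_per_g",
    "equilibrium_fraction",
    "ellipsoid_volume",
    "KNOWN_ORGANS",
]

#: Controlled organ vocabulary (extensible via allow_new_organs).
KNOWN_ORGANS = frozenset(
    {
        "tumor", "liver", "spleen", "kidneys", "lungs", "blood", "heart",
        "bone", "muscle", "skin", "stomach", "intestine", "pancreas",
        "brain", "bladder", "testes", "tail",
    }
)

_CSV_COLUMNS = ["animal_id", "organ", "time_h", "pct_ia_per_g", "organ_mass_g"]
_OPTIONAL_COLUMNS = ["body_mass_g"]


class BiodistValidationError(ValueError):
    """A study or file violating the biodistribution-data contract."""


@dataclass(frozen=True)
class BiodistMeasurement:
    animal_id: str
    organ: str
    time_h: float
    pct_ia_per_g: float
    organ_mass_g: float
    body_mass_g: float | None = None

    def validate(self, allow_new_organs: bool = False) -> None:
        if self.time_h < 0:
            raise BiodistValidationError(f"{self.animal_id}/{self.organ}: negative time {self.time_h}")
        if self.pct_ia_per_g < 0:
            raise BiodistValidationError(
                f"{self.animal_id}/{self.organ}: negative %IA/g {self.pct_ia_per_g}"
            )
        if not self.organ_mass_g > 0:
            raise BiodistValidationError(
                f"{self.animal_id}/{self.organ}: organ mass must be > 0, got {self.organ_mass_g}"
            )
        if self.body_mass_g is not None and not self.body_mass_g > 0:
            raise BiodistValidationError(f"{self.animal_id}: body mass must be > 0")
        if not allow_new_organs and self.organ not in KNOWN_ORGANS:
            raise BiodistValidationError(f"unknown organ {self.organ!r} (pass allow_new_organs to accept)")


@dataclass
class BiodistStudy:
    """A single-radionuclide biodistribution study with design metadata."""

    radionuclide: str
    measurements: list[BiodistMeasurement]
    tumor_model: str = "other"
    specific_activity_ug_per_MBq: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def timepoints_h(self) -> list[float]:
        return sorted({m.time_h for m in self.measurements})

    @property
    def organs(self) -> list[str]:
        return sorted({m.organ for m in self.measurements})

    def for_organ(self, organ: str) -> list[BiodistMeasurement]:
        return [m for m in self.measurements if m.organ == organ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "animal_id": m.animal_id,
                    "organ": m.organ,
                    "time_h": m.time_h,
                    "pct_ia_per_g": m.pct_ia_per_g,
                    "organ_mass_g": m.organ_mass_g,
                    "body_mass_g": m.body_mass_g,
                }
                for m in self.measurements
            ]
        )

    def validate(self, allow_new_organs: bool = False, require_dosimetry_design: bool = False) -> None:
        for m in self.measurements:
            m.validate(allow_new_organs=allow_new_organs)
        if require_dosimetry_design:
            for organ in self.organs:
                pts = {m.time_h for m in self.for_organ(organ)}
                if len(pts) < 2:
                    raise BiodistValidationError(
                        f"organ {organ!r} has {len(pts)} time point(s); dosimetry needs ≥ 2"
                    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_biodist_csv(path, allow_new_organs: bool = False) -> BiodistStudy:
    """Read a biodistribution CSV (with ``# key: value`` header comments as
    study metadata) into a validated :class:`BiodistStudy`.

    Unparseable or invalid rows are rejected with their line number.
    """
    text = Path(path).read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    line_numbers: list[int] = []
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        if line.strip():
            data_lines.append(line)
            line_numbers.append(i)

    if not data_lines:
        raise BiodistValidationError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO("\n".join(data_lines)))
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise BiodistValidationError(f"{path}: missing columns {missing}")

    measurements = []
    for idx, row in df.iterrows():
        lineno = line_numbers[idx + 1] if idx + 1 < len(line_numbers) else line_numbers[-1]
        try:
            body = row.get("body_mass_g")
            m = BiodistMeasurement(
                animal_id=str(row["animal_id"]),
                organ=str(row["organ"]),
                time_h=float(row["time_h"]),
                pct_ia_per_g=float(row["pct_ia_per_g"]),
                organ_mass_g=float(row["organ_mass_g"]),
                body_mass_g=None if body is None or pd.isna(body) else float(body),
            )
            m.validate(allow_new_organs=allow_new_organs)
        except (ValueError, TypeError) as exc:
            raise BiodistValidationError(f"{path}:{lineno}: {exc}") from exc
        measurements.append(m)

    sa = meta.get("specific_activity_ug_per_MBq")
    return BiodistStudy(
        radionuclide=meta.get("radionuclide", "unknown"),
        tumor_model=meta.get("tumor_model", "other"),
        specific_activity_ug_per_MBq=float(sa) if sa else None,
        measurements=measurements,
        metadata={k: v for k, v in meta.items() if k not in ("radionuclide", "tumor_model")},
    )


def write_biodist_csv(study: BiodistStudy, path) -> None:
    """Write a study with a provenance header (round-trips losslessly)."""
    lines = [
        f"# radionuclide: {study.radionuclide}",
        f"# tumor_model: {study.tumor_model}",
    ]
    if study.specific_activity_ug_per_MBq is not None:
        lines.append(f"# specific_activity_ug_per_MBq: {study.specific_activity_ug_per_MBq!r}")
    for key, value in study.metadata.items():
        lines.append(f"# {key}: {value}")
    buf = io.StringIO()
    df = study.to_frame()
    if df["body_mass_g"].isna().all():
        df = df.drop(columns=["body_mass_g"])
    df.to_csv(buf, index=False, float_format="%.12g")
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Activity bookkeeping primitives
# ---------------------------------------------------------------------------

def decay_correct(measured_activity: float, elapsed_s: float, nuclide: Nuclide) -> float:
    """Correct a measured activity back to the reference (injection) time.

    Inverse of physical decay: ``measured × 2^(elapsed/T½)``.
    """
    if elapsed_s < 0:
        raise ValueError(f"elapsed must be ≥ 0, got {elapsed_s}")
    return measured_activity * 2.0 ** (elapsed_s / nuclide.half_life_s)


def percent_ia_per_g(decay_corrected_activity: float, injected_activity: float, mass_g: float) -> float:
    """%IA/g = 100 × activity / (injected activity × mass)."""
    if not injected_activity > 0:
        raise ValueError(f"injected activity must be > 0, got {injected_activity}")
    if not mass_g > 0:
        raise ValueError(f"mass must be > 0, got {mass_g}")
    return 100.0 * decay_corrected_activity / (injected_activity * mass_g)


def equilibrium_fraction(chain: DecayChain, counted_daughter: str, wait_s: float) -> float:
    """Fraction of secular-equilibrium activity a counted daughter has reached
    after a post-excision wait (pure parent at excision).

    For ²²⁵Ac samples counted via ²¹³Bi photons, this quantifies the overnight
    equilibration the counting protocol relies on; → 1 as the wait grows.
    """
    if counted_daughter not in chain:
        raise BiodistValidationError(f"{counted_daughter!r} not in chain rooted at {chain.root}")
    if counted_daughter == chain.root:
        return 1.0
    ratios = equilibrium_ratios(chain)
    acts = bateman_activities(chain, 1.0, wait_s)
    parent_now = acts[chain.root]
    return acts[counted_daughter] / (ratios[counted_daughter] * parent_now)


def ellipsoid_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Caliper tumor volume, (π/6)·L·W·H in mm³.

    This is the standard ellipsoid convention; the common spheroid shortcut
    ½·L·W² is deliberately not the default (reports record which was used).
    """
    for v in (length_mm, width_mm, height_mm):
        if not v > 0:
            raise ValueError(f"all dimensions must be > 0, got {(length_mm, width_mm, height_mm)}")
    return math.pi / 6.0 * length_mm * width_mm * height_mm
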