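"""Force-curve records and the plain-text file dialect used to exchange them.

One indentation measurement is a :class:`ForceCurve`: the sampled piezo
height and cantilever deflection (or pre-calibrated force) of one
approach/retract cycle, plus the calibration and protocol metadata needed
to analyse it. Curves are stored one per file in a UTF-8 text dialect:

* header lines ``# key: value`` carrying calibration and setpoints
  (``spring_constant_N_per_m``, ``bead_radius_um``, ``setpoint_force_nN``,
  ``setpoint_speed_um_per_s``, ``sample_rate_Hz``, ``position_x_um``,
  ``position_y_um``, ``postmortem_h``, ``temperature_C``,
  ``extend_end_index``, optional ``sensitivity_m_per_V`` and
  ``force_calibrated``),
* a tab-separated table ``time_s  height_m  deflection_m`` (the third
  column is ``force_N`` when ``force_calibrated: true``).

A directory of such files plus a manifest CSV (``x_um, y_um, curve_file,
label``) describes one elasticity map. All in-memory series are SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Cantilever",
    "ForceCurve",
    "ParseError",
    "read_force_curve",
    "write_force_curve",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["x_um", "y_um", "curve_file", "label"]
VALID_LABELS = {"gray", "white", "excluded"}


class ParseError(ValueError):
    """Raised when a curve file or manifest does not match the dialect."""


@dataclass(frozen=True)
class Cantilever:
    """AFM cantilever calibration: spring constant ``k_c`` (N/m), optical
    lever sensitivity (m/V) and a free-text identifier.

    ``k_c`` converts deflection to force (F = k_c * d) and is distinct from
    the tissue stiffness k reported by the slope fit.
    """

    spring_constant: float
    sensitivity: Optional[float] = None
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError(
                f"cantilever spring constant must be positive, got {self.spring_constant}"
            )


@dataclass
class ForceCurve:
    """One raw force-distance record in SI units.

    ``height`` is the piezo z position, increasing toward the sample during
    the extend segment. Either ``deflection`` (m) or, for pre-calibrated
    records, ``force`` (N) is present; :func:`elastimap.processing.calibrate`
    attaches the missing force series.
    """

    time: np.ndarray
    height: np.ndarray
    deflection: Optional[np.ndarray]
    extend_end: int
    cantilever: Optional[Cantilever] = None
    bead_radius: float = math.nan
    force: Optional[np.ndarray] = None
    position: tuple[float, float] = (math.nan, math.nan)
    setpoint_force: float = math.nan
    setpoint_speed: float = math.nan
    sample_rate: float = math.nan
    postmortem_h: float = math.nan
    temperature_C: float = math.nan
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.height)
        if len(self.time) != n:
            raise ValueError("time and height series must have equal length")
        if self.deflection is not None and len(self.deflection) != n:
            raise ValueError("deflection series length mismatch")
        if self.force is not None and len(self.force) != n:
            raise ValueError("force series length mismatch")
        if not (2 <= self.extend_end <= n):
            raise ValueError(
                f"extend segment must contain >= 2 samples within the record "
                f"(extend_end={self.extend_end}, n={n})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.height)

    @property
    def n_extend(self) -> int:
        return self.extend_end

    @property
    def is_calibrated(self) -> bool:
        return self.force is not None

    def extend(self) -> "ForceCurve":
        """View of the extend segment only (arrays sliced, metadata shared)."""
        sl = slice(0, self.extend_end)
        return replace(
            self,
            time=self.time[sl],
            height=self.height[sl],
            deflection=None if self.deflection is None else self.deflection[sl],
            force=None if self.force is None else self.force[sl],
            extend_end=self.extend_end,
        )


_REQUIRED_KEYS = (
    "spring_constant_N_per_m",
    "bead_radius_um",
    "setpoint_force_nN",
    "setpoint_speed_um_per_s",
    "sample_rate_Hz",
    "extend_end_index",
)


def _parse_header(lines: list[str], path: Path) -> dict:
    header: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        body = line[1:].strip()
        if not body:
            continue
        if ":" not in body:
            raise ParseError(f"{path}:{lineno}: malformed header line {line!r}")
        key, _, value = body.partition(":")
        header[key.strip()] = value.strip()
    return header


def read_force_curve(path, dialect: str = "elastimap") -> ForceCurve:
    """Read one curve file in the documented text dialect.

    Raises :class:`ParseError` naming the offending field or line when the
    file does not conform (missing spring constant, bad column count, ...).
    """
    if dialect != "elastimap":
        raise ParseError(f"unknown force-curve dialect {dialect!r}")
    path = Path(path)
    header_lines: list[str] = []
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                header_lines.append(stripped)
            else:
                data_lines.append(stripped)
    header = _parse_header(header_lines, path)
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise ParseError(f"{path}: missing required header field {key!r}")

    def as_float(key: str, default: float = math.nan) -> float:
        if key not in header:
            return default
        try:
            return float(header[key])
        except ValueError as exc:
            raise ParseError(f"{path}: header field {key!r} is not numeric: "
                             f"{header[key]!r}") from exc

    calibrated = header.get("force_calibrated", "false").lower() == "true"
    try:
        table = np.array(
            [[float(v) for v in row.split("\t")] for row in data_lines], dtype=float
        )
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value in data table: {exc}") from exc
    if table.ndim != 2 or table.shape[1] != 3:
        raise ParseError(
            f"{path}: expected 3 tab-separated columns "
            f"(time_s, height_m, {'force_N' if calibrated else 'deflection_m'})"
        )

    cantilever = Cantilever(
        spring_constant=as_float("spring_constant_N_per_m"),
        sensitivity=(as_float("sensitivity_m_per_V")
                     if "sensitivity_m_per_V" in header else None),
        identifier=header.get("cantilever_id", ""),
    )
    truth = {
        key[len("truth_"):]: as_float(key)
        for key in header
        if key.startswith("truth_")
    }
    return ForceCurve(
        time=table[:, 0],
        height=table[:, 1],
        deflection=None if calibrated else table[:, 2],
        force=table[:, 2] if calibrated else None,
        extend_end=int(as_float("extend_end_index")),
        cantilever=cantilever,
        bead_radius=as_float("bead_radius_um") * 1e-6,
        position=(as_float("position_x_um") * 1e-6, as_float("position_y_um") * 1e-6),
        setpoint_force=as_float("setpoint_force_nN") * 1e-9,
        setpoint_speed=as_float("setpoint_speed_um_per_s") * 1e-6,
        sample_rate=as_float("sample_rate_Hz"),
        postmortem_h=as_float("postmortem_h"),
        temperature_C=as_float("temperature_C"),
        ground_truth=truth,
    )


def write_force_curve(curve: ForceCurve, path) -> None:
    """Write ``curve`` in the text dialect; inverse of :func:`read_force_curve`."""
    path = Path(path)
    if curve.cantilever is None:
        raise ValueError("cannot write a curve without cantilever calibration")
    lines = [
        f"# spring_constant_N_per_m: {float(curve.cantilever.spring_constant)!r}",
        f"# bead_radius_um: {float(curve.bead_radius * 1e6)!r}",
        f"# setpoint_force_nN: {float(curve.setpoint_force * 1e9)!r}",
        f"# setpoint_speed_um_per_s: {float(curve.setpoint_speed * 1e6)!r}",
        f"# sample_rate_Hz: {float(curve.sample_rate)!r}",
        f"# extend_end_index: {curve.extend_end}",
        f"# position_x_um: {float(curve.position[0] * 1e6)!r}",
        f"# position_y_um: {float(curve.position[1] * 1e6)!r}",
        f"# postmortem_h: {float(curve.postmortem_h)!r}",
        f"# temperature_C: {float(curve.temperature_C)!r}",
    ]
    if curve.cantilever.sensitivity is not None:
        lines.append(f"# sensitivity_m_per_V: {float(curve.cantilever.sensitivity)!r}")
    if curve.cantilever.identifier:
        lines.append(f"# cantilever_id: {curve.cantilever.identifier}")
    calibrated = curve.deflection is None
    lines.append(f"# force_calibrated: {'true' if calibrated else 'false'}")
    for key, value in sorted(curve.ground_truth.items()):
        lines.append(f"# truth_{key}: {float(value)!r}")
    third = curve.force if calibrated else curve.deflection
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        for t, z, v in zip(curve.time, curve.height, third):
            fh.write(f"{float(t)!r}\t{float(z)!r}\t{float(v)!r}\n")


def read_manifest(path) -> pd.DataFrame:
    """Read a map manifest CSV and validate its schema and labels."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    bad = set(df["label"].unique()) - VALID_LABELS
    if bad:
        raise ParseError(f"{path}: unknown compartment labels {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)
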