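"""Ground-truth tissue phantoms and simulated AFM force-distance curves.

The generator emulates the measurement physics of sphere-indentation AFM
on a two-compartment (gray/white matter) tissue section, so every
pipeline stage can be verified against a known truth without animal
data:

* a **phantom** is an outline polygon with interior gray-matter region(s);
  each compartment carries a :class:`ResponseModel` giving its true
  reduced modulus as a smooth function of measurement force, speed,
  postmortem time and temperature;
* a **curve** is synthesised by integrating the closed-loop ramp
  kinematics: the piezo advances at the setpoint speed, the cantilever
  deflects as ``d = F / k_c`` with F from the chosen elastic contact
  model at the current depth, and the ramp stops when F reaches the
  setpoint force; baseline tilt and Gaussian deflection noise are added
  afterwards;
* an **experiment** is a grid of such curves over a phantom for a
  protocol of setpoint forces, speeds, timepoints and temperatures, with
  the generating parameters recorded in a ground-truth table.

Determinism: a single integer seed governs an experiment through
hierarchical ``numpy`` seed sequences, so identical inputs give
byte-identical outputs and any subset is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Point, Polygon

from .contact import ElasticHalfSpace, Indenter, model_force, model_depth
from .io import Cantilever, ForceCurve, write_force_curve, write_manifest

__all__ = [
    "ResponseModel",
    "TissuePhantom",
    "NoiseModel",
    "Protocol",
    "SimulatedMap",
    "make_phantom",
    "true_modulus",
    "simulate_curve",
    "simulate_experiment",
    "REFERENCE_CONDITIONS",
]

#: the standard measurement protocol: 30 nN setpoint at 20 um/s, maps started
#: ~1.5 h postmortem near the dish-heater temperature.
REFERENCE_CONDITIONS = dict(force=30e-9, speed=20e-6, t_pm=1.5, temperature=32.5)

DEFAULT_CANTILEVER = Cantilever(spring_constant=0.09, identifier="tipless-soft")
STIFF_CANTILEVER = Cantilever(spring_constant=2.0, identifier="tipless-stiff")


@dataclass(frozen=True)
class ResponseModel:
    """True reduced modulus of one compartment as a function of conditions.

    ``K(F, s, t, T) = K_ref * f_Fs(F, s) * f_pm(t) * f_T(T)`` with

    * ``f_Fs = (1 + A_F (1 - exp(-F/F_c))) (1 + A_s (1 - exp(-s/s_c)))`` —
      a saturating strain/strain-rate stiffening: effects are strongest at
      the low end of the force and speed range and level off beyond the
      saturation constants;
    * ``f_pm`` — a plateau-decline-plateau postmortem decay, implemented as
      a logistic step from 1 down to the terminal fraction ``f_end``
      centred between the onset ``t_on`` and end ``t_off`` hours;
    * ``f_T = 1 + (rho/100)(T - 38)`` — linear temperature softening with
      relative slope ``rho`` (%/degC) anchored at 38 degC body temperature.

    ``K_ref`` is therefore the modulus at vanishing force and speed, zero
    postmortem time and 38 degC.
    """

    K_ref: float
    A_F: float = 1.0
    F_c: float = 200e-9
    A_s: float = 0.6
    s_c: float = 150e-6
    t_on: float = 3.0
    t_off: float = 6.0
    f_end: float = 2.0 / 3.0
    rho: float = -3.9
    T_anchor: float = 38.0

    def __post_init__(self) -> None:
        if self.K_ref <= 0:
            raise ValueError(f"base modulus must be positive, got {self.K_ref}")
        if not 0 < self.f_end <= 1:
            raise ValueError(f"terminal fraction must be in (0, 1], got {self.f_end}")
        if self.t_off <= self.t_on:
            raise ValueError("postmortem decay end must come after its onset")
        if self.A_F < 0 or self.A_s < 0 or self.F_c <= 0 or self.s_c <= 0:
            raise ValueError("stiffening amplitudes must be >= 0 and constants > 0")
        for T in (15.0, 40.0):
            if 1 + self.rho / 100.0 * (T - self.T_anchor) <= 0:
                raise ValueError(
                    f"temperature slope rho={self.rho} makes K non-positive at {T} degC"
                )

    def factor_force_speed(self, force: float, speed: float) -> float:
        fF = 1.0 + self.A_F * (1.0 - math.exp(-force / self.F_c))
        fs = 1.0 + self.A_s * (1.0 - math.exp(-speed / self.s_c))
        return fF * fs

    def factor_postmortem(self, t_pm: float) -> float:
        t_mid = 0.5 * (self.t_on + self.t_off)
        tau = (self.t_off - self.t_on) / 8.0
        sigma = 1.0 / (1.0 + math.exp((t_pm - t_mid) / tau))
        return self.f_end + (1.0 - self.f_end) * sigma

    def factor_temperature(self, temperature: float) -> float:
        return 1.0 + self.rho / 100.0 * (temperature - self.T_anchor)

    def modulus(self, force: float, speed: float, t_pm: float, temperature: float) -> float:
        return (self.K_ref * self.factor_force_speed(force, speed)
                * self.factor_postmortem(t_pm) * self.factor_temperature(temperature))


def _ellipse(cx: float, cy: float, rx: float, ry: float) -> Polygon:
    circle = Point(0.0, 0.0).buffer(1.0, quad_segs=64)
    return affinity.translate(affinity.scale(circle, rx, ry), cx, cy)


@dataclass
class TissuePhantom:
    """Two-compartment section phantom: white matter outside, gray inside."""

    outline: Polygon
    gray_regions: list[Polygon]
    gray: ResponseModel
    white: ResponseModel
    plane: str = "transverse"

    def __post_init__(self) -> None:
        for g in self.gray_regions:
            if not self.outline.contains(g):
                raise ValueError("gray region must lie strictly inside the outline")

    @property
    def K_g0(self) -> float:
        return self.gray.K_ref

    @property
    def K_w0(self) -> float:
        return self.white.K_ref

    def compartment(self, position: tuple[float, float]) -> str:
        p = Point(*position)
        if not self.outline.covers(p):
            raise ValueError(f"position {position} lies outside the phantom outline")
        return "gray" if any(g.covers(p) for g in self.gray_regions) else "white"

    def scaled(self, gray_factor: float, white_factor: Optional[float] = None) -> "TissuePhantom":
        """Phantom with base moduli multiplied by per-compartment factors
        (animal-to-animal variability; compartments vary independently)."""
        if white_factor is None:
            white_factor = gray_factor
        return replace(
            self,
            gray=replace(self.gray, K_ref=self.gray.K_ref * gray_factor),
            white=replace(self.white, K_ref=self.white.K_ref * white_factor),
        )


# Preset geometry (m) and per-compartment responses. White matter stiffens
# more with force and speed than gray matter (A_F, A_s gray < white), which
# is what drives the gray-to-white ratio down the force/speed axes; in the
# transverse plane white matter barely responds to speed. Longitudinal
# (horizontal/sagittal) white matter is stiffer at baseline, pulling the
# ratio toward 1.
_PRESETS: dict[str, dict] = {
    "transverse": dict(
        outline=(0.0, 0.0, 1.7e-3, 1.2e-3),
        gray=(0.0, 0.0, 0.9e-3, 0.55e-3),
        K_g0=200.0, K_w0=65.0,
        gray_kwargs=dict(A_F=1.0, F_c=200e-9, A_s=0.6, s_c=150e-6,
                         t_on=3.0, t_off=6.0, f_end=2.0 / 3.0, rho=-3.9),
        white_kwargs=dict(A_F=3.0, F_c=300e-9, A_s=0.1, s_c=200e-6,
                          t_on=0.0, t_off=6.0, f_end=0.5, rho=-3.7),
    ),
    "horizontal": dict(
        outline=(0.0, 0.0, 2.4e-3, 1.0e-3),
        gray=(0.0, 0.0, 1.4e-3, 0.45e-3),
        K_g0=200.0, K_w0=90.0,
        gray_kwargs=dict(A_F=1.0, F_c=200e-9, A_s=0.6, s_c=150e-6,
                         t_on=3.0, t_off=6.0, f_end=2.0 / 3.0, rho=-3.9),
        white_kwargs=dict(A_F=3.0, F_c=300e-9, A_s=1.5, s_c=200e-6,
                          t_on=0.0, t_off=6.0, f_end=0.5, rho=-3.7),
    ),
    "sagittal": dict(
        outline=(0.0, 0.0, 2.4e-3, 1.0e-3),
        gray=(0.0, -0.1e-3, 1.5e-3, 0.35e-3),
        K_g0=200.0, K_w0=95.0,
        gray_kwargs=dict(A_F=1.0, F_c=200e-9, A_s=0.6, s_c=150e-6,
                         t_on=3.0, t_off=6.0, f_end=2.0 / 3.0, rho=-3.9),
        white_kwargs=dict(A_F=3.0, F_c=300e-9, A_s=1.5, s_c=200e-6,
                          t_on=0.0, t_off=6.0, f_end=0.5, rho=-3.7),
    ),
}


def make_phantom(preset: str = "transverse", **overrides) -> TissuePhantom:
    """Deterministic phantom for one anatomical plane.

    ``overrides`` may replace the base moduli (``K_g0``, ``K_w0``) or any
    :class:`ResponseModel` parameter per compartment via ``gray=dict(...)``
    / ``white=dict(...)``. Invalid values raise at construction.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown phantom preset {preset!r}; "
                         f"expected one of {sorted(_PRESETS)}")
    cfg = _PRESETS[preset]
    gray_kwargs = dict(cfg["gray_kwargs"], K_ref=overrides.pop("K_g0", cfg["K_g0"]))
    white_kwargs = dict(cfg["white_kwargs"], K_ref=overrides.pop("K_w0", cfg["K_w0"]))
    gray_kwargs.update(overrides.pop("gray", {}))
    white_kwargs.update(overrides.pop("white", {}))
    if overrides:
        raise ValueError(f"unknown phantom overrides {sorted(overrides)}")
    return TissuePhantom(
        outline=_ellipse(*cfg["outline"]),
        gray_regions=[_ellipse(*cfg["gray"])],
        gray=ResponseModel(**gray_kwargs),
        white=ResponseModel(**white_kwargs),
        plane=preset,
    )


def true_modulus(
    phantom: TissuePhantom,
    position: tuple[float, float],
    force: float = REFERENCE_CONDITIONS["force"],
    speed: float = REFERENCE_CONDITIONS["speed"],
    t_pm: float = REFERENCE_CONDITIONS["t_pm"],
    temperature: float = REFERENCE_CONDITIONS["temperature"],
) -> float:
    """Ground-truth K (Pa) at a map position under the given conditions."""
    compartment = phantom.compartment(position)
    model = phantom.gray if compartment == "gray" else phantom.white
    return model.modulus(force, speed, t_pm, temperature)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections added to a simulated deflection trace.

    ``noise_fraction`` sets the Gaussian deflection noise SD as a fraction
    of the setpoint-force-equivalent deflection (``deflection_sd`` in m
    overrides it); baseline offset (N) and tilt (N/m) are drawn uniformly
    from +/- their ranges, emulating photodiode offset and optical-path
    drift along the ramp.
    """

    noise_fraction: float = 0.01
    deflection_sd: Optional[float] = None
    baseline_offset_range: float = 0.5e-9
    baseline_tilt_range: float = 1.0e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_fraction < 0 or (self.deflection_sd or 0) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.baseline_offset_range < 0 or self.baseline_tilt_range < 0:
            raise ValueError("baseline ranges must be non-negative")

    def sd_for(self, setpoint_force: float, spring_constant: float) -> float:
        if self.deflection_sd is not None:
            return self.deflection_sd
        return self.noise_fraction * setpoint_force / spring_constant


QUIET = NoiseModel(noise_fraction=0.0, baseline_offset_range=0.0,
                   baseline_tilt_range=0.0)


def simulate_curve(
    K_true: float,
    cantilever: Cantilever = DEFAULT_CANTILEVER,
    indenter: Indenter = Indenter(),
    setpoint_force: float = REFERENCE_CONDITIONS["force"],
    speed: float = REFERENCE_CONDITIONS["speed"],
    noise: NoiseModel = QUIET,
    model: str = "hertz",
    sample_rate: Optional[float] = None,
    approach_factor: float = 1.2,
    z_range: Optional[float] = None,
    min_extend_points: int = 2500,
    rng: Optional[np.random.Generator] = None,
    position: tuple[float, float] = (math.nan, math.nan),
    postmortem_h: float = math.nan,
    temperature_C: float = math.nan,
) -> ForceCurve:
    """Synthesise one closed-loop extend segment over a sample of modulus
    ``K_true``.

    The piezo advances at ``speed``; at piezo travel ``u`` past contact the
    quasi-static balance ``u = delta + F(delta)/k_c`` fixes the indentation
    and the deflection ``d = u - delta``. The ramp ends when F reaches the
    setpoint. The pre-contact approach is ``approach_factor`` times the
    contact travel, so roughly half the record is baseline. If ``z_range``
    (m) is too short to reach the setpoint the ramp is truncated — the
    resulting curve deliberately misses its force setpoint, for exercising
    QC exclusion. The generating truth (contact point, K, depth, duration)
    rides along in ``ForceCurve.ground_truth``.
    """
    if K_true <= 0 or setpoint_force <= 0 or speed <= 0:
        raise ValueError("physical parameters must be positive")
    k_c = cantilever.spring_constant
    half = ElasticHalfSpace(K_true)
    delta_max = float(model_depth(model, half, indenter, setpoint_force))
    d_max = setpoint_force / k_c
    contact_travel = delta_max + d_max
    approach = approach_factor * contact_travel
    total = approach + contact_travel
    truncated = z_range is not None and total > z_range
    if truncated:
        total = float(z_range)
    duration = total / speed
    if sample_rate is None:
        sample_rate = max(1000.0, min_extend_points / duration)
    n = max(min_extend_points if not truncated else 2, int(math.ceil(duration * sample_rate)))
    t = np.linspace(0.0, duration, n)
    z = speed * t
    z_c = approach

    # quasi-static inversion of u = delta + F(delta)/k_c on a dense table
    dgrid = np.linspace(0.0, delta_max * 1.0000001 + 1e-15, 20000)
    ugrid = dgrid + np.asarray(model_force(model, half, indenter, dgrid)) / k_c
    u = np.clip(z - z_c, 0.0, None)
    delta = np.interp(u, ugrid, dgrid)
    deflection = u - delta

    if rng is None:
        rng = np.random.default_rng(noise.seed)
    sd = noise.sd_for(setpoint_force, k_c)
    offset = rng.uniform(-noise.baseline_offset_range, noise.baseline_offset_range) \
        if noise.baseline_offset_range else 0.0
    tilt = rng.uniform(-noise.baseline_tilt_range, noise.baseline_tilt_range) \
        if noise.baseline_tilt_range else 0.0
    deflection = deflection + (offset + tilt * z) / k_c
    if sd > 0:
        deflection = deflection + rng.normal(0.0, sd, size=n)

    return ForceCurve(
        time=t,
        height=z,
        deflection=deflection,
        extend_end=n,
        cantilever=cantilever,
        bead_radius=indenter.radius,
        position=position,
        setpoint_force=setpoint_force,
        setpoint_speed=speed,
        sample_rate=sample_rate,
        postmortem_h=postmortem_h,
        temperature_C=temperature_C,
        ground_truth=dict(
            z_c=z_c,
            K=K_true,
            delta_max=delta_max if not truncated else float(delta[-1]),
            t_delta=contact_travel / speed if not truncated
            else (total - approach) / speed,
            baseline_offset=offset,
            baseline_tilt=tilt,
            truncated=float(truncated),
        ),
    )


@dataclass(frozen=True)
class Protocol:
    """One simulated acquisition protocol over a phantom."""

    grid_resolution: float = 300e-6
    setpoint_forces: tuple[float, ...] = (REFERENCE_CONDITIONS["force"],)
    speeds: tuple[float, ...] = (REFERENCE_CONDITIONS["speed"],)
    timepoints: tuple[float, ...] = (REFERENCE_CONDITIONS["t_pm"],)
    temperatures: tuple[float, ...] = (REFERENCE_CONDITIONS["temperature"],)
    seed: int = 0
    noise: NoiseModel = QUIET
    cantilever: Cantilever = DEFAULT_CANTILEVER
    indenter: Indenter = Indenter()
    model: str = "hertz"

    def conditions(self):
        for F in self.setpoint_forces:
            for s in self.speeds:
                for t_pm in self.timepoints:
                    for T in self.temperatures:
                        yield F, s, t_pm, T


@dataclass
class SimulatedMap:
    """All curves of one condition over one phantom grid, plus truth."""

    condition: dict
    curves: list[ForceCurve]
    manifest: pd.DataFrame
    truth: pd.DataFrame


def simulate_experiment(
    phantom: TissuePhantom,
    protocol: Protocol,
    out_dir: Optional[str] = None,
) -> list[SimulatedMap]:
    """Simulate every protocol condition over the phantom's measurement grid.

    Returns one :class:`SimulatedMap` per (force, speed, timepoint,
    temperature) condition. When ``out_dir`` is given, each condition is
    written to its own subdirectory as curve files in the text dialect plus
    ``manifest.csv``, with a combined ``ground_truth.csv`` at the top level.
    The protocol seed is spawned hierarchically: condition ``i``, curve
    ``j`` always receives the same random stream regardless of which subset
    is generated.
    """
    from .mapping import build_grid  # local import to avoid a cycle

    positions = build_grid(phantom.outline, protocol.grid_resolution)
    if len(positions) == 0:
        raise ValueError("protocol grid resolution yields no positions on the phantom")
    root = np.random.SeedSequence(protocol.seed)
    maps: list[SimulatedMap] = []
    truth_rows_all = []
    base = Path(out_dir) if out_dir is not None else None
    if base is not None:
        base.mkdir(parents=True, exist_ok=True)
    for ci, (F, s, t_pm, T) in enumerate(protocol.conditions()):
        cond_seq = np.random.SeedSequence(protocol.seed, spawn_key=(ci,))
        child_seqs = cond_seq.spawn(len(positions))
        curves, man_rows, truth_rows = [], [], []
        cond_tag = (f"F{F * 1e9:g}nN_s{s * 1e6:g}ums_t{t_pm:g}h_T{T:g}C")
        for j, (x, y) in enumerate(positions):
            label = phantom.compartment((x, y))
            K_true = true_modulus(phantom, (x, y), F, s, t_pm, T)
            curve = simulate_curve(
                K_true, cantilever=protocol.cantilever, indenter=protocol.indenter,
                setpoint_force=F, speed=s, noise=protocol.noise,
                model=protocol.model,
                rng=np.random.default_rng(child_seqs[j]),
                position=(x, y), postmortem_h=t_pm, temperature_C=T,
            )
            fname = f"{cond_tag}/curve_{j:04d}.txt"
            curves.append(curve)
            man_rows.append({"x_um": x * 1e6, "y_um": y * 1e6,
                             "curve_file": fname, "label": label})
            truth_rows.append({
                "x_um": x * 1e6, "y_um": y * 1e6, "compartment": label,
                "K_true_Pa": K_true, "setpoint_force_nN": F * 1e9,
                "setpoint_speed_um_per_s": s * 1e6, "postmortem_h": t_pm,
                "temperature_C": T, "seed": protocol.seed, "curve_file": fname,
            })
        manifest = pd.DataFrame(man_rows)
        truth = pd.DataFrame(truth_rows)
        condition = dict(setpoint_force=F, speed=s, t_pm=t_pm, temperature=T,
                         tag=cond_tag)
        maps.append(SimulatedMap(condition=condition, curves=curves,
                                 manifest=manifest, truth=truth))
        truth_rows_all.extend(truth_rows)
        if base is not None:
            cond_dir = base / cond_tag
            cond_dir.mkdir(exist_ok=True)
            for j, curve in enumerate(curves):
                write_force_curve(curve, cond_dir / f"curve_{j:04d}.txt")
            local = manifest.copy()
            local["curve_file"] = [Path(f).name for f in local["curve_file"]]
            write_manifest(local, cond_dir / "manifest.csv")
    if base is not None:
        pd.DataFrame(truth_rows_all).to_csv(base / "ground_truth.csv", index=False)
    return maps
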