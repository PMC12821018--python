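"""Per-curve analysis: from a raw force-distance record to a fitted modulus.

The stages mirror how one AFM indentation is analysed in practice:

1. **calibrate** — convert cantilever deflection to force, ``F = k_c d``.
2. **fit_baseline** — least-squares line over the pre-contact part of the
   extend segment (photodiode offset plus tilt/drift), subtracted before
   any contact fitting.
3. **find_contact_point** — grid search over candidate contact points on
   the sampled piezo heights; each candidate is scored by the per-point
   residual sum of squares of a least-squares Hertz/Sneddon fit to the
   samples beyond it, and the winner is refined by local parabolic
   interpolation of the RSS profile.
4. **compute_indentation** — AFM kinematics ``delta = (z - z_c) - (d - d_c)``:
   piezo travel past contact minus cantilever deflection past contact.
5. **fit_modulus** — closed-form least squares of ``F = K g(delta)`` (the
   contact models are linear in K) over all extend samples past contact,
   reporting the reduced apparent elastic modulus K (Pa) and whether the
   curve stayed in the Hertz-validity regime ``delta_max / R < 1/3``.
6. **fit_stiffness** — model-independent slope k (N/m) of force versus
   indentation over the 90-100% exerted-force window.
7. **qc_setpoints** — exclude curves whose achieved force or speed missed
   the commanded setpoint by more than 10% (default), or whose fit failed.

Failed fits are data, not exceptions: batch runs always complete and emit
one QC verdict per curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contact import (
    HERTZ_VALIDITY_RATIO,
    ElasticHalfSpace,
    Indenter,
    model_force,
    unit_force_shape,
)
from .io import Cantilever, ForceCurve, read_force_curve

__all__ = [
    "IndentationCurve",
    "FitResult",
    "StiffnessResult",
    "QCVerdict",
    "ContactNotFoundError",
    "InsufficientDataError",
    "calibrate",
    "fit_baseline",
    "find_contact_point",
    "compute_indentation",
    "fit_modulus",
    "fit_stiffness",
    "qc_setpoints",
    "process_curve",
    "process_batch",
    "BATCH_COLUMNS",
]

DEFAULT_QC_TOLERANCE = 0.10
DEFAULT_BASELINE_FRACTION = 0.5
DEFAULT_STIFFNESS_WINDOW = (0.90, 1.00)
MIN_FIT_POINTS = 20
MIN_BASELINE_POINTS = 10


class ContactNotFoundError(RuntimeError):
    """The RSS profile over candidate contact points has no interior minimum."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested fit window."""


@dataclass
class IndentationCurve:
    """Baseline-corrected force versus indentation for one extend segment.

    ``indentation`` covers every extend sample (negative before contact, kept
    for diagnostics); ``contact_mask`` marks the samples past contact that
    enter fits.
    """

    indentation: np.ndarray
    force: np.ndarray
    contact_point: float
    baseline: tuple[float, float] = (0.0, 0.0)

    @property
    def contact_mask(self) -> np.ndarray:
        return self.indentation > 0

    @property
    def delta_max(self) -> float:
        m = self.contact_mask
        return float(np.max(self.indentation[m])) if np.any(m) else 0.0


@dataclass
class FitResult:
    """Outcome of one contact-model fit (K in Pa); ``ok`` is False when the
    fit failed, in which case the failure travels into the QC verdict instead
    of raising."""

    K: float
    model: str
    contact_point: float
    delta_max: float
    delta_max_over_R: float
    residual_rms: float
    n_points_fit: int
    hertz_regime: bool
    ok: bool = True
    failure_reason: str = ""
    qc: Optional["QCVerdict"] = None

    @classmethod
    def failure(cls, model: str, reason: str, contact_point: float = np.nan) -> "FitResult":
        return cls(
            K=np.nan, model=model, contact_point=contact_point, delta_max=np.nan,
            delta_max_over_R=np.nan, residual_rms=np.nan, n_points_fit=0,
            hertz_regime=False, ok=False, failure_reason=reason,
        )


@dataclass
class StiffnessResult:
    """Model-independent stiffness k (N/m): slope of F versus delta over a
    fraction-of-maximum-force window (default 90-100%)."""

    k: float
    force_fraction_window: tuple[float, float]
    n_points: int


@dataclass
class QCVerdict:
    """Keep/exclude decision for one curve with machine-readable reasons."""

    keep: bool
    reasons: list[str] = field(default_factory=list)
    achieved_force: float = np.nan
    achieved_speed: float = np.nan

    def __post_init__(self) -> None:
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be true exactly when reasons is empty")


def calibrate(curve: ForceCurve, cantilever: Optional[Cantilever] = None) -> ForceCurve:
    """Attach the force series ``F = k_c d``; idempotent on calibrated curves."""
    if curve.force is not None and curve.deflection is None:
        if cantilever is not None and curve.cantilever is not None \
                and cantilever.spring_constant != curve.cantilever.spring_constant:
            raise ValueError(
                "curve is flagged pre-calibrated but a different cantilever was supplied"
            )
        return curve
    cant = cantilever or curve.cantilever
    if cant is None:
        raise ValueError("no cantilever calibration available for this curve")
    if curve.deflection is None:
        raise ValueError("curve has neither deflection nor force series")
    return replace(curve, force=cant.spring_constant * curve.deflection, cantilever=cant)


def fit_baseline(
    curve: ForceCurve,
    precontact_fraction: float = DEFAULT_BASELINE_FRACTION,
    z_limit: Optional[float] = None,
) -> tuple[float, float]:
    """Fit the pre-contact baseline line ``F_b(z) = offset + tilt * z``.

    The window is the first ``precontact_fraction`` of the extend segment by
    z span; when a provisional contact point is known, pass it as ``z_limit``
    so the fraction applies to the pre-contact span only.
    """
    if not 0 < precontact_fraction <= 0.9:
        raise ValueError("precontact_fraction must be in (0, 0.9]")
    if curve.force is None:
        raise ValueError("calibrate the curve before baseline fitting")
    z = curve.height[: curve.extend_end]
    F = curve.force[: curve.extend_end]
    z_end = z_limit if z_limit is not None else z[-1]
    cutoff = z[0] + precontact_fraction * (z_end - z[0])
    mask = z <= cutoff
    if np.count_nonzero(mask) < MIN_BASELINE_POINTS:
        raise InsufficientDataError(
            f"baseline window holds {np.count_nonzero(mask)} samples; "
            f"need >= {MIN_BASELINE_POINTS}"
        )
    tilt, offset = np.polyfit(z[mask], F[mask], 1)
    return float(offset), float(tilt)


def _subtract_baseline(curve: ForceCurve, baseline: tuple[float, float]) -> ForceCurve:
    offset, tilt = baseline
    return replace(curve, force=curve.force - (offset + tilt * curve.height))


def _candidate_rss(z, F, k_c, R, model, i, shape_fn):
    """Per-point RSS of the best K fit for contact at sample ``i``."""
    dz = z[i + 1:] - z[i]
    delta = dz - (F[i + 1:] - F[i]) / k_c
    mask = (delta > 0) & (delta < R)
    n = int(np.count_nonzero(mask))
    if n < MIN_FIT_POINTS:
        return np.inf, np.nan, n
    g = shape_fn(delta[mask])
    denom = float(g @ g)
    if denom <= 0:
        return np.inf, np.nan, n
    K = float(g @ F[i + 1:][mask]) / denom
    if not np.isfinite(K) or K <= 0:
        return np.inf, K, n
    resid = F[i + 1:][mask] - K * g
    return float(resid @ resid) / n, K, n


def find_contact_point(
    curve: ForceCurve,
    indenter: Indenter,
    model: str = "hertz",
    n_coarse: int = 200,
) -> tuple[float, "FitResult"]:
    """Locate the contact point by coarse-to-fine RSS grid search.

    Candidates are the sampled piezo heights of the (baseline-corrected)
    extend segment; the candidate minimising the per-point residual sum of
    squares of its least-squares contact fit wins, then a parabola through
    the RSS profile around the winner refines ``z_c`` below the sampling
    pitch. Returns the refined ``z_c`` and the fit at that contact point.

    Raises :class:`ContactNotFoundError` when no candidate yields a valid
    fit or the minimum sits on the edge of the candidate range (e.g. a
    never-contacting baseline sweep).
    """
    if curve.force is None:
        raise ValueError("calibrate (and baseline-correct) the curve first")
    z = curve.height[: curve.extend_end]
    F = curve.force[: curve.extend_end]
    if len(z) < 50:
        raise InsufficientDataError("need >= 50 extend samples for contact search")
    k_c = curve.cantilever.spring_constant if curve.cantilever else np.inf
    R = indenter.radius

    # one shape interpolant per curve; reused by every candidate
    span = float(z[-1] - z[0])
    probe = np.linspace(0, min(span, 0.999 * R), 8)[1:]
    shape_table = unit_force_shape(model, indenter, probe)

    def shape_fn(delta):
        if model == "hertz":
            return (4.0 / 3.0) * np.sqrt(R) * delta ** 1.5
        return np.interp(delta, probe, shape_table)

    if model == "sneddon":
        probe = np.linspace(0, min(span, 0.999 * R), 4096)
        shape_table = unit_force_shape(model, indenter, probe)

    last = len(z) - MIN_FIT_POINTS - 1
    if last < 1:
        raise InsufficientDataError("too few samples past any candidate contact point")
    stride = max(1, last // n_coarse)
    coarse = np.arange(0, last + 1, stride)
    rss = np.full(len(z), np.inf)
    for i in coarse:
        rss[i] = _candidate_rss(z, F, k_c, R, model, i, shape_fn)[0]
    finite = np.isfinite(rss[coarse])
    if not np.any(finite):
        raise ContactNotFoundError("no candidate contact point admits a positive-K fit")
    best = coarse[np.argmin(rss[coarse])]
    lo, hi = max(0, best - stride), min(last, best + stride)
    for i in range(lo, hi + 1):
        if not np.isfinite(rss[i]):
            rss[i] = _candidate_rss(z, F, k_c, R, model, i, shape_fn)[0]
    window = np.arange(lo, hi + 1)
    best = window[np.argmin(rss[window])]
    if best == 0 or best >= last:
        raise ContactNotFoundError(
            "RSS profile has no interior minimum over candidate contact points"
        )
    # local parabolic refinement of the RSS minimum between samples
    for j in (best - 1, best + 1):
        if not np.isfinite(rss[j]):
            rss[j] = _candidate_rss(z, F, k_c, R, model, j, shape_fn)[0]
    z_c = float(z[best])
    if np.isfinite(rss[best - 1]) and np.isfinite(rss[best + 1]):
        x0, x1, x2 = z[best - 1], z[best], z[best + 1]
        r0, r1, r2 = rss[best - 1], rss[best], rss[best + 1]
        num = (x1 - x0) ** 2 * (r1 - r2) - (x1 - x2) ** 2 * (r1 - r0)
        den = (x1 - x0) * (r1 - r2) - (x1 - x2) * (r1 - r0)
        if den != 0:
            vertex = x1 - 0.5 * num / den
            if x0 < vertex < x2:
                z_c = float(vertex)
    ind = compute_indentation(curve, z_c)
    fit = fit_modulus(ind, indenter, model)
    if fit.ok:
        # a genuine contact must rise well above the residual noise floor;
        # a never-contacting baseline sweep fits only noise
        predicted_peak = fit.K * float(
            unit_force_shape(model, indenter, np.array([fit.delta_max]))[0])
        if fit.residual_rms > 0 and predicted_peak < 5.0 * fit.residual_rms:
            raise ContactNotFoundError(
                "no contact signal: fitted force never exceeds the noise floor"
            )
    return z_c, fit


def compute_indentation(curve: ForceCurve, z_c: float) -> IndentationCurve:
    """Indentation kinematics ``delta = (z - z_c) - (d - d_c)``.

    ``d_c`` is the baseline-model deflection at contact — zero on a
    baseline-corrected curve — rather than the (noisy) sampled value, which
    keeps the single-sample noise at contact out of every depth.
    """
    if curve.force is None:
        raise ValueError("calibrate the curve before computing indentation")
    z = curve.height[: curve.extend_end]
    F = curve.force[: curve.extend_end]
    if not (z[0] <= z_c <= z[-1]):
        raise ValueError(
            f"contact point {z_c:.4g} m outside extend z range [{z[0]:.4g}, {z[-1]:.4g}]"
        )
    k_c = curve.cantilever.spring_constant if curve.cantilever else np.inf
    delta = (z - z_c) - F / k_c
    return IndentationCurve(indentation=delta, force=F, contact_point=z_c)


def fit_modulus(ind: IndentationCurve, indenter: Indenter, model: str = "hertz") -> FitResult:
    """Least-squares reduced modulus K over all samples past contact.

    The contact models are linear in K, so the fit is the closed form
    ``K = sum(g F) / sum(g^2)`` with ``g`` the unit-K force shape. A
    non-positive or singular estimate yields a failure verdict, not an
    exception.
    """
    mask = ind.contact_mask
    n = int(np.count_nonzero(mask))
    if n < MIN_FIT_POINTS:
        return FitResult.failure(model, "insufficient_points", ind.contact_point)
    delta = ind.indentation[mask]
    F = ind.force[mask]
    R = indenter.radius
    dmax = float(np.max(delta))
    if dmax >= R:
        return FitResult.failure(model, "indentation_exceeds_radius", ind.contact_point)
    g = unit_force_shape(model, indenter, delta)
    denom = float(g @ g)
    if denom <= 0:
        return FitResult.failure(model, "fit_failure", ind.contact_point)
    K = float(g @ F) / denom
    if not np.isfinite(K) or K <= 0:
        return FitResult.failure(model, "fit_failure", ind.contact_point)
    resid = F - K * g
    ratio = dmax / R
    if model == "hertz" and ratio >= HERTZ_VALIDITY_RATIO:
        warnings.warn(
            f"Hertz fit requested at delta_max/R = {ratio:.2f} >= 1/3; "
            "the sphere (Sneddon) model is more accurate at this depth",
            stacklevel=2,
        )
    return FitResult(
        K=K, model=model, contact_point=ind.contact_point, delta_max=dmax,
        delta_max_over_R=ratio, residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        n_points_fit=n, hertz_regime=bool(ratio < HERTZ_VALIDITY_RATIO),
    )


def fit_stiffness(
    ind: IndentationCurve,
    window: tuple[float, float] = DEFAULT_STIFFNESS_WINDOW,
) -> StiffnessResult:
    """Slope k of F versus delta over the ``window`` fraction of peak force."""
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"invalid force-fraction window {window}")
    mask = ind.contact_mask
    if not np.any(mask):
        raise InsufficientDataError("no samples past contact")
    F = ind.force[mask]
    delta = ind.indentation[mask]
    fmax = float(np.max(F))
    sel = (F >= lo * fmax) & (F <= hi * fmax)
    n = int(np.count_nonzero(sel))
    if n < 5:
        raise InsufficientDataError(
            f"stiffness window {window} holds {n} samples; need >= 5"
        )
    slope = float(np.polyfit(delta[sel], F[sel], 1)[0])
    return StiffnessResult(k=slope, force_fraction_window=window, n_points=n)


def _achieved_speed(curve: ForceCurve, z_c: Optional[float]) -> float:
    """Median dz/dt over the contact portion of the extend segment."""
    z = curve.height[: curve.extend_end]
    t = curve.time[: curve.extend_end]
    if z_c is not None and np.isfinite(z_c):
        sel = z > z_c
        if np.count_nonzero(sel) >= 3:
            z, t = z[sel], t[sel]
    dz = np.diff(z)
    dt = np.diff(t)
    good = dt > 0
    if not np.any(good):
        return np.nan
    return float(np.median(dz[good] / dt[good]))


def qc_setpoints(
    curve: ForceCurve,
    fit: FitResult,
    tolerance: float = DEFAULT_QC_TOLERANCE,
    corrected_force: Optional[np.ndarray] = None,
) -> QCVerdict:
    """Verdict on the 10% setpoint-deviation exclusion rule.

    ``keep`` is true only if the achieved maximum force and the achieved
    approach speed are both within ``tolerance`` (relative) of their
    setpoints and the modulus fit succeeded. Always returns a verdict.
    """
    F = corrected_force if corrected_force is not None else curve.force
    reasons: list[str] = []
    achieved_force = np.nan
    if F is not None:
        achieved_force = float(np.max(F[: curve.extend_end]))
    achieved_speed = _achieved_speed(curve, fit.contact_point if fit.ok else None)
    if not fit.ok:
        reasons.append("insufficient_points" if fit.failure_reason ==
                       "insufficient_points" else "fit_failure")
    if np.isfinite(curve.setpoint_force) and np.isfinite(achieved_force):
        if abs(achieved_force - curve.setpoint_force) > tolerance * curve.setpoint_force:
            reasons.append("force_deviation")
    if np.isfinite(curve.setpoint_speed) and np.isfinite(achieved_speed):
        if abs(achieved_speed - curve.setpoint_speed) > tolerance * curve.setpoint_speed:
            reasons.append("speed_deviation")
    return QCVerdict(
        keep=not reasons, reasons=reasons,
        achieved_force=achieved_force, achieved_speed=achieved_speed,
    )


def process_curve(
    curve: ForceCurve,
    model: str = "hertz",
    indenter: Optional[Indenter] = None,
    qc_tolerance: float = DEFAULT_QC_TOLERANCE,
    baseline_fraction: float = DEFAULT_BASELINE_FRACTION,
    stiffness_window: tuple[float, float] = DEFAULT_STIFFNESS_WINDOW,
) -> tuple[FitResult, Optional[StiffnessResult], QCVerdict]:
    """Full single-curve pipeline: calibrate, baseline, contact, fit, QC.

    The baseline is fitted twice: a first pass over the leading fraction of
    the whole extend span locates a provisional contact point, after which
    the baseline is refitted over the pre-contact span only and the contact
    search repeated once. Any stage failure is folded into the QC verdict.
    """
    if indenter is None:
        indenter = Indenter(curve.bead_radius) if np.isfinite(curve.bead_radius) else Indenter()
    try:
        cal = calibrate(curve)
    except ValueError:
        fit = FitResult.failure(model, "fit_failure")
        return fit, None, qc_setpoints(curve, fit, qc_tolerance)
    try:
        baseline = fit_baseline(cal, baseline_fraction)
        corrected = _subtract_baseline(cal, baseline)
        z_c, fit = find_contact_point(corrected, indenter, model)
        # second pass: refit the baseline strictly before the provisional contact
        try:
            baseline = fit_baseline(cal, baseline_fraction, z_limit=z_c)
            corrected = _subtract_baseline(cal, baseline)
            z_c, fit = find_contact_point(corrected, indenter, model)
        except InsufficientDataError:
            pass
        ind = compute_indentation(corrected, z_c)
        ind.baseline = baseline
        fit = fit_modulus(ind, indenter, model)
    except (ContactNotFoundError, InsufficientDataError, ValueError) as exc:
        reason = "insufficient_points" if isinstance(exc, InsufficientDataError) else "fit_failure"
        fit = FitResult.failure(model, reason)
        verdict = qc_setpoints(cal, fit, qc_tolerance)
        fit.qc = verdict
        return fit, None, verdict
    stiffness: Optional[StiffnessResult] = None
    if fit.ok:
        try:
            stiffness = fit_stiffness(ind, stiffness_window)
        except InsufficientDataError:
            stiffness = None
    verdict = qc_setpoints(cal, fit, qc_tolerance, corrected_force=corrected.force)
    fit.qc = verdict
    return fit, stiffness, verdict


BATCH_COLUMNS = [
    "curve_file", "x_um", "y_um", "K_Pa", "k_N_per_m", "z_c_um", "delta_max_um",
    "delta_max_over_R", "model", "residual_rms_N", "n_points_fit", "hertz_regime",
    "keep", "reasons", "achieved_force_nN", "achieved_speed_um_per_s",
    "setpoint_force_nN", "setpoint_speed_um_per_s", "postmortem_h", "temperature_C",
]


def process_batch(
    curves: Sequence[ForceCurve | str],
    model: str = "hertz",
    **kwargs,
) -> pd.DataFrame:
    """Process many curves (objects or file paths) into one result table.

    Every input yields exactly one row; failures appear as excluded rows with
    their QC reasons rather than aborting the batch.
    """
    rows = []
    for item in curves:
        name = ""
        if isinstance(item, (str,)) or hasattr(item, "__fspath__"):
            name = str(item)
            curve = read_force_curve(item)
        else:
            curve = item
        fit, stiff, verdict = process_curve(curve, model=model, **kwargs)
        rows.append({
            "curve_file": name,
            "x_um": curve.position[0] * 1e6,
            "y_um": curve.position[1] * 1e6,
            "K_Pa": fit.K,
            "k_N_per_m": stiff.k if stiff is not None else np.nan,
            "z_c_um": fit.contact_point * 1e6,
            "delta_max_um": fit.delta_max * 1e6,
            "delta_max_over_R": fit.delta_max_over_R,
            "model": fit.model,
            "residual_rms_N": fit.residual_rms,
            "n_points_fit": fit.n_points_fit,
            "hertz_regime": fit.hertz_regime,
            "keep": verdict.keep,
            "reasons": ";".join(verdict.reasons),
            "achieved_force_nN": verdict.achieved_force * 1e9,
            "achieved_speed_um_per_s": verdict.achieved_speed * 1e6,
            "setpoint_force_nN": curve.setpoint_force * 1e9,
            "setpoint_speed_um_per_s": curve.setpoint_speed * 1e6,
            "postmortem_h": curve.postmortem_h,
            "temperature_C": curve.temperature_C,
        })
    return pd.DataFrame(rows, columns=BATCH_COLUMNS)
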