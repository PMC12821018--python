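"""Spatial elasticity maps: compartment medians, ratios, and time binning.

A *map* is a grid of indentation measurements over one tissue section.
Each grid position carries a fitted reduced modulus K, a manual
compartment label (``gray`` / ``white`` / ``excluded``) and the QC verdict
of its curve. Repeated measurements at one position are averaged
(QC-passing ones only), per-map summaries report the median K of each
compartment and their ratio ``K_g / K_w`` (median gray over median
white), and postmortem time courses are binned into one-hour bins
starting at 1.5 h after death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .processing import FitResult

__all__ = [
    "ElasticityMap",
    "CompartmentSummary",
    "build_grid",
    "aggregate_repeats",
    "assemble_map",
    "summarize_map",
    "bin_timeseries",
    "compare_halves",
    "IncompleteDesignError",
    "SUMMARY_COLUMNS",
    "BINNED_COLUMNS",
]

ENTRY_COLUMNS = ["x_um", "y_um", "K_Pa", "label", "keep",
                 "postmortem_h", "temperature_C", "curve_file"]
SUMMARY_COLUMNS = [
    "median_K_gray_Pa", "median_K_white_Pa", "ratio_gw", "n_gray", "n_white",
    "median_postmortem_gray_h", "median_postmortem_white_h", "mean_postmortem_h",
    "median_temperature_gray_C", "median_temperature_white_C", "mean_temperature_C",
]
BINNED_COLUMNS = ["bin_start_h", "mean", "sd", "n", "underflow"]


class IncompleteDesignError(ValueError):
    """A paired or repeated-measures comparison is missing a required timepoint."""


@dataclass
class ElasticityMap:
    """One spatial elasticity map: per-position entries plus acquisition metadata.

    ``entries`` columns: x_um, y_um, K_Pa, label, keep, postmortem_h,
    temperature_C, curve_file. Summaries only ever use rows with
    ``keep == True`` and a gray/white label.
    """

    entries: pd.DataFrame
    setpoint_force: float = math.nan
    setpoint_speed: float = math.nan
    plane: str = "transverse"
    grid_resolution: float = math.nan

    def __post_init__(self) -> None:
        missing = [c for c in ("x_um", "y_um", "K_Pa", "label") if c not in self.entries]
        if missing:
            raise ValueError(f"map entries missing columns {missing}")
        for col, default in (("keep", True), ("postmortem_h", math.nan),
                             ("temperature_C", math.nan), ("curve_file", "")):
            if col not in self.entries:
                self.entries[col] = default

    def retained(self) -> pd.DataFrame:
        e = self.entries
        return e[e["keep"] & e["label"].isin(["gray", "white"]) & e["K_Pa"].notna()]


@dataclass
class CompartmentSummary:
    """Median K per compartment and the gray-to-white ratio for one map."""

    median_K_gray: float = math.nan
    median_K_white: float = math.nan
    ratio: float = math.nan
    n_gray: int = 0
    n_white: int = 0
    median_postmortem_gray: float = math.nan
    median_postmortem_white: float = math.nan
    mean_postmortem: float = math.nan
    median_temperature_gray: float = math.nan
    median_temperature_white: float = math.nan
    mean_temperature: float = math.nan

    def as_row(self) -> dict:
        return {
            "median_K_gray_Pa": self.median_K_gray,
            "median_K_white_Pa": self.median_K_white,
            "ratio_gw": self.ratio,
            "n_gray": self.n_gray,
            "n_white": self.n_white,
            "median_postmortem_gray_h": self.median_postmortem_gray,
            "median_postmortem_white_h": self.median_postmortem_white,
            "mean_postmortem_h": self.mean_postmortem,
            "median_temperature_gray_C": self.median_temperature_gray,
            "median_temperature_white_C": self.median_temperature_white,
            "mean_temperature_C": self.mean_temperature,
        }


def build_grid(outline, resolution: float) -> np.ndarray:
    """Regular square lattice of measurement positions clipped to ``outline``.

    Lattice points are the cell centres of a global grid of pitch
    ``resolution`` (coordinates ``(i + 1/2) * resolution``), retained when
    the polygon covers them — a point exactly on the outline counts as
    inside. Ordering is row-major with x as the fast axis. Returns an
    (n, 2) array of positions in the outline's units.
    """
    if resolution <= 0:
        raise ValueError("grid resolution must be positive")
    poly = outline if isinstance(outline, Polygon) else Polygon(outline)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("degenerate outline polygon")
    xmin, ymin, xmax, ymax = poly.bounds
    i0 = math.floor(xmin / resolution - 0.5)
    i1 = math.ceil(xmax / resolution - 0.5)
    j0 = math.floor(ymin / resolution - 0.5)
    j1 = math.ceil(ymax / resolution - 0.5)
    pts = []
    for j in range(j0, j1 + 1):
        y = (j + 0.5) * resolution
        for i in range(i0, i1 + 1):
            x = (i + 0.5) * resolution
            if poly.covers(Point(x, y)):
                pts.append((x, y))
    return np.array(pts, dtype=float).reshape(-1, 2)


def aggregate_repeats(results: Sequence[FitResult | float],
                      keep: Optional[Sequence[bool]] = None) -> float:
    """Arithmetic mean of K over QC-passing repeats at one position.

    Accepts :class:`FitResult` objects (their own QC verdicts apply) or raw
    K values paired with an explicit ``keep`` mask. Returns ``nan`` when no
    repeat passes QC.
    """
    values: list[float] = []
    for idx, r in enumerate(results):
        if isinstance(r, FitResult):
            ok = r.ok and (r.qc is None or r.qc.keep)
            val = r.K
        else:
            ok = True if keep is None else bool(keep[idx])
            val = float(r)
        if ok and np.isfinite(val):
            values.append(val)
    if not values:
        return math.nan
    return float(np.mean(values))


def assemble_map(
    results: pd.DataFrame,
    manifest: pd.DataFrame,
    on_missing: str = "raise",
    **metadata,
) -> ElasticityMap:
    """Join per-curve fit results with a compartment-label manifest.

    Positions are matched exactly on ``curve_file`` when present in both
    tables, otherwise on rounded (x_um, y_um) keys; unmatched manifest rows
    raise a keyed error listing the offending positions (``on_missing=
    'raise'``) or are dropped. Repeated measurements at one position are
    averaged over QC-passing rows.
    """
    res = results.copy()
    man = manifest.copy()
    use_file = "curve_file" in man and "curve_file" in res and res["curve_file"].astype(bool).all()
    if use_file:
        merged = man.merge(res.drop(columns=["x_um", "y_um"], errors="ignore"),
                           on="curve_file", how="left", suffixes=("", "_r"))
    else:
        for df in (res, man):
            df["_key"] = list(zip(df["x_um"].round(3), df["y_um"].round(3)))
        merged = man.merge(res.drop(columns=["x_um", "y_um"]), on="_key", how="left")
        merged = merged.drop(columns="_key")
    unmatched = merged["K_Pa"].isna() & ~merged["label"].eq("excluded")
    if unmatched.any() and on_missing == "raise":
        bad = merged.loc[unmatched, ["x_um", "y_um"]].values.tolist()
        raise KeyError(f"manifest positions with no fitted curve: {bad}")
    if "keep" not in merged:
        merged["keep"] = True
    merged["keep"] = [bool(v) if pd.notna(v) else False for v in merged["keep"]]
    for col, default in (("postmortem_h", math.nan), ("temperature_C", math.nan),
                         ("curve_file", "")):
        if col not in merged:
            merged[col] = default
    # average QC-passing repeats per position
    rows = []
    for (x, y, label), grp in merged.groupby(
            [merged["x_um"].round(3), merged["y_um"].round(3), "label"], sort=True):
        kept = grp[grp["keep"] & grp["K_Pa"].notna()]
        rows.append({
            "x_um": x, "y_um": y, "label": label,
            "K_Pa": float(kept["K_Pa"].mean()) if len(kept) else math.nan,
            "keep": bool(len(kept)),
            "postmortem_h": float(kept["postmortem_h"].median()) if len(kept) else math.nan,
            "temperature_C": float(kept["temperature_C"].median()) if len(kept) else math.nan,
            "curve_file": kept["curve_file"].iloc[0] if len(kept) and "curve_file" in kept else "",
        })
    entries = pd.DataFrame(rows, columns=ENTRY_COLUMNS)
    return ElasticityMap(entries=entries, **metadata)


def summarize_map(emap: ElasticityMap) -> CompartmentSummary:
    """Per-compartment medians, the K_g/K_w ratio, and paired timestamps.

    The ratio is median-gray over median-white (never a median of pointwise
    ratios) and is reported missing when either compartment is empty.
    Timestamps follow the same pairing: median postmortem time (and
    temperature) per compartment, plus the mean of the two medians for
    ratio records.
    """
    kept = emap.retained()
    if len(kept) == 0:
        raise ValueError("map has no retained entries")
    out = CompartmentSummary()
    for label in ("gray", "white"):
        sub = kept[kept["label"] == label]
        n = len(sub)
        med = float(sub["K_Pa"].median()) if n else math.nan
        t_med = float(sub["postmortem_h"].median()) if n else math.nan
        T_med = float(sub["temperature_C"].median()) if n else math.nan
        if label == "gray":
            out.median_K_gray, out.n_gray = med, n
            out.median_postmortem_gray, out.median_temperature_gray = t_med, T_med
        else:
            out.median_K_white, out.n_white = med, n
            out.median_postmortem_white, out.median_temperature_white = t_med, T_med
    if out.n_gray and out.n_white:
        out.ratio = out.median_K_gray / out.median_K_white

        def _mean_of_medians(a: float, b: float) -> float:
            finite = [v for v in (a, b) if math.isfinite(v)]
            return float(np.mean(finite)) if finite else math.nan

        out.mean_postmortem = _mean_of_medians(
            out.median_postmortem_gray, out.median_postmortem_white)
        out.mean_temperature = _mean_of_medians(
            out.median_temperature_gray, out.median_temperature_white)
    return out


def bin_timeseries(
    times: Iterable[float],
    values: Iterable[float],
    bin_start: float = 1.5,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Mean +/- SD of ``values`` in fixed-width time bins.

    Bins are ``[bin_start + i*w, bin_start + (i+1)*w)`` hours postmortem
    (defaults: one-hour bins from 1.5 h). Records earlier than ``bin_start``
    land in a flagged underflow bin rather than being dropped, so bin counts
    always sum to the number of inputs. SD uses the n-1 denominator and is
    reported only for n >= 2.
    """
    t = np.asarray(list(times), dtype=float)
    v = np.asarray(list(values), dtype=float)
    if len(t) != len(v):
        raise ValueError("times and values must have equal length")
    idx = np.floor((t - bin_start) / bin_width).astype(int)
    rows = []
    if np.any(idx < 0):
        sel = v[idx < 0]
        rows.append({
            "bin_start_h": -math.inf, "mean": float(np.mean(sel)),
            "sd": float(np.std(sel, ddof=1)) if len(sel) >= 2 else math.nan,
            "n": int(len(sel)), "underflow": True,
        })
    for i in range(0, int(idx.max(initial=-1)) + 1):
        sel = v[idx == i]
        if len(sel) == 0:
            continue
        rows.append({
            "bin_start_h": bin_start + i * bin_width, "mean": float(np.mean(sel)),
            "sd": float(np.std(sel, ddof=1)) if len(sel) >= 2 else math.nan,
            "n": int(len(sel)), "underflow": False,
        })
    return pd.DataFrame(rows, columns=BINNED_COLUMNS)


def _half_change(maps: Sequence[ElasticityMap]) -> dict:
    if len(maps) < 2:
        raise IncompleteDesignError(
            "each half needs at least a first and a last timepoint map"
        )
    summaries = [(summarize_map(m), m) for m in maps]
    summaries.sort(key=lambda sm: sm[0].mean_postmortem
                   if math.isfinite(sm[0].mean_postmortem)
                   else sm[0].median_postmortem_gray)
    first, last = summaries[0][0], summaries[-1][0]
    return {
        "gray": last.median_K_gray / first.median_K_gray,
        "white": last.median_K_white / first.median_K_white,
    }


def compare_halves(
    half_a: Sequence[ElasticityMap],
    half_b: Sequence[ElasticityMap],
) -> dict:
    """Measurement-effect control: compare K changes between section halves.

    One half of a section is remeasured repeatedly while the other is
    measured only first and last; if measuring itself softened the tissue,
    the remeasured half would decay faster. Returns each half's last/first
    relative change of median K per compartment and the between-half ratio
    of those changes (1 means no measurement effect).
    """
    a = _half_change(half_a)
    b = _half_change(half_b)
    return {
        "half_a": a,
        "half_b": b,
        "change_ratio": {c: a[c] / b[c] for c in ("gray", "white")},
    }


def summaries_to_frame(summaries: Sequence[CompartmentSummary]) -> pd.DataFrame:
    """Stack per-map summaries into the summary CSV schema."""
    return pd.DataFrame([s.as_row() for s in summaries], columns=SUMMARY_COLUMNS)
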