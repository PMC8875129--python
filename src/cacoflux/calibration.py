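"""Segmented linear calibration curves and bioanalytical QC statistics.

HPLC quantitation over a wide concentration span (three orders of
magnitude here) is usually handled with two linear standard curves, a
low-range and a high-range segment sharing a boundary standard. This
module fits those segments by ordinary least squares (optionally 1/x or
1/x^2 weighted), inverts them to back-calculate concentrations from
signals, and computes the standard method-validation statistics:
intra-day and inter-day precision (RSD, %) and accuracy (relative
recovery, %) at low/mid/high QC levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Segment",
    "CalibrationCurve",
    "BackCalc",
    "fit_calibration",
    "back_calculate",
    "qc_stats",
    "R_WARN_DEFAULT",
    "RSD_LIMIT_DEFAULT",
    "RECOVERY_BAND_DEFAULT",
]

#: Warn when a segment's correlation coefficient falls below this.
R_WARN_DEFAULT = 0.99
#: Advisory QC acceptance bands (report-only, data are never auto-rejected).
RSD_LIMIT_DEFAULT = 10.0
RECOVERY_BAND_DEFAULT = (85.0, 115.0)


@dataclass(frozen=True)
class Segment:
    """One linear segment: ``signal = slope * conc + intercept`` on [lo, hi]."""

    lo: float
    hi: float
    slope: float
    intercept: float
    r: float

    def signal(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def conc(self, signal: float) -> float:
        return (signal - self.intercept) / self.slope


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordered low-to-high linear segments for one analyte.

    ``lloq`` (lower limit of quantitation) is the lowest standard of the
    lowest segment. Segment ranges may share only their boundary point.
    """

    analyte: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.lo))
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("calibration curve needs at least one segment")
        for s in segs:
            if s.slope <= 0:
                raise ValueError("calibration slopes must be positive")
            if s.hi <= s.lo:
                raise ValueError("segment range must have hi > lo")
        for a, b in zip(segs, segs[1:]):
            if b.lo < a.hi:
                raise ValueError("segment ranges overlap beyond the shared boundary")

    @property
    def lloq(self) -> float:
        return self.segments[0].lo

    @property
    def range(self) -> tuple[float, float]:
        return self.segments[0].lo, self.segments[-1].hi


@dataclass(frozen=True)
class BackCalc:
    """Back-calculated concentration with quantitation flags.

    ``below_lloq`` marks values under the lower limit of quantitation
    (returned, not censored); ``non_quantifiable`` marks signals mapping
    to negative concentration; ``extrapolated`` marks signals falling in
    no segment's range (assigned to the nearest segment with a warning).
    """

    conc: float
    segment: int
    below_lloq: bool = False
    non_quantifiable: bool = False
    extrapolated: bool = False

    def __float__(self) -> float:
        return self.conc


def _ols_line(x: np.ndarray, y: np.ndarray, weighting: str | None):
    if weighting is None:
        fit = stats.linregress(x, y)
        return float(fit.slope), float(fit.intercept), float(fit.rvalue)
    if weighting == "1/x":
        w = 1.0 / x
    elif weighting in ("1/x2", "1/x^2", "1/x**2"):
        w = 1.0 / x ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r} (use None, '1/x' or '1/x2')")
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    r = float(np.corrcoef(x, y)[0, 1])  # unweighted r, the conventionally reported one
    return float(slope), float(intercept), r


def fit_calibration(standards, split_at: float | None = None, *,
                    analyte: str | None = None, weighting: str | None = None,
                    r_warn: float = R_WARN_DEFAULT) -> CalibrationCurve:
    """Fit a (possibly segmented) linear standard curve.

    Parameters
    ----------
    standards : DataFrame or pair of arrays
        Either a frame with columns ``nominal_conc_ug_per_ml`` and
        ``signal`` (optionally ``analyte``), or an ``(concs, signals)``
        pair.
    split_at : float, optional
        Boundary concentration between the low and high segments. The
        boundary standard is included in *both* segments. None fits a
        single line.
    weighting : {None, "1/x", "1/x2"}
        Least-squares weighting; default unweighted.
    r_warn : float
        Emit a warning for any segment with correlation coefficient
        below this (default 0.99); the fit is still returned.
    """
    if isinstance(standards, pd.DataFrame):
        if analyte is None:
            names = standards["analyte"].unique() if "analyte" in standards else []
            analyte = names[0] if len(names) == 1 else "analyte"
        x = standards["nominal_conc_ug_per_ml"].to_numpy(dtype=float)
        y = standards["signal"].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in standards)
        analyte = analyte or "analyte"
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be positive")

    if split_at is None:
        masks = [np.ones_like(x, dtype=bool)]
    else:
        masks = [x <= split_at, x >= split_at]
    segments = []
    for mask in masks:
        xs, ys = x[mask], y[mask]
        if xs.size < 3:
            raise ValueError("each calibration segment needs at least 3 standards")
        if np.ptp(xs) == 0:
            raise ValueError("zero concentration variance in a calibration segment")
        slope, intercept, r = _ols_line(xs, ys, weighting)
        if r < r_warn:
            warnings.warn(
                f"{analyte}: segment [{xs.min():g}, {xs.max():g}] r={r:.4f} < {r_warn}",
                stacklevel=2)
        segments.append(Segment(float(xs.min()), float(xs.max()),
                                slope, intercept, r))
    return CalibrationCurve(analyte=analyte, segments=tuple(segments))


def back_calculate(curve: CalibrationCurve, signal: float) -> BackCalc:
    """Invert the standard curve: signal -> concentration (ug/mL).

    The segment whose back-calculated value falls inside its own range
    is used (the lower segment wins on the shared boundary). Signals
    mapping below zero are flagged non-quantifiable; signals landing
    between or beyond segment ranges are assigned to the nearest segment
    and flagged extrapolated, with a warning. Values below the LLOQ are
    returned flagged, never censored.
    """
    if not math.isfinite(signal):
        raise ValueError("back_calculate: signal must be finite")
    cands = [(i, s.conc(signal)) for i, s in enumerate(curve.segments)]
    for i, c in cands:
        s = curve.segments[i]
        if s.lo <= c <= s.hi:
            return BackCalc(conc=c, segment=i, below_lloq=False)
    # no in-range segment: negative => non-quantifiable, else nearest segment
    if all(c < 0 for _, c in cands):
        i, c = cands[0]
        return BackCalc(conc=c, segment=i, below_lloq=True, non_quantifiable=True)
    # distance from the candidate value to the segment's own range
    def dist(item):
        i, c = item
        s = curve.segments[i]
        return max(s.lo - c, c - s.hi, 0.0)
    i, c = min(cands, key=dist)
    warnings.warn(
        f"{curve.analyte}: signal {signal:g} outside fitted ranges; "
        f"assigned to segment {i}", stacklevel=2)
    return BackCalc(conc=c, segment=i, below_lloq=c < curve.lloq,
                    extrapolated=True)


def qc_stats(qc_samples: pd.DataFrame, nominal: dict[str, float] | None = None,
             ) -> pd.DataFrame:
    """Precision and accuracy statistics from QC-sample measurements.

    Parameters
    ----------
    qc_samples : DataFrame
        Columns ``level`` (label or nominal value), ``measured`` (back-
        calculated concentration, ug/mL), optional ``day``; needs >= 2
        replicates per level per day for a within-day RSD.
    nominal : mapping, optional
        Level label -> nominal concentration. If omitted, ``level`` must
        itself be numeric and is used as the nominal.

    Returns
    -------
    DataFrame indexed by level with columns ``nominal``,
    ``intra_day_rsd`` (mean of within-day SD/mean, %), ``inter_day_rsd``
    (SD of daily means / mean of daily means, %), ``recovery``
    (grand mean measured / nominal * 100, %), and ``n``. RSDs that need
    more replicates or days than available are NaN (reported missing),
    never fabricated. Sample SDs use the n-1 denominator.
    """
    df = qc_samples.copy()
    if "day" not in df:
        df["day"] = 1
    if "measured" not in df or "level" not in df:
        raise ValueError("qc_samples needs 'level' and 'measured' columns")

    def rsd(x: np.ndarray) -> float:
        if x.size < 2:
            return float("nan")
        return float(np.std(x, ddof=1) / np.mean(x) * 100.0)

    rows = []
    for level, g in df.groupby("level", sort=True):
        if nominal is not None:
            nom = float(nominal[level])
        else:
            nom = float(level)
        meas = g["measured"].to_numpy(dtype=float)
        daily = [grp["measured"].to_numpy(dtype=float) for _, grp in g.groupby("day")]
        within = [rsd(d) for d in daily]
        intra = float(np.nanmean(within)) if not all(math.isnan(w) for w in within) else float("nan")
        day_means = np.array([np.mean(d) for d in daily])
        inter = rsd(day_means) if day_means.size >= 2 else float("nan")
        rows.append({"level": level, "nominal": nom, "n": meas.size,
                     "intra_day_rsd": intra, "inter_day_rsd": inter,
                     "recovery": float(np.mean(meas) / nom * 100.0)})
    return pd.DataFrame(rows).set_index("level")
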