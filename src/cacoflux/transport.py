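"""Core permeability math for bidirectional Transwell assays.

Implements the quantities a Caco-2 transport study reports:

* TEER, the transepithelial electrical resistance ``(R1 - R0) * A`` in
  ohm*cm^2, used as a monolayer-integrity check;
* the sampling-dilution-corrected cumulative transported amount
  ``dQ_n = C_n * VR + VS * sum_{i<n} C_i`` (micrograms), which adds back
  the drug mass removed in earlier receiver samples that were replaced
  with blank buffer;
* the transport rate ``v`` (ug/s), the least-squares slope of dQ versus
  time;
* the apparent permeability coefficient
  ``Papp = v / (A * C0)`` in cm/s;
* the efflux ratio ``ER = Papp(BL->AP) / Papp(AP->BL)`` and the
  ``ER > 1.5`` rule of thumb for transporter-mediated (active) efflux;
* per-condition group summaries (mean +/- SD Papp per direction, ER,
  mechanism label).

Concentrations are ug/mL, volumes mL, areas cm^2, input times minutes
(converted to seconds for rates), so Papp comes out in cm/s and is
conventionally reported as a multiple of 1e-6 cm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AP_TO_BL",
    "BL_TO_AP",
    "WellTimeSeries",
    "TransportResult",
    "TEERRecord",
    "GroupSummary",
    "teer",
    "teer_record",
    "cumulative_amounts",
    "transport_rate",
    "papp",
    "efflux_ratio",
    "classify_mechanism",
    "analyze_well",
    "summarize_group",
    "PASSIVE",
    "ACTIVE",
    "UNDETERMINED",
]

# Direction labels. AP->BL models intestinal absorption (apical donor),
# BL->AP models secretion/efflux (basolateral donor).
AP_TO_BL = "AP-BL"
BL_TO_AP = "BL-AP"
_DIRECTIONS = (AP_TO_BL, BL_TO_AP)

PASSIVE = "passive-consistent"
ACTIVE = "active-transport-likely"
UNDETERMINED = "undetermined"

#: Default efflux-ratio threshold above which transporter involvement is
#: suspected (strict inequality).
ER_THRESHOLD = 1.5

#: Advisory monolayer-integrity threshold, ohm*cm^2. Configurable; a TEER
#: below it flags a possibly leaky monolayer but never rejects data.
TEER_THRESHOLD = 300.0


def normalize_direction(direction: str) -> str:
    """Map common spellings of the two transport directions to canonical tags."""
    key = str(direction).strip().upper().replace("→", "-")
    key = key.replace("_", "-").replace(">", "-").replace("--", "-")
    key = "-".join(p for p in key.split("-") if p)
    if key in ("AP-BL", "A-B", "AB"):
        return AP_TO_BL
    if key in ("BL-AP", "B-A", "BA"):
        return BL_TO_AP
    raise ValueError(f"unrecognized transport direction: {direction!r}")


@dataclass
class WellTimeSeries:
    """Receiver-compartment concentration time course for one well.

    Parameters
    ----------
    well_id : str
        Unique well identifier.
    compound : str
        Analyte name.
    direction : str
        ``"AP-BL"`` or ``"BL-AP"`` (other spellings are normalized).
    c0 : float
        Initial donor concentration C0, ug/mL.
    vr : float
        Receiver volume VR, mL.
    vs : float
        Sample volume VS withdrawn (and replaced with blank buffer) at
        each time point, mL.
    area : float
        Membrane area A, cm^2.
    times : array-like
        Strictly increasing sampling times, minutes.
    concs : array-like
        Measured receiver concentrations C_n at each time, ug/mL.
        NaN marks a missing (non-quantifiable) measurement.
    condition : str, optional
        Experimental condition label used for grouping.
    """

    well_id: str
    compound: str
    direction: str
    c0: float
    vr: float
    vs: float
    area: float
    times: np.ndarray
    concs: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.direction = normalize_direction(self.direction)
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError(f"well {self.well_id}: times must be a non-empty 1-d array")
        if self.times.shape != self.concs.shape:
            raise ValueError(f"well {self.well_id}: times and concs length mismatch")
        if not np.all(np.diff(self.times) > 0) or self.times[0] <= 0:
            raise ValueError(f"well {self.well_id}: times must be strictly increasing and > 0")
        for name in ("c0", "vr", "vs", "area"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"well {self.well_id}: {name} must be positive and finite")
        if self.vs >= self.vr:
            raise ValueError(f"well {self.well_id}: sample volume vs must be < receiver volume vr")
        with np.errstate(invalid="ignore"):
            if np.any(self.concs < 0):
                raise ValueError(f"well {self.well_id}: negative concentrations")


@dataclass
class TransportResult:
    """Per-well analysis output: corrected dQ sequence, rate fit and Papp."""

    well: WellTimeSeries
    dq: np.ndarray                # corrected cumulative amount, ug, per time point
    rate: float                   # ug/s
    rate_r2: float
    papp: float                   # cm/s
    fit_window: tuple[float, float]  # minutes, inclusive

    @property
    def papp_e6(self) -> float:
        """Papp in the conventional 1e-6 cm/s reporting unit."""
        return self.papp * 1e6


@dataclass(frozen=True)
class TEERRecord:
    """One TEER measurement: ``teer = (r1 - r0) * area``.

    ``context`` records which reference resistance R0 means: a blank
    (cell-free) insert before the experiment, or the same well pre-dose
    during the experiment. ``flagged`` marks values at or below the
    integrity threshold (including negative values, which indicate
    monolayer failure); it is advisory only.
    """

    well_id: str
    r1: float
    r0: float
    area: float
    context: str = "pre-experiment"
    threshold: float = TEER_THRESHOLD

    @property
    def teer(self) -> float:
        return teer(self.r1, self.r0, self.area)

    @property
    def flagged(self) -> bool:
        return self.teer < self.threshold


@dataclass
class GroupSummary:
    """Per-condition summary mirroring a bidirectional-assay report row.

    Papp means/SDs are stored in cm/s; ``*_e6`` accessors give the
    1e-6 cm/s reporting scale. ``er`` is the ratio of direction means
    (the primary statistic); ``er_well_mean``/``er_well_sd`` summarize
    per-well paired ratios when replicate pairing was available.
    """

    condition: str
    n_ab: int
    n_ba: int
    papp_ab_mean: float
    papp_ab_sd: float
    papp_ba_mean: float
    papp_ba_sd: float
    er: float                       # NaN when the BL->AP arm is absent
    classification: str
    er_well_mean: float = float("nan")
    er_well_sd: float = float("nan")
    papp_ab: np.ndarray = field(default_factory=lambda: np.array([]))
    papp_ba: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def papp_ab_mean_e6(self) -> float:
        return self.papp_ab_mean * 1e6

    @property
    def papp_ba_mean_e6(self) -> float:
        return self.papp_ba_mean * 1e6


def teer(r1: float, r0: float, area: float) -> float:
    """Transepithelial electrical resistance, ohm*cm^2.

    ``(r1 - r0) * area`` where ``r1`` is the measured resistance of the
    cell-bearing insert and ``r0`` the reference (blank insert or
    pre-dose) resistance, both in ohms. A negative result is allowed
    (it signals monolayer failure) but callers should flag it; see
    :class:`TEERRecord`.
    """
    if not (math.isfinite(r1) and math.isfinite(r0) and math.isfinite(area)):
        raise ValueError("teer: non-finite input")
    if area <= 0:
        raise ValueError("teer: area must be positive")
    return (r1 - r0) * area


def teer_record(well_id: str, r1: float, r0: float, area: float,
                context: str = "pre-experiment",
                threshold: float = TEER_THRESHOLD) -> TEERRecord:
    """Build a :class:`TEERRecord`, validating inputs through :func:`teer`."""
    teer(r1, r0, area)  # validation side effect
    return TEERRecord(well_id, r1, r0, area, context, threshold)


def cumulative_amounts(series: WellTimeSeries) -> np.ndarray:
    """Dilution-corrected cumulative transported amount dQ_n, ug.

    Each receiver sample withdraws volume VS and is replaced with blank
    buffer, so later concentrations under-report the transported mass.
    The correction adds back the withdrawn masses:

        dQ_n = C_n * VR + VS * sum_{i=0}^{n-1} C_i,   C_0 := 0

    where the index runs over sampling events and C_0 is the receiver
    concentration at time zero (zero by definition).

    A missing (NaN) concentration makes that and every later dQ NaN,
    because the prefix sum is no longer known.
    """
    concs = series.concs
    prefix = np.concatenate(([0.0], np.cumsum(concs)[:-1]))
    dq = concs * series.vr + series.vs * prefix
    # NaN contaminates all later prefix sums: propagate explicitly so the
    # first NaN poisons the tail even though cumsum already does this.
    bad = np.isnan(concs)
    if bad.any():
        dq[bad.argmax():] = np.nan
    return dq


def transport_rate(dq: np.ndarray, times_min: np.ndarray,
                   window: tuple[float, float] | None = None) -> tuple[float, float]:
    """Least-squares transport rate v (ug/s) and r^2 of the fit.

    Fits an ordinary least-squares line (free intercept) to dQ versus
    time, with time converted from minutes to seconds. ``window`` is an
    inclusive ``(t_lo, t_hi)`` range in minutes restricting the points
    used; the default uses all points. The free intercept absorbs any
    initial lag phase.
    """
    dq = np.asarray(dq, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if window is not None:
        lo, hi = window
        keep = (t >= lo) & (t <= hi)
        dq, t = dq[keep], t[keep]
    keep = ~np.isnan(dq)
    dq, t = dq[keep], t[keep]
    if t.size < 2:
        raise ValueError("transport_rate: need at least 2 points in the fit window")
    if np.ptp(t) == 0:
        raise ValueError("transport_rate: zero time variance")
    t_sec = t * 60.0
    fit = stats.linregress(t_sec, dq)
    r2 = fit.rvalue ** 2 if np.ptp(dq) > 0 else 1.0  # exact fit on constant data
    return float(fit.slope), float(r2)


def papp(rate: float, area: float, c0: float) -> float:
    """Apparent permeability coefficient, cm/s: ``rate / (area * c0)``."""
    if area <= 0 or c0 <= 0:
        raise ValueError("papp: area and c0 must be positive")
    return rate / (area * c0)


def efflux_ratio(papp_bl_to_ap: float, papp_ap_to_bl: float) -> float:
    """Efflux ratio ``ER = Papp(BL->AP) / Papp(AP->BL)``.

    Returns NaN when the BL->AP arm is missing (NaN), mirroring reports
    that omit the secretory arm. Raises if the absorptive Papp is not
    positive, since the ratio is then meaningless.
    """
    if papp_ap_to_bl is None or not math.isfinite(papp_ap_to_bl) or papp_ap_to_bl <= 0:
        raise ValueError("efflux_ratio: Papp(AP->BL) must be positive and finite")
    if papp_bl_to_ap is None or math.isnan(papp_bl_to_ap):
        return float("nan")
    return papp_bl_to_ap / papp_ap_to_bl


def classify_mechanism(er: float | None, threshold: float = ER_THRESHOLD) -> str:
    """Label the transport mechanism from the efflux ratio.

    ``er > threshold`` (strictly) suggests transporter-mediated, active
    efflux; ``er <= threshold`` is consistent with passive diffusion;
    a missing ER is undetermined.
    """
    if er is None or (isinstance(er, float) and math.isnan(er)):
        return UNDETERMINED
    if er <= 0:
        raise ValueError("classify_mechanism: er must be positive or missing")
    return ACTIVE if er > threshold else PASSIVE


def analyze_well(series: WellTimeSeries,
                 window: tuple[float, float] | None = None) -> TransportResult:
    """Full per-well analysis: corrected dQ, rate fit, Papp."""
    dq = cumulative_amounts(series)
    rate, r2 = transport_rate(dq, series.times, window)
    p = papp(rate, series.area, series.c0)
    if window is None:
        window = (float(series.times[0]), float(series.times[-1]))
    return TransportResult(well=series, dq=dq, rate=rate, rate_r2=r2,
                           papp=p, fit_window=tuple(window))


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    # sample SD (n-1); SD undefined for a single well
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return m, s


def summarize_group(results: Iterable[TransportResult],
                    condition: str | None = None,
                    er_threshold: float = ER_THRESHOLD,
                    pairing: Sequence[tuple[str, str]] | None = None) -> GroupSummary:
    """Summarize one condition's wells into a report row.

    Computes per-direction mean +/- SD Papp, the ratio-of-means efflux
    ratio, and the mechanism label. ``pairing`` optionally lists
    ``(ap_bl_well_id, bl_ap_well_id)`` pairs; when given (or when both
    directions have equal well counts, in which case wells are paired in
    order), the mean +/- SD of per-well ER is reported alongside.

    The AP->BL (absorptive) arm is required; the BL->AP arm may be
    absent, in which case ER is NaN and the label is undetermined.
    """
    results = list(results)
    if not results:
        raise ValueError("summarize_group: no wells")
    if condition is None:
        labels = {r.well.condition for r in results if r.well.condition}
        condition = labels.pop() if len(labels) == 1 else "group"
    by_dir: dict[str, list[TransportResult]] = {AP_TO_BL: [], BL_TO_AP: []}
    for r in results:
        by_dir[r.well.direction].append(r)
    ab = by_dir[AP_TO_BL]
    ba = by_dir[BL_TO_AP]
    if not ab:
        raise ValueError(f"summarize_group[{condition}]: no AP->BL wells; summary invalid")
    papp_ab = np.array([r.papp for r in ab])
    papp_ba = np.array([r.papp for r in ba])
    ab_mean, ab_sd = _mean_sd(papp_ab)
    if ba:
        ba_mean, ba_sd = _mean_sd(papp_ba)
        er = efflux_ratio(ba_mean, ab_mean)
    else:
        ba_mean = ba_sd = er = float("nan")

    er_w_mean = er_w_sd = float("nan")
    pairs: list[tuple[TransportResult, TransportResult]] = []
    if pairing is not None:
        idx = {r.well.well_id: r for r in results}
        pairs = [(idx[a], idx[b]) for a, b in pairing]
    elif ba and len(ab) == len(ba):
        pairs = list(zip(ab, ba))
    if pairs:
        ratios = np.array([efflux_ratio(b.papp, a.papp) for a, b in pairs])
        er_w_mean, er_w_sd = _mean_sd(ratios)

    return GroupSummary(
        condition=condition, n_ab=len(ab), n_ba=len(ba),
        papp_ab_mean=ab_mean, papp_ab_sd=ab_sd,
        papp_ba_mean=ba_mean, papp_ba_sd=ba_sd,
        er=er, classification=classify_mechanism(er if not math.isnan(er) else None,
                                                 er_threshold),
        er_well_mean=er_w_mean, er_well_sd=er_w_sd,
        papp_ab=papp_ab, papp_ba=papp_ba,
    )
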