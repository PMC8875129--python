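"""Mechanistic simulation of bidirectional Transwell transport assays.

The model is a lumped two-compartment (donor/receiver) description of drug
movement across a cell monolayer. Net flux density from donor to receiver
(ug cm^-2 s^-1) is

    J = p_passive * (C_d - C_r) - s * (1 - inhibition) * vmax * C_d / (km + C_d)

where ``s = +1`` for AP->BL runs (apically directed efflux opposes
absorption) and ``s = -1`` for BL->AP runs (efflux adds to secretion).
The saturable Michaelis-Menten term stands in for P-gp/MRP2-type
transporters; ``inhibition`` scales it down, emulating co-incubation with
an efflux inhibitor such as verapamil or cyclosporin. An intracellular
compartment is deliberately omitted: only donor and receiver are observed
in the assay, and a third compartment would add unidentifiable parameters.

The measurement process is reproduced faithfully: at each scheduled time
the receiver is sampled (volume ``vs``), the measured concentration is the
pre-withdrawal receiver concentration perturbed by multiplicative
lognormal noise (mean 1, coefficient of variation ``noise_cv``), and the
withdrawn volume is replaced with blank buffer, diluting the receiver.

Between sampling events the single ODE state is the receiver mass; the
donor mass is recovered as total-in-system minus receiver, so mass is
conserved to machine precision by construction. Sampling is an
instantaneous state jump (withdraw, then dilute).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .transport import AP_TO_BL, BL_TO_AP, WellTimeSeries, normalize_direction

__all__ = [
    "TransportSimParams",
    "SamplingSchedule",
    "WellTruth",
    "SimulatedDataset",
    "simulate_well",
    "simulate_condition",
    "generate_standards",
    "passive_params",
    "efflux_params",
    "DEFAULT_SCHEDULE",
    "DEFAULT_STANDARD_CONCS",
]

#: Calibration-standard concentration grid, ug/mL.
DEFAULT_STANDARD_CONCS = (
    0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.5, 5.0, 7.5, 10.0, 15.0, 30.0, 50.0, 100.0,
)


@dataclass(frozen=True)
class TransportSimParams:
    """Mechanistic parameters of the two-compartment monolayer model.

    Parameters
    ----------
    p_passive : float
        Passive permeability coefficient, cm/s. Typical well-absorbed
        compounds sit around 1e-6 to 1e-5 cm/s.
    vmax : float
        Maximal efflux flux density, ug cm^-2 s^-1. Zero gives a purely
        passive compound.
    km : float
        Efflux half-saturation concentration, ug/mL. Donor concentrations
        well above ``km`` saturate the transporter, shrinking the efflux
        ratio — the signature saturation behaviour of P-gp.
    inhibition : float
        Fraction in [0, 1] multiplying ``(1 - inhibition)`` onto ``vmax``;
        1 means complete inhibitor block of the efflux transporter.
    area : float
        Membrane area, cm^2 (default 1.12, the 12-well Transwell insert).
    vol_ap, vol_bl : float
        Apical and basolateral chamber volumes, mL (defaults 0.5 and 1.5,
        the 12-well convention).
    noise_cv : float
        Coefficient of variation of the multiplicative lognormal
        measurement noise (0 = noiseless).
    seed : int or None
        Default random seed used when the simulation call does not pass
        its own.
    """

    p_passive: float
    vmax: float = 0.0
    km: float = 25.0
    inhibition: float = 0.0
    area: float = 1.12
    vol_ap: float = 0.5
    vol_bl: float = 1.5
    noise_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.p_passive) and self.p_passive >= 0):
            raise ValueError("p_passive must be >= 0")
        if not (math.isfinite(self.vmax) and self.vmax >= 0):
            raise ValueError("vmax must be >= 0")
        if not (math.isfinite(self.km) and self.km > 0):
            raise ValueError("km must be > 0")
        if not (0.0 <= self.inhibition <= 1.0):
            raise ValueError("inhibition must be in [0, 1]")
        if self.area <= 0 or self.vol_ap <= 0 or self.vol_bl <= 0:
            raise ValueError("area and volumes must be positive")
        if not (math.isfinite(self.noise_cv) and self.noise_cv >= 0):
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class SamplingSchedule:
    """Receiver sampling scheme: times (minutes) and per-sample volume (mL).

    At every time the sampled volume ``vs`` is withdrawn and replaced
    with blank buffer (default 0.2 mL).
    """

    times: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0)
    vs: float = 0.2

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        object.__setattr__(self, "times", t)
        if len(t) == 0 or t[0] <= 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing and > 0")
        if not (math.isfinite(self.vs) and self.vs > 0):
            raise ValueError("vs must be > 0")


DEFAULT_SCHEDULE = SamplingSchedule()


def passive_params(p_passive: float = 2e-6, noise_cv: float = 0.0,
                   **kw) -> TransportSimParams:
    """Parameters for a purely passive compound (no efflux)."""
    return TransportSimParams(p_passive=p_passive, vmax=0.0,
                              noise_cv=noise_cv, **kw)


def efflux_params(p_passive: float = 2e-6, vmax: float = 1.25e-4,
                  km: float = 25.0, inhibition: float = 0.0,
                  noise_cv: float = 0.0, **kw) -> TransportSimParams:
    """Parameters for an efflux-substrate compound.

    The defaults give an efflux ratio near 3 at a 100 ug/mL donor
    concentration that falls toward 1.8 at 200 ug/mL — the saturating,
    strongly directional pattern an efflux substrate shows in the assay.
    """
    return TransportSimParams(p_passive=p_passive, vmax=vmax, km=km,
                              inhibition=inhibition, noise_cv=noise_cv, **kw)


@dataclass
class WellTruth:
    """Noiseless bookkeeping for one simulated well.

    ``conc_true`` are the pre-withdrawal receiver concentrations, ug/mL;
    ``cum_mass_true`` the exact cumulative transported mass (receiver
    content plus everything previously withdrawn), ug; ``withdrawn`` the
    mass removed at each sampling event, ug; ``donor_mass`` the donor
    content at each sampling time, ug.
    """

    well_id: str
    direction: str
    c0: float
    times: np.ndarray
    conc_true: np.ndarray
    cum_mass_true: np.ndarray
    withdrawn: np.ndarray
    donor_mass: np.ndarray
    initial_donor_mass: float

    def mass_balance_error(self) -> float:
        """Max relative error of donor + receiver + withdrawn vs initial."""
        # receiver mass pre-withdrawal = cum_mass_true - sum(withdrawn before n)
        prev = np.concatenate(([0.0], np.cumsum(self.withdrawn)[:-1]))
        receiver_pre = self.cum_mass_true - prev
        total = self.donor_mass + receiver_pre + prev
        return float(np.max(np.abs(total - self.initial_donor_mass))
                     / self.initial_donor_mass)


@dataclass
class SimulatedDataset:
    """A batch of simulated wells with their generating truth."""

    wells: list[WellTimeSeries]
    truth: dict[str, WellTruth]
    params: TransportSimParams
    schedule: SamplingSchedule
    seed: int | None = None
    standards: pd.DataFrame | None = None

    def wells_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-measurement table (the wells CSV dialect)."""
        rows = []
        for w in self.wells:
            for t, c in zip(w.times, w.concs):
                rows.append({
                    "well_id": w.well_id, "condition": w.condition or "",
                    "compound": w.compound, "direction": w.direction,
                    "c0_ug_per_ml": w.c0, "vr_ml": w.vr, "vs_ml": w.vs,
                    "area_cm2": w.area, "time_min": t, "conc_ug_per_ml": c,
                })
        return pd.DataFrame(rows)

    def truth_frame(self) -> pd.DataFrame:
        """Tidy sidecar with the exact noiseless trajectories."""
        rows = []
        for wid, tr in self.truth.items():
            for i, t in enumerate(tr.times):
                rows.append({
                    "well_id": wid, "time_min": t,
                    "conc_true_ug_per_ml": tr.conc_true[i],
                    "cum_mass_true_ug": tr.cum_mass_true[i],
                    "withdrawn_ug": tr.withdrawn[i],
                    "donor_mass_ug": tr.donor_mass[i],
                })
        return pd.DataFrame(rows)


def _compartments(params: TransportSimParams, direction: str) -> tuple[float, float, float]:
    """(donor volume, receiver volume, efflux sign) for a direction."""
    if direction == AP_TO_BL:
        return params.vol_ap, params.vol_bl, +1.0
    return params.vol_bl, params.vol_ap, -1.0


@lru_cache(maxsize=512)
def _noiseless_trajectory(p_passive: float, vmax: float, km: float,
                          inhibition: float, area: float,
                          vol_ap: float, vol_bl: float,
                          times: tuple[float, ...], vs: float,
                          direction: str, c0: float):
    """Integrate one noiseless well; cached on the scalar parameter tuple.

    Returns tuples (conc_true, cum_mass, withdrawn, donor_mass, m0).
    Replicate wells differ only in noise, so the cache turns repeated
    Monte-Carlo conditions into a single ODE solve.
    """
    params = TransportSimParams(p_passive, vmax, km, inhibition, area,
                                vol_ap, vol_bl)
    vd, vr, sign = _compartments(params, direction)
    if vs >= vr:
        raise ValueError("sample volume vs must be < receiver volume")
    eff = (1.0 - inhibition) * vmax

    m0 = c0 * vd               # initial donor mass, ug
    m_r = 0.0                  # receiver mass, ug
    m_tot = m0                 # mass currently in the two chambers, ug

    def rhs(_t, y):
        mr = y[0]
        cd = (rhs.m_tot - mr) / vd
        cr = mr / vr
        j = p_passive * (cd - cr) - sign * eff * cd / (km + cd)
        return (area * j,)

    conc, cum, wdr, dmass = [], [], [], []
    removed = 0.0
    t_prev = 0.0
    for t_min in times:
        t_end = t_min * 60.0
        rhs.m_tot = m_tot
        sol = solve_ivp(rhs, (t_prev * 60.0, t_end), (m_r,), method="LSODA",
                        rtol=1e-11, atol=1e-14 * max(m0, 1.0))
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise RuntimeError(f"flux integration failed: {sol.message}")
        m_r = float(sol.y[0, -1])
        c_r = m_r / vr
        conc.append(c_r)
        cum.append(m_r + removed)
        dmass.append(m_tot - m_r)
        # sampling event: withdraw vs at concentration c_r, refill with blank
        w = c_r * vs
        wdr.append(w)
        removed += w
        m_r -= w
        m_tot -= w
        t_prev = t_min
    return tuple(conc), tuple(cum), tuple(wdr), tuple(dmass), m0


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and CV ``cv``."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def simulate_well(params: TransportSimParams, schedule: SamplingSchedule,
                  direction: str, c0: float, *,
                  well_id: str = "w1", compound: str = "drug",
                  condition: str | None = None,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[WellTimeSeries, WellTruth]:
    """Simulate one well and its measurement series.

    Returns the measured (noisy) :class:`WellTimeSeries` and the exact
    :class:`WellTruth` record of the noiseless trajectory.
    """
    direction = normalize_direction(direction)
    if not (math.isfinite(c0) and c0 > 0):
        raise ValueError("c0 must be positive")
    conc, cum, wdr, dmass, m0 = _noiseless_trajectory(
        params.p_passive, params.vmax, params.km, params.inhibition,
        params.area, params.vol_ap, params.vol_bl,
        schedule.times, schedule.vs, direction, c0)
    conc = np.array(conc)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    measured = conc * _noise_factors(rng, params.noise_cv, conc.size)
    _, vr, _ = _compartments(params, direction)
    series = WellTimeSeries(
        well_id=well_id, compound=compound, direction=direction, c0=c0,
        vr=vr, vs=schedule.vs, area=params.area,
        times=np.array(schedule.times), concs=measured, condition=condition)
    truth = WellTruth(
        well_id=well_id, direction=direction, c0=c0,
        times=np.array(schedule.times), conc_true=conc,
        cum_mass_true=np.array(cum), withdrawn=np.array(wdr),
        donor_mass=np.array(dmass), initial_donor_mass=m0)
    return series, truth


def simulate_condition(params: TransportSimParams, schedule: SamplingSchedule,
                       c0_list: Sequence[float], n_wells: int, seed: int | None = None,
                       *, directions: Sequence[str] = (AP_TO_BL, BL_TO_AP),
                       compound: str = "drug",
                       condition: str | None = None) -> SimulatedDataset:
    """Simulate a full condition: each donor concentration in both
    directions with ``n_wells`` replicates.

    Per-well random streams are spawned deterministically from the master
    seed, so the dataset is bit-reproducible and wells are independent.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    directions = [normalize_direction(d) for d in directions]
    if seed is None:
        seed = params.seed
    root = np.random.SeedSequence(seed)
    n_streams = len(c0_list) * len(directions) * n_wells
    children = root.spawn(n_streams)
    wells: list[WellTimeSeries] = []
    truth: dict[str, WellTruth] = {}
    k = 0
    for c0 in c0_list:
        for direction in directions:
            dir_tag = direction.replace("-", "")
            for i in range(n_wells):
                wid = f"{compound}_{c0:g}_{dir_tag}_{i + 1:02d}"
                label = condition or f"{compound}-{c0:g}"
                s, t = simulate_well(
                    params, schedule, direction, c0, well_id=wid,
                    compound=compound, condition=label,
                    rng=np.random.default_rng(children[k]))
                wells.append(s)
                truth[wid] = t
                k += 1
    return SimulatedDataset(wells=wells, truth=truth, params=params,
                            schedule=schedule, seed=seed)


def generate_standards(slope, intercept=None, nominal_concs=DEFAULT_STANDARD_CONCS,
                       noise_cv: float = 0.0, seed: int | None = None,
                       analyte: str = "analyte", day: int | None = None,
                       segments=None) -> pd.DataFrame:
    """Emit a (nominal concentration, signal) calibration-standards table.

    Signals follow ``signal = slope * conc + intercept`` perturbed by
    multiplicative lognormal noise of coefficient of variation
    ``noise_cv``. For a segmented truth pass ``segments`` as a list of
    ``(lo, hi, slope, intercept)`` tuples instead; a concentration on a
    shared boundary uses the lower segment.
    """
    concs = np.asarray(nominal_concs, dtype=float)
    if np.any(concs < 0):
        raise ValueError("nominal concentrations must be non-negative")
    if segments is not None:
        signal = np.empty_like(concs)
        for j, c in enumerate(concs):
            for lo, hi, m, b in segments:
                if lo <= c <= hi:
                    signal[j] = m * c + b
                    break
            else:
                raise ValueError(f"concentration {c} outside every segment")
    else:
        if intercept is None:
            raise ValueError("intercept required when segments not given")
        signal = slope * concs + intercept
    rng = np.random.default_rng(seed)
    signal = signal * _noise_factors(rng, noise_cv, signal.size)
    out = pd.DataFrame({"analyte": analyte,
                        "nominal_conc_ug_per_ml": concs,
                        "signal": signal})
    if day is not None:
        out["day"] = day
    return out
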