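"""Run configuration: one human-editable YAML file, every option defaulted.

The configuration round-trips losslessly through YAML and records both
the analysis options (fit window, efflux-ratio threshold, TEER
threshold, test choice, alpha) and the simulation block (mechanistic
parameters, sampling schedule, replicate count, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .simdata import SamplingSchedule, TransportSimParams
from .transport import ER_THRESHOLD, TEER_THRESHOLD

__all__ = ["SimBlock", "RunConfig"]


@dataclass(frozen=True)
class SimBlock:
    """Simulation request: parameters, schedule, design and seed."""

    params: TransportSimParams = field(
        default_factory=lambda: TransportSimParams(p_passive=2e-6, noise_cv=0.05))
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)
    c0_list: tuple[float, ...] = (100.0,)
    n_wells: int = 6
    compound: str = "drug"
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    """All knobs of an analysis or simulation run, with defaults."""

    wells_csv: str | None = None
    standards_csv: str | None = None
    resistance_csv: str | None = None
    out_dir: str = "cacoflux-out"
    window: tuple[float, float] | None = None      # minutes; None = all points
    er_threshold: float = ER_THRESHOLD
    teer_threshold: float = TEER_THRESHOLD
    sd_ddof: int = 1                               # sample SD convention
    test: str = "welch"                            # or "student"
    alpha: float = 0.05
    calibration_split: float | None = None         # segment boundary conc
    simulation: SimBlock = field(default_factory=SimBlock)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["window"] = list(self.window) if self.window else None
        doc["simulation"]["schedule"]["times"] = list(self.simulation.schedule.times)
        doc["simulation"]["c0_list"] = list(self.simulation.c0_list)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        sim = doc.pop("simulation", None)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if doc.get("window"):
            doc["window"] = tuple(float(x) for x in doc["window"])
        cfg = cls(**doc)
        if sim is not None:
            params = TransportSimParams(**sim.get("params", {"p_passive": 2e-6}))
            sched = sim.get("schedule", {})
            schedule = SamplingSchedule(
                times=tuple(sched.get("times", SamplingSchedule().times)),
                vs=float(sched.get("vs", SamplingSchedule().vs)))
            block = SimBlock(params=params, schedule=schedule,
                             c0_list=tuple(sim.get("c0_list", (100.0,))),
                             n_wells=int(sim.get("n_wells", 6)),
                             compound=str(sim.get("compound", "drug")),
                             seed=int(sim.get("seed", 0)))
            cfg = replace(cfg, simulation=block)
        return cfg
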