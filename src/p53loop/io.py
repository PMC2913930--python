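"""Result serialization, run manifests and canned fixtures.

CSV dialect: UTF-8, comma-separated, header row, '.' decimal; times in
hours, concentrations in nM, counts in molecules.  Every CLI run emits a
RunManifest (JSON) recording the tool version, parameters, scenario,
solver settings and seeds, sufficient to reproduce deterministic outputs
byte-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import Trajectory, simulate
from .model import SystemState
from .params import ModelParameters
from .stress import StressScenario, builtin_scenarios

__all__ = [
    "trajectory_to_frame",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "RunManifest",
    "fixtures",
]

_TRAJ_COLUMNS = ["time_h", "p_nM", "mm_nM", "m_nM", "c_nM", "total_p53_nM"]


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_h": traj.times,
            "p_nM": traj.p,
            "mm_nM": traj.m_m,
            "m_nM": traj.m,
            "c_nM": traj.c,
            "total_p53_nM": traj.total_p53,
        }
    )


def write_trajectory_csv(traj: Trajectory, path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return Trajectory(
        times=df["time_h"].to_numpy(),
        states=df[["p_nM", "mm_nM", "m_nM", "c_nM"]].to_numpy(),
    )


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one CLI run."""

    command: str
    parameters: dict
    scenario: dict | None
    solver: dict
    seeds: dict
    outputs: list[str]
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _sinusoid_trajectory() -> Trajectory:
    """Synthetic wave 100 + 50*sin(2*pi*t/6) injected as the free-p53
    channel; used to pin the metric definitions (period 6 h, amplitude
    100 as max minus min, spikyness 1)."""
    t = np.arange(0.0, 60.0 + 1e-9, 0.01)
    p = 100.0 + 50.0 * np.sin(2 * np.pi * t / 6.0)
    states = np.column_stack([p, np.zeros_like(t), np.zeros_like(t), np.ones_like(t)])
    return Trajectory(times=t, states=states, meta={"synthetic": "sinusoid"})


def fixtures() -> dict:
    """Deterministic canned inputs for tests and examples.

    Includes the default parameters, the gamma-doubled oscillator, the
    calibrated DNA-damage scenario and the synthetic sinusoid trajectory.
    """
    defaults = ModelParameters()
    return {
        "default_parameters": defaults,
        "gamma_x2_parameters": defaults.with_updates(gamma=2 * defaults.gamma),
        "dna_damage_scenario": builtin_scenarios()["dna_damage"],
        "sinusoid_trajectory": _sinusoid_trajectory(),
    }


def scenario_to_dict(scenario: StressScenario) -> dict:
    return {
        "name": scenario.name,
        "fold_changes": dict(scenario.fold_changes),
        "sign_pattern": dict(scenario.sign_pattern),
    }


def scenario_from_dict(data: dict) -> StressScenario:
    return StressScenario(
        name=data["name"],
        fold_changes={k: float(v) for k, v in data["fold_changes"].items()},
        sign_pattern=dict(data.get("sign_pattern", {})),
    )
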