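"""Gait-trial container: synchronized stance-phase time series of one trial.

All mechanical channels (joint angles, experimental net joint moments,
external knee frontal moment and axial intersegmental force) and the
normalised EMG envelopes live on a common 100 Hz grid spanning the stance
phase; raw EMG, when present, is a separate 2000 Hz series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .geometry import DOFS
from .signals import TimeSeries
from . import sto

ANGLE_COLS = tuple(f"q_{d}" for d in DOFS)
MOMENT_COLS = tuple(f"M_{d}" for d in DOFS)
EXT_COLS = ("ext_frontal_moment", "ext_axial_force")


@dataclass
class GaitTrial:
    """One stance-phase trial (angles rad, moments N*m, forces N, envelopes [0,1])."""

    task: str
    time: np.ndarray
    angles: pd.DataFrame            # columns q_HAA .. q_AFE
    envelopes: pd.DataFrame | None  # one column per EMG channel, MVC-normalised
    exp_moments: pd.DataFrame       # columns M_HAA .. M_AFE
    ext_frontal_moment: np.ndarray
    ext_axial_force: np.ndarray
    raw_emg: TimeSeries | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time)
        for name, df in (("angles", self.angles), ("exp_moments", self.exp_moments)):
            if len(df) != n:
                raise InputError(f"{name} length {len(df)} != time length {n}")
        if self.envelopes is not None and len(self.envelopes) != n:
            raise InputError("envelopes length mismatch")
        if len(self.ext_frontal_moment) != n or len(self.ext_axial_force) != n:
            raise InputError("external load channel length mismatch")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def events(self):
        """(t_contact, t_toeoff); stance trials span the whole series by default."""
        return (
            self.meta.get("t_contact", float(self.time[0])),
            self.meta.get("t_toeoff", float(self.time[-1])),
        )

    # -- file round-trip ---------------------------------------------------
    def to_sto(self, path) -> None:
        df = pd.concat(
            [
                self.angles[list(ANGLE_COLS)],
                self.exp_moments[list(MOMENT_COLS)],
                pd.DataFrame(
                    {
                        "ext_frontal_moment": self.ext_frontal_moment,
                        "ext_axial_force": self.ext_axial_force,
                    }
                ),
            ]
            + ([self.envelopes.add_prefix("env_")] if self.envelopes is not None else []),
            axis=1,
        )
        sto.write_sto(path, self.time, df, name=self.task)
        if self.raw_emg is not None:
            p = Path(path)
            sto.write_sto(p.with_name(p.stem + "_emg" + p.suffix),
                          self.raw_emg.time, self.raw_emg.data, name=self.task + "_emg")

    def mirrored(self) -> "GaitTrial":
        """Mirror a left-limb trial into the internal right-limb convention.

        Flips the sign of the frontal-plane channels: hip adduction angle and
        moment, and the external knee frontal moment (varus stays positive
        for the mirrored limb).  Sagittal channels are side-symmetric.
        """
        angles = self.angles.copy()
        angles["q_HAA"] = -angles["q_HAA"]
        moments = self.exp_moments.copy()
        moments["M_HAA"] = -moments["M_HAA"]
        return GaitTrial(
            task=self.task, time=self.time.copy(), angles=angles,
            envelopes=None if self.envelopes is None else self.envelopes.copy(),
            exp_moments=moments,
            ext_frontal_moment=-np.asarray(self.ext_frontal_moment),
            ext_axial_force=np.asarray(self.ext_axial_force).copy(),
            raw_emg=self.raw_emg,
            meta={**self.meta, "mirrored": True},
        )

    @classmethod
    def from_sto(cls, path, meta: dict | None = None) -> "GaitTrial":
        name, time, df = sto.read_sto(path)
        env_cols = [c for c in df.columns if c.startswith("env_")]
        envelopes = df[env_cols].rename(columns=lambda c: c[4:]) if env_cols else None
        p = Path(path)
        emg_path = p.with_name(p.stem + "_emg" + p.suffix)
        raw = None
        if emg_path.exists():
            _, t_emg, d_emg = sto.read_sto(emg_path)
            raw = TimeSeries(t_emg, d_emg)
        return cls(
            task=(meta or {}).get("task", name),
            time=time,
            angles=df[list(ANGLE_COLS)],
            envelopes=envelopes,
            exp_moments=df[list(MOMENT_COLS)],
            ext_frontal_moment=df["ext_frontal_moment"].to_numpy(),
            ext_axial_force=df["ext_axial_force"].to_numpy(),
            raw_emg=raw,
            meta=dict(meta or {}),
        )
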