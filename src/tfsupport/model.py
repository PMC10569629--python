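"""The musculoskeletal model container and its default 34-MTU parameter set.

The default lower-limb roster covers the muscles an EMG-driven knee analysis
needs: the medial (SM, ST, GR, SR) and lateral (BFLH, BFSH) hamstrings, the
quadriceps, hip gluteals/adductors/flexors, triceps surae and the remaining
ankle movers — 34 MTUs driven by 16 surface-EMG channels (deep or unmeasured
muscles are mapped to a synergist's channel, e.g. the medial-hamstring
electrode drives both SM and ST).

The geometry is a surrogate parameter table (polynomial moment arms,
frontal-plane line-of-action offsets and axial fractions): synthetic defaults
informed by published lower-limb anatomy, not fitted to any particular
subject.  It is serialisable to JSON and fully editable.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field

from .errors import ConfigError
from .geometry import JOINT_RANGES, CompartmentGeometry, MuscleGeometry
from .model_core import MTUParameters

#: the 16 surface EMG channels
EMG_CHANNELS = (
    "medial_hamstring", "biceps_femoris", "adductor_group", "rectus_femoris",
    "vastus_lateralis", "vastus_medialis", "gracilis", "tfl", "sartorius",
    "gluteus_maximus", "gluteus_medius", "medial_gastroc", "lateral_gastroc",
    "soleus", "tibialis_anterior", "peroneals",
)

#: the two graft donor muscles
DONOR_MTUS = ("st", "gr")

# name: (channel, FmMAX N, lmo m, lts m, phi deg, segments, arms, z_F, c_ax)
# arms: {dof: ascending poly coeffs in that dof's angle, m}; flexor-positive
# KFE, adduction-positive HAA, flexion-positive HFE, dorsiflexion-positive AFE.
# z_F: poly in q_KFE, m, lateral positive; c_ax: poly in q_KFE, clipped [0,1].
_DEFAULT_TABLE = {
    # --- knee-crossing muscles -------------------------------------------
    "sm":    ("medial_hamstring", 1300, 0.100, 0.345, 15, {"thigh": 0.7, "shank": 0.3},
              {"HFE": (-0.050, -0.008), "KFE": (0.030, -0.009)}, (-0.018, 0.006), (0.95, -0.05)),
    "st":    ("medial_hamstring", 410, 0.190, 0.240, 5, {"thigh": 0.7, "shank": 0.3},
              {"HFE": (-0.042, -0.016), "KFE": (0.042, -0.017)}, (-0.012, 0.005), (0.95, -0.05)),
    "bflh":  ("biceps_femoris", 900, 0.110, 0.330, 12, {"thigh": 0.7, "shank": 0.3},
              {"HFE": (-0.054, -0.004), "KFE": (0.024, -0.006)}, (0.018, -0.006), (0.94, -0.05)),
    "bfsh":  ("biceps_femoris", 320, 0.170, 0.105, 15, {"thigh": 0.6, "shank": 0.4},
              {"KFE": (0.031, -0.013)}, (0.019, -0.006), (0.93, -0.05)),
    "gr":    ("gracilis", 140, 0.230, 0.160, 5, {"thigh": 0.7, "shank": 0.3},
              {"HAA": (0.030, -0.004), "HFE": (0.008,), "KFE": (0.032, -0.010)},
              (-0.016, 0.005), (0.94, -0.05)),
    "rf":    ("rectus_femoris", 1200, 0.115, 0.310, 8, {"thigh": 1.0},
              {"HFE": (0.045, -0.006), "KFE": (-0.042, 0.013)}, (0.004, -0.002), (0.90, -0.04)),
    "vl":    ("vastus_lateralis", 1900, 0.100, 0.220, 14, {"thigh": 1.0},
              {"KFE": (-0.044, 0.013)}, (0.015, -0.005), (0.90, -0.04)),
    "vm":    ("vastus_medialis", 1300, 0.095, 0.200, 16, {"thigh": 1.0},
              {"KFE": (-0.041, 0.009)}, (-0.014, 0.005), (0.90, -0.04)),
    "vi":    ("vastus_lateralis", 1600, 0.090, 0.195, 6, {"thigh": 1.0},
              {"KFE": (-0.052, 0.022)}, (0.002, -0.001), (0.90, -0.04)),
    "sr":    ("sartorius", 160, 0.420, 0.110, 2, {"thigh": 0.8, "shank": 0.2},
              {"HAA": (-0.012,), "HFE": (0.040, -0.005), "KFE": (0.018, -0.006)},
              (-0.020, 0.007), (0.92, -0.05)),
    "tfl":   ("tfl", 230, 0.095, 0.400, 3, {"thigh": 0.8, "shank": 0.2},
              {"HAA": (-0.035, 0.004), "HFE": (0.030, -0.004), "KFE": (-0.004, 0.005)},
              (0.026, -0.007), (0.50, -0.10)),
    "mg":    ("medial_gastroc", 1550, 0.062, 0.390, 17, {"thigh": 0.15, "shank": 0.85},
              {"KFE": (0.018, -0.006), "AFE": (-0.042, 0.005)}, (-0.017, 0.005), (0.90, -0.05)),
    "lg":    ("lateral_gastroc", 720, 0.066, 0.380, 8, {"thigh": 0.15, "shank": 0.85},
              {"KFE": (0.014, -0.003), "AFE": (-0.038, 0.010)}, (0.017, -0.005), (0.90, -0.05)),
    # --- hip-only muscles -------------------------------------------------
    "gmax1": ("gluteus_maximus", 550, 0.140, 0.120, 5, {"pelvis": 0.5, "thigh": 0.5},
              {"HFE": (-0.036, -0.014), "HAA": (-0.014,)}, (0.0,), (0.0,)),
    "gmax2": ("gluteus_maximus", 750, 0.155, 0.110, 0, {"pelvis": 0.5, "thigh": 0.5},
              {"HFE": (-0.051, -0.002), "HAA": (0.004,)}, (0.0,), (0.0,)),
    "gmax3": ("gluteus_maximus", 550, 0.165, 0.140, 5, {"pelvis": 0.5, "thigh": 0.5},
              {"HFE": (-0.060, -0.012), "HAA": (0.018,)}, (0.0,), (0.0,)),
    "gmed1": ("gluteus_medius", 820, 0.054, 0.078, 8, {"pelvis": 0.5, "thigh": 0.5},
              {"HAA": (-0.042, 0.010), "HFE": (0.014,)}, (0.0,), (0.0,)),
    "gmed2": ("gluteus_medius", 600, 0.084, 0.053, 0, {"pelvis": 0.5, "thigh": 0.5},
              {"HAA": (-0.044, -0.002), "HFE": (-0.003,)}, (0.0,), (0.0,)),
    "gmed3": ("gluteus_medius", 650, 0.065, 0.053, 19, {"pelvis": 0.5, "thigh": 0.5},
              {"HAA": (-0.036, 0.002), "HFE": (-0.016,)}, (0.0,), (0.0,)),
    "gmin":  ("gluteus_medius", 600, 0.048, 0.051, 10, {"pelvis": 0.5, "thigh": 0.5},
              {"HAA": (-0.028, 0.008), "HFE": (0.007,)}, (0.0,), (0.0,)),
    "addlong": ("adductor_group", 620, 0.138, 0.110, 6, {"pelvis": 0.5, "thigh": 0.5},
                {"HAA": (0.035, -0.010), "HFE": (0.022, -0.006)}, (0.0,), (0.0,)),
    "addbrev": ("adductor_group", 430, 0.133, 0.028, 0, {"pelvis": 0.5, "thigh": 0.5},
                {"HAA": (0.028, 0.004), "HFE": (0.010, 0.003)}, (0.0,), (0.0,)),
    "addmag": ("adductor_group", 1300, 0.145, 0.130, 12, {"pelvis": 0.5, "thigh": 0.5},
               {"HAA": (0.042, -0.006), "HFE": (-0.025, -0.005)}, (0.0,), (0.0,)),
    "pect":  ("adductor_group", 180, 0.133, 0.028, 0, {"pelvis": 0.5, "thigh": 0.5},
              {"HAA": (0.024, -0.002), "HFE": (0.016, -0.008)}, (0.0,), (0.0,)),
    "iliacus": ("rectus_femoris", 1000, 0.100, 0.090, 7, {"pelvis": 0.5, "thigh": 0.5},
                {"HFE": (0.040, -0.012), "HAA": (0.008,)}, (0.0,), (0.0,)),
    "psoas": ("rectus_femoris", 1000, 0.104, 0.130, 8, {"pelvis": 0.5, "thigh": 0.5},
              {"HFE": (0.043, 0.006), "HAA": (-0.006,)}, (0.0,), (0.0,)),
    # --- ankle-only muscles ----------------------------------------------
    "sol":   ("soleus", 3600, 0.055, 0.250, 25, {"shank": 0.9, "foot": 0.1},
              {"AFE": (-0.043, 0.007)}, (0.0,), (0.0,)),
    "ta":    ("tibialis_anterior", 900, 0.098, 0.223, 5, {"shank": 0.9, "foot": 0.1},
              {"AFE": (0.040, -0.010)}, (0.0,), (0.0,)),
    "edl":   ("tibialis_anterior", 500, 0.102, 0.345, 8, {"shank": 0.9, "foot": 0.1},
              {"AFE": (0.026, 0.012)}, (0.0,), (0.0,)),
    "perl":  ("peroneals", 950, 0.059, 0.345, 10, {"shank": 0.9, "foot": 0.1},
              {"AFE": (-0.016, 0.006)}, (0.0,), (0.0,)),
    "perb":  ("peroneals", 350, 0.058, 0.161, 5, {"shank": 0.9, "foot": 0.1},
              {"AFE": (-0.009, -0.003)}, (0.0,), (0.0,)),
    "tibpost": ("soleus", 1600, 0.041, 0.310, 12, {"shank": 0.9, "foot": 0.1},
                {"AFE": (-0.015, -0.004)}, (0.0,), (0.0,)),
    "fdl":   ("soleus", 310, 0.044, 0.400, 7, {"shank": 0.9, "foot": 0.1},
              {"AFE": (-0.009, 0.006)}, (0.0,), (0.0,)),
    "fhl":   ("soleus", 520, 0.052, 0.380, 10, {"shank": 0.9, "foot": 0.1},
              {"AFE": (-0.014, -0.006)}, (0.0,), (0.0,)),
}

#: tendon pre-strain at the neutral pose used to seat the reference length
_NEUTRAL_PRESTRAIN = 0.004


@dataclass
class MusculoskeletalModel:
    """34 MTUs + surrogate geometry + compartment geometry + EMG mapping."""

    mtus: dict
    geometry: dict
    compartment: CompartmentGeometry = field(default_factory=CompartmentGeometry)
    emg_map: dict = field(default_factory=dict)
    joint_ranges: dict = field(default_factory=lambda: dict(JOINT_RANGES))

    @property
    def names(self):
        return list(self.mtus)

    def knee_spanning(self):
        """Names of MTUs that load the tibiofemoral joint."""
        return [n for n, g in self.geometry.items() if g.crosses_knee()]

    def channel_for(self, name: str) -> str:
        try:
            return self.emg_map[name]
        except KeyError:
            raise ConfigError(f"MTU {name!r} has no EMG channel mapping") from None

    def copy(self) -> "MusculoskeletalModel":
        return copy.deepcopy(self)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mtus": {n: vars(p).copy() for n, p in self.mtus.items()},
            "geometry": {
                n: {
                    "ref_length": g.ref_length,
                    "moment_arms": {d: list(c) for d, c in g.moment_arms.items()},
                    "z_offset": list(g.z_offset),
                    "axial_fraction": list(g.axial_fraction),
                    "segment_fractions": dict(g.segment_fractions),
                }
                for n, g in self.geometry.items()
            },
            "compartment": {"d_med": self.compartment.d_med, "d_lat": self.compartment.d_lat},
            "emg_map": dict(self.emg_map),
            "joint_ranges": {d: list(r) for d, r in self.joint_ranges.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MusculoskeletalModel":
        return cls(
            mtus={n: MTUParameters(**p) for n, p in d["mtus"].items()},
            geometry={
                n: MuscleGeometry(
                    ref_length=g["ref_length"],
                    moment_arms={k: tuple(v) for k, v in g["moment_arms"].items()},
                    z_offset=tuple(g["z_offset"]),
                    axial_fraction=tuple(g["axial_fraction"]),
                    segment_fractions=dict(g["segment_fractions"]),
                )
                for n, g in d["geometry"].items()
            },
            compartment=CompartmentGeometry(**d["compartment"]),
            emg_map=dict(d["emg_map"]),
            joint_ranges={k: tuple(v) for k, v in d["joint_ranges"].items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MusculoskeletalModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_model() -> MusculoskeletalModel:
    """Build the generic 34-MTU model from the default parameter table."""
    mtus, geoms, emg_map = {}, {}, {}
    for name, (channel, fmax, lmo, lts, phi_deg, segs, arms, z, cax) in _DEFAULT_TABLE.items():
        phi = math.radians(phi_deg)
        mtus[name] = MTUParameters(name=name, FmMAX=fmax, lmo=lmo, lts=lts, phi_o=phi)
        ref = lmo * math.cos(phi) + lts * (1.0 + _NEUTRAL_PRESTRAIN)
        geoms[name] = MuscleGeometry(
            ref_length=ref,
            moment_arms={d: tuple(c) for d, c in arms.items()},
            z_offset=tuple(z),
            axial_fraction=tuple(cax),
            segment_fractions=dict(segs),
        )
        emg_map[name] = channel
    return MusculoskeletalModel(mtus=mtus, geometry=geoms, emg_map=emg_map)
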