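"""Shared fixtures: the generic model, a small toy model, and a tiny study."""

import numpy as np
import pandas as pd
import pytest

import tfsupport as tf
from tfsupport.geometry import DOFS, MuscleGeometry
from tfsupport.model import MusculoskeletalModel
from tfsupport.model_core import MTUParameters
from tfsupport.trial import GaitTrial


@pytest.fixture(scope="session")
def generic_model():
    return tf.default_model()


def make_toy_model():
    """Three distinct MTUs (knee flexor, knee extensor, plantarflexor)."""
    mtus = {
        "flex": MTUParameters("flex", FmMAX=1000, lmo=0.10, lts=0.25, phi_o=0.1),
        "ext": MTUParameters("ext", FmMAX=1500, lmo=0.09, lts=0.20, phi_o=0.05),
        "pf": MTUParameters("pf", FmMAX=2000, lmo=0.06, lts=0.30, phi_o=0.2),
    }
    geoms = {
        "flex": MuscleGeometry(
            ref_length=0.10 * np.cos(0.1) + 0.25 * 1.004,
            moment_arms={"KFE": (0.035, -0.010)},
            z_offset=(-0.015, 0.005), axial_fraction=(0.95, -0.05),
            segment_fractions={"thigh": 0.7, "shank": 0.3},
        ),
        "ext": MuscleGeometry(
            ref_length=0.09 * np.cos(0.05) + 0.20 * 1.004,
            moment_arms={"KFE": (-0.042, 0.013)},
            z_offset=(0.012, -0.004), axial_fraction=(0.9, -0.04),
            segment_fractions={"thigh": 1.0},
        ),
        "pf": MuscleGeometry(
            ref_length=0.06 * np.cos(0.2) + 0.30 * 1.004,
            moment_arms={"AFE": (-0.040, 0.006)},
            z_offset=(0.0,), axial_fraction=(0.0,),
            segment_fractions={"shank": 1.0},
        ),
    }
    emg_map = {"flex": "ham", "ext": "quad", "pf": "calf"}
    return MusculoskeletalModel(mtus=mtus, geometry=geoms, emg_map=emg_map)


def make_toy_trial(model, seed=0, n=40, dt=0.01, noise=0.0, task="sidestep"):
    """A model-consistent trial for the toy model (moments from the model itself)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    tau = t / t[-1]
    angles = pd.DataFrame({
        "q_HAA": 0.05 * np.sin(np.pi * tau),
        "q_HFE": 0.4 - 0.3 * tau,
        "q_KFE": 0.3 + 0.4 * np.sin(np.pi * tau),
        "q_AFE": -0.1 + 0.2 * np.sin(np.pi * tau),
    })
    env = pd.DataFrame({
        "ham": 0.05 + 0.6 * np.exp(-((tau - 0.25) ** 2) / 0.02),
        "quad": 0.05 + 0.7 * np.exp(-((tau - 0.4) ** 2) / 0.03),
        "calf": 0.05 + 0.6 * np.exp(-((tau - 0.65) ** 2) / 0.03),
    })
    trial = GaitTrial(
        task=task, time=t, angles=angles, envelopes=env,
        exp_moments=pd.DataFrame(np.zeros((n, 4)), columns=[f"M_{d}" for d in DOFS]),
        ext_frontal_moment=np.zeros(n), ext_axial_force=np.zeros(n),
        meta={"task": task},
    )
    pred = tf.predicted_joint_moments(model, trial)
    exp = pred.moments.copy()
    if noise > 0:
        for c in exp.columns:
            exp[c] = exp[c] + rng.normal(0, noise, size=n)
    trial.exp_moments = exp
    return trial


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def toy_trial(toy_model):
    return make_toy_trial(toy_model)
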