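"""Fully synthetic study generator.

Builds a cohort of subjects with known ("ground-truth") musculoskeletal
models — segment-scaled variants of the generic model with sampled strength
coefficients, activation dynamics and small fibre/tendon-length
perturbations — plus donor-muscle (ST/GR) morphology deficits and tendon
regeneration statuses matching the 7 both / 5 one (4 GR, 1 ST) / 6 none
cohort split.  For each subject it synthesises model-consistent gait trials:
smooth joint-angle templates per task (walk, run, 45-degree sidestep cut),
per-channel excitation bursts, forces and net joint moments from the
ground-truth forward model, experimental moments with declared noise, an
external knee frontal moment balancing the net muscle frontal moment, an
axial intersegmental compression profile, and raw surface EMG synthesised as
excitation-modulated band-limited noise at 2000 Hz.

Everything is deterministic under (config, seed), so calibration recovery
and the standard-vs-adjusted analysis are testable without external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as _cal
from .adjustment import NO_REGENERATION, REGENERATED, MorphologyMeasurement
from .errors import InputError
from .geometry import DOFS, knee_load_components, linear_scale_model
from .model import EMG_CHANNELS, MusculoskeletalModel, default_model
from .signals import TimeSeries, _filtfilt
from .trial import GaitTrial

logger = logging.getLogger(__name__)

TASKS = ("walk", "run", "sidestep")
GRAVITY = 9.81

#: per-channel excitation bursts (amplitude, centre, width) in stance fraction
_BURSTS = {
    "medial_hamstring": [(0.70, 0.15, 0.15), (0.30, 0.70, 0.20)],
    "biceps_femoris": [(0.60, 0.15, 0.15), (0.25, 0.70, 0.20)],
    "gracilis": [(0.50, 0.20, 0.15)],
    "adductor_group": [(0.50, 0.35, 0.20)],
    "rectus_femoris": [(0.60, 0.35, 0.18)],
    "vastus_lateralis": [(0.85, 0.30, 0.18)],
    "vastus_medialis": [(0.80, 0.30, 0.18)],
    "sartorius": [(0.40, 0.25, 0.20)],
    "tfl": [(0.50, 0.30, 0.20)],
    "gluteus_maximus": [(0.60, 0.20, 0.18)],
    "gluteus_medius": [(0.70, 0.25, 0.20)],
    "medial_gastroc": [(0.70, 0.55, 0.20)],
    "lateral_gastroc": [(0.60, 0.55, 0.20)],
    "soleus": [(0.80, 0.60, 0.20)],
    "tibialis_anterior": [(0.50, 0.10, 0.12), (0.20, 0.90, 0.10)],
    "peroneals": [(0.50, 0.50, 0.20)],
}
_TASK_EXC_SCALE = {"walk": 0.45, "run": 0.90, "sidestep": 1.0}

#: task-specific relative emphasis per channel (walking is plantarflexor-
#: dominated, running quadriceps-dominated, cutting frontal-plane-dominated);
#: also decorrelates channel envelopes across the calibration tasks
_TASK_CHANNEL_SCALE = {
    "walk": {"vastus_lateralis": 0.6, "vastus_medialis": 0.6, "rectus_femoris": 0.6,
             "soleus": 1.4, "medial_gastroc": 1.3, "lateral_gastroc": 1.2,
             "tibialis_anterior": 1.3, "gluteus_maximus": 0.7, "adductor_group": 0.7,
             "gluteus_medius": 0.8},
    "run": {"soleus": 1.2, "rectus_femoris": 1.15, "gluteus_maximus": 1.1,
            "adductor_group": 0.75, "tfl": 0.85},
    "sidestep": {"adductor_group": 1.2, "gluteus_medius": 1.15, "peroneals": 1.2,
                 "tfl": 1.1},
}

#: per-task shift of the burst centres (stance fraction)
_TASK_BURST_SHIFT = {"walk": 0.06, "run": -0.03, "sidestep": 0.0}
_TASK_AXIAL_PEAK = {"walk": 1.1, "run": 2.2, "sidestep": 2.0}   # x body weight
_TASK_STANCE_S = {"walk": (0.34, 0.38), "run": (0.22, 0.26), "sidestep": (0.25, 0.35)}

#: typical contralateral donor morphology (volume cm^3, peak CSA cm^2)
_DONOR_REFERENCE = {"ST": (220.0, 11.0), "GR": (100.0, 5.5)}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort (defaults = the study design)."""

    n_subjects: int = 18
    sidestep_trials: int = 4
    walk_trials: int = 1
    run_trials: int = 1
    dt: float = 0.01                      # kinematics sampling, s (100 Hz)
    emg_fs: float = 2000.0                # raw EMG sampling, Hz
    moment_noise_frac: float = 0.02       # sd of moment noise, fraction of range
    angle_jitter: float = 0.03            # trial-to-trial amplitude jitter
    excitation_jitter: float = 0.08
    lmo_lts_jitter: float = 0.03          # truth fibre/tendon-length perturbation
    strength_range: tuple = (0.8, 1.5)
    c_range: tuple = (-0.5, -0.05)        # truth C1/C2
    a_shape_range: tuple = (-2.5, -0.5)
    segment_scale_sd: float = 0.03
    volume_deficit_mean: float = 0.35
    csa_deficit_mean: float = 0.30
    deficit_sd: float = 0.08
    deficit_max: float = 0.60
    regen_split: str = "cohort"           # cohort | all_both | all_none
    #: semimembranosus strength multiplier by regeneration group — surgical
    #: legs show SM hypertrophy, most pronounced when the donor tendons do
    #: not regenerate (the SM has carried the donors' share for years)
    sm_compensation: dict = field(
        default_factory=lambda: {"both": 1.0, "one": 1.1, "none": 1.25}
    )
    mass_mean: float = 82.0
    mass_sd: float = 16.0
    synth_raw_emg: bool = True

    @classmethod
    def noise_free(cls, **kw) -> "GeneratorConfig":
        """Model-consistent, noise-free conditions for recovery experiments."""
        kw.setdefault("moment_noise_frac", 0.0)
        kw.setdefault("lmo_lts_jitter", 0.0)
        kw.setdefault("synth_raw_emg", False)
        return cls(**kw)


@dataclass
class SyntheticSubject:
    """A subject with fully known ground truth."""

    id: str
    mass: float
    segment_scales: dict
    truth_model: MusculoskeletalModel
    morphology: dict                      # "ST"/"GR" -> MorphologyMeasurement
    mvc_max: dict                         # channel -> MVC envelope amplitude
    seed: int

    @property
    def regeneration(self) -> dict:
        return {k: m.regeneration for k, m in self.morphology.items()}

    @property
    def regen_group(self) -> str:
        st, gr = self.regeneration["ST"], self.regeneration["GR"]
        if st == REGENERATED and gr == REGENERATED:
            return "both"
        if st == NO_REGENERATION and gr == NO_REGENERATION:
            return "none"
        return "one"


@dataclass
class SubjectData:
    subject: SyntheticSubject
    trials: dict                          # task -> list[GaitTrial]

    def calibration_trials(self):
        """One trial per task (walk, run, sidestep)."""
        return [self.trials[t][0] for t in TASKS if self.trials.get(t)]

    def sidestep_trials(self):
        return list(self.trials.get("sidestep", []))


@dataclass
class Cohort:
    config: GeneratorConfig
    seed: int
    subjects: list


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

def _regen_statuses(n: int, rng: np.random.Generator, split: str):
    """(ST, GR) regeneration statuses matching the 7/5(4 GR,1 ST)/6 cohort split."""
    if split == "all_both":
        kinds = ["both"] * n
    elif split == "all_none":
        kinds = ["none"] * n
    else:
        base = {"both": 7, "gr_only": 4, "st_only": 1, "none": 6}
        if n == 18:
            counts = base
        else:  # largest-remainder scaling of the cohort proportions
            raw = {k: v * n / 18.0 for k, v in base.items()}
            counts = {k: int(np.floor(v)) for k, v in raw.items()}
            rem = n - sum(counts.values())
            for k in sorted(raw, key=lambda k: raw[k] - np.floor(raw[k]), reverse=True)[:rem]:
                counts[k] += 1
        kinds = sum(([k] * v for k, v in counts.items()), [])
    rng.shuffle(kinds)
    table = {
        "both": (REGENERATED, REGENERATED),
        "gr_only": (NO_REGENERATION, REGENERATED),
        "st_only": (REGENERATED, NO_REGENERATION),
        "none": (NO_REGENERATION, NO_REGENERATION),
    }
    return [table[k] for k in kinds]


def _sample_deficit(rng, mean, sd, dmax):
    if mean <= 0.0 or dmax <= 0.0:  # deficit-free preset
        return 0.0
    for _ in range(100):
        d = rng.normal(mean, sd)
        if 0.0 < d < dmax:
            return d
    return float(np.clip(d, 1e-3, dmax - 1e-3))


def generate_subject(
    config: GeneratorConfig,
    seed: int,
    subject_id: str = "S00",
    regeneration: tuple = (REGENERATED, REGENERATED),
    generic: MusculoskeletalModel | None = None,
) -> SyntheticSubject:
    """Sample one subject's ground truth (deterministic under (config, seed))."""
    rng = np.random.default_rng(seed)
    generic = generic or default_model()

    scales = {
        seg: float(np.clip(rng.normal(1.0, config.segment_scale_sd), 0.9, 1.1))
        for seg in ("pelvis", "thigh", "shank", "foot")
    }
    truth = linear_scale_model(generic, scales)

    st_status, gr_status = regeneration
    regen_group = (
        "both" if (st_status, gr_status) == (REGENERATED, REGENERATED)
        else "none" if (st_status, gr_status) == (NO_REGENERATION, NO_REGENERATION)
        else "one"
    )
    sm_boost = config.sm_compensation.get(regen_group, 1.0)

    c1, c2 = rng.uniform(*config.c_range, size=2)
    a_shape = rng.uniform(*config.a_shape_range)
    j = config.lmo_lts_jitter
    for name, p in truth.mtus.items():
        s = rng.uniform(*config.strength_range)
        if name == "sm":
            s = min(s * sm_boost, 2.2)  # keep inside the calibration bounds
        lmo = p.lmo * (1.0 + rng.uniform(-j, j)) if j > 0 else p.lmo
        lts = p.lts * (1.0 + rng.uniform(-j, j)) if j > 0 else p.lts
        truth.mtus[name] = p.replace(
            strength_coeff=float(s), lmo=float(lmo), lts=float(lts),
            C1=float(c1), C2=float(c2), A_shape=float(a_shape),
        )

    morphology = {}
    for label, status in (("ST", st_status), ("GR", gr_status)):
        v_ref, csa_ref = _DONOR_REFERENCE[label]
        v_c = v_ref * rng.uniform(0.85, 1.15)
        csa_c = csa_ref * rng.uniform(0.85, 1.15)
        dv = _sample_deficit(rng, config.volume_deficit_mean, config.deficit_sd, config.deficit_max)
        dc = _sample_deficit(rng, config.csa_deficit_mean, config.deficit_sd, config.deficit_max)
        morphology[label] = MorphologyMeasurement(
            muscle=label,
            V_surgical=v_c * (1.0 - dv), V_contralateral=v_c,
            CSA_surgical=csa_c * (1.0 - dc), CSA_contralateral=csa_c,
            regeneration=status,
        )

    mvc = {ch: float(rng.uniform(0.3, 1.0)) for ch in EMG_CHANNELS}
    mass = float(np.clip(rng.normal(config.mass_mean, config.mass_sd), 50.0, 120.0))
    return SyntheticSubject(
        id=subject_id, mass=mass, segment_scales=scales, truth_model=truth,
        morphology=morphology, mvc_max=mvc, seed=seed,
    )


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

def _angle_templates(task: str, tau: np.ndarray, rng, jitter: float) -> dict:
    def jit():
        return 1.0 + jitter * rng.standard_normal()

    s1, s2 = np.sin(np.pi * tau), np.sin(2 * np.pi * tau)
    if task == "sidestep":
        q = {
            "KFE": 0.35 + 0.17 * tau + 0.50 * jit() * s1,
            "HFE": 0.60 - 0.45 * tau + 0.08 * jit() * s2,
            "HAA": 0.02 + 0.08 * jit() * s1,
            "AFE": -0.05 + 0.15 * jit() * s1 - 0.30 * tau**2,
        }
    elif task == "walk":
        q = {
            "KFE": 0.10 + 0.18 * jit() * s1 + 0.25 * tau**2,
            "HFE": 0.45 - 0.55 * tau,
            "HAA": 0.05 * jit() * s1,
            "AFE": -0.08 + 0.12 * jit() * s1 - 0.25 * tau**2,
        }
    elif task == "run":
        q = {
            "KFE": 0.25 + 0.45 * jit() * s1 + 0.10 * tau,
            "HFE": 0.55 - 0.50 * tau,
            "HAA": 0.04 * jit() * s1,
            "AFE": -0.10 + 0.18 * jit() * s1 - 0.30 * tau**2,
        }
    else:
        raise InputError(f"unknown task {task!r}")
    from .geometry import JOINT_RANGES

    return {d: np.clip(q[d], *JOINT_RANGES[d]) for d in DOFS}


def _excitations(task: str, tau: np.ndarray, rng, jitter: float) -> pd.DataFrame:
    scale = _TASK_EXC_SCALE[task]
    ch_scale = _TASK_CHANNEL_SCALE[task]
    shift = _TASK_BURST_SHIFT[task]
    out = {}
    for ch, bursts in _BURSTS.items():
        e = np.full_like(tau, 0.03)
        k = scale * ch_scale.get(ch, 1.0)
        for amp, c, w in bursts:
            a = amp * max(1.0 + jitter * rng.standard_normal(), 0.1)
            e = e + k * a * np.exp(-((tau - c - shift) ** 2) / (2 * w**2))
        out[ch] = np.clip(e, 0.0, 1.0)
    return pd.DataFrame(out)


def synthesize_raw_emg(profile: np.ndarray, fs: float, rng,
                       band=(30.0, 500.0), amplitude: float = 1.0) -> np.ndarray:
    """Excitation-modulated band-limited noise carrier.

    The carrier is white noise band-passed to ``band`` and normalised to unit
    mean rectified value, so the linear-envelope pipeline recovers
    ``amplitude * profile`` in expectation.
    """
    n = len(profile)
    carrier = rng.standard_normal(n)
    carrier = _filtfilt(carrier, "bandpass", band, fs)
    carrier /= np.mean(np.abs(carrier))
    return amplitude * np.asarray(profile, dtype=float) * carrier


def generate_trial(
    subject: SyntheticSubject,
    task: str,
    seed: int,
    config: GeneratorConfig | None = None,
) -> GaitTrial:
    """Synthesise one model-consistent stance-phase trial.

    Experimental moments equal the ground-truth forward-model net joint
    moments plus Gaussian noise (sd = ``moment_noise_frac`` of each DOF's
    range); the external knee frontal moment is the negative of the net
    muscle frontal knee moment plus a small residual; raw EMG (when enabled)
    is excitation-modulated 30-500 Hz noise scaled by the subject's MVC
    maxima.  If the equilibrium solve fails for a pathological draw the trial
    is re-sampled with a new derived seed (logged).
    """
    config = config or GeneratorConfig()
    if task not in TASKS:
        raise InputError(f"unknown task {task!r}")
    last_err = None
    for attempt in range(5):
        rng = np.random.default_rng(seed + 7919 * attempt)
        try:
            return _generate_trial_once(subject, task, rng, config, seed)
        except Exception as exc:  # pathological draw: retry with derived seed
            last_err = exc
            logger.warning("trial generation retry %d for %s/%s: %s",
                           attempt + 1, subject.id, task, exc)
    raise last_err


def _generate_trial_once(subject, task, rng, config, seed) -> GaitTrial:
    lo, hi = _TASK_STANCE_S[task]
    duration = rng.uniform(lo, hi)
    n = int(round(duration / config.dt)) + 1
    time = np.arange(n) * config.dt
    tau = time / time[-1]

    q = _angle_templates(task, tau, rng, config.angle_jitter)
    angles = pd.DataFrame({f"q_{d}": q[d] for d in DOFS})
    envelopes = _excitations(task, tau, rng, config.excitation_jitter)

    trial = GaitTrial(
        task=task,
        time=time,
        angles=angles,
        envelopes=envelopes,
        exp_moments=pd.DataFrame(np.zeros((n, 4)), columns=[f"M_{d}" for d in DOFS]),
        ext_frontal_moment=np.zeros(n),
        ext_axial_force=np.zeros(n),
        meta={"task": task, "subject": subject.id, "seed": int(seed),
              "mass": subject.mass, "t_contact": 0.0, "t_toeoff": float(time[-1])},
    )
    pred = _cal.predicted_joint_moments(subject.truth_model, trial)

    # experimental (inverse-dynamics-like) moments = truth + declared noise
    exp = pred.moments.copy()
    if config.moment_noise_frac > 0:
        for c in exp.columns:
            rng_span = np.ptp(exp[c].to_numpy()) or 1.0
            exp[c] = exp[c] + rng.normal(0.0, config.moment_noise_frac * rng_span, size=n)
    trial.exp_moments = exp.rename(columns=lambda c: c)

    # external knee loads
    Mk = np.zeros(n)
    qk = angles["q_KFE"].to_numpy()
    for name in subject.truth_model.knee_spanning():
        mk, _ = knee_load_components(pred.forces[name].to_numpy(), qk,
                                     subject.truth_model.geometry[name])
        Mk += mk
    resid = np.zeros(n)
    if config.moment_noise_frac > 0:
        resid = (config.moment_noise_frac * (np.ptp(Mk) or 1.0)
                 * np.sin(np.pi * tau + rng.uniform(0, 2 * np.pi)))
    trial.ext_frontal_moment = -Mk + resid
    peak = _TASK_AXIAL_PEAK[task] * (1.0 + 0.05 * rng.standard_normal())
    trial.ext_axial_force = subject.mass * GRAVITY * peak * np.sin(np.pi * tau) ** 0.8

    trial.meta["truth_forces"] = pred.forces
    trial.meta["truth_moments"] = pred.moments

    if config.synth_raw_emg:
        # EMG is recorded continuously around stance: pad the synthesis
        # window so envelope extraction has real data at the stance edges
        pad = 0.15
        n_emg = int(round((duration + 2 * pad) * config.emg_fs)) + 1
        t_emg = np.arange(n_emg) / config.emg_fs - pad
        raw = {}
        for ch in envelopes.columns:
            prof = np.interp(t_emg, time, envelopes[ch].to_numpy())
            raw[ch] = synthesize_raw_emg(prof, config.emg_fs, rng,
                                         amplitude=subject.mvc_max[ch])
        trial.raw_emg = TimeSeries(t_emg, pd.DataFrame(raw))
    return trial


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> Cohort:
    """Generate the full synthetic study (optionally written to disk).

    The on-disk layout is ``subjects/<id>/<task><k>.sto`` plus
    ``morphology.csv`` and a ``manifest.json`` holding every piece of ground
    truth; :func:`load_cohort` round-trips it.
    """
    config = config or GeneratorConfig()
    if config.n_subjects < 2:
        raise InputError("need at least 2 subjects")
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(4 * config.n_subjects + 1, dtype=np.uint32)
    statuses = _regen_statuses(
        config.n_subjects, np.random.default_rng(int(child[0]) % 2**31), config.regen_split
    )
    subjects = []
    generic = default_model()
    for i in range(config.n_subjects):
        sid = f"S{i:02d}"
        s_seed = int(child[1 + 4 * i]) % 2**31
        subj = generate_subject(config, s_seed, sid, statuses[i], generic)
        trials = {}
        for k, task in enumerate(TASKS):
            n_trials = {"walk": config.walk_trials, "run": config.run_trials,
                        "sidestep": config.sidestep_trials}[task]
            t_seed0 = int(child[2 + 4 * i + k]) % 2**31
            trials[task] = [
                generate_trial(subj, task, t_seed0 + 131 * j, config)
                for j in range(n_trials)
            ]
        subjects.append(SubjectData(subject=subj, trials=trials))
    cohort = Cohort(config=config, seed=seed, subjects=subjects)
    if out_dir is not None:
        save_cohort(cohort, out_dir)
    return cohort


def save_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cohort.seed, "config": asdict(cohort.config), "subjects": {}}
    morph_rows = []
    for sd in cohort.subjects:
        s = sd.subject
        subj_dir = out / "subjects" / s.id
        subj_dir.mkdir(parents=True, exist_ok=True)
        trial_files = {}
        for task, trials in sd.trials.items():
            trial_files[task] = []
            for j, tr in enumerate(trials):
                fname = f"{task}{j}.sto"
                tr.to_sto(subj_dir / fname)
                trial_files[task].append(fname)
        manifest["subjects"][s.id] = {
            "mass": s.mass,
            "segment_scales": s.segment_scales,
            "seed": s.seed,
            "mvc_max": s.mvc_max,
            "truth_model": s.truth_model.to_dict(),
            "regeneration": s.regeneration,
            "trials": trial_files,
        }
        for label, m in s.morphology.items():
            morph_rows.append(
                dict(subject=s.id, muscle=label,
                     volume_surgical_cm3=m.V_surgical, volume_contralateral_cm3=m.V_contralateral,
                     peak_csa_surgical_cm2=m.CSA_surgical,
                     peak_csa_contralateral_cm2=m.CSA_contralateral,
                     regeneration=m.regeneration)
            )
    pd.DataFrame(morph_rows).to_csv(out / "morphology.csv", index=False,
                                    float_format="%.17g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_cohort(in_dir) -> Cohort:
    """Reload a cohort written by :func:`save_cohort` (ground truth included)."""
    root = Path(in_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_d = manifest["config"]
    for k in ("strength_range", "c_range", "a_shape_range"):
        cfg_d[k] = tuple(cfg_d[k])
    config = GeneratorConfig(**cfg_d)
    morph = pd.read_csv(root / "morphology.csv", float_precision="round_trip")
    subjects = []
    for sid, rec in manifest["subjects"].items():
        rows = morph[morph.subject == sid].set_index("muscle")
        morphology = {
            label: MorphologyMeasurement(
                muscle=label,
                V_surgical=float(rows.loc[label, "volume_surgical_cm3"]),
                V_contralateral=float(rows.loc[label, "volume_contralateral_cm3"]),
                CSA_surgical=float(rows.loc[label, "peak_csa_surgical_cm2"]),
                CSA_contralateral=float(rows.loc[label, "peak_csa_contralateral_cm2"]),
                regeneration=str(rows.loc[label, "regeneration"]),
            )
            for label in ("ST", "GR")
        }
        subj = SyntheticSubject(
            id=sid, mass=rec["mass"], segment_scales=rec["segment_scales"],
            truth_model=MusculoskeletalModel.from_dict(rec["truth_model"]),
            morphology=morphology, mvc_max=rec["mvc_max"], seed=rec["seed"],
        )
        trials = {
            task: [
                GaitTrial.from_sto(root / "subjects" / sid / f,
                                   meta={"task": task, "subject": sid})
                for f in files
            ]
            for task, files in rec["trials"].items()
        }
        subjects.append(SubjectData(subject=subj, trials=trials))
    return Cohort(config=config, seed=manifest["seed"], subjects=subjects)
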