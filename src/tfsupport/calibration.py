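"""Closed-loop functional calibration and open-loop prediction.

The calibration adjusts EMG-driven model parameters so that predicted joint
moments track experimental (inverse-dynamics) moments about four DOF (hip
add/abduction, hip flexion, knee flexion, ankle flexion) over one trial per
gait task, with a quadratic penalty keeping fibres inside their physiological
length range.  Two structural facts make this fast and reliable:

* the compliant-tendon equilibrium is independent of the strength
  coefficients (they multiply both sides), so per-MTU strength coefficients
  enter the predicted moments *linearly* and are solved in closed form by
  bounded linear least squares at every step; and
* the remaining adjustables (the shared activation-dynamics constants C1, C2
  and the nonlinearity shape A) form a low-dimensional smooth problem handled
  by a seeded multi-start followed by local (Powell) refinement.

Open-loop prediction then evaluates muscle forces and joint moments from EMG
and joint angles with the calibrated parameters, with no further fitting.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.optimize import lsq_linear, minimize

from .errors import ConfigError, InputError
from .geometry import DOFS, mtu_kinematics
from .model import MusculoskeletalModel
from .model_core import DEFAULT_CURVES, HillCurves, solve_fiber_lengths_multi
from .trial import GaitTrial

logger = logging.getLogger(__name__)

#: physiological normalised fibre-length window and penalty weight
FIBER_WINDOW = (0.5, 1.5)
PENALTY_LAMBDA = 10.0


@dataclass(frozen=True)
class AdjustableSpec:
    """What the calibration may change, and within which bounds.

    ``fixed`` MTUs keep every parameter bit-identical (used for the adjusted
    donor muscles).  Strength coefficients of the remaining MTUs are bounded
    in ``strength_bounds``; the shared activation-dynamics constants are
    adjusted when ``adjust_activation`` is set; per-MTU optimal-fibre /
    tendon-slack lengths may additionally be refined within
    ``fiber_tendon_frac`` of their post-scaling values.
    """

    strength_bounds: tuple = (0.5, 2.5)
    adjust_activation: bool = True
    c_bounds: tuple = (-0.95, -0.01)
    a_shape_bounds: tuple = (-3.0, -1e-3)
    adjust_fiber_tendon: bool = False
    fiber_tendon_frac: float = 0.05
    fixed: frozenset = frozenset()

    def __post_init__(self):
        for lo, hi in (self.strength_bounds, self.c_bounds, self.a_shape_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InputError(f"invalid bounds ({lo}, {hi})")


@dataclass
class CalibrationBudget:
    """Optimizer effort: number of seeded global starts and local budget.

    ``polish_maxfev`` adds a high-precision simplex polish after the Powell
    refinement; parameter-recovery experiments need it (the strength solve
    amplifies small activation-constant errors), routine tracking does not.
    """

    n_starts: int = 6
    local_maxfev: int = 120
    n_refine: int = 1          # how many of the best starts get local refinement
    polish_maxfev: int = 0
    fiber_tendon_passes: int = 1


@dataclass
class CalibrationResult:
    model: MusculoskeletalModel
    objective: float
    rms_errors: pd.DataFrame    # rows = trials, columns = DOFS, N*m
    penalty: float
    converged: bool
    seed: int
    n_evals: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class PredictionResult:
    moments: pd.DataFrame        # columns M_HAA .. M_AFE
    forces: pd.DataFrame         # one column per MTU, N
    fiber_lengths: pd.DataFrame  # normalised
    activations: pd.DataFrame


def fixed_block_hash(model: MusculoskeletalModel, names) -> str:
    """Hash of the parameter block of the given MTUs (immutability checks)."""
    h = hashlib.sha256()
    for n in sorted(names):
        h.update(repr(vars(model.mtus[n])).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Forward machinery
# ---------------------------------------------------------------------------

@dataclass
class _TrialCache:
    L: np.ndarray            # (T, M) MTU lengths
    r: dict                  # dof -> (T, M) moment arms
    env: np.ndarray          # (T, M) mapped EMG envelopes
    Mexp: np.ndarray | None  # (T, 4)
    w: np.ndarray | None     # (4,) weights 1/(N_t * Var)
    dt: float


def _build_cache(model: MusculoskeletalModel, trial: GaitTrial, need_moments=True) -> _TrialCache:
    names = model.names
    if trial.envelopes is None:
        raise InputError("trial carries no EMG envelopes")
    q = {d: trial.angles[f"q_{d}"].to_numpy(dtype=float) for d in DOFS}
    T = len(trial.time)
    M = len(names)
    L = np.empty((T, M))
    r = {d: np.zeros((T, M)) for d in DOFS}
    env = np.empty((T, M))
    for j, n in enumerate(names):
        g = model.geometry[n]
        Lj, rj = mtu_kinematics(q, g)
        L[:, j] = Lj
        for d, arr in rj.items():
            r[d][:, j] = arr
        ch = model.channel_for(n)
        if ch not in trial.envelopes.columns:
            raise ConfigError(f"trial is missing EMG channel {ch!r} (needed by MTU {n!r})")
        env[:, j] = trial.envelopes[ch].to_numpy(dtype=float)
    Mexp = w = None
    if need_moments:
        missing = [c for c in (f"M_{d}" for d in DOFS) if c not in trial.exp_moments.columns]
        if missing:
            raise InputError(f"trial is missing experimental moment channels {missing}")
        Mexp = trial.exp_moments[[f"M_{d}" for d in DOFS]].to_numpy(dtype=float)
        var = Mexp.var(axis=0)
        var = np.where(var > 1e-12, var, 1.0)  # degenerate (constant) DOF: unit weight
        w = 1.0 / (T * var)
    return _TrialCache(L=L, r=r, env=env, Mexp=Mexp, w=w, dt=trial.dt)


def _activations(cache: _TrialCache, params_list, dt: float) -> np.ndarray:
    """EMG envelopes -> activations, grouping MTUs that share filter constants."""
    env = cache.env
    out = np.empty_like(env)
    groups: dict = {}
    for j, p in enumerate(params_list):
        groups.setdefault((p.C1, p.C2, p.A_shape, p.emd), []).append(j)
    for (c1, c2, A, emd), idx in groups.items():
        e = env[:, idx]
        d = int(round(emd / dt))
        if d > 0:
            shifted = np.empty_like(e)
            shifted[: min(d, e.shape[0])] = e[0]
            if d < e.shape[0]:
                shifted[d:] = e[:-d]
            e = shifted
        b1, b2 = c1 + c2, c1 * c2
        alpha = 1.0 + b1 + b2
        u = np.clip(_sig.lfilter([alpha], [1.0, b1, b2], e, axis=0), 0.0, 1.0)
        out[:, idx] = np.expm1(A * u) / np.expm1(A)
    return out


def _forward_unit(model, cache: _TrialCache, params_list, curves: HillCurves):
    """Fibre solve and per-MTU unit-strength tendon force / moment bases.

    Returns (ln (T,M), f_unit (T,M), bases {dof: (T,M)}): multiplying
    ``f_unit`` by each MTU's strength coefficient gives its force.
    """
    lmo = np.array([p.lmo for p in params_list])
    lts = np.array([p.lts for p in params_list])
    phi = np.array([p.phi_o for p in params_list])
    fmax = np.array([p.FmMAX for p in params_list])
    a = _activations(cache, params_list, cache.dt)
    ln = solve_fiber_lengths_multi(cache.L, a, lmo, lts, phi, cache.dt, curves)
    cosp = np.sqrt(1.0 - (np.sin(phi) / ln) ** 2)
    eps = (cache.L - ln * lmo * cosp) / lts - 1.0
    f_unit = fmax * curves.tendon(eps)
    bases = {d: cache.r[d] * f_unit for d in DOFS}
    return ln, f_unit, bases, a


def _fiber_penalty(ln: np.ndarray) -> float:
    lo, hi = FIBER_WINDOW
    return float(np.sum(np.maximum(0.0, ln - hi) ** 2 + np.maximum(0.0, lo - ln) ** 2))


def predicted_joint_moments(
    model: MusculoskeletalModel, trial: GaitTrial, curves: HillCurves = DEFAULT_CURVES
) -> PredictionResult:
    """Open-loop prediction: per-MTU forces and the four net joint moments."""
    cache = _build_cache(model, trial, need_moments=False)
    params_list = [model.mtus[n] for n in model.names]
    ln, f_unit, bases, act = _forward_unit(model, cache, params_list, curves)
    s = np.array([p.strength_coeff for p in params_list])
    forces = f_unit * s
    moments = {f"M_{d}": bases[d] @ s for d in DOFS}
    return PredictionResult(
        moments=pd.DataFrame(moments),
        forces=pd.DataFrame(forces, columns=model.names),
        fiber_lengths=pd.DataFrame(ln, columns=model.names),
        activations=pd.DataFrame(act, columns=model.names),
    )


def calibration_objective(
    model: MusculoskeletalModel,
    trials,
    spec: AdjustableSpec | None = None,
    curves: HillCurves = DEFAULT_CURVES,
) -> float:
    """Variance-normalised squared moment-tracking error plus fibre penalty.

    objective = sum_trials sum_dof sum_t (M_pred - M_exp)^2 / (N_t Var(M_exp))
                + lambda * sum_MTU sum_t penalty(l~m)
    """
    if not trials:
        raise InputError("at least one trial is required")
    obj = 0.0
    params_list = [model.mtus[n] for n in model.names]
    s = np.array([p.strength_coeff for p in params_list])
    for tr in trials:
        cache = _build_cache(model, tr)
        ln, _, bases, _ = _forward_unit(model, cache, params_list, curves)
        for k, d in enumerate(DOFS):
            resid = bases[d] @ s - cache.Mexp[:, k]
            obj += float(cache.w[k] * np.sum(resid**2))
        obj += PENALTY_LAMBDA * _fiber_penalty(ln)
    return obj


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _theta_of(model: MusculoskeletalModel, adj_names) -> np.ndarray:
    p = model.mtus[adj_names[0]]
    return np.array([p.C1, p.C2, p.A_shape])


def _apply_theta(params_list, names, fixed, theta):
    c1, c2, A = theta
    return [
        p if n in fixed else p.replace(C1=float(c1), C2=float(c2), A_shape=float(A))
        for p, n in zip(params_list, names)
    ]


def calibrate(
    model: MusculoskeletalModel,
    trials,
    spec: AdjustableSpec,
    seed: int = 0,
    budget: CalibrationBudget | None = None,
    curves: HillCurves = DEFAULT_CURVES,
) -> CalibrationResult:
    """Bounded global-then-local calibration of the adjustable parameters.

    Deterministic given ``(seed, inputs)``; never returns a model whose
    objective exceeds the input model's; fixed MTUs are bit-identical
    before/after.
    """
    if not trials:
        raise InputError("at least one calibration trial is required")
    budget = budget or CalibrationBudget()
    names = model.names
    fixed = set(spec.fixed)
    adj = [n for n in names if n not in fixed]
    if not adj and spec.adjust_activation:
        raise InputError("no adjustable MTUs")
    caches = [_build_cache(model, tr) for tr in trials]
    base_params = [model.mtus[n] for n in names]
    adj_idx = np.array([j for j, n in enumerate(names) if n not in fixed], dtype=int)
    fix_idx = np.array([j for j, n in enumerate(names) if n in fixed], dtype=int)
    s_fixed = np.array([base_params[j].strength_coeff for j in fix_idx])
    s0_adj = np.clip(
        np.array([base_params[j].strength_coeff for j in adj_idx]),
        spec.strength_bounds[0], spec.strength_bounds[1],
    )
    n_evals = 0

    def eval_theta(theta, params_override=None, solve_strengths=True):
        nonlocal n_evals
        n_evals += 1
        params_list = params_override or _apply_theta(base_params, names, fixed, theta)
        rows_A, rows_b, penalty = [], [], 0.0
        for cache in caches:
            ln, _, bases, _ = _forward_unit(model, cache, params_list, curves)
            penalty += _fiber_penalty(ln)
            for k, d in enumerate(DOFS):
                sw = np.sqrt(cache.w[k])
                B = bases[d]
                fixed_m = B[:, fix_idx] @ s_fixed if len(fix_idx) else 0.0
                rows_A.append(sw * B[:, adj_idx])
                rows_b.append(sw * (cache.Mexp[:, k] - fixed_m))
        A = np.vstack(rows_A)
        b = np.concatenate(rows_b)
        if solve_strengths and len(adj_idx):
            res = lsq_linear(A, b, bounds=spec.strength_bounds, tol=1e-12)
            s_adj = res.x
        else:
            s_adj = s0_adj
        obj = float(np.sum((A @ s_adj - b) ** 2) + PENALTY_LAMBDA * penalty)
        return obj, s_adj, penalty

    # objective of the incoming model (its own strengths, its own constants)
    obj_in, _, _ = eval_theta(None, params_override=base_params, solve_strengths=False)

    if spec.adjust_activation and adj:
        rng = np.random.default_rng(seed)
        lo = np.array([spec.c_bounds[0], spec.c_bounds[0], spec.a_shape_bounds[0]])
        hi = np.array([spec.c_bounds[1], spec.c_bounds[1], spec.a_shape_bounds[1]])
        starts = [_theta_of(model, adj)]
        starts += [lo + rng.random(3) * (hi - lo) for _ in range(max(budget.n_starts - 1, 0))]
        scored = sorted(
            ((eval_theta(th)[0], i, th) for i, th in enumerate(starts)), key=lambda t: t[:2]
        )
        best_obj, _, best_theta = scored[0]
        best_s = eval_theta(best_theta)[1]
        converged = False
        for _, _, th in scored[: max(budget.n_refine, 1)]:
            res = minimize(
                lambda x: eval_theta(x)[0],
                th,
                method="Powell",
                bounds=list(zip(lo, hi)),
                options={"maxfev": budget.local_maxfev, "xtol": 1e-8, "ftol": 1e-12},
            )
            if res.fun < best_obj:
                best_obj, best_theta = float(res.fun), np.asarray(res.x)
                best_s = eval_theta(best_theta)[1]
                converged = bool(res.success)
        if budget.polish_maxfev > 0:
            res = minimize(
                lambda x: eval_theta(np.clip(x, lo, hi))[0],
                best_theta,
                method="Nelder-Mead",
                options={"maxfev": budget.polish_maxfev,
                         "fatol": 1e-14, "xatol": 1e-9},
            )
            if res.fun < best_obj:
                best_obj = float(res.fun)
                best_theta = np.clip(np.asarray(res.x), lo, hi)
                best_s = eval_theta(best_theta)[1]
        theta_out = best_theta
    else:
        theta_out = _theta_of(model, adj) if adj else np.zeros(3)
        best_obj, best_s, _ = eval_theta(theta_out)
        converged = True

    # assemble the calibrated model
    out = model.copy()
    for j, sj in zip(adj_idx, best_s):
        n = names[j]
        p = out.mtus[n]
        if spec.adjust_activation:
            p = p.replace(C1=float(theta_out[0]), C2=float(theta_out[1]),
                          A_shape=float(theta_out[2]))
        out.mtus[n] = p.replace(strength_coeff=float(sj))

    # optional per-MTU fibre/tendon-length refinement (coordinate descent)
    if spec.adjust_fiber_tendon and adj:
        out, best_obj = _refine_fiber_tendon(
            out, model, trials, spec, curves, budget, fixed, best_obj
        )

    if best_obj > obj_in + 1e-9:  # never degrade the incoming model
        logger.info("calibration kept the incoming model (%.4g <= %.4g)", obj_in, best_obj)
        out = model.copy()
        best_obj = obj_in
        converged = False

    rms = _rms_table(out, trials, curves)
    return CalibrationResult(
        model=out,
        objective=float(best_obj),
        rms_errors=rms,
        penalty=float(
            sum(
                _fiber_penalty(
                    _forward_unit(out, _build_cache(out, tr), [out.mtus[n] for n in names], curves)[0]
                )
                for tr in trials
            )
        ),
        converged=converged,
        seed=seed,
        n_evals=n_evals,
        diagnostics={
            "theta": [float(v) for v in theta_out],
            "fixed_hash": fixed_block_hash(out, fixed) if fixed else None,
            "objective_in": float(obj_in),
        },
    )


def _refine_fiber_tendon(out, model, trials, spec, curves, budget, fixed, best_obj):
    frac = spec.fiber_tendon_frac
    for _ in range(max(budget.fiber_tendon_passes, 1)):
        for n in out.names:
            if n in fixed:
                continue
            p = out.mtus[n]
            base = (p.lmo, p.lts)

            def f(x, _n=n, _p=p):
                trial_model = out.copy()
                trial_model.mtus[_n] = _p.replace(lmo=float(x[0]), lts=float(x[1]))
                return calibration_objective(trial_model, trials, curves=curves)

            res = minimize(
                f, np.array(base), method="Powell",
                bounds=[(base[0] * (1 - frac), base[0] * (1 + frac)),
                        (base[1] * (1 - frac), base[1] * (1 + frac))],
                options={"maxfev": 40, "xtol": 1e-6},
            )
            if res.fun < best_obj:
                best_obj = float(res.fun)
                out.mtus[n] = p.replace(lmo=float(res.x[0]), lts=float(res.x[1]))
    return out, best_obj


def _rms_table(model, trials, curves) -> pd.DataFrame:
    rows = []
    for tr in trials:
        pred = predicted_joint_moments(model, tr, curves)
        rows.append(
            {
                d: float(
                    np.sqrt(
                        np.mean(
                            (pred.moments[f"M_{d}"].to_numpy() - tr.exp_moments[f"M_{d}"].to_numpy())
                            ** 2
                        )
                    )
                )
                for d in DOFS
            }
        )
    return pd.DataFrame(rows, index=[tr.task for tr in trials])
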