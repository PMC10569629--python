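"""Hill-type muscle-tendon mechanics.

Each muscle-tendon unit (MTU) is a contractile element (the muscle fibres,
with active force-length, force-velocity and parallel-elastic behaviour and a
constant-thickness pennation model) in series with a compliant tendon whose
force-strain curve is normalised to tendon slack length and peak isometric
force.  EMG linear envelopes are turned into activation by a second-order
recursive filter with unit DC gain followed by an exponential-shape
nonlinearity.  At every frame the fibre length is found so that the force the
fibre projects along the tendon equals the tendon force — the classic
compliant-tendon equilibrium used by EMG-driven neuromusculoskeletal models.

All curves are dimensionless: fibre length is normalised to optimal fibre
length ``lmo``, fibre velocity to the maximum shortening velocity
(``vmax`` optimal lengths per second), tendon strain to slack length ``lts``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as _sig

from .errors import EquilibriumError, GeometryError, InputError, ParameterError

__all__ = [
    "MTUParameters",
    "MTUStateSeries",
    "HillCurves",
    "DEFAULT_CURVES",
    "emg_to_activation",
    "evaluate_muscle_curves",
    "evaluate_tendon_curve",
    "pennation",
    "solve_equilibrium",
    "solve_fiber_lengths_multi",
]


@dataclass(frozen=True)
class MTUParameters:
    """Constants of one muscle-tendon unit.

    Parameters
    ----------
    name : identifier of the MTU.
    FmMAX : maximum isometric force of the fibres, N.
    lmo : optimal fibre length, m.
    lts : tendon slack length, m.
    phi_o : pennation angle at optimal fibre length, rad.
    strength_coeff : dimensionless calibrated multiplier on ``FmMAX``.
    C1, C2 : recursive activation-filter constants (each must lie in (-1, 1)
        for filter stability).
    A_shape : activation nonlinearity shape factor, in [-3, 0).
    emd : electromechanical delay, s (rounded to whole samples on use).
    """

    name: str
    FmMAX: float
    lmo: float
    lts: float
    phi_o: float = 0.0
    strength_coeff: float = 1.0
    C1: float = -0.30
    C2: float = -0.15
    A_shape: float = -1.5
    emd: float = 0.015

    def __post_init__(self) -> None:
        if not self.FmMAX > 0:
            raise ParameterError(f"{self.name}: FmMAX must be > 0, got {self.FmMAX}")
        if not self.lmo > 0:
            raise ParameterError(f"{self.name}: lmo must be > 0, got {self.lmo}")
        if self.lts < 0:
            raise ParameterError(f"{self.name}: lts must be >= 0, got {self.lts}")
        if not 0.0 <= self.phi_o < math.pi / 2:
            raise ParameterError(f"{self.name}: phi_o must be in [0, pi/2), got {self.phi_o}")
        if self.strength_coeff < 0:
            raise ParameterError(f"{self.name}: strength_coeff must be >= 0")
        if abs(self.C1) >= 1 or abs(self.C2) >= 1:
            raise ParameterError(
                f"{self.name}: |C1| and |C2| must be < 1 for a stable activation "
                f"filter, got C1={self.C1}, C2={self.C2}"
            )
        if not -3.0 <= self.A_shape < 0.0:
            raise ParameterError(f"{self.name}: A_shape must be in [-3, 0), got {self.A_shape}")
        if not 0.0 <= self.emd <= 0.1:
            raise ParameterError(f"{self.name}: emd must be in [0, 0.1] s, got {self.emd}")

    def replace(self, **kwargs) -> "MTUParameters":
        return replace(self, **kwargs)


@dataclass
class MTUStateSeries:
    """Per-frame mechanical state of one MTU over a trial."""

    activation: np.ndarray          # a(t) in [0, 1]
    norm_fiber_length: np.ndarray   # l~m = lm / lmo
    norm_fiber_velocity: np.ndarray  # v~m, normalised by vmax
    pennation: np.ndarray           # rad
    tendon_strain: np.ndarray       # eps = lt/lts - 1
    F_MTU: np.ndarray               # tendon-transmitted force, N (>= 0)


@dataclass(frozen=True)
class HillCurves:
    """Normalised Hill curve set (pluggable).

    active force-length  f_a(l) = exp(-(l-1)^2 / gamma)
    passive              f_p(l) = (exp(4(l-1)/0.6) - 1)/(exp(4) - 1) for l > 1, else 0
    force-velocity       Hill hyperbola for shortening, saturating eccentric
                         branch with plateau ``ecc_plateau``; f_v(0)=1, f_v(-1)=0
    tendon               quadratic toe then linear:
                         f_t = k_toe*eps^2 for 0 < eps < eps_toe,
                         k_lin*eps - c_lin for eps >= eps_toe; 0 for eps <= 0.
    ``tendon_stiffness_scale`` multiplies the whole tendon curve (a near-rigid
    tendon is obtained with a very large scale).
    """

    gamma: float = 0.45
    passive_strain: float = 0.6
    vmax: float = 10.0            # optimal fibre lengths / s
    ecc_plateau: float = 1.4
    af_con: float = 0.25
    af_ecc: float = 0.30
    k_toe: float = 1480.3
    eps_toe: float = 0.0127
    k_lin: float = 37.526
    c_lin: float = 0.2375
    tendon_stiffness_scale: float = 1.0

    # -- muscle -------------------------------------------------------------
    def active(self, lnorm):
        return np.exp(-((np.asarray(lnorm, dtype=float) - 1.0) ** 2) / self.gamma)

    def passive(self, lnorm):
        l = np.asarray(lnorm, dtype=float)
        f = (np.exp(4.0 * (l - 1.0) / self.passive_strain) - 1.0) / (np.exp(4.0) - 1.0)
        return np.where(l > 1.0, f, 0.0)

    def velocity(self, vnorm):
        v = np.asarray(vnorm, dtype=float)
        con = np.clip(1.0 + v, 0.0, None) / (1.0 - np.minimum(v, 0.0) / self.af_con)
        ecc = self.ecc_plateau - (self.ecc_plateau - 1.0) * self.af_ecc / (
            self.af_ecc + np.maximum(v, 0.0)
        )
        return np.where(v < 0.0, con, ecc)

    # -- tendon -------------------------------------------------------------
    def tendon(self, strain):
        """Normalised tendon force.  ``tendon_stiffness_scale`` compresses the
        strain axis, so every slope (toe and linear) is multiplied by it."""
        e = np.asarray(strain, dtype=float) * self.tendon_stiffness_scale
        toe = self.k_toe * e * e
        lin = self.k_lin * e - self.c_lin
        f = np.where(e < self.eps_toe, toe, lin)
        return np.where(e > 0.0, f, 0.0)

    def tendon_derivative(self, strain):
        """d f_t / d strain (accounts for the stiffness scale)."""
        e = np.asarray(strain, dtype=float) * self.tendon_stiffness_scale
        d = np.where(e < self.eps_toe, 2.0 * self.k_toe * e, self.k_lin)
        return self.tendon_stiffness_scale * np.where(e > 0.0, d, 0.0)


DEFAULT_CURVES = HillCurves()

# Root bracket for the normalised fibre length and iteration cap of the
# bracket-safeguarded Newton solve (converges to ~1e-14 in a handful of steps;
# the bracket guarantees global progress when a Newton step is rejected).
_LN_MAX = 2.0
_MAX_ITER = 80
_X_TOL = 1e-14


def emg_to_activation(envelope: np.ndarray, params: MTUParameters, dt: float) -> np.ndarray:
    """Map a normalised EMG linear envelope to muscle activation.

    Neural activation ``u`` follows the discrete second-order recursion

        u(t) = alpha * e(t - d) - beta1 * u(t - dt) - beta2 * u(t - 2 dt)

    with ``beta1 = C1 + C2``, ``beta2 = C1*C2`` and ``alpha = 1 + beta1 + beta2``
    (unit DC gain), ``d`` the electromechanical delay rounded to samples.  The
    activation nonlinearity is ``a = (exp(A u) - 1)/(exp(A) - 1)``, which maps
    u=0 -> 0 and u=1 -> 1 exactly for every admissible shape factor ``A``.
    """
    e = np.asarray(envelope, dtype=float)
    if dt <= 0:
        raise InputError(f"dt must be > 0, got {dt}")
    if e.ndim != 1:
        raise InputError("envelope must be one-dimensional")
    if e.size and (e.min() < -1e-12 or e.max() > 1.0 + 1e-9):
        raise InputError(
            f"envelope values must lie in [0, 1]; got range "
            f"[{e.min():.4g}, {e.max():.4g}]"
        )
    if abs(params.C1) >= 1 or abs(params.C2) >= 1:
        raise ParameterError(f"{params.name}: unstable filter constants")

    d = int(round(params.emd / dt))
    if d > 0 and e.size:
        shifted = np.empty_like(e)
        shifted[: min(d, e.size)] = e[0]  # hold the first sample during the delay
        if d < e.size:
            shifted[d:] = e[:-d]
        e = shifted

    beta1 = params.C1 + params.C2
    beta2 = params.C1 * params.C2
    alpha = 1.0 + beta1 + beta2
    u = _sig.lfilter([alpha], [1.0, beta1, beta2], e)
    u = np.clip(u, 0.0, 1.0)
    A = params.A_shape
    return np.expm1(A * u) / np.expm1(A)


def evaluate_muscle_curves(lnorm, vnorm, curves: HillCurves = DEFAULT_CURVES) -> dict:
    """Evaluate the normalised active, passive and velocity curves."""
    l = np.asarray(lnorm, dtype=float)
    if np.any(l <= 0):
        raise InputError("normalised fibre length must be > 0")
    return {
        "f_active": curves.active(l),
        "f_passive": curves.passive(l),
        "f_velocity": curves.velocity(vnorm),
    }


def evaluate_tendon_curve(strain, curves: HillCurves = DEFAULT_CURVES):
    """Normalised tendon force; zero at or below slack, quadratic toe, then linear."""
    e = np.asarray(strain, dtype=float)
    if not np.all(np.isfinite(e)):
        raise InputError("tendon strain must be finite")
    return curves.tendon(e)


def pennation(lnorm, phi_o: float):
    """Constant-thickness pennation: phi = asin(sin(phi_o) / l~m)."""
    l = np.asarray(lnorm, dtype=float)
    s = math.sin(phi_o)
    if np.any(l <= s):
        raise GeometryError(
            f"normalised fibre length {np.min(l):.4g} <= sin(phi_o) = {s:.4g}"
        )
    return np.arcsin(s / l)


def _residual_frame(ln, L, a, lmo, lts, sinp, ln_prev, dt, curves: HillCurves):
    """Equilibrium residual at one frame, vectorised over MTUs.

    R = (a f_a f_v + f_p) cos(phi) - f_t(eps); the strength coefficient and
    FmMAX multiply both sides and cancel, so the root is independent of them.
    Fibre velocity is implicit backward-difference: v~ = (ln - ln_prev)/(vmax dt).
    """
    cosp = np.sqrt(1.0 - (sinp / ln) ** 2)
    lt = L - ln * lmo * cosp
    eps = lt / lts - 1.0
    if ln_prev is None:
        fv = 1.0
    else:
        vn = (ln - ln_prev) / (curves.vmax * dt)
        fv = curves.velocity(vn)
    muscle = (a * curves.active(ln) * fv + curves.passive(ln)) * cosp
    return muscle - curves.tendon(eps)


_EXP4M1 = float(np.exp(4.0) - 1.0)


def _residual_and_derivative(ln, L, a, lmo, lts, sinp, ln_prev, dt, cv: HillCurves):
    """Fused residual R(ln) and analytic derivative dR/dln (hot path)."""
    inv = 1.0 / ln
    so = sinp * inv
    cosp = np.sqrt(1.0 - so * so)
    dcosp = sinp * sinp * inv * inv * inv / cosp
    lt = L - ln * lmo * cosp
    dlt = -lmo * (cosp + ln * dcosp)
    eps = lt / lts - 1.0
    deps = dlt / lts
    es = eps * cv.tendon_stiffness_scale
    taut = es > 0.0
    toe = es < cv.eps_toe
    ft = np.where(taut, np.where(toe, cv.k_toe * es * es, cv.k_lin * es - cv.c_lin), 0.0)
    dft = (
        np.where(taut, np.where(toe, 2.0 * cv.k_toe * es, cv.k_lin), 0.0)
        * cv.tendon_stiffness_scale
        * deps
    )
    dl1 = ln - 1.0
    fa = np.exp(-dl1 * dl1 / cv.gamma)
    dfa = -2.0 * dl1 / cv.gamma * fa
    ex = np.exp(4.0 * dl1 / cv.passive_strain) / _EXP4M1
    pos = dl1 > 0.0
    fp = np.where(pos, ex - 1.0 / _EXP4M1, 0.0)
    dfp = np.where(pos, 4.0 / cv.passive_strain * ex, 0.0)
    if ln_prev is None:
        fv = 1.0
        dfv = 0.0
    else:
        dvn = 1.0 / (cv.vmax * dt)
        vn = (ln - ln_prev) * dvn
        neg = vn < 0.0
        den = 1.0 - np.minimum(vn, 0.0) / cv.af_con
        con = np.clip(1.0 + vn, 0.0, None) / den
        dcon = np.where(vn <= -1.0, 0.0, (1.0 + 1.0 / cv.af_con) / (den * den))
        be = cv.af_ecc + np.maximum(vn, 0.0)
        ecc = cv.ecc_plateau - (cv.ecc_plateau - 1.0) * cv.af_ecc / be
        decc = (cv.ecc_plateau - 1.0) * cv.af_ecc / (be * be)
        fv = np.where(neg, con, ecc)
        dfv = np.where(neg, dcon, decc) * dvn
    mus = a * fa * fv + fp
    R = mus * cosp - ft
    dR = (a * (dfa * fv + fa * dfv) + dfp) * cosp + mus * dcosp - dft
    return R, dR


def solve_fiber_lengths_multi(
    L: np.ndarray,
    a: np.ndarray,
    lmo: np.ndarray,
    lts: np.ndarray,
    phi_o: np.ndarray,
    dt: float,
    curves: HillCurves = DEFAULT_CURVES,
    static: bool = False,
) -> np.ndarray:
    """Solve the compliant-tendon equilibrium for a batch of MTUs.

    ``L`` and ``a`` have shape (T, M); the parameter arrays have shape (M,).
    Frames are solved in order (the fibre velocity couples frame t to t-1);
    within a frame, all MTUs are bisected simultaneously over the bracket
    l~m in (sin(phi_o) + 1e-6, 2].  Returns the (T, M) normalised fibre lengths.
    With ``static=True`` every frame is treated as an independent isometric
    pose (no velocity coupling), as used for operating-range matching.

    Raises :class:`EquilibriumError` (with the frame index) if the residual
    has no sign change in the bracket for some MTU.
    """
    L = np.asarray(L, dtype=float)
    a = np.asarray(a, dtype=float)
    if L.ndim != 2 or a.shape != L.shape:
        raise InputError("L and a must both have shape (T, M)")
    if np.any(L <= 0):
        raise InputError("MTU length must be > 0 throughout")
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-9):
        raise InputError("activation must lie in [0, 1]")
    T, M = L.shape
    sinp = np.sin(np.asarray(phi_o, dtype=float))
    lmo = np.asarray(lmo, dtype=float)
    lts = np.asarray(lts, dtype=float)
    if np.any(lts <= 0):
        raise ParameterError("solve_fiber_lengths_multi requires lts > 0")

    lo0 = sinp + 1e-6
    out = np.empty((T, M))
    ln_prev = None
    x = np.ones(M)  # warm start; subsequent frames reuse the previous solution
    for t in range(T):
        lo = lo0.copy()
        hi = np.full(M, _LN_MAX)
        r_lo = _residual_frame(lo, L[t], a[t], lmo, lts, sinp, ln_prev, dt, curves)
        r_hi = _residual_frame(hi, L[t], a[t], lmo, lts, sinp, ln_prev, dt, curves)
        bad = (r_lo > 0) & (r_hi > 0)
        if np.any(bad) or np.any(r_hi < 0):
            i = int(np.argmax(bad | (r_hi < 0)))
            raise EquilibriumError(
                f"no equilibrium root in bracket at frame {t} (MTU index {i}): "
                f"R(lo)={r_lo[i]:.3g}, R(hi)={r_hi[i]:.3g}",
                frame=t,
            )
        x = np.clip(x, lo + 1e-9, hi - 1e-9)
        done = np.zeros(M, dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            for _ in range(_MAX_ITER):
                R, dR = _residual_and_derivative(
                    x, L[t], a[t], lmo, lts, sinp, ln_prev, dt, curves
                )
                lo = np.where(~done & (R < 0), x, lo)
                hi = np.where(~done & (R >= 0), x, hi)
                # an element is converged once its residual is at noise level
                # or its bracket has collapsed (both far below the reported
                # accuracy)
                done |= (np.abs(R) < 1e-12) | (hi - lo < 1e-11)
                xn = x - R / dR
                # a step leaving the bracket is clamped just inside the
                # violated edge (the stiff force-velocity branch makes plain
                # Newton overshoot); this shrinks the bracket geometrically
                # instead of falling back to slow midpoint bisection
                width = hi - lo
                xn = np.where(np.isfinite(xn), xn, 0.5 * (lo + hi))
                xn = np.clip(xn, lo + 0.05 * width, hi - 0.05 * width)
                xn = np.where(done, x, xn)
                shift = np.max(np.abs(xn - x))
                x = xn
                if done.all() or shift < _X_TOL:
                    break
        out[t] = x
        if not static:
            ln_prev = out[t]
    return out


def solve_equilibrium(
    L_mtu: np.ndarray,
    activation: np.ndarray,
    params: MTUParameters,
    dt: float,
    curves: HillCurves = DEFAULT_CURVES,
) -> MTUStateSeries:
    """Per-frame compliant-tendon equilibrium for a single MTU.

    At each frame the fibre length solves

        s * FmMAX * (a f_a(l~) f_v(v~) + f_p(l~)) cos(phi) = s * FmMAX * f_t(eps)

    with ``lt = L_mtu - lm cos(phi)`` and the fibre velocity from a backward
    finite difference of the solved fibre lengths (first frame isometric).
    ``F_MTU = strength_coeff * FmMAX * f_t(eps) >= 0``; a zero strength
    coefficient yields identically zero force (the equilibrium itself does not
    depend on the strength coefficient, which cancels from both sides).

    With ``lts == 0`` the tendon is inextensible and the fibre length follows
    directly from the pennation geometry.
    """
    L = np.asarray(L_mtu, dtype=float)
    a = np.asarray(activation, dtype=float)
    if L.ndim != 1 or a.shape != L.shape:
        raise InputError("L_mtu and activation must be 1-D arrays of equal length")
    if dt <= 0:
        raise InputError("dt must be > 0")
    if np.any(L <= 0):
        raise InputError("L_mtu must be > 0 throughout")
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-9):
        raise InputError("activation must lie in [0, 1]")

    sinp = math.sin(params.phi_o)
    if params.lts == 0.0:
        # Rigid tendon: lm cos(phi) = L and lm sin(phi) = lmo sin(phi_o).
        lm = np.hypot(L, params.lmo * sinp)
        ln = lm / params.lmo
        eps = np.zeros_like(L)
        phi = np.arcsin(np.clip(sinp / ln, 0.0, 1.0))
        vn = np.zeros_like(ln)
        vn[1:] = np.diff(ln) / (curves.vmax * dt)
        fv = curves.velocity(vn)
        fmus = (a * curves.active(ln) * fv + curves.passive(ln)) * np.cos(phi)
        F = params.strength_coeff * params.FmMAX * np.clip(fmus, 0.0, None)
        return MTUStateSeries(a, ln, vn, phi, eps, F)

    ln = solve_fiber_lengths_multi(
        L[:, None],
        a[:, None],
        np.array([params.lmo]),
        np.array([params.lts]),
        np.array([params.phi_o]),
        dt,
        curves,
    )[:, 0]
    vn = np.zeros_like(ln)
    if ln.size > 1:
        vn[1:] = np.diff(ln) / (curves.vmax * dt)
    phi = np.arcsin(sinp / ln) if sinp > 0 else np.zeros_like(ln)
    lt = L - ln * params.lmo * np.cos(phi)
    eps = lt / params.lts - 1.0
    F = params.strength_coeff * params.FmMAX * curves.tendon(eps)
    return MTUStateSeries(a, ln, vn, phi, eps, np.clip(F, 0.0, None))
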