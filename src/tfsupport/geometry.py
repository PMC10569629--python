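"""Musculoskeletal geometry surrogates.

MTU lengths and moment arms are represented by per-DOF polynomials in the
joint angles: the moment arm about a DOF is a polynomial in that DOF's angle,
and the MTU length is the neutral-pose reference length minus the path
integral of the moment arms (so ``r_dof = -dL/dq_dof`` holds analytically).
Frontal-plane knee loading of each MTU is summarised by a medio-lateral
line-of-action offset ``z_F(q_KFE)`` (lateral positive) and an axial-force
fraction ``c_ax(q_KFE)``; muscle loads and external loads are decomposed into
frontal-plane moments about the medial and lateral tibiofemoral contact
points (varus positive, right-limb convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.optimize import least_squares

from . import model_core
from .errors import InputError
from .model_core import HillCurves, DEFAULT_CURVES

logger = logging.getLogger(__name__)

DOFS = ("HAA", "HFE", "KFE", "AFE")

#: physiological joint-angle ranges, rad (adduction, flexion, knee flexion and
#: dorsiflexion positive respectively)
JOINT_RANGES = {
    "HAA": (-0.7, 0.7),
    "HFE": (-0.6, 2.1),
    "KFE": (0.0, 2.4),
    "AFE": (-0.9, 0.7),
}


@dataclass(frozen=True)
class JointPose:
    """Angles of the four model DOF, rad (knee flexion and hip adduction positive)."""

    q_HAA: float = 0.0
    q_HFE: float = 0.0
    q_KFE: float = 0.0
    q_AFE: float = 0.0

    def angle(self, dof: str) -> float:
        return getattr(self, f"q_{dof}")

    def as_dict(self) -> dict:
        return {d: self.angle(d) for d in DOFS}


@dataclass
class MuscleGeometry:
    """Surrogate path of one MTU.

    ``moment_arms`` maps a DOF name to ascending polynomial coefficients of
    the moment arm (m) in that DOF's angle; a DOF absent from the mapping is
    not crossed.  ``z_offset`` / ``axial_fraction`` are ascending polynomial
    coefficients in the knee flexion angle for the medio-lateral position of
    the force line relative to the knee centre (m, lateral positive) and the
    fraction of MTU force acting as tibial-axis compression.
    ``segment_fractions`` gives the share of the path owned by each body
    segment, used for composite linear scaling.
    """

    ref_length: float
    moment_arms: dict = field(default_factory=dict)
    z_offset: tuple = (0.0,)
    axial_fraction: tuple = (0.0,)
    segment_fractions: dict = field(default_factory=lambda: {"thigh": 1.0})

    def arm(self, dof: str, q):
        if dof not in self.moment_arms:
            return np.zeros_like(np.asarray(q, dtype=float))
        return P.polyval(np.asarray(q, dtype=float), self.moment_arms[dof])

    def length(self, q_by_dof: dict):
        """MTU length at the given angles: ref_length - sum of arm integrals."""
        L = self.ref_length
        for dof, coeffs in self.moment_arms.items():
            anti = P.polyint(coeffs)
            L = L - P.polyval(np.asarray(q_by_dof[dof], dtype=float), anti)
        return L

    def z_f(self, q_kfe):
        return P.polyval(np.asarray(q_kfe, dtype=float), self.z_offset)

    def c_ax(self, q_kfe):
        return np.clip(P.polyval(np.asarray(q_kfe, dtype=float), self.axial_fraction), 0.0, 1.0)

    def composite_scale(self, segment_scales: dict) -> float:
        return sum(
            frac * segment_scales.get(seg, 1.0)
            for seg, frac in self.segment_fractions.items()
        )

    def crosses_knee(self) -> bool:
        return np.any(np.asarray(self.axial_fraction) != 0.0) or "KFE" in self.moment_arms


@dataclass(frozen=True)
class CompartmentGeometry:
    """Medial/lateral contact-point distances from the knee centre, m (> 0)."""

    d_med: float = 0.0225
    d_lat: float = 0.0225

    def __post_init__(self):
        if self.d_med <= 0 or self.d_lat <= 0:
            raise InputError("compartment contact distances must be > 0")


def _clamped(q_by_dof: dict, ranges: dict = JOINT_RANGES) -> dict:
    out = {}
    for dof, q in q_by_dof.items():
        lo, hi = ranges[dof]
        q = np.asarray(q, dtype=float)
        if np.any(q < lo - 1e-12) or np.any(q > hi + 1e-12):
            logger.warning("pose out of declared %s range [%g, %g]; clamping", dof, lo, hi)
        out[dof] = np.clip(q, lo, hi)
    return out


def mtu_kinematics(pose, geom: MuscleGeometry, clamp: bool = True):
    """MTU length and per-DOF moment arms at a pose (or arrays of angles).

    ``pose`` is a :class:`JointPose` or a dict ``{dof: angle or array}``.
    Out-of-range angles are clamped with a logged warning.
    Returns ``(L_mtu, {dof: moment arm})``.
    """
    q = pose.as_dict() if isinstance(pose, JointPose) else {d: pose[d] for d in DOFS}
    if clamp:
        q = _clamped(q)
    L = geom.length(q)
    r = {dof: geom.arm(dof, q[dof]) for dof in geom.moment_arms}
    return L, r


def knee_load_components(F_MTU, q_kfe, geom: MuscleGeometry):
    """Frontal-plane knee moment (varus positive) and axial compression of one MTU.

    ``F_ax = c_ax(q_KFE) * F_MTU``; ``M_k = -F_ax * z_F(q_KFE)`` so that a
    compressive force medial of the knee centre (z_F < 0) produces a varus
    (positive) moment about the knee centre.
    """
    F = np.asarray(F_MTU, dtype=float)
    F_ax = geom.c_ax(q_kfe) * F
    M_k = -F_ax * geom.z_f(q_kfe)
    return M_k, F_ax


def compartment_moments(M_k, F_ax, cg: CompartmentGeometry):
    """Decompose a knee-centre frontal moment + axial force about both condyles.

    ``M_med = M_k - F_ax * d_med``; ``M_lat = M_k + F_ax * d_lat`` (varus
    positive; compression loads both condyles: valgus about the medial
    contact point, varus about the lateral one).  The identity
    ``M_lat - M_med = F_ax * (d_med + d_lat)`` holds exactly.  Applies
    identically to muscle loads and to external loads.
    """
    M_k = np.asarray(M_k, dtype=float)
    F_ax = np.asarray(F_ax, dtype=float)
    return M_k - F_ax * cg.d_med, M_k + F_ax * cg.d_lat


# ---------------------------------------------------------------------------
# Anatomical scaling
# ---------------------------------------------------------------------------

def linear_scale_model(generic, segment_scales: dict):
    """Linearly scale a model by per-segment factors.

    Reference lengths, moment-arm coefficients, lmo and lts scale with each
    MTU's composite (span-fraction-weighted) factor; frontal offsets and the
    compartment contact distances scale with the shank factor.
    Returns a new model; the input is untouched.
    """
    from .model import MusculoskeletalModel  # local import to avoid a cycle

    if any(v <= 0 for v in segment_scales.values()):
        raise InputError(f"segment scale factors must be > 0: {segment_scales}")
    shank = segment_scales.get("shank", 1.0)
    mtus, geoms = {}, {}
    for name, p in generic.mtus.items():
        g = generic.geometry[name]
        k = g.composite_scale(segment_scales)
        geoms[name] = replace(
            g,
            ref_length=g.ref_length * k,
            moment_arms={d: tuple(np.asarray(c) * k) for d, c in g.moment_arms.items()},
            z_offset=tuple(np.asarray(g.z_offset) * shank),
        )
        mtus[name] = p.replace(lmo=p.lmo * k, lts=p.lts * k)
    cg = CompartmentGeometry(generic.compartment.d_med * shank, generic.compartment.d_lat * shank)
    return MusculoskeletalModel(
        mtus=mtus,
        geometry=geoms,
        compartment=cg,
        emg_map=dict(generic.emg_map),
        joint_ranges=dict(generic.joint_ranges),
    )


def default_pose_grid(n: int = 24, ranges: dict = JOINT_RANGES, margin: float = 0.15):
    """Evenly spread poses across the physiological ranges (inner ``margin`` trimmed)."""
    n = max(n, 2)
    poses = []
    for i in range(n):
        f = i / (n - 1)
        q = {}
        for j, dof in enumerate(DOFS):
            lo, hi = ranges[dof]
            span = hi - lo
            lo, hi = lo + margin * span, hi - margin * span
            # stagger the DOFs so the grid is not a diagonal line
            fj = (f + 0.17 * (j + 1)) % 1.0
            q[dof] = lo + fj * (hi - lo)
        poses.append(JointPose(**{f"q_{d}": q[d] for d in DOFS}))
    return poses


def _static_norm_states(params, geom, poses, a_ref, curves, lmo=None, lts=None):
    """Normalised fibre length and tendon strain at a reference activation."""
    q = {d: np.array([p.angle(d) for p in poses]) for d in DOFS}
    L, _ = mtu_kinematics(q, geom, clamp=False)
    L = np.atleast_1d(np.asarray(L, dtype=float))
    lmo = params.lmo if lmo is None else lmo
    lts = params.lts if lts is None else lts
    a = np.full_like(L, a_ref)
    P = L.size
    # independent isometric poses: solve them as a single vectorised frame
    ln = model_core.solve_fiber_lengths_multi(
        L[None, :], a[None, :],
        np.full(P, lmo), np.full(P, lts), np.full(P, params.phi_o),
        dt=1.0, curves=curves, static=True,
    )[0]
    cosp = np.cos(np.arcsin(np.sin(params.phi_o) / ln))
    eps = (L - ln * lmo * cosp) / lts - 1.0
    return ln, eps


def optimize_fiber_tendon_lengths(
    scaled,
    generic,
    pose_grid,
    a_ref: float = 0.5,
    curves: HillCurves = DEFAULT_CURVES,
    rest_weight: float = 30.0,
    min_poses: int = 20,
):
    """Refine (lmo, lts) so normalised operating curves match the generic model.

    For every MTU, (lmo, lts) minimise the summed squared differences between
    the scaled and generic models' normalised fibre lengths and tendon strains
    over the pose grid (static equilibrium at reference activation ``a_ref``),
    with a penalty keeping the MTU rest length ``lmo cos(phi_o) + lts`` within
    1% of its linearly scaled value.  Non-convergent MTUs fall back to their
    linearly scaled values (logged).
    """
    if len(pose_grid) < min_poses:
        raise InputError(
            f"pose grid must span the physiological ranges with at least "
            f"{min_poses} poses; got {len(pose_grid)}"
        )
    out = scaled.copy()
    for name, p_s in scaled.mtus.items():
        p_g = generic.mtus[name]
        g_g = generic.geometry[name]
        g_s = scaled.geometry[name]
        ln_ref, eps_ref = _static_norm_states(p_g, g_g, pose_grid, a_ref, curves)
        rest_target = p_s.lmo * np.cos(p_s.phi_o) + p_s.lts

        def resid(x, _ps=p_s, _gs=g_s, _lr=ln_ref, _er=eps_ref, _rt=rest_target):
            lmo, lts = x
            try:
                ln, eps = _static_norm_states(_ps, _gs, pose_grid, a_ref, curves, lmo, lts)
            except Exception:
                return np.full(2 * len(pose_grid) + 1, 1e3)
            rest = (lmo * np.cos(_ps.phi_o) + lts - _rt) / _rt
            return np.concatenate([ln - _lr, eps - _er, [rest_weight * rest]])

        x0 = np.array([p_s.lmo, p_s.lts])
        try:
            sol = least_squares(
                resid, x0, bounds=([0.5 * p_s.lmo, 0.5 * p_s.lts], [1.5 * p_s.lmo, 1.5 * p_s.lts]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=60,
            )
            lmo_new, lts_new = sol.x
            rest_new = lmo_new * np.cos(p_s.phi_o) + lts_new
            if not np.isfinite(sol.cost) or abs(rest_new - rest_target) / rest_target > 0.01:
                raise RuntimeError("rest-length drift")
        except Exception as exc:  # fall back to the linearly scaled values
            logger.warning("lmo/lts optimisation fell back to linear scaling for %s (%s)", name, exc)
            lmo_new, lts_new = p_s.lmo, p_s.lts
        out.mtus[name] = p_s.replace(lmo=float(lmo_new), lts=float(lts_new))
    return out
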