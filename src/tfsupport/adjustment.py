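"""Donor-muscle morphology adjustment and fixed-donor recalibration.

After hamstring-graft harvest the semitendinosus (ST) and gracilis (GR) lose
volume and peak cross-sectional area.  Measured surgical/contralateral ratios
are mapped onto Hill-model parameters:

* strength coefficient scales with the CSA ratio (force ~ cross-section),
* optimal fibre length scales with the volume/CSA ratio (volume = area x length),
* tendon slack length changes so the MTU rest length
  ``lmo cos(phi_o) + lts`` is preserved exactly (the muscle-tendon pathway is
  untouched and the normalised tendon curve — hence its normalised linear
  stiffness — is unchanged).

A donor whose tendon did not regenerate transmits no force: its strength
coefficient is set to zero.  The adjusted donors are then *fixed* and the
remaining 32 MTUs are recalibrated against the same experimental moments.
Each parameter mapping is a pluggable strategy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .calibration import (
    AdjustableSpec,
    CalibrationBudget,
    CalibrationResult,
    calibrate,
    fixed_block_hash,
)
from .errors import InputError
from .model import DONOR_MTUS
from .model_core import MTUParameters

logger = logging.getLogger(__name__)

REGENERATED = "regenerated"
NO_REGENERATION = "none"

#: morphology-muscle label -> MTU name in the model
DONOR_NAME_MAP = {"ST": "st", "GR": "gr"}


@dataclass(frozen=True)
class MorphologyMeasurement:
    """MRI volume/peak-CSA of one donor muscle, surgical vs contralateral side."""

    muscle: str                 # "ST" | "GR"
    V_surgical: float           # cm^3
    V_contralateral: float      # cm^3
    CSA_surgical: float         # cm^2
    CSA_contralateral: float    # cm^2
    regeneration: str = REGENERATED

    def __post_init__(self):
        if self.muscle not in DONOR_NAME_MAP:
            raise InputError(f"unknown donor muscle {self.muscle!r} (expected ST or GR)")
        for f in ("V_surgical", "V_contralateral", "CSA_surgical", "CSA_contralateral"):
            if not getattr(self, f) > 0:
                raise InputError(f"{self.muscle}: {f} must be > 0, got {getattr(self, f)}")
        if self.regeneration not in (REGENERATED, NO_REGENERATION):
            raise InputError(f"regeneration must be '{REGENERATED}' or '{NO_REGENERATION}'")


@dataclass(frozen=True)
class MorphologyRatios:
    """Surgical/contralateral ratios: CSA, volume, and implied length (V/CSA)."""

    r_CSA: float
    r_V: float
    r_L: float


def morphology_ratios(m: MorphologyMeasurement) -> MorphologyRatios:
    """Surgical-to-contralateral ratios; r_L = r_V / r_CSA."""
    r_csa = m.CSA_surgical / m.CSA_contralateral
    r_v = m.V_surgical / m.V_contralateral
    r_l = r_v / r_csa
    for label, r in (("CSA", r_csa), ("volume", r_v), ("length", r_l)):
        if r > 1.5 or r < 0.2:
            logger.warning("%s %s ratio %.3g outside the plausible (0.2, 1.5) band",
                           m.muscle, label, r)
    return MorphologyRatios(r_CSA=r_csa, r_V=r_v, r_L=r_l)


def adjust_mtu_parameters(p: MTUParameters, r: MorphologyRatios) -> MTUParameters:
    """Map morphology ratios onto one donor MTU's Hill parameters.

    strength' = strength * r_CSA; lmo' = lmo * r_L;
    lts' = lts + (lmo - lmo') cos(phi_o)  (MTU rest length preserved exactly).
    """
    lmo_new = p.lmo * r.r_L
    lts_new = p.lts + (p.lmo - lmo_new) * math.cos(p.phi_o)
    if lts_new <= 0:
        raise InputError(
            f"{p.name}: adjusted tendon slack length {lts_new:.4g} m is non-positive"
        )
    return p.replace(
        strength_coeff=p.strength_coeff * r.r_CSA, lmo=lmo_new, lts=lts_new
    )


def apply_regeneration(p: MTUParameters, status: str) -> MTUParameters:
    """A non-regenerated donor tendon transmits no force: strength set to zero."""
    if status == NO_REGENERATION:
        return p.replace(strength_coeff=0.0)
    if status == REGENERATED:
        return p
    raise InputError(f"unknown regeneration status {status!r}")


def build_adjusted_model(
    standard: CalibrationResult,
    morphology: dict,
    calibration_trials,
    seed: int = 0,
    budget: CalibrationBudget | None = None,
    spec: AdjustableSpec | None = None,
    curves=None,
) -> CalibrationResult:
    """Adjust the donors, fix them, and recalibrate the 32 non-donor MTUs.

    ``morphology`` maps "ST"/"GR" to :class:`MorphologyMeasurement`.  A
    regenerated donor gets morphology-adjusted parameters; a non-regenerated
    donor is additionally zeroed.  Donor pathways (geometry) are unchanged.
    """
    from .model_core import DEFAULT_CURVES

    curves = curves or DEFAULT_CURVES
    missing = [k for k in DONOR_NAME_MAP if k not in morphology]
    if missing:
        raise InputError(f"missing morphology for donors: {missing}")
    model = standard.model.copy()
    for label, mtu_name in DONOR_NAME_MAP.items():
        m = morphology[label]
        p = model.mtus[mtu_name]
        p = adjust_mtu_parameters(p, morphology_ratios(m))
        p = apply_regeneration(p, m.regeneration)
        model.mtus[mtu_name] = p
    fixed = frozenset(DONOR_MTUS)
    base = spec or AdjustableSpec()
    spec_fixed = replace(base, fixed=frozenset(set(base.fixed) | fixed))
    pre_hash = fixed_block_hash(model, fixed)
    result = calibrate(
        model, calibration_trials, spec_fixed, seed=seed, budget=budget, curves=curves
    )
    post_hash = fixed_block_hash(result.model, fixed)
    assert pre_hash == post_hash, "donor parameter block changed during recalibration"
    result.diagnostics["donor_hash"] = post_hash
    result.diagnostics["regeneration"] = {
        k: morphology[k].regeneration for k in DONOR_NAME_MAP
    }
    return result
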