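"""Outcome computations: compartment moments, muscular support, statistics.

A muscle's frontal-plane moments about the medial and lateral tibiofemoral
contact points (varus positive) are summarised as *contributions to muscular
support*: at each stance point, the supporting direction of a compartment is
the sign of the net muscle moment about it (valgus about the medial condyle,
varus about the lateral condyle in cutting data), and each muscle receives
the percentage of the total supporting-direction moment it produces; muscles
acting against the supporting direction receive negative percentages, so the
supporting muscles sum to exactly 100% at every time point.

The standard-vs-adjusted comparisons use a two-level repeated-measures design
(equivalent to a paired t-test), point-by-point paired t-tests across the
stance grid, and an a-priori none-vs-both tendon-regeneration contrast
(independent two-sample t with pooled variance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import InputError
from .geometry import CompartmentGeometry, compartment_moments

logger = logging.getLogger(__name__)

COMPARTMENTS = ("medial", "lateral")


@dataclass
class ContributionResult:
    """Per-muscle compartment moments and contribution-to-support summaries."""

    moments: dict                  # compartment -> DataFrame (grid x muscles), N*m
    contributions: dict            # compartment -> DataFrame (grid x muscles), %
    stance_average: dict           # compartment -> Series (muscle -> %)
    peak: dict                     # compartment -> Series (muscle -> signed N*m)
    support_sign: dict             # compartment -> +1 (varus) or -1 (valgus)
    masked: dict = field(default_factory=dict)   # compartment -> bool array (grid,)


def support_contributions(per_muscle_moments: dict, support_sign: dict | None = None) -> ContributionResult:
    """Contribution of each muscle to muscular support about each compartment.

    ``per_muscle_moments`` maps compartment -> DataFrame of varus-positive
    moment curves (rows = stance grid, columns = muscles).  The supporting
    direction defaults to the sign of the stance-averaged net muscle moment.
    Points where no muscle acts in the supporting direction are masked (NaN)
    and logged.
    """
    moments, contrib, avg, peak, signs, masked = {}, {}, {}, {}, {}, {}
    for comp, df in per_muscle_moments.items():
        if df.shape[1] < 1:
            raise InputError("need at least one muscle")
        M = df.to_numpy(dtype=float)
        if support_sign and comp in support_sign:
            s = float(np.sign(support_sign[comp])) or 1.0
        else:
            net = M.sum(axis=1).mean()
            s = 1.0 if net >= 0 else -1.0
        supp = np.clip(M * s, 0.0, None)
        denom = supp.sum(axis=1)
        bad = denom <= 0
        if bad.any():
            logger.info("%s compartment: %d stance points have no supporting moment (masked)",
                        comp, int(bad.sum()))
        denom_safe = np.where(bad, np.nan, denom)
        c = 100.0 * (M * s) / denom_safe[:, None]
        cdf = pd.DataFrame(c, index=df.index, columns=df.columns)
        moments[comp] = df
        contrib[comp] = cdf
        avg[comp] = cdf.mean(axis=0, skipna=True)
        idx = np.nanargmax(np.abs(M), axis=0)
        peak[comp] = pd.Series(
            M[idx, np.arange(M.shape[1])], index=df.columns, name="peak_Nm"
        )
        signs[comp] = s
        masked[comp] = bad
    return ContributionResult(
        moments=moments, contributions=contrib, stance_average=avg,
        peak=peak, support_sign=signs, masked=masked,
    )


def net_and_external_compartment_curves(
    per_muscle_moments: dict,
    ext_frontal_moment: np.ndarray,
    ext_axial_force: np.ndarray,
    cg: CompartmentGeometry,
    include_external_axial: bool = True,
) -> pd.DataFrame:
    """Net muscle and external moment curves about both compartments.

    The net muscle curve is the sum of the per-muscle curves; the external
    curve decomposes the external knee frontal moment plus (optionally) the
    axial intersegmental force about the two contact points.
    """
    F_ax = np.asarray(ext_axial_force, dtype=float)
    if not include_external_axial:
        F_ax = np.zeros_like(F_ax)
    e_med, e_lat = compartment_moments(np.asarray(ext_frontal_moment, dtype=float), F_ax, cg)
    return pd.DataFrame(
        {
            "net_muscle_medial": per_muscle_moments["medial"].sum(axis=1).to_numpy(),
            "net_muscle_lateral": per_muscle_moments["lateral"].sum(axis=1).to_numpy(),
            "external_medial": e_med,
            "external_lateral": e_lat,
        }
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def paired_model_test(standard: np.ndarray, adjusted: np.ndarray) -> dict:
    """Two-level within-subject model comparison as a paired t-test.

    For two conditions the repeated-measures F satisfies F = t^2, so the
    paired t is reported directly (two-sided p).  Zero variance of the
    differences flags a degenerate result with undefined p.
    """
    x = np.asarray(standard, dtype=float)
    y = np.asarray(adjusted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired samples must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise InputError("need at least 3 paired observations")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return {"t": np.nan, "df": n - 1, "p": np.nan, "degenerate": True, "n": n}
    t, p = _st.ttest_rel(x, y)
    return {"t": float(t), "df": n - 1, "p": float(p), "degenerate": False, "n": n}


def pointwise_paired_ttest(standard: np.ndarray, adjusted: np.ndarray,
                           bonferroni: bool = False) -> dict:
    """Paired t-test at every point of the stance grid.

    ``standard`` and ``adjusted`` are (subjects x points) arrays of the same
    subjects.  Uncorrected two-sided p-values are returned (point-by-point
    curves, as conventionally plotted); ``bonferroni=True`` multiplies them by
    the number of points.  Degenerate points (zero difference variance) are
    masked NaN.
    """
    X = np.atleast_2d(np.asarray(standard, dtype=float))
    Y = np.atleast_2d(np.asarray(adjusted, dtype=float))
    if X.shape != Y.shape:
        raise InputError("curve sets must have identical shape")
    n = X.shape[0]
    if n < 3:
        raise InputError("need at least 3 subjects")
    D = X - Y
    sd = D.std(axis=0, ddof=1)
    degenerate = np.isclose(sd, 0.0)
    mean = D.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * _st.t.sf(np.abs(t), df=n - 1)
    if bonferroni:
        p = np.minimum(p * D.shape[1], 1.0)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    return {"t": t, "p": p, "df": n - 1, "degenerate": degenerate}


def regeneration_group_contrast(values: np.ndarray, groups) -> dict:
    """A-priori contrast: no-regeneration vs both-tendons-regenerated.

    Independent two-sample t-test with pooled variance on the subjects of the
    two contrasted groups; subjects with exactly one regenerated tendon are
    excluded from the contrast (but reported in the descriptives).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise InputError("values and groups must align")
    a = v[g == "none"]
    b = v[g == "both"]
    if len(a) < 2 or len(b) < 2:
        raise InputError(
            f"need >= 2 subjects per contrasted group (none: {len(a)}, both: {len(b)})"
        )
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        # degenerate: no within-group variability
        t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    else:
        t, p = _st.ttest_ind(a, b, equal_var=True)
    desc = {
        lvl: {"mean": float(v[g == lvl].mean()), "sd": float(v[g == lvl].std(ddof=1)),
              "n": int((g == lvl).sum())}
        for lvl in ("none", "one", "both")
        if (g == lvl).any()
    }
    return {
        "contrast": float(a.mean() - b.mean()),
        "t": float(t),
        "p": float(p),
        "df": len(a) + len(b) - 2,
        "descriptives": desc,
    }
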