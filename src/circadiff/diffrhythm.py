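"""Two-group joint cosinor comparison (CircaCompare-style) per gene.

For a gene measured at times :math:`t` in groups :math:`G \\in \\{0, 1\\}`
(0 = young reference, 1 = old) the joint model is

.. math:: y = (k + k_1 G) + (\\alpha + \\alpha_1 G)
          \\cos(\\omega (t - \\phi_0 - \\phi_1 G)) + \\varepsilon .

With all six parameters free, this is an exact reparameterization of the
linear model with group-specific intercepts and group-specific cos/sin
coefficients, so the global least-squares solution is obtained in closed
form by OLS on a 6-column design and transformed to
:math:`(k, k_1, \\alpha, \\alpha_1, \\phi_0, \\phi_1)`.  Amplitudes
:math:`\\sqrt{\\beta^2 + \\gamma^2}` are nonnegative by construction, and
Wald standard errors for the between-group differences follow from the OLS
covariance by the delta method — identical to the asymptotic covariance of
the equivalent nonlinear fit at the same solution.  Difference p-values use
the t distribution with n - 6 df; per-group rhythmicity is the per-group
zero-amplitude F-test.  Per-gene p-values are BH-adjusted across genes
within each parameter family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionTimeCourse
from .cosinor import wrap_signed

__all__ = ["DiffRhythmFit", "fit_joint_cosinor", "diff_rhythm_table", "P_FAMILIES"]

#: p-value families that receive a separate BH adjustment across genes
P_FAMILIES = ("mesor_diff", "amp_diff", "phase_diff", "rhythm_young", "rhythm_old")


@dataclass(frozen=True)
class DiffRhythmFit:
    """Joint-model estimates for one gene (young = reference group)."""

    mesor_young: float
    mesor_old: float
    mesor_diff: float
    amp_young: float
    amp_old: float
    amp_diff: float
    phase_young: float
    phase_old: float
    phase_diff: float  # hours, signed, in (-period/2, period/2]; >0 = old peaks later
    se_mesor_diff: float
    se_amp_diff: float
    se_phase_diff: float
    p_mesor_diff: float
    p_amp_diff: float
    p_phase_diff: float
    p_rhythm_young: float
    p_rhythm_old: float
    converged: bool
    flat: bool
    n_obs: int
    period: float = 24.0


def _joint_design(t: np.ndarray, g: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    c, s = np.cos(w * t), np.sin(w * t)
    gy = 1.0 - g
    return np.column_stack([gy, g, gy * c, gy * s, g * c, g * s])


def _batch_joint_fit(t: np.ndarray, g: np.ndarray, Y: np.ndarray, period: float) -> dict:
    """Vectorized joint fit for Y of shape (n_genes, n_obs).

    All genes share the same design, so a single pseudoinverse solves every
    gene at once.  Returns a dict of per-gene arrays.
    """
    n = len(t)
    if n < 8:
        raise ValueError(f"joint fit needs >= 8 observations, got {n}")
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be present")
    for grp, mask in (("young", g == 0), ("old", g == 1)):
        if np.count_nonzero(mask) < 4 or len(np.unique(np.round(np.mod(t[mask], period), 9))) < 3:
            raise ValueError(f"group '{grp}' has a degenerate cosinor design")

    w = 2.0 * np.pi / period
    X = _joint_design(t, g, period)
    XtX = X.T @ X
    C = np.linalg.inv(XtX)  # unscaled covariance of the linear coefficients
    B = Y @ X @ C  # (n_genes, 6): [mY, mO, bY, gY, bO, gO]
    resid = Y - B @ X.T
    sse = np.einsum("ij,ij->i", resid, resid)
    df = n - 6
    sigma2 = sse / df

    mY, mO, bY, gY, bO, gO = (B[:, j].copy() for j in range(6))
    flat = np.ptp(Y, axis=1) == 0.0
    if flat.any():
        # constant series: exact flat fit, free of lstsq rounding noise
        for arr in (bY, gY, bO, gO):
            arr[flat] = 0.0
        mY[flat] = Y[flat, 0]
        mO[flat] = Y[flat, 0]
    aY = np.hypot(bY, gY)
    aO = np.hypot(bO, gO)
    with np.errstate(invalid="ignore", divide="ignore"):
        phY = np.mod(np.arctan2(gY, bY) / w, period)
        phO = np.mod(np.arctan2(gO, bO) / w, period)
    phY = np.where(aY > 0, phY, 0.0)
    phO = np.where(aO > 0, phO, 0.0)
    k1 = mO - mY
    a1 = aO - aY
    ph1 = np.asarray(wrap_signed(phO - phY, period), dtype=float)

    # delta-method gradients w.r.t. [mY, mO, bY, gY, bO, gO]
    z = np.zeros_like(aY)
    with np.errstate(invalid="ignore", divide="ignore"):
        H_amp = np.stack([z, z, -bY / aY, -gY / aY, bO / aO, gO / aO], axis=1)
        H_ph = np.stack(
            [z, z, gY / (w * aY**2), -bY / (w * aY**2), -gO / (w * aO**2), bO / (w * aO**2)],
            axis=1,
        )
    var_k1 = (C[0, 0] + C[1, 1] - 2.0 * C[0, 1]) * sigma2
    var_a1 = np.einsum("ij,jk,ik->i", H_amp, C, H_amp) * sigma2
    var_p1 = np.einsum("ij,jk,ik->i", H_ph, C, H_ph) * sigma2

    def _wald(est, var):
        se = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            tt = est / se
        p = 2.0 * stats.t.sf(np.abs(tt), df)
        # exact fits (se = 0): p = 1 for a zero difference, 0 otherwise
        p = np.where(se > 0, p, np.where(np.abs(est) < 1e-12, 1.0, 0.0))
        return se, np.clip(p, 0.0, 1.0)

    se_k1, p_k1 = _wald(k1, var_k1)
    se_a1, p_a1 = _wald(a1, var_a1)
    se_p1, p_p1 = _wald(ph1, var_p1)
    # a group with zero fitted amplitude has no identified phase
    degenerate_amp = (aY == 0) | (aO == 0)
    p_a1 = np.where(degenerate_amp & flat, 1.0, p_a1)
    p_p1 = np.where(degenerate_amp, 1.0, p_p1)
    se_p1 = np.where(degenerate_amp, np.nan, se_p1)
    p_k1 = np.where(flat, 1.0, p_k1)

    # per-group zero-amplitude F-tests (joint fit restricted to a group's
    # rows is exactly the per-group cosinor OLS fit)
    p_rhythm = {}
    for key, mask in (("young", g == 0), ("old", g == 1)):
        ng = int(np.count_nonzero(mask))
        sse1 = np.einsum("ij,ij->i", resid[:, mask], resid[:, mask])
        yg = Y[:, mask]
        sse0 = np.einsum("ij,ij->i", yg - yg.mean(axis=1, keepdims=True), yg - yg.mean(axis=1, keepdims=True))
        dfg = ng - 3
        with np.errstate(invalid="ignore", divide="ignore"):
            F = ((sse0 - sse1) / 2.0) / (sse1 / dfg)
        p = np.where(sse1 > 1e-30 * np.maximum(sse0, 1.0), stats.f.sf(F, 2, dfg), 0.0)
        p = np.where(sse0 <= 0, 1.0, p)  # constant within the group
        p_rhythm[key] = np.clip(p, 0.0, 1.0)

    return {
        "mesor_young": mY, "mesor_old": mO, "mesor_diff": k1,
        "amp_young": aY, "amp_old": aO, "amp_diff": a1,
        "phase_young": phY, "phase_old": phO, "phase_diff": ph1,
        "se_mesor_diff": np.sqrt(np.maximum(var_k1, 0.0)), "se_amp_diff": se_a1, "se_phase_diff": se_p1,
        "p_mesor_diff": p_k1, "p_amp_diff": p_a1, "p_phase_diff": p_p1,
        "p_rhythm_young": p_rhythm["young"], "p_rhythm_old": p_rhythm["old"],
        "flat": flat, "n_obs": np.full(Y.shape[0], n), "sse": sse,
    }


def fit_joint_cosinor(times, values, group, period: float = 24.0) -> DiffRhythmFit:
    """Fit the joint two-group cosinor model for a single series.

    ``group`` is 0/1 (young/old) per observation.  Estimation is by exact
    least squares (see module docstring); the closed-form solve always
    converges, so ``converged`` is True except for zero-variance input,
    which is returned as a flat fit with difference p-values of 1.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(group, dtype=float)
    y = np.asarray(values, dtype=float)[None, :]
    r = _batch_joint_fit(t, g, y, period)
    flat = bool(r["flat"][0])
    return DiffRhythmFit(
        **{k: float(r[k][0]) for k in (
            "mesor_young", "mesor_old", "mesor_diff",
            "amp_young", "amp_old", "amp_diff",
            "phase_young", "phase_old", "phase_diff",
            "se_mesor_diff", "se_amp_diff", "se_phase_diff",
            "p_mesor_diff", "p_amp_diff", "p_phase_diff",
            "p_rhythm_young", "p_rhythm_old",
        )},
        converged=True,
        flat=flat,
        n_obs=int(r["n_obs"][0]),
        period=period,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (statsmodels fdr_bh)."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def diff_rhythm_table(etc: ExpressionTimeCourse, period: float = 24.0) -> pd.DataFrame:
    """Joint two-group cosinor fits for every gene in the matrix.

    Returns one row per gene with per-group estimates, old-minus-young
    differences, Wald p-values and BH q-values per family.  Zero-variance
    genes are fitted as flat (A = 0, difference p = 1) and flagged via the
    ``flat`` column, not dropped.
    """
    t = etc.samples["time_h"].to_numpy(dtype=float)
    g = etc.group_indicator().to_numpy(dtype=float)
    Y = etc.values.to_numpy(dtype=float)
    r = _batch_joint_fit(t, g, Y, period)
    out = pd.DataFrame(
        {k: v for k, v in r.items() if k != "sse"}, index=etc.values.index.copy()
    )
    out["converged"] = True
    for fam in P_FAMILIES:
        out[f"q_{fam}"] = benjamini_hochberg(out[f"p_{fam}"].to_numpy())
    order = [
        "mesor_young", "mesor_old", "mesor_diff", "se_mesor_diff", "p_mesor_diff", "q_mesor_diff",
        "amp_young", "amp_old", "amp_diff", "se_amp_diff", "p_amp_diff", "q_amp_diff",
        "phase_young", "phase_old", "phase_diff", "se_phase_diff", "p_phase_diff", "q_phase_diff",
        "p_rhythm_young", "q_rhythm_young", "p_rhythm_old", "q_rhythm_old",
        "n_obs", "converged", "flat",
    ]
    return out[order]
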