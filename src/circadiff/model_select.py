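"""Four-model rhythmicity classification per gene via BIC weights.

Each gene is fit with four ordinary-least-squares models that always carry
group-specific intercepts (so MESOR differences cannot masquerade as
rhythmicity differences) and differ only in which groups receive cos/sin
rhythm terms:

* BOTH        — rhythm terms in young and old (own beta/gamma per group)
* YOUNG_ONLY  — rhythm terms in young only
* OLD_ONLY    — rhythm terms in old only
* NEITHER     — no rhythm terms

Under a Gaussian likelihood, BIC_m = n*ln(SSE_m/n) + p_m*ln(n) with p_m the
number of mean parameters plus one for the variance.  Schwarz weights
w_m = exp(-(BIC_m - BIC_min)/2) / sum_j exp(-(BIC_j - BIC_min)/2) lie in
[0, 1] and sum to 1; a gene is assigned the arg-max class when its weight
exceeds the threshold (default 0.75), otherwise UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionTimeCourse

__all__ = ["MODEL_NAMES", "ModelWeights", "fit_four_models", "classify_matrix"]

MODEL_NAMES = ("both", "neither", "young_only", "old_only")
_CLASS_OF_MODEL = {
    "both": "BOTH",
    "neither": "NEITHER",
    "young_only": "YOUNG_ONLY",
    "old_only": "OLD_ONLY",
}


@dataclass(frozen=True)
class ModelWeights:
    """BIC values and Schwarz weights for one gene."""

    bic_both: float
    bic_neither: float
    bic_young_only: float
    bic_old_only: float
    w_both: float
    w_neither: float
    w_young_only: float
    w_old_only: float
    assigned_class: str
    threshold: float


def _model_designs(t: np.ndarray, g: np.ndarray, period: float) -> dict:
    w = 2.0 * np.pi / period
    c, s = np.cos(w * t), np.sin(w * t)
    gy = 1.0 - g
    intercepts = [gy, g]
    return {
        "neither": np.column_stack(intercepts),
        "young_only": np.column_stack(intercepts + [gy * c, gy * s]),
        "old_only": np.column_stack(intercepts + [g * c, g * s]),
        "both": np.column_stack(intercepts + [gy * c, gy * s, g * c, g * s]),
    }


def _batch_bic(t: np.ndarray, g: np.ndarray, Y: np.ndarray, period: float) -> dict:
    """BIC per gene per model; Y has shape (n_genes, n_obs)."""
    n = len(t)
    if n < 8:
        raise ValueError(f"model selection needs >= 8 observations, got {n}")
    if len(np.unique(g)) < 2:
        raise ValueError("both groups must be present")
    designs = _model_designs(t, g, period)
    total_ss = np.einsum("ij,ij->i", Y - Y.mean(axis=1, keepdims=True), Y - Y.mean(axis=1, keepdims=True))
    floor = 1e-14 * np.maximum(total_ss, 1.0)
    bic = {}
    for name, X in designs.items():
        coef = Y @ X @ np.linalg.inv(X.T @ X)
        resid = Y - coef @ X.T
        sse = np.einsum("ij,ij->i", resid, resid)
        p_m = X.shape[1] + 1  # mean parameters + variance
        bic[name] = n * np.log(np.maximum(sse, floor) / n) + p_m * np.log(n)
    return bic


def _weights_from_bic(bic: dict) -> np.ndarray:
    """Schwarz weights, rows ordered as MODEL_NAMES; shape (n_genes, 4)."""
    stack = np.stack([bic[m] for m in MODEL_NAMES], axis=1)
    delta = stack - stack.min(axis=1, keepdims=True)
    raw = np.exp(-delta / 2.0)
    return raw / raw.sum(axis=1, keepdims=True)


def fit_four_models(times, values, group, period: float = 24.0, threshold: float = 0.75) -> ModelWeights:
    """Fit the four rhythmicity models for a single series and weight them."""
    t = np.asarray(times, dtype=float)
    g = np.asarray(group, dtype=float)
    y = np.asarray(values, dtype=float)[None, :]
    df = _classify_batch(t, g, y, period, threshold)
    row = df.iloc[0]
    return ModelWeights(
        bic_both=float(row["bic_both"]), bic_neither=float(row["bic_neither"]),
        bic_young_only=float(row["bic_young_only"]), bic_old_only=float(row["bic_old_only"]),
        w_both=float(row["w_both"]), w_neither=float(row["w_neither"]),
        w_young_only=float(row["w_young_only"]), w_old_only=float(row["w_old_only"]),
        assigned_class=str(row["assigned_class"]), threshold=threshold,
    )


def _classify_batch(t, g, Y, period, threshold) -> pd.DataFrame:
    bic = _batch_bic(t, g, Y, period)
    W = _weights_from_bic(bic)
    best = np.argmax(W, axis=1)
    wmax = W[np.arange(len(best)), best]
    classes = np.array([_CLASS_OF_MODEL[MODEL_NAMES[j]] for j in best], dtype=object)
    classes = np.where(wmax > threshold, classes, "UNCLASSIFIED")
    # zero-variance genes are NEITHER by definition
    flat = np.ptp(Y, axis=1) == 0.0
    if flat.any():
        classes = np.where(flat, "NEITHER", classes)
        W = W.copy()
        W[flat] = [0.0, 0.0, 0.0, 0.0]
        W[flat, MODEL_NAMES.index("neither")] = 1.0
    out = pd.DataFrame({f"bic_{m}": bic[m] for m in MODEL_NAMES})
    for j, m in enumerate(MODEL_NAMES):
        out[f"w_{m}"] = W[:, j]
    out["assigned_class"] = classes
    out["threshold"] = threshold
    return out


def classify_matrix(etc: ExpressionTimeCourse, period: float = 24.0, threshold: float = 0.75) -> pd.DataFrame:
    """Four-model BIC-weight classification for every gene in the matrix.

    Returns one row per gene: the four BICs, the four Schwarz weights, the
    assigned class (UNCLASSIFIED when no weight exceeds the threshold) and
    the threshold used.  Deterministic; rows are independent.
    """
    t = etc.samples["time_h"].to_numpy(dtype=float)
    g = etc.group_indicator().to_numpy(dtype=float)
    Y = etc.values.to_numpy(dtype=float)
    out = _classify_batch(t, g, Y, period, threshold)
    out.index = etc.values.index.copy()
    return out
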