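"""Gene categorization, subset export, and heatmap normalization.

Combines the joint-cosinor difference tests with the BIC-weight rhythm
classes to label each gene: loss/gain of rhythmicity from the weight class,
and — for genes rhythmic in both groups — direction calls for MESOR,
amplitude and phase at a q cutoff, with fold-change filters.

MESOR log2 fold change is (M_old - M_young) * log2(10): MESORs live on the
log10(1 + count) scale, so their difference is already a log fold change up
to base conversion.  Amplitude log2 fold change is log2(A_old / A_young)
since amplitudes are magnitudes.  Both conventions are configurable at the
call sites that consume them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionTimeCourse

__all__ = ["categorize", "heatmap_normalize", "export_subsets", "SUBSET_NAMES"]

LOG2_10 = np.log2(10.0)

#: the seven gene subsets exported for downstream enrichment tools
SUBSET_NAMES = (
    "decreased_mesor",
    "increased_mesor",
    "phase_advance",
    "phase_delay",
    "loss_of_rhythmicity",
    "gain_of_rhythmicity",
    "rhythmic_in_both",
)


def categorize(
    diff: pd.DataFrame,
    weights: pd.DataFrame,
    q_cut: float = 0.05,
    mesor_fc_cut: float = 0.25,
    amp_fc_cut: float = 0.1,
) -> pd.DataFrame:
    """Per-gene category record from difference tests and model weights.

    Change fields (mesor/amp/phase) are only awarded to genes whose weight
    class is BOTH; direction comes from the sign of the old-minus-young
    difference at q < ``q_cut``.  Phase: negative difference = ADVANCE (old
    peaks earlier), positive = DELAY.
    """
    if not diff.index.equals(weights.index):
        if set(diff.index) != set(weights.index):
            raise ValueError("diff table and weights table must share the same gene universe")
        weights = weights.loc[diff.index]
    rclass = weights["assigned_class"].astype(str)
    is_both = (rclass == "BOTH").to_numpy()

    def _direction(qcol: str, dcol: str, pos: str, neg: str) -> np.ndarray:
        sig = (diff[qcol].to_numpy() < q_cut) & is_both
        d = diff[dcol].to_numpy()
        out = np.full(len(diff), "NONE", dtype=object)
        out[sig & (d > 0)] = pos
        out[sig & (d < 0)] = neg
        return out

    mesor_change = _direction("q_mesor_diff", "mesor_diff", "UP", "DOWN")
    amp_change = _direction("q_amp_diff", "amp_diff", "UP", "DOWN")
    phase_change = _direction("q_phase_diff", "phase_diff", "DELAY", "ADVANCE")

    mesor_log2fc = diff["mesor_diff"].to_numpy() * LOG2_10
    amp_y = diff["amp_young"].to_numpy()
    amp_o = diff["amp_old"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        amp_log2fc = np.where((amp_y > 0) & (amp_o > 0), np.log2(amp_o / np.where(amp_y > 0, amp_y, 1.0)), np.nan)
    amp_fc_undefined = is_both & ~((amp_y > 0) & (amp_o > 0))

    return pd.DataFrame(
        {
            "rhythm_class": rclass.to_numpy(),
            "mesor_change": mesor_change,
            "amp_change": amp_change,
            "phase_change": phase_change,
            "mesor_log2fc": mesor_log2fc,
            "amp_log2fc": amp_log2fc,
            "passes_mesor_fc_filter": np.abs(mesor_log2fc) > mesor_fc_cut,
            "passes_amp_fc_filter": np.abs(np.nan_to_num(amp_log2fc, nan=0.0)) > amp_fc_cut,
            "amp_fc_undefined": amp_fc_undefined,
        },
        index=diff.index.copy(),
    )


def heatmap_normalize(etc: ExpressionTimeCourse, ddof: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-round normalization for heatmap display.

    Round 1 divides each gene's values by their mean within each
    (group, subject) block; round 2 collapses replicates by averaging per
    (group, timepoint); round 3 z-scores each gene across timepoints within
    each group.  Output has one column per (group, timepoint), named
    ``{group}_{time:g}``.  Zero block means (round 1) and zero sds
    (round 3) produce zeros and are flagged.

    Returns (normalized matrix, per-gene boolean flags).
    """
    vals = etc.values
    samples = etc.samples
    genes = vals.index
    flags = pd.DataFrame(
        {"zero_block_mean": False, "zero_sd": False}, index=genes.copy()
    )

    # round 1: per-(group, subject) mean normalization
    r1 = vals.to_numpy(dtype=float).copy()
    for _, idx in samples.groupby(["group", "subject"], sort=False).groups.items():
        cols = vals.columns.get_indexer(idx)
        block = r1[:, cols]
        mean = block.mean(axis=1)
        zero = mean == 0.0
        safe = np.where(zero, 1.0, mean)
        block = block / safe[:, None]
        block[zero, :] = 0.0
        r1[:, cols] = block
        flags.loc[zero, "zero_block_mean"] = True

    # round 2: collapse replicates per (group, timepoint) by mean
    keys = list(samples.groupby(["group", "time_h"], sort=False).groups.items())
    # stable ordering: young then old, time ascending
    keys.sort(key=lambda kv: (kv[0][0] != "young", kv[0][1]))
    col_names, cols_data, col_groups = [], [], []
    for (group, time_h), idx in keys:
        cols = vals.columns.get_indexer(idx)
        cols_data.append(r1[:, cols].mean(axis=1))
        col_names.append(f"{group}_{time_h:g}")
        col_groups.append(group)
    r2 = np.column_stack(cols_data)
    col_groups = np.array(col_groups)

    # round 3: z-score per gene across timepoints within each group
    r3 = np.empty_like(r2)
    for group in pd.unique(col_groups):
        mask = col_groups == group
        block = r2[:, mask]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=ddof, keepdims=True)
        zero = sd[:, 0] == 0.0
        safe = np.where(zero[:, None], 1.0, sd)
        z = (block - mu) / safe
        z[zero, :] = 0.0
        r3[:, mask] = z
        flags.loc[zero, "zero_sd"] = True

    return pd.DataFrame(r3, index=genes.copy(), columns=col_names), flags


def subset_membership(records: pd.DataFrame) -> dict[str, list[str]]:
    """Gene ids per exported category, in record order."""
    rc = records["rhythm_class"].astype(str)
    masks = {
        "decreased_mesor": (rc == "BOTH") & (records["mesor_change"] == "DOWN"),
        "increased_mesor": (rc == "BOTH") & (records["mesor_change"] == "UP"),
        "phase_advance": (rc == "BOTH") & (records["phase_change"] == "ADVANCE"),
        "phase_delay": (rc == "BOTH") & (records["phase_change"] == "DELAY"),
        "loss_of_rhythmicity": rc == "YOUNG_ONLY",
        "gain_of_rhythmicity": rc == "OLD_ONLY",
        "rhythmic_in_both": rc == "BOTH",
    }
    return {name: list(records.index[mask]) for name, mask in masks.items()}


def export_subsets(records: pd.DataFrame, outdir: str | Path) -> dict[str, list[str]]:
    """Write one plain-text gene-list file per category (one id per line).

    Returns the membership mapping.  Always writes all seven files, empty
    when no gene qualifies.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    members = subset_membership(records)
    for name in SUBSET_NAMES:
        genes = members[name]
        (outdir / f"{name}.txt").write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
    return members
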