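"""Synthetic expression time courses and wearable streams with known truth.

Emulates the serum-synchronization study design: two age groups (``young``,
``old``) of serum donors, four sera per group, fibroblast samples collected
every 2 h from 32 to 58 h post serum addition (14 timepoints, one replicate
per serum per timepoint, 112 samples).  Each gene carries a planted
rhythmicity class (rhythmic in both groups, in one, or in neither) and
per-group cosinor parameters; values are generated directly on the
log10(1 + normalized count) scale as

    y = M_g + b_s + A_g * cos(2*pi*(t - t_peak_g)/tau) + eps,

with per-serum baseline offsets b_s ~ N(0, subject_offset_sd^2) and
iid Gaussian noise eps ~ N(0, noise_sd^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionTimeCourse

__all__ = ["SimConfig", "simulate_expression", "simulate_wearable", "CLASSES"]

CLASSES = ("BOTH", "YOUNG_ONLY", "OLD_ONLY", "NEITHER")

_DEFAULT_TIMEPOINTS = tuple(range(32, 60, 2))
_SUBJECT_LABELS = "ABCD"


@dataclass
class SimConfig:
    """Study-design and effect-size parameters for the expression simulator.

    Proportions assign genes to rhythmicity classes deterministically by
    index (the remainder after the three rhythmic fractions is arrhythmic).
    MESORs and amplitudes are in log10(1 + count) units; peak hours are on
    [0, period).  ``mesor_shift_sd`` / ``phase_shift_sd`` scale the planted
    old-minus-young differences; setting them to 0 gives identical groups.
    """

    n_genes: int = 2000
    frac_both: float = 0.10
    frac_young_only: float = 0.10
    frac_old_only: float = 0.05
    timepoints: tuple = _DEFAULT_TIMEPOINTS
    subjects_per_group: int = 4
    period: float = 24.0
    mesor_range: tuple = (1.0, 3.0)
    amplitude_range: tuple = (0.5, 1.0)
    mesor_shift_sd: float = 0.1
    phase_shift_sd: float = 0.5
    noise_sd: float = 0.2
    subject_offset_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.timepoints) < 4:
            raise ValueError("need >= 4 timepoints (cosinor underdetermined otherwise)")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.subjects_per_group < 1:
            raise ValueError("subjects_per_group must be >= 1")
        if self.period <= 0:
            raise ValueError("period must be positive")
        fracs = (self.frac_both, self.frac_young_only, self.frac_old_only)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("class proportions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("class proportions must sum to <= 1")
        for name in ("mesor_shift_sd", "phase_shift_sd", "noise_sd", "subject_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _assign_classes(cfg: SimConfig) -> np.ndarray:
    """Deterministic class assignment by gene index: the first
    ceil(frac_both*n) genes are BOTH, the next block YOUNG_ONLY, then
    OLD_ONLY, remainder NEITHER.  Stable across seeds."""
    n = cfg.n_genes
    n_both = math.ceil(cfg.frac_both * n)
    n_young = math.ceil(cfg.frac_young_only * n)
    n_old = math.ceil(cfg.frac_old_only * n)
    n_both = min(n_both, n)
    n_young = min(n_young, n - n_both)
    n_old = min(n_old, n - n_both - n_young)
    classes = np.full(n, "NEITHER", dtype=object)
    classes[:n_both] = "BOTH"
    classes[n_both:n_both + n_young] = "YOUNG_ONLY"
    classes[n_both + n_young:n_both + n_young + n_old] = "OLD_ONLY"
    return classes


def simulate_expression(cfg: SimConfig) -> tuple[ExpressionTimeCourse, pd.DataFrame]:
    """Generate a gene x sample matrix plus the ground-truth table.

    Returns the annotated matrix (n_genes rows, |timepoints| x
    subjects_per_group x 2 columns) and a truth DataFrame with one row per
    gene: rhythm class and per-group MESOR, amplitude and peak hour.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    tau = cfg.period
    classes = _assign_classes(cfg)
    rhythmic_y = np.isin(classes, ("BOTH", "YOUNG_ONLY"))
    rhythmic_o = np.isin(classes, ("BOTH", "OLD_ONLY"))

    mesor_y = rng.uniform(*cfg.mesor_range, size=n)
    mesor_o = mesor_y + rng.normal(0.0, cfg.mesor_shift_sd, size=n) if cfg.mesor_shift_sd > 0 else mesor_y.copy()

    # one amplitude draw per gene, shared across groups where rhythmic in both
    amp = rng.uniform(*cfg.amplitude_range, size=n)
    amp_y = np.where(rhythmic_y, amp, 0.0)
    amp_o = np.where(rhythmic_o, amp, 0.0)

    peak_y = rng.uniform(0.0, tau, size=n)
    phase_shift = rng.normal(0.0, cfg.phase_shift_sd, size=n) if cfg.phase_shift_sd > 0 else np.zeros(n)
    # genes rhythmic only in old get an independent peak; BOTH genes get a shifted one
    peak_o_indep = rng.uniform(0.0, tau, size=n)
    peak_o = np.where(classes == "BOTH", np.mod(peak_y + phase_shift, tau), peak_o_indep)

    truth = pd.DataFrame(
        {
            "rhythm_class": classes,
            "mesor_young": mesor_y,
            "mesor_old": mesor_o,
            "amp_young": amp_y,
            "amp_old": amp_o,
            "peak_young": peak_y,
            "peak_old": peak_o,
        },
        index=pd.Index([f"gene_{i:05d}" for i in range(n)], name="gene_id"),
    )

    times = np.asarray(cfg.timepoints)
    n_t = len(times)
    n_s = cfg.subjects_per_group
    cols, group_col, subj_col, time_col = [], [], [], []
    for g in ("young", "old"):
        for s in range(n_s):
            label = _SUBJECT_LABELS[s] if s < len(_SUBJECT_LABELS) else f"S{s+1}"
            for t in times:
                cols.append(f"{g}_{label}_{t:g}h")
                group_col.append(g)
                subj_col.append(label)
                time_col.append(float(t))
    samples = pd.DataFrame(
        {"group": group_col, "subject": subj_col, "time_h": time_col},
        index=pd.Index(cols, name="sample_id"),
    )

    w = 2.0 * np.pi / tau
    # per (gene, serum) baseline offsets; sera are the 2 * n_s donors
    offsets = (
        rng.normal(0.0, cfg.subject_offset_sd, size=(n, 2 * n_s))
        if cfg.subject_offset_sd > 0
        else np.zeros((n, 2 * n_s))
    )
    mat = np.empty((n, 2 * n_s * n_t))
    col = 0
    for gi, (mes, am, pk) in enumerate(
        ((mesor_y, amp_y, peak_y), (mesor_o, amp_o, peak_o))
    ):
        for s in range(n_s):
            block = (
                mes[:, None]
                + offsets[:, gi * n_s + s][:, None]
                + am[:, None] * np.cos(w * (times[None, :] - pk[:, None]))
            )
            mat[:, col:col + n_t] = block
            col += n_t
    if cfg.noise_sd > 0:
        mat += rng.normal(0.0, cfg.noise_sd, size=mat.shape)

    values = pd.DataFrame(mat, index=truth.index.copy(), columns=samples.index)
    return ExpressionTimeCourse(values=values, samples=samples), truth


def simulate_wearable(
    n_subjects_per_group: int = 8,
    days: int = 7,
    bin_minutes: int = 60,
    mesor: dict | None = None,
    amplitude: dict | None = None,
    peak_hour: dict | None = None,
    noise_sd: float = 200.0,
    phase_jitter_sd: float = 1.0,
    level_jitter_sd: float = 100.0,
    period: float = 24.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate binned wearable streams (e.g. activity counts) per subject.

    One value per subject per bin at bin midpoints: the group cosine curve
    with per-subject phase and level jitter plus Gaussian noise.  Defaults
    emulate wrist-actigraphy vector-magnitude counts with the old group
    phase-advanced by ~2 h relative to young.

    Returns a DataFrame with columns subject_id, group, time_h, value.
    """
    if n_subjects_per_group < 1 or days < 1:
        raise ValueError("n_subjects_per_group and days must be positive")
    if bin_minutes <= 0 or 60 % bin_minutes != 0:
        raise ValueError("bin_minutes must be positive and divide 60")
    mesor = mesor or {"young": 2000.0, "old": 2000.0}
    amplitude = amplitude or {"young": 1500.0, "old": 1500.0}
    peak_hour = peak_hour or {"young": 16.0, "old": 14.0}

    rng = np.random.default_rng(seed)
    n_bins = int(days * 24 * 60 / bin_minutes)
    t = (np.arange(n_bins) + 0.5) * bin_minutes / 60.0
    w = 2.0 * np.pi / period
    frames = []
    for group in ("young", "old"):
        for s in range(n_subjects_per_group):
            phi = peak_hour[group] + rng.normal(0.0, phase_jitter_sd)
            level = mesor[group] + rng.normal(0.0, level_jitter_sd)
            y = level + amplitude[group] * np.cos(w * (t - phi))
            if noise_sd > 0:
                y = y + rng.normal(0.0, noise_sd, size=n_bins)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": f"{group}_{s + 1:02d}",
                        "group": group,
                        "time_h": t,
                        "value": y,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
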