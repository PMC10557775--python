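"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: brute
force grids, exhaustive enumeration and direct textbook formulas, used to
cross-check the closed-form estimators and library-backed statistics.
"""

import itertools

import numpy as np
import pytest

TAU = 24.0
STUDY_TIMES = np.arange(32.0, 60.0, 2.0)  # 14 timepoints, 2 h apart


# --------------------------------------------------------------- oracles
def grid_cosinor_oracle(t, y, period=TAU, coarse=0.01):
    """Profiled brute-force cosinor: scan peak hour on a grid, solve (M, A)
    linearly at each candidate phase, keep the SSE minimizer, then refine
    the phase grid locally down to 1e-6 h."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)

    def solve_at(phi):
        X = np.column_stack([np.ones_like(t), np.cos(2 * np.pi * (t - phi) / period)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return coef[0], coef[1], float(r @ r)

    def scan(grid):
        best = None
        for phi in grid:
            m, a, sse = solve_at(phi)
            if best is None or sse < best[3] - 1e-15:
                best = (phi, m, a, sse)
        return best

    phi, m, a, sse = scan(np.arange(0.0, period, coarse))
    step = coarse
    while step > 1e-6:
        lo, hi = phi - step, phi + step
        step /= 20.0
        phi, m, a, sse = scan(np.arange(lo, hi + step / 2, step))
    if a < 0:  # (M, -A, phi) == (M, A, phi + period/2)
        a, phi = -a, phi + period / 2.0
    return m, a, float(np.mod(phi, period)), sse


def joint_grid_oracle(t, y, g, period=TAU):
    """Brute-force joint two-group cosinor: the SSE is separable by group,
    so profile each group independently with the grid oracle and combine."""
    t, y, g = (np.asarray(a, float) for a in (t, y, g))
    mY, aY, pY, sseY = grid_cosinor_oracle(t[g == 0], y[g == 0], period)
    mO, aO, pO, sseO = grid_cosinor_oracle(t[g == 1], y[g == 1], period)
    d = np.mod(pO - pY, period)
    if d > period / 2:
        d -= period
    return {
        "mesor_young": mY, "mesor_diff": mO - mY,
        "amp_young": aY, "amp_diff": aO - aY,
        "phase_young": pY, "phase_diff": d,
        "sse": sseY + sseO,
    }


def bic_normal_equations_oracle(t, y, g, period=TAU):
    """BIC of the four rhythmicity models from an independent
    normal-equations least-squares solve."""
    t, y, g = (np.asarray(a, float) for a in (t, y, g))
    n = len(t)
    w = 2 * np.pi / period
    c, s = np.cos(w * t), np.sin(w * t)
    gy = 1.0 - g
    cols = {
        "neither": [gy, g],
        "young_only": [gy, g, gy * c, gy * s],
        "old_only": [gy, g, g * c, g * s],
        "both": [gy, g, gy * c, gy * s, g * c, g * s],
    }
    out = {}
    for name, cl in cols.items():
        X = np.column_stack(cl)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        sse = float(r @ r)
        out[name] = n * np.log(sse / n) + (X.shape[1] + 1) * np.log(n)
    return out


def ranksum_enum_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled ranks (no ties assumed): P(|W - mu| >= |w_obs - mu|)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


def kuiper_v_oracle(x, y, period=TAU):
    """Scalar Kuiper V = sup(F-G) + sup(G-F) from first principles."""
    x = np.mod(np.asarray(x, float), period)
    y = np.mod(np.asarray(y, float), period)
    zs = np.unique(np.concatenate([x, y]))
    d = np.array([np.mean(x <= z) - np.mean(y <= z) for z in zs])
    return max(d.max(), 0.0) + max((-d).max(), 0.0)


def kuiper_exact_oracle(x, y, period=TAU):
    """Exact relabeling p-value: the fraction of all C(n+m, n) splits of the
    pooled sample whose V is >= the observed V."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    pooled = np.concatenate([x, y])
    v_obs = kuiper_v_oracle(x, y, period)
    idx = set(range(len(pooled)))
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        a = pooled[list(combo)]
        b = pooled[sorted(idx - set(combo))]
        total += 1
        if kuiper_v_oracle(a, b, period) >= v_obs - 1e-12:
            count += 1
    return count / total


def bh_oracle(p):
    """Direct BH step-up adjusted p-values: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def naive_minute_bins(timestamps, values, bin_minutes=1, reducer=sum):
    """Dict-based per-bin grouping for cross-checking aggregate_bins."""
    groups = {}
    for ts, v in zip(timestamps, values):
        groups.setdefault(int(np.floor(ts * 60.0 / bin_minutes)), []).append(v)
    return {k: reducer(vs) for k, vs in sorted(groups.items())}


# -------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def study_times():
    return STUDY_TIMES.copy()


@pytest.fixture(scope="session")
def study_design():
    """(times, group) arrays for the 4+4 sera x 14 timepoints design."""
    t = np.tile(STUDY_TIMES, 8)
    g = np.repeat([0.0, 1.0], 4 * len(STUDY_TIMES))
    return t, g


def make_gene(times, group, mesor=(2.0, 2.0), amp=(0.5, 0.5), peak=(8.0, 8.0),
              noise_sd=0.0, period=TAU, seed=None):
    """Generate one gene's values under the two-group cosinor model (test-
    local generator, independent of the package simulator)."""
    rng = np.random.default_rng(seed)
    w = 2 * np.pi / period
    gi = group.astype(int)
    m = np.asarray(mesor)[gi]
    a = np.asarray(amp)[gi]
    p = np.asarray(peak)[gi]
    y = m + a * np.cos(w * (times - p))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(times))
    return y
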